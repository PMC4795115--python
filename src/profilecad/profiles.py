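"""Extraction and length-normalization of 1D fluorescence intensity profiles.

Two profile geometries are supported:

* **IN (internuclear)** — intensity sampled along the segment joining the
  nucleus centers of two contiguous cells.  On the normalized axis,
  position 0 is the first centroid, position 1 the second, and the shared
  plasma membrane is expected near 0.5 for similar-sized cells.
* **RD (radial)** — intensity sampled along rays anchored at a nucleus
  center, one per angle; position 0 is the nucleus center and 1 the ray
  end (fixed per-population ray length).

Profiles are resampled by linear interpolation to a constant length of
100 samples on the inclusive grid x_j = j/(L-1), which keeps a length-100
profile unchanged and preserves the endpoints of monotone profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .io import ChannelImage

DEFAULT_LENGTH = 100


@dataclass
class Profile1D:
    """A raw sampled intensity trace with its source geometry."""

    samples: np.ndarray
    geometry: str  # "IN" or "RD"
    anchors: dict = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 2:
            raise ValueError("a profile needs at least 2 samples")


@dataclass
class NormalizedProfile:
    """A profile resampled to L samples on the axis x_j = j/(L-1)."""

    samples: np.ndarray
    parent: Optional[Profile1D] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def axis(self) -> np.ndarray:
        L = self.samples.size
        return np.linspace(0.0, 1.0, L)


@dataclass
class ProfileMap:
    """Length-normalized profiles stacked as columns on a common axis."""

    values: np.ndarray  # (L, N)
    stage: str = "raw"  # "raw" | "denoised" | "compensated"
    warps: Optional[list] = None  # per-column knot displacements when compensated
    provenance: list = field(default_factory=list)

    @property
    def n_profiles(self) -> int:
        return self.values.shape[1]

    @property
    def length(self) -> int:
        return self.values.shape[0]


def _sample_line(pixels: np.ndarray, p0: np.ndarray, p1: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    coords = np.outer(1 - t, p0) + np.outer(t, p1)
    return ndimage.map_coordinates(pixels, coords.T, order=1, mode="constant", cval=0.0)


def _inside(shape: tuple[int, int], p: np.ndarray) -> bool:
    return bool(0 <= p[0] <= shape[0] - 1 and 0 <= p[1] <= shape[1] - 1)


def extract_in_profile(protein: ChannelImage, c1: tuple[float, float], c2: tuple[float, float],
                       step_px: float = 1.0, source_id: str = "") -> Profile1D:
    """Sample the protein channel along the segment ``c1 -> c2``.

    Bilinear interpolation at ``floor(|c1c2| / step_px) + 1`` points spaced
    uniformly from c1 to c2 inclusive.  Raises if either endpoint lies
    outside the image (the selection is invalid); the interior of the
    segment is then inside by convexity.
    """
    p0, p1 = np.asarray(c1, dtype=float), np.asarray(c2, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("the two nucleus points must differ")
    if not (_inside(protein.shape, p0) and _inside(protein.shape, p1)):
        raise ValueError(f"IN segment endpoint outside image bounds: {c1} -> {c2}")
    dist = float(np.linalg.norm(p1 - p0))
    n = int(np.floor(dist / step_px)) + 1
    if n < 2:
        raise ValueError("nucleus points closer than one sampling step")
    samples = _sample_line(protein.pixels, p0, p1, n)
    return Profile1D(samples=samples, geometry="IN",
                     anchors={"c1": tuple(p0), "c2": tuple(p1)}, source_id=source_id)


def extract_rd_profiles(protein: ChannelImage, center: tuple[float, float], n_angles: int = 72,
                        ray_length: float = 60.0, step_px: float = 1.0,
                        source_id: str = "") -> list[Profile1D]:
    """Sample rays from a nucleus center at angles ``2*pi*k / n_angles``.

    Angle k points along ``(sin, cos)`` in (row, col) coordinates, so angle
    0 is the +col direction.  Rays whose endpoint leaves the image are
    flagged with a warning and excluded; the remaining profiles are
    returned, each carrying its angle in ``anchors``.
    """
    if n_angles < 4:
        raise ValueError("n_angles must be at least 4")
    if ray_length <= 0:
        raise ValueError("ray_length must be positive")
    p0 = np.asarray(center, dtype=float)
    if not _inside(protein.shape, p0):
        raise ValueError(f"ray center {center} outside image bounds")
    n = int(np.floor(ray_length / step_px)) + 1
    profiles: list[Profile1D] = []
    excluded = []
    for k in range(n_angles):
        theta = 2.0 * np.pi * k / n_angles
        p1 = p0 + ray_length * np.array([np.sin(theta), np.cos(theta)])
        if not _inside(protein.shape, p1):
            excluded.append(k)
            continue
        samples = _sample_line(protein.pixels, p0, p1, n)
        profiles.append(Profile1D(samples=samples, geometry="RD",
                                  anchors={"center": tuple(p0), "angle": theta,
                                           "ray_length": ray_length},
                                  source_id=source_id))
    if excluded:
        warnings.warn(f"{len(excluded)} of {n_angles} rays left the image and were excluded "
                      f"(angles {excluded})", stacklevel=2)
    return profiles


def normalize_length(profile: Profile1D | np.ndarray, L: int = DEFAULT_LENGTH) -> NormalizedProfile:
    """Resample a profile onto L uniformly spaced positions spanning its extent."""
    parent = profile if isinstance(profile, Profile1D) else Profile1D(np.asarray(profile), geometry="IN")
    y = parent.samples
    x_src = np.linspace(0.0, 1.0, y.size)
    x_dst = np.linspace(0.0, 1.0, L)
    return NormalizedProfile(samples=np.interp(x_dst, x_src, y), parent=parent)


def build_map(profiles: list[NormalizedProfile]) -> ProfileMap:
    """Stack normalized profiles as the columns of an L x N map."""
    if not profiles:
        raise ValueError("need at least one profile to build a map")
    lengths = {p.samples.size for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"profiles have mixed lengths {sorted(lengths)}")
    values = np.column_stack([p.samples for p in profiles])
    provenance = []
    for p in profiles:
        src = p.parent
        provenance.append({"geometry": src.geometry if src else "?",
                           "anchors": src.anchors if src else {},
                           "source_id": src.source_id if src else ""})
    return ProfileMap(values=values, stage="raw", provenance=provenance)
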