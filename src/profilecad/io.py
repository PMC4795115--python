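"""Image, selection-file and configuration I/O.

Fluorescence channels travel through the pipeline as :class:`ChannelImage`
objects holding a float array of non-negative intensities plus minimal
metadata.  Only single-plane 8- or 16-bit grayscale TIFFs are accepted;
anything else (RGB, float TIFFs, stacks) is rejected with an explicit
message rather than silently coerced.

The selection CSV replaces the interactive point-and-click step of the
original workflow: each row records either a single nucleus point
(``point``) or a pair of nucleus points in two contiguous cells (``pair``),
in 0-based ``(row, col)`` pixel coordinates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

SELECTION_COLUMNS = ["type", "image_id", "row1", "col1", "row2", "col2"]


@dataclass
class ChannelImage:
    """One grayscale fluorescence channel.

    Parameters
    ----------
    pixels : ndarray of shape (rows, cols)
        Non-negative, finite intensities in arbitrary units.
    bit_depth : int
        Bit depth of the source file (8 or 16); synthetic float images use 16.
    pixel_size : float, optional
        Physical pixel size in micrometres per pixel, if known.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D grayscale image, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Selection:
    """One operator selection: a nucleus point or a pair of nucleus points."""

    kind: str  # "point" or "pair"
    image_id: str
    p1: tuple[float, float]
    p2: Optional[tuple[float, float]] = None


def read_channel_tiff(path: str | Path) -> ChannelImage:
    """Read an 8- or 16-bit grayscale TIFF as a :class:`ChannelImage`."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: unsupported TIFF layout with shape {arr.shape}; "
            "expected a single 2D grayscale plane (RGB and stacks are not supported)"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(
            f"{path}: unsupported TIFF dtype {arr.dtype}; only 8- and 16-bit grayscale are accepted"
        )
    return ChannelImage(pixels=arr.astype(float), bit_depth=depth)


def write_channel_tiff(path: str | Path, image: ChannelImage | np.ndarray, bit_depth: int = 16) -> None:
    """Write intensities as an 8- or 16-bit grayscale TIFF (values clipped to range)."""
    arr = image.pixels if isinstance(image, ChannelImage) else np.asarray(image, dtype=float)
    if bit_depth == 8:
        out = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    tifffile.imwrite(str(path), out)


def read_selection_csv(path: str | Path) -> list[Selection]:
    """Parse a selection CSV, validating the dialect row by row.

    Malformed rows raise ``ValueError`` naming the 1-based line number.
    """
    df = pd.read_csv(path, dtype={"type": str, "image_id": str})
    missing = [c for c in SELECTION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: selection CSV missing required columns {missing}")
    selections: list[Selection] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        kind = str(row["type"]).strip().lower()
        if kind not in ("point", "pair"):
            raise ValueError(f"{path}:{line_no}: unknown selection type {row['type']!r}")
        try:
            p1 = (float(row["row1"]), float(row["col1"]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line_no}: bad point-one coordinates") from exc
        p2 = None
        if kind == "pair":
            try:
                p2 = (float(row["row2"]), float(row["col2"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{line_no}: pair row lacks valid point-two coordinates") from exc
            if not (np.isfinite(p2[0]) and np.isfinite(p2[1])):
                raise ValueError(f"{path}:{line_no}: pair row lacks valid point-two coordinates")
        if not (np.isfinite(p1[0]) and np.isfinite(p1[1])):
            raise ValueError(f"{path}:{line_no}: non-finite point-one coordinates")
        selections.append(Selection(kind=kind, image_id=str(row["image_id"]), p1=p1, p2=p2))
    return selections


def write_selection_csv(path: str | Path, selections: list[Selection]) -> None:
    rows = []
    for s in selections:
        rows.append(
            {
                "type": s.kind,
                "image_id": s.image_id,
                "row1": s.p1[0],
                "col1": s.p1[1],
                "row2": s.p2[0] if s.p2 is not None else np.nan,
                "col2": s.p2[1] if s.p2 is not None else np.nan,
            }
        )
    pd.DataFrame(rows, columns=SELECTION_COLUMNS).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Every tunable parameter of the pipeline, JSON round-trippable.

    Defaults are the package's documented analysis conditions; all are
    overridable per run.
    """

    # segmentation
    smoothing_sigma: float = 1.0
    min_area: float = 30.0
    seed_separation: int = 5
    max_snap_distance: float = 10.0
    # profile extraction
    step_px: float = 1.0
    n_angles: int = 72
    ray_length: float = 60.0
    profile_length: int = 100
    # denoising / compensation
    denoise_strength: float = 0.5
    warp_knots: int = 5
    max_shift: float = 0.15
    warp_smoothness: float = 1e-4
    comp_tol: float = 1e-4
    comp_max_iter: int = 50
    # statistics
    membrane_window: float = 0.05
    alpha: float = 0.05
    exact_max_n: int = 8
    # virtual cell
    enhance_low_pct: float = 1.0
    enhance_high_pct: float = 99.0
    # randomness
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.membrane_window < 0.5:
            raise ValueError("membrane_window must lie in (0, 0.5)")
        if self.n_angles < 4:
            raise ValueError("n_angles must be at least 4")
        if self.profile_length < 2:
            raise ValueError("profile_length must be at least 2")
        if not 0 < self.max_shift < 0.5:
            raise ValueError("max_shift must lie in (0, 0.5)")
        if self.warp_knots < 1:
            raise ValueError("warp_knots must be at least 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, input checksums, outputs."""

    config_hash: str
    input_checksums: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    log_path: str = ""
    counts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
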