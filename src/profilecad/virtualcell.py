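"""2D virtual-cell reconstruction from compensated radial profiles.

The per-angle average radial profiles of a population form a polar
intensity matrix (angles x 100 radial positions).  Inverse polar mapping
with bilinear interpolation in (angle, radius) renders a disk of radius
100 px — a qualitative "typical cell" of the population on normalized
geometry, deliberately excluding per-cell morphology.  A percentile-
stretched contrast-enhanced version aids visual inspection; neither
rendering is a quantitative output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compensation import AverageProfile

DISK_RADIUS = 100  # px; virtual cells live on normalized geometry
DISPLAY_MAX = 255.0


@dataclass
class VirtualCell:
    polar: np.ndarray  # (A, L) per-angle mean radial profiles
    cartesian: np.ndarray  # (2R+1, 2R+1) reconstructed image
    enhancement: str = "none"  # "none" | "contrast_enhanced"
    clipped_constant: bool = False


def build_virtual_cell(rd_profiles: list[AverageProfile] | np.ndarray) -> VirtualCell:
    """Reconstruct the Cartesian virtual cell from per-angle mean profiles.

    ``rd_profiles`` is either a list of per-angle :class:`AverageProfile`
    (mean used) or an (A, L) array, angle k at ``2*pi*k/A``.  Radial
    sample i maps to radius ``i/(L-1) * DISK_RADIUS``; pixels beyond the
    disk are background 0 and the center pixel is the mean of the
    radius-0 values.
    """
    if isinstance(rd_profiles, np.ndarray):
        polar = np.asarray(rd_profiles, dtype=float)
    else:
        lengths = {p.mean.size for p in rd_profiles}
        if len(lengths) != 1:
            raise ValueError(f"per-angle profiles have inconsistent lengths {sorted(lengths)}")
        polar = np.vstack([p.mean for p in rd_profiles])
    if polar.ndim != 2 or polar.shape[0] < 4:
        raise ValueError("need an (A, L) polar matrix with at least 4 angles")
    A, L = polar.shape
    R = DISK_RADIUS
    side = 2 * R + 1
    rr, cc = np.mgrid[0:side, 0:side]
    dr = rr - R
    dc = cc - R
    rho = np.hypot(dr, dc)
    inside = rho <= R

    # angle convention matches extract_rd_profiles: theta from +col axis, (sin, cos) step
    theta = np.arctan2(dr, dc) % (2 * np.pi)
    a = theta / (2 * np.pi) * A
    a0 = np.floor(a).astype(int) % A
    a1 = (a0 + 1) % A
    wa = a - np.floor(a)

    r = rho / R * (L - 1)
    r0 = np.clip(np.floor(r).astype(int), 0, L - 1)
    r1 = np.clip(r0 + 1, 0, L - 1)
    wr = r - np.floor(r)

    img = ((1 - wa) * ((1 - wr) * polar[a0, r0] + wr * polar[a0, r1])
           + wa * ((1 - wr) * polar[a1, r0] + wr * polar[a1, r1]))
    img[~inside] = 0.0
    img[R, R] = polar[:, 0].mean()
    return VirtualCell(polar=polar, cartesian=img, enhancement="none")


def enhance_contrast(cell: VirtualCell, low_pct: float = 1.0, high_pct: float = 99.0) -> VirtualCell:
    """Percentile-clipped linear stretch of the disk to the display range.

    Percentiles are taken over the disk pixels only (the square's
    background corners stay 0).  Rank order of intensities is preserved.
    A constant disk cannot be stretched and is returned unchanged with
    ``clipped_constant=True``.
    """
    if not low_pct < high_pct:
        raise ValueError("low_pct must be smaller than high_pct")
    img = cell.cartesian
    R = (img.shape[0] - 1) // 2
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    inside = np.hypot(rr - R, cc - R) <= R
    lo, hi = np.percentile(img[inside], [low_pct, high_pct])
    if hi <= lo:
        return VirtualCell(polar=cell.polar, cartesian=img.copy(),
                           enhancement="contrast_enhanced", clipped_constant=True)
    out = np.clip((img - lo) / (hi - lo), 0.0, 1.0) * DISPLAY_MAX
    out[~inside] = 0.0
    return VirtualCell(polar=cell.polar, cartesian=out, enhancement="contrast_enhanced")


def radial_band_mean(cell: VirtualCell, inner_frac: float, outer_frac: float) -> float:
    """Mean intensity of disk pixels with radius in [inner, outer] fractions."""
    img = cell.cartesian
    R = (img.shape[0] - 1) // 2
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    rho = np.hypot(rr - R, cc - R) / R
    sel = (rho >= inner_frac) & (rho <= outer_frac)
    return float(img[sel].mean())
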