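"""Nucleus segmentation: Otsu thresholding plus watershed splitting.

The nuclear counterstain channel is smoothed, binarized with Otsu's
between-class-variance criterion, and touching nuclei are split by a
watershed seeded from maxima of the Euclidean distance transform.
Centroids are geometric (binary) centers, since downstream profiles are
anchored at the geometrical centers of the nuclei.

Coordinates are 0-based ``(row, col)`` with pixel centers at integers;
centroids are sub-pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .io import ChannelImage


@dataclass
class NucleusLabelMap:
    """Labeled nuclei: 0 = background, labels consecutive 1..K."""

    labels: np.ndarray
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)
    areas: dict[int, float] = field(default_factory=dict)

    @property
    def n_nuclei(self) -> int:
        return len(self.centroids)


def otsu_threshold(image: ChannelImage | np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance of the intensity histogram.

    For 8-bit (or small-integer) data the 256 integer levels are used
    directly: the optimal split assigns levels <= t to background, and the
    returned threshold is t + 0.5 so that ``pixels > threshold`` realizes
    the split.  Otherwise the histogram uses ``nbins`` equal bins over the
    intensity range and the returned threshold is the boundary between the
    optimal pair of bins.  Ties are broken toward the lowest threshold.  A
    constant image has no threshold and raises ``ValueError``.
    """
    pixels = image.pixels if isinstance(image, ChannelImage) else np.asarray(image, dtype=float)
    flat = pixels.ravel()
    if flat.min() == flat.max():
        raise ValueError("cannot threshold a constant image")

    is_8bit = isinstance(image, ChannelImage) and image.bit_depth == 8
    integral = np.allclose(flat, np.round(flat)) and flat.max() <= 255 and flat.min() >= 0
    if is_8bit or integral:
        counts = np.bincount(flat.astype(np.int64), minlength=256).astype(float)
        centers = np.arange(256, dtype=float)
    else:
        counts, edges = np.histogram(flat, bins=nbins)
        counts = counts.astype(float)
        centers = 0.5 * (edges[:-1] + edges[1:])

    total = counts.sum()
    w0 = np.cumsum(counts)  # class 0 = bins[0..t]
    w1 = total - w0
    s0 = np.cumsum(counts * centers)
    s_total = s0[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / w0
        mu1 = (s_total - s0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~np.isfinite(var_between)] = -np.inf
    var_between[-1] = -np.inf  # splitting nothing off is not a threshold
    t = int(np.argmax(var_between))  # argmax takes the first (lowest) tie
    if is_8bit or integral:
        return float(centers[t]) + 0.5
    return float(0.5 * (centers[t] + centers[t + 1]))


def segment_nuclei(image: ChannelImage, min_area: float = 30.0, smoothing_sigma: float = 1.0,
                   seed_separation: int = 5) -> NucleusLabelMap:
    """Segment nuclei: smooth, Otsu-binarize, watershed-split, filter, relabel.

    Watershed seeds are local maxima of the Euclidean distance transform
    separated by at least ``seed_separation`` px; every connected component
    is guaranteed at least one seed, so the watershed never merges
    components.  Components smaller than ``min_area`` px^2 are dropped and
    the survivors relabeled 1..K with geometric centroids.
    """
    pixels = image.pixels
    if smoothing_sigma > 0:
        pixels = gaussian(pixels, sigma=smoothing_sigma, preserve_range=True)
    thr = otsu_threshold(ChannelImage(pixels=np.maximum(pixels, 0.0), bit_depth=image.bit_depth))
    mask = pixels > thr
    if not mask.any():
        return NucleusLabelMap(labels=np.zeros(pixels.shape, dtype=np.int32))

    distance = ndimage.distance_transform_edt(mask)
    coords = peak_local_max(distance, min_distance=max(1, int(seed_separation)),
                            labels=mask, exclude_border=False)
    markers = np.zeros(pixels.shape, dtype=np.int32)
    for k, (r, c) in enumerate(coords, start=1):
        markers[r, c] = k
    # guarantee a marker in every connected component
    comp, n_comp = ndimage.label(mask)
    seeded = set(np.unique(comp[markers > 0]))
    next_id = len(coords) + 1
    for ci in range(1, n_comp + 1):
        if ci not in seeded:
            inside = np.where(comp == ci)
            best = np.argmax(distance[inside])
            markers[inside[0][best], inside[1][best]] = next_id
            next_id += 1
    labels = watershed(-distance, markers=markers, mask=mask)

    out = np.zeros(pixels.shape, dtype=np.int32)
    centroids: dict[int, tuple[float, float]] = {}
    areas: dict[int, float] = {}
    next_label = 1
    for prop in regionprops(labels):
        if prop.area < min_area:
            continue
        out[labels == prop.label] = next_label
        centroids[next_label] = (float(prop.centroid[0]), float(prop.centroid[1]))
        areas[next_label] = float(prop.area)
        next_label += 1
    return NucleusLabelMap(labels=out, centroids=centroids, areas=areas)


def match_selection(label_map: NucleusLabelMap, clicked_points: list[tuple[float, float]],
                    max_snap_distance: float = 10.0) -> tuple[list[int | None], list[int]]:
    """Map operator-clicked points to nucleus labels.

    A point inside a labeled region takes that label; a point on background
    snaps to the nearest labeled pixel within ``max_snap_distance`` px.
    Returns ``(matches, unmatched_indices)`` where unmatched points carry
    ``None`` and trigger a warning.
    """
    labels = label_map.labels
    rows, cols = labels.shape
    if labels.max() > 0:
        dist, (ir, ic) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    else:
        dist = np.full(labels.shape, np.inf)
        ir = ic = None
    matches: list[int | None] = []
    unmatched: list[int] = []
    for i, (pr, pc) in enumerate(clicked_points):
        r = int(np.clip(round(pr), 0, rows - 1))
        c = int(np.clip(round(pc), 0, cols - 1))
        lab = int(labels[r, c])
        if lab == 0 and ir is not None and dist[r, c] <= max_snap_distance:
            lab = int(labels[ir[r, c], ic[r, c]])
        if lab == 0:
            warnings.warn(f"selection point {i} at ({pr:.1f}, {pc:.1f}) is farther than "
                          f"{max_snap_distance} px from any nucleus; excluded", stacklevel=2)
            matches.append(None)
            unmatched.append(i)
        else:
            matches.append(lab)
    return matches, unmatched
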