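"""Synthetic two-channel immunofluorescence image generator.

Emulates confluent monolayers of roughly convex epithelial cells with
DAPI-like nuclei (nuclear channel) and a membrane protein such as
E-cadherin (protein channel).  Wild-type-like cells concentrate the
protein in a ridge along the shared cell-cell boundaries; mutant-like
cells show a reduced membrane ridge and, optionally, a perinuclear
accumulation placed at a fixed fraction of the nucleus-to-membrane
distance (an endoplasmic-reticulum-retention phenotype).

Cell geometry is a Voronoi tessellation of a hexagonally offset, jittered
grid of seed points: contiguous polygonal cells with shared membranes and
controllable size/shape variability, as in a confluent epithelial sheet.

All randomness derives from a single integer seed, so every output is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Point, Polygon, box

from .io import ChannelImage, Selection, write_channel_tiff, write_selection_csv

TIFF_SCALE = 64.0  # fixed linear factor from float intensity to stored uint16
NUCLEAR_INTENSITY = 160.0
MIN_CELL_PITCH = 16.0  # px; below this the image cannot host the requested cells


@dataclass
class PhenotypeSpec:
    """Parameters of a protein-localization phenotype.

    ``perinuclear_peak_position`` is the fraction of the nucleus-center-to-
    membrane distance at which the perinuclear annulus is centred (0 =
    nucleus center, 1 = membrane).
    """

    membrane_amplitude: float = 100.0
    cytoplasm_baseline: float = 20.0
    perinuclear_peak_amplitude: float = 0.0
    perinuclear_peak_position: float = 0.8
    perinuclear_peak_width: float = 0.05
    membrane_thickness_px: float = 4.0
    noise_model: str = "none"  # "none" | "poisson"
    photon_scale: float = 10.0  # counts per intensity unit for Poisson draws

    def __post_init__(self) -> None:
        if min(self.membrane_amplitude, self.cytoplasm_baseline, self.perinuclear_peak_amplitude) < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0.0 < self.perinuclear_peak_position < 1.0:
            raise ValueError("perinuclear_peak_position must lie strictly inside (0, 1)")
        if self.membrane_thickness_px <= 0:
            raise ValueError("membrane_thickness_px must be positive")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")


def wt_phenotype(noise_model: str = "poisson") -> PhenotypeSpec:
    """Wild-type-like phenotype: strong membrane ridge, no cytoplasmic peak."""
    return PhenotypeSpec(membrane_amplitude=100.0, cytoplasm_baseline=20.0,
                         perinuclear_peak_amplitude=0.0, noise_model=noise_model)


def mutant_phenotype(noise_model: str = "poisson") -> PhenotypeSpec:
    """Mutant-like phenotype: reduced membrane, perinuclear accumulation at 0.8."""
    return PhenotypeSpec(membrane_amplitude=40.0, cytoplasm_baseline=20.0,
                         perinuclear_peak_amplitude=80.0, perinuclear_peak_position=0.8,
                         noise_model=noise_model)


@dataclass
class CellGeometry:
    nucleus_center: tuple[float, float]  # (row, col)
    nucleus_radius: float
    polygon: np.ndarray  # (k, 2) vertices in (row, col)


@dataclass
class SyntheticScene:
    """Ground-truth geometry of a synthetic cell population."""

    cells: list[CellGeometry]
    image_shape: tuple[int, int]
    seed: int
    seed_points: np.ndarray = field(repr=False)  # (n, 2) tessellation seeds, (row, col)

    _label_cache: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def label_map(self) -> np.ndarray:
        """Integer cell labels 1..n for every pixel (nearest tessellation seed)."""
        if self._label_cache is None:
            rows, cols = self.image_shape
            rr, cc = np.mgrid[0:rows, 0:cols]
            pts = np.column_stack([rr.ravel(), cc.ravel()])
            if self.n_cells == 1:
                lab = np.ones((rows, cols), dtype=np.int32)
            else:
                _, idx = cKDTree(self.seed_points).query(pts)
                lab = (idx.astype(np.int32) + 1).reshape(rows, cols)
            self._label_cache = lab
        return self._label_cache

    def boundary_mask(self) -> np.ndarray:
        """Pixels on an inter-cell boundary (either side of a label change)."""
        lab = self.label_map()
        b = np.zeros_like(lab, dtype=bool)
        d = lab[1:, :] != lab[:-1, :]
        b[1:, :] |= d
        b[:-1, :] |= d
        d = lab[:, 1:] != lab[:, :-1]
        b[:, 1:] |= d
        b[:, :-1] |= d
        return b

    def nucleus_mask(self) -> np.ndarray:
        rows, cols = self.image_shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        mask = np.zeros((rows, cols), dtype=bool)
        for cell in self.cells:
            r0, c0 = cell.nucleus_center
            mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= cell.nucleus_radius**2
        return mask

    def adjacency_pairs(self) -> list[tuple[int, int]]:
        """Sorted (i, j) cell-index pairs (0-based) sharing a rasterized boundary."""
        lab = self.label_map()
        pairs = set()
        a, b = lab[1:, :].ravel(), lab[:-1, :].ravel()
        for x, y in zip(a[a != b], b[a != b]):
            pairs.add((min(x, y) - 1, max(x, y) - 1))
        a, b = lab[:, 1:].ravel(), lab[:, :-1].ravel()
        for x, y in zip(a[a != b], b[a != b]):
            pairs.add((min(x, y) - 1, max(x, y) - 1))
        return sorted(pairs)

    def interior_cells(self, margin: float = 2.0) -> list[int]:
        """Indices of cells whose polygon stays `margin` px inside the image."""
        rows, cols = self.image_shape
        out = []
        for i, cell in enumerate(self.cells):
            p = cell.polygon
            if (p[:, 0].min() > margin and p[:, 1].min() > margin
                    and p[:, 0].max() < rows - 1 - margin and p[:, 1].max() < cols - 1 - margin):
                out.append(i)
        return out


def _hex_grid(n_cells: int, rows: int, cols: int) -> tuple[np.ndarray, float]:
    """Hexagonally offset grid of >= n_cells seed points covering the image."""
    aspect = rows / cols
    nr = max(1, int(round(math.sqrt(n_cells * aspect))))
    nc = max(1, math.ceil(n_cells / nr))
    while nr * nc < n_cells:
        nc += 1
    pitch_r, pitch_c = rows / nr, cols / nc
    pts = []
    for i in range(nr):
        for j in range(nc):
            r = (i + 0.5) * pitch_r
            c = (j + 0.5) * pitch_c + (0.25 * pitch_c if i % 2 else -0.25 * pitch_c)
            pts.append((r, c % cols))
    return np.array(pts), min(pitch_r, pitch_c)


def make_scene(n_cells: int, image_shape: tuple[int, int] = (512, 512),
               shape_jitter: float = 0.2, seed: int = 0) -> SyntheticScene:
    """Tessellate the image into ``n_cells`` contiguous cells with nuclei.

    Cells are Voronoi regions of a hexagonally offset grid of seeds, each
    jittered by ``shape_jitter`` (0 = regular lattice, 1 = strong
    irregularity).  Each nucleus is a disk at a jittered interior point of
    its cell.  Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= shape_jitter <= 1.0:
        raise ValueError("shape_jitter must lie in [0, 1]")
    rows, cols = image_shape
    rng = np.random.default_rng(seed)

    if n_cells == 1:
        poly = np.array([[0.0, 0.0], [0.0, cols - 1.0], [rows - 1.0, cols - 1.0], [rows - 1.0, 0.0]])
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
        radius = 0.15 * min(rows, cols)
        cell = CellGeometry(nucleus_center=center, nucleus_radius=radius, polygon=poly)
        return SyntheticScene(cells=[cell], image_shape=image_shape, seed=seed,
                              seed_points=np.array([center]))

    grid, pitch = _hex_grid(n_cells, rows, cols)
    grid = grid[:]
    if pitch < MIN_CELL_PITCH:
        raise ValueError(
            f"image {image_shape} is too small to host {n_cells} cells "
            f"(cell pitch {pitch:.1f} px < {MIN_CELL_PITCH} px)"
        )
    # keep exactly n_cells seeds, preferring those nearest the image center
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    order = np.argsort(((grid - center) ** 2).sum(axis=1), kind="stable")
    seeds = grid[np.sort(order[:n_cells])]
    jitter = rng.uniform(-0.5, 0.5, size=seeds.shape) * shape_jitter * pitch * 0.7
    seeds = seeds + jitter
    seeds[:, 0] = np.clip(seeds[:, 0], 1.0, rows - 2.0)
    seeds[:, 1] = np.clip(seeds[:, 1], 1.0, cols - 2.0)

    polygons = _bounded_voronoi(seeds, rows, cols)
    cells = []
    for i, poly in enumerate(polygons):
        shp = Polygon(poly)
        centroid = np.array([shp.centroid.x, shp.centroid.y])  # stored as (row, col)
        d_centroid = shp.exterior.distance(Point(*centroid))
        ang = rng.uniform(0, 2 * np.pi)
        mag = rng.uniform(0, 1) * shape_jitter * 0.35 * d_centroid
        cand = centroid + mag * np.array([np.sin(ang), np.cos(ang)])
        if mag > 0 and shp.contains(Point(*cand)):
            centroid = cand
        d = shp.exterior.distance(Point(*centroid))
        radius = min(0.55 * d, 0.30 * math.sqrt(shp.area)) * rng.uniform(0.9, 1.1)
        radius = max(radius, 3.0)
        cells.append(CellGeometry(nucleus_center=(float(centroid[0]), float(centroid[1])),
                                  nucleus_radius=float(radius), polygon=poly))
    return SyntheticScene(cells=cells, image_shape=image_shape, seed=seed, seed_points=seeds)


def _bounded_voronoi(seeds: np.ndarray, rows: int, cols: int) -> list[np.ndarray]:
    """Voronoi polygons of `seeds` clipped to the image rectangle.

    Uses the reflection trick: seeds mirrored across the four image edges
    guarantee every original region is finite, then regions are clipped.
    """
    r, c = seeds[:, 0], seeds[:, 1]
    mirrored = np.vstack([
        seeds,
        np.column_stack([-r, c]),
        np.column_stack([2 * (rows - 1) - r, c]),
        np.column_stack([r, -c]),
        np.column_stack([r, 2 * (cols - 1) - c]),
    ])
    vor = Voronoi(mirrored)
    rect = box(0.0, 0.0, rows - 1.0, cols - 1.0)
    polygons = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        shp = Polygon(verts).intersection(rect)
        if shp.is_empty or shp.geom_type != "Polygon":
            raise RuntimeError("degenerate Voronoi region; seeds too close together")
        xy = np.asarray(shp.exterior.coords[:-1])
        polygons.append(xy)
    return polygons


def render_channels(scene: SyntheticScene, phenotype: PhenotypeSpec) -> tuple[ChannelImage, ChannelImage]:
    """Render the nuclear and protein channels of a scene.

    Protein channel = cytoplasm baseline + Gaussian ridge (sigma =
    membrane_thickness_px / 2) along inter-cell boundaries + optional
    perinuclear Gaussian annulus centred at ``perinuclear_peak_position``
    of the nucleus-center-to-membrane distance.  Poisson noise, when on,
    is drawn as photon counts at ``photon_scale`` and rescaled.
    """
    rows, cols = scene.image_shape
    nuclear = np.where(scene.nucleus_mask(), NUCLEAR_INTENSITY, 0.0)

    protein = np.full((rows, cols), float(phenotype.cytoplasm_baseline))
    boundary = scene.boundary_mask()
    sigma = phenotype.membrane_thickness_px / 2.0
    dist_b = ndimage.distance_transform_edt(~boundary) if boundary.any() else None
    if dist_b is not None and phenotype.membrane_amplitude > 0:
        protein += phenotype.membrane_amplitude * np.exp(-(dist_b**2) / (2 * sigma**2))

    if phenotype.perinuclear_peak_amplitude > 0:
        if dist_b is None:
            dist_b = np.full((rows, cols), np.inf)
        lab = scene.label_map()
        centers = np.array([c.nucleus_center for c in scene.cells])
        rr, cc = np.mgrid[0:rows, 0:cols]
        ctr = centers[lab - 1]
        dcen = np.hypot(rr - ctr[..., 0], cc - ctr[..., 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(np.isinf(dist_b), 0.0, dcen / np.maximum(dcen + dist_b, 1e-9))
        w = phenotype.perinuclear_peak_width
        protein += phenotype.perinuclear_peak_amplitude * np.exp(
            -((u - phenotype.perinuclear_peak_position) ** 2) / (2 * w**2)
        )

    if phenotype.noise_model == "poisson":
        scale = phenotype.photon_scale
        rng_nuc = np.random.default_rng(np.random.SeedSequence([int(scene.seed) & 0x7FFFFFFF, 101]))
        rng_pro = np.random.default_rng(np.random.SeedSequence([int(scene.seed) & 0x7FFFFFFF, 202]))
        nuclear = rng_nuc.poisson(nuclear * scale).astype(float) / scale
        protein = rng_pro.poisson(protein * scale).astype(float) / scale

    return (ChannelImage(pixels=nuclear), ChannelImage(pixels=protein))


def apply_poisson_noise(values: np.ndarray, photon_scale: float, seed: int) -> np.ndarray:
    """Poisson photon noise at ``photon_scale`` counts per intensity unit."""
    rng = np.random.default_rng(seed)
    return rng.poisson(np.asarray(values, dtype=float) * photon_scale).astype(float) / photon_scale


def median_membrane_distance(scene: SyntheticScene, n_angles: int = 36,
                             max_radius: float = 200.0) -> float:
    """Median distance from nucleus centers to the membrane along rays.

    Sampled over interior cells and ``n_angles`` directions; the standard
    way to pick a per-population radial ray length (rays should end just
    past the typical membrane crossing, e.g. length = median / 0.95).
    """
    lab = scene.label_map()
    rows, cols = scene.image_shape
    interior = scene.interior_cells(margin=2.0)
    if not interior:
        interior = list(range(scene.n_cells))
    dists = []
    ts = np.arange(1, int(max_radius))
    for i in interior:
        c = scene.cells[i].nucleus_center
        own = lab[int(round(c[0])), int(round(c[1]))]
        for k in range(n_angles):
            theta = 2 * np.pi * k / n_angles
            rr = np.round(c[0] + ts * np.sin(theta)).astype(int)
            cc = np.round(c[1] + ts * np.cos(theta)).astype(int)
            ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
            hits = np.where(lab[rr[ok], cc[ok]] != own)[0]
            if hits.size:
                dists.append(ts[ok][hits[0]])
    return float(np.median(dists))


def write_fixture(scene: SyntheticScene, phenotype: PhenotypeSpec, directory: str | Path,
                  image_id: str = "scene") -> Path:
    """Write TIFF channels, ground-truth selection CSV and a JSON manifest.

    The selection CSV holds one ``point`` row per nucleus center and one
    ``pair`` row per adjacent cell pair of the tessellation.  Returns the
    manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nuclear, protein = render_channels(scene, phenotype)
    nuc_path = directory / "nuclear.tif"
    pro_path = directory / "protein.tif"
    write_channel_tiff(nuc_path, nuclear.pixels * TIFF_SCALE)
    write_channel_tiff(pro_path, protein.pixels * TIFF_SCALE)

    selections: list[Selection] = []
    for cell in scene.cells:
        selections.append(Selection(kind="point", image_id=image_id, p1=cell.nucleus_center))
    for i, j in scene.adjacency_pairs():
        selections.append(Selection(kind="pair", image_id=image_id,
                                    p1=scene.cells[i].nucleus_center,
                                    p2=scene.cells[j].nucleus_center))
    sel_path = directory / "selections.csv"
    write_selection_csv(sel_path, selections)

    manifest = {
        "image_id": image_id,
        "n_cells": scene.n_cells,
        "image_shape": list(scene.image_shape),
        "seed": scene.seed,
        "phenotype": dataclasses.asdict(phenotype),
        "intensity_scale": TIFF_SCALE,
        "files": {
            "nuclear": nuc_path.name,
            "protein": pro_path.name,
            "selections": sel_path.name,
        },
        "checksums": {
            nuc_path.name: hashlib.sha256(nuc_path.read_bytes()).hexdigest(),
            pro_path.name: hashlib.sha256(pro_path.read_bytes()).hexdigest(),
        },
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
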