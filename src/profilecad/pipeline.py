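"""End-to-end analysis pipeline: segment -> profiles -> denoise ->
compensate -> summarize -> statistics -> virtual cell.

The pipeline consumes, per population, a nuclear-channel TIFF, a
protein-channel TIFF and a selection CSV of operator-chosen nucleus
points (``point`` rows, used for radial profiles) and nucleus pairs
(``pair`` rows, used for internuclear profiles).  Every intermediate is
persisted as plain text or TIFF so each stage can be inspected and rerun
independently, and every exclusion (unmatched point, invalid segment,
clipped ray) is counted and logged — input selections always equal used
plus excluded-with-reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as pstats
from .compensation import AverageProfile, compensate_map, denoise_map, summarize_map
from .io import (ChannelImage, RunConfig, RunManifest, Selection, config_hash,
                 file_checksum, read_channel_tiff, read_selection_csv, write_channel_tiff)
from .profiles import ProfileMap, build_map, extract_in_profile, extract_rd_profiles, normalize_length
from .segmentation import NucleusLabelMap, match_selection, segment_nuclei
from .virtualcell import VirtualCell, build_virtual_cell, enhance_contrast

logger = logging.getLogger("profilecad")


@dataclass
class PopulationInput:
    name: str
    nuclear: str | Path
    protein: str | Path
    selections: str | Path
    denoise_gain: float = 1.0


@dataclass
class PopulationResult:
    name: str
    label_map: NucleusLabelMap
    in_raw: Optional[ProfileMap] = None
    in_compensated: Optional[ProfileMap] = None
    in_average: Optional[AverageProfile] = None
    features: list = field(default_factory=list)
    summary: Optional[pstats.PopulationSummary] = None
    rd_polar: Optional[np.ndarray] = None
    virtual_cell: Optional[VirtualCell] = None
    virtual_cell_enhanced: Optional[VirtualCell] = None
    counts: dict = field(default_factory=dict)


def analyze_population(name: str, nuclear: ChannelImage, protein: ChannelImage,
                       selections: list[Selection], config: RunConfig,
                       denoise_gain: float = 1.0, do_rd: bool = True) -> PopulationResult:
    """Run the full per-population analysis in memory."""
    config.validate()
    label_map = segment_nuclei(nuclear, min_area=config.min_area,
                               smoothing_sigma=config.smoothing_sigma,
                               seed_separation=config.seed_separation)
    logger.info("[%s] segmented %d nuclei", name, label_map.n_nuclei)
    result = PopulationResult(name=name, label_map=label_map)
    counts = {"selections_total": len(selections), "pairs_used": 0, "pairs_excluded": 0,
              "points_used": 0, "points_excluded": 0, "rays_excluded": 0}

    pairs = [s for s in selections if s.kind == "pair"]
    points = [s for s in selections if s.kind == "point"]

    # ------------------------------------------------------------------ IN
    in_profiles = []
    for i, sel in enumerate(pairs):
        matched, _ = match_selection(label_map, [sel.p1, sel.p2],
                                     max_snap_distance=config.max_snap_distance)
        if matched[0] is None or matched[1] is None or matched[0] == matched[1]:
            counts["pairs_excluded"] += 1
            logger.warning("[%s] pair %d excluded: points do not match two distinct nuclei", name, i)
            continue
        c1 = label_map.centroids[matched[0]]
        c2 = label_map.centroids[matched[1]]
        try:
            prof = extract_in_profile(protein, c1, c2, step_px=config.step_px,
                                      source_id=f"{sel.image_id}:pair{i}")
        except ValueError as exc:
            counts["pairs_excluded"] += 1
            logger.warning("[%s] pair %d excluded: %s", name, i, exc)
            continue
        in_profiles.append(normalize_length(prof, L=config.profile_length))
        counts["pairs_used"] += 1

    if len(in_profiles) >= 2:
        raw = build_map(in_profiles)
        denoised = denoise_map(raw, strength=config.denoise_strength, gain=denoise_gain)
        compensated, _comp = compensate_map(denoised, max_iter=config.comp_max_iter,
                                            tol=config.comp_tol, warp_knots=config.warp_knots,
                                            max_shift=config.max_shift,
                                            smoothness=config.warp_smoothness)
        result.in_raw = raw
        result.in_compensated = compensated
        result.in_average = summarize_map(compensated)
        result.features = [pstats.profile_features(compensated.values[:, j],
                                                   window=config.membrane_window,
                                                   profile_id=raw.provenance[j]["source_id"])
                           for j in range(compensated.n_profiles)]
        result.summary = pstats.summarize_population(result.features, name=name,
                                                     average_profile=result.in_average)

    # ------------------------------------------------------------------ RD
    if do_rd and points:
        rows, cols = protein.shape
        per_angle: dict[int, list] = {}
        n_angles = config.n_angles
        for i, sel in enumerate(points):
            matched, _ = match_selection(label_map, [sel.p1],
                                         max_snap_distance=config.max_snap_distance)
            if matched[0] is None:
                counts["points_excluded"] += 1
                logger.warning("[%s] point %d excluded: no nucleus within snap distance", name, i)
                continue
            center = label_map.centroids[matched[0]]
            margin = config.ray_length + 1.0
            if not (margin <= center[0] <= rows - 1 - margin
                    and margin <= center[1] <= cols - 1 - margin):
                counts["points_excluded"] += 1
                logger.info("[%s] point %d excluded: rays would leave the image", name, i)
                continue
            profs = extract_rd_profiles(protein, center, n_angles=n_angles,
                                        ray_length=config.ray_length, step_px=config.step_px,
                                        source_id=f"{sel.image_id}:cell{i}")
            counts["rays_excluded"] += n_angles - len(profs)
            for p in profs:
                k = int(round(p.anchors["angle"] * n_angles / (2 * np.pi))) % n_angles
                per_angle.setdefault(k, []).append(normalize_length(p, L=config.profile_length))
            counts["points_used"] += 1

        if len(per_angle) == n_angles and all(len(v) >= 2 for v in per_angle.values()):
            polar = np.zeros((n_angles, config.profile_length))
            for k in range(n_angles):
                amap = build_map(per_angle[k])
                amap = denoise_map(amap, strength=config.denoise_strength, gain=denoise_gain)
                comp, _ = compensate_map(amap, max_iter=config.comp_max_iter, tol=config.comp_tol,
                                         warp_knots=config.warp_knots, max_shift=config.max_shift,
                                         smoothness=config.warp_smoothness)
                polar[k] = summarize_map(comp).mean
            result.rd_polar = polar
            result.virtual_cell = build_virtual_cell(polar)
            result.virtual_cell_enhanced = enhance_contrast(result.virtual_cell,
                                                            config.enhance_low_pct,
                                                            config.enhance_high_pct)
        elif per_angle:
            logger.warning("[%s] virtual cell skipped: not every angle has >= 2 usable rays", name)

    result.counts = counts
    return result


def write_population_outputs(result: PopulationResult, out_dir: Path) -> dict:
    """Persist all per-population intermediates; returns path mapping."""
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    write_channel_tiff(out_dir / "nuclei_labels.tif", result.label_map.labels.astype(float))
    outputs["nuclei_labels"] = str(out_dir / "nuclei_labels.tif")
    cent = pd.DataFrame([(lab, rc[0], rc[1], result.label_map.areas[lab])
                         for lab, rc in result.label_map.centroids.items()],
                        columns=["label", "row", "col", "area"])
    cent.to_csv(out_dir / "nuclei_centroids.csv", index=False)
    outputs["nuclei_centroids"] = str(out_dir / "nuclei_centroids.csv")

    if result.in_raw is not None:
        np.savetxt(out_dir / "in_map_raw.csv", result.in_raw.values, delimiter=",")
        np.savetxt(out_dir / "in_map_compensated.csv", result.in_compensated.values, delimiter=",")
        warps = [list(map(float, w)) for w in (result.in_compensated.warps or [])]
        (out_dir / "in_warps.json").write_text(json.dumps(warps))
        avg = result.in_average
        pd.DataFrame({"position": np.linspace(0, 1, avg.mean.size),
                      "mean": avg.mean, "sd": avg.sd, "n": avg.n}).to_csv(
            out_dir / "in_average_profile.csv", index=False)
        pd.DataFrame([{"profile_id": f.profile_id, "membrane_mean": f.membrane_mean,
                       "mmr": f.mmr, "peak_position": f.peak_position}
                      for f in result.features]).to_csv(out_dir / "features.csv", index=False)
        outputs.update({k: str(out_dir / v) for k, v in
                        {"in_map_raw": "in_map_raw.csv", "in_map_compensated": "in_map_compensated.csv",
                         "in_warps": "in_warps.json", "in_average_profile": "in_average_profile.csv",
                         "features": "features.csv"}.items()})

    if result.virtual_cell is not None:
        import imageio.v3 as iio

        np.savetxt(out_dir / "rd_polar.csv", result.rd_polar, delimiter=",")
        vmax = result.virtual_cell.cartesian.max()
        plain = result.virtual_cell.cartesian / vmax * 255 if vmax > 0 else result.virtual_cell.cartesian
        iio.imwrite(out_dir / "virtual_cell.png", plain.astype(np.uint8))
        iio.imwrite(out_dir / "virtual_cell_enhanced.png",
                    result.virtual_cell_enhanced.cartesian.astype(np.uint8))
        outputs.update({"rd_polar": str(out_dir / "rd_polar.csv"),
                        "virtual_cell": str(out_dir / "virtual_cell.png"),
                        "virtual_cell_enhanced": str(out_dir / "virtual_cell_enhanced.png")})
    return outputs


def write_report(summaries: list[pstats.PopulationSummary],
                 comparisons: list[pstats.ComparisonResult], out_dir: Path) -> dict:
    """Summary and comparison tables as CSV plus a human-readable text report."""
    out_dir.mkdir(parents=True, exist_ok=True)
    sdf = pd.DataFrame([{"population": s.name, "n_profiles": s.n_profiles,
                         "membrane_mean": s.membrane_mean_mean, "membrane_mean_se": s.membrane_mean_se,
                         "mmr": s.mmr_mean, "mmr_se": s.mmr_se} for s in summaries])
    sdf.to_csv(out_dir / "summary.csv", index=False)
    cdf = pd.DataFrame([{"population": c.population, "reference": c.reference, "feature": c.feature,
                         "U": c.statistic, "p_raw": c.p_raw, "alpha_corrected": c.alpha_corrected,
                         "n_comparisons": c.n_comparisons, "significant": c.significant}
                        for c in comparisons])
    cdf.to_csv(out_dir / "comparisons.csv", index=False)

    lines = ["Population summary (membrane mean fluorescence and MMR, mean +/- SE)", ""]
    for s in summaries:
        lines.append(f"  {s.name:>12s}  n={s.n_profiles:<5d} "
                     f"membrane mean {s.membrane_mean_mean:8.2f} (+/-{s.membrane_mean_se:.3f})  "
                     f"MMR {s.mmr_mean:6.3f} (+/-{s.mmr_se:.4f})")
    lines += ["", "Pairwise Mann-Whitney tests vs reference (Bonferroni-corrected)", ""]
    for c in comparisons:
        flag = "SIGNIFICANT" if c.significant else "n.s."
        lines.append(f"  {c.population:>12s} vs {c.reference}  {c.feature:<14s} "
                     f"U={c.statistic:10.1f}  p={c.p_raw:.3e}  "
                     f"alpha_corr={c.alpha_corrected:.4f} ({c.n_comparisons} tests)  {flag}")
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return {"summary": str(out_dir / "summary.csv"),
            "comparisons": str(out_dir / "comparisons.csv"),
            "report": str(out_dir / "report.txt")}


def run_pipeline(config: RunConfig, populations: list[PopulationInput], out_dir: str | Path,
                 reference: Optional[str] = None) -> RunManifest:
    """Run every stage for every population and write a full report.

    Stage errors abort with the population and stage named; outputs
    produced so far are retained on disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest = RunManifest(config_hash=config_hash(config), log_path=str(log_path))
    try:
        results = []
        for pop in populations:
            for path in (pop.nuclear, pop.protein, pop.selections):
                manifest.input_checksums[str(path)] = file_checksum(path)
            logger.info("analyzing population %s", pop.name)
            nuclear = read_channel_tiff(pop.nuclear)
            protein = read_channel_tiff(pop.protein)
            selections = read_selection_csv(pop.selections)
            res = analyze_population(pop.name, nuclear, protein, selections, config,
                                     denoise_gain=pop.denoise_gain)
            results.append(res)
            manifest.outputs[pop.name] = write_population_outputs(res, out_dir / pop.name)
            manifest.counts[pop.name] = res.counts

        summaries = [r.summary for r in results if r.summary is not None]
        comparisons = []
        ref = reference or (populations[0].name if populations else None)
        pops_with_features = {r.name: r.features for r in results if r.features}
        if ref in pops_with_features and len(pops_with_features) >= 2:
            comparisons = pstats.compare_populations(pops_with_features, reference=ref,
                                                     alpha=config.alpha,
                                                     exact_max_n=config.exact_max_n)
        manifest.outputs["report"] = write_report(summaries, comparisons, out_dir / "report")
        config.to_json(out_dir / "config.json")
        manifest.to_json(out_dir / "manifest.json")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return manifest
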