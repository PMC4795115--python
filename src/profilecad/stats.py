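"""Quantitative descriptors of fluorescence profiles and population tests.

Per profile, two features summarize membrane localization:

* **membrane mean fluorescence** — mean intensity in a window around the
  expected membrane position (0.5 on the normalized internuclear axis);
* **MMR (maximum mean ratio)** — the profile's maximum divided by its
  mean.  MMR >= 1 always, with equality only for a constant profile; a
  sharp membrane peak gives a high MMR, diffuse cytoplasmic signal pulls
  it toward 1.  MMR is invariant to intensity rescaling.

Populations are compared feature-wise with two-sided Mann-Whitney U
tests under a Bonferroni correction whose denominator is the number of
tests in the batch.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .compensation import AverageProfile
from .profiles import NormalizedProfile


@dataclass
class ProfileFeatures:
    membrane_mean: float
    mmr: float
    peak_position: float
    profile_id: str = ""


@dataclass
class PopulationSummary:
    name: str
    n_profiles: int
    membrane_mean_mean: float
    membrane_mean_se: float
    mmr_mean: float
    mmr_se: float
    average_profile: Optional[AverageProfile] = None
    se_defined: bool = True


@dataclass
class ComparisonResult:
    population: str
    reference: str
    feature: str
    statistic: float
    p_raw: float
    alpha_corrected: float
    n_comparisons: int
    significant: bool


def _as_samples(profile: NormalizedProfile | np.ndarray) -> np.ndarray:
    if isinstance(profile, NormalizedProfile):
        return profile.samples
    return np.asarray(profile, dtype=float)


def compute_mmr(profile: NormalizedProfile | np.ndarray) -> float:
    """Maximum mean ratio: max(samples) / mean(samples)."""
    y = _as_samples(profile)
    m = float(np.mean(y))
    if m <= 0:
        raise ValueError("MMR undefined: profile mean is not positive")
    return float(np.max(y)) / m


def membrane_mean(profile: NormalizedProfile | np.ndarray, window: float = 0.05) -> float:
    """Mean intensity at normalized positions within ``0.5 +/- window``."""
    if not 0 < window < 0.5:
        raise ValueError("window must lie in (0, 0.5)")
    y = _as_samples(profile)
    x = np.linspace(0.0, 1.0, y.size)
    sel = (x >= 0.5 - window) & (x <= 0.5 + window)
    return float(np.mean(y[sel]))


def peak_position(profile: NormalizedProfile | np.ndarray) -> float:
    """Normalized axis position of the profile maximum."""
    y = _as_samples(profile)
    return float(np.argmax(y) / (y.size - 1))


def profile_features(profile: NormalizedProfile | np.ndarray, window: float = 0.05,
                     profile_id: str = "") -> ProfileFeatures:
    return ProfileFeatures(membrane_mean=membrane_mean(profile, window),
                           mmr=compute_mmr(profile),
                           peak_position=peak_position(profile),
                           profile_id=profile_id)


def summarize_population(features: list[ProfileFeatures], name: str = "",
                         average_profile: Optional[AverageProfile] = None) -> PopulationSummary:
    """Mean and standard error (sample SD / sqrt(n)) of the per-profile features."""
    if not features:
        raise ValueError("need at least one feature set")
    mm = np.array([f.membrane_mean for f in features])
    mmr = np.array([f.mmr for f in features])
    n = len(features)
    if n > 1:
        mm_se = float(mm.std(ddof=1) / math.sqrt(n))
        mmr_se = float(mmr.std(ddof=1) / math.sqrt(n))
        se_defined = True
    else:
        mm_se = mmr_se = 0.0
        se_defined = False
    return PopulationSummary(name=name, n_profiles=n,
                             membrane_mean_mean=float(mm.mean()), membrane_mean_se=mm_se,
                             mmr_mean=float(mmr.mean()), mmr_se=mmr_se,
                             average_profile=average_profile, se_defined=se_defined)


def _rank_sum_u(pooled_ranks: np.ndarray, idx_a: tuple[int, ...], n_a: int, n_b: int) -> float:
    r_a = pooled_ranks[list(idx_a)].sum()
    return r_a - n_a * (n_a + 1) / 2.0


def mann_whitney(a, b, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)``.

    When both samples have at most ``exact_max_n`` observations, the exact
    permutation p-value is computed by enumerating all C(n_a+n_b, n_a)
    group labelings of the pooled midranks (ties handled naturally):
    p = P(|U' - n_a n_b / 2| >= |U - n_a n_b / 2|).  Larger samples use
    the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    u_obs = _rank_sum_u(ranks, tuple(range(n_a)), n_a, n_b)

    if n_a <= exact_max_n and n_b <= exact_max_n:
        mu = n_a * n_b / 2.0
        dev_obs = abs(u_obs - mu)
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            u = _rank_sum_u(ranks, idx, n_a, n_b)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)
    return float(u_obs), min(1.0, p)


def compare_populations(populations: dict[str, list[ProfileFeatures]], reference: str,
                        alpha: float = 0.05, exact_max_n: int = 8) -> list[ComparisonResult]:
    """Test every non-reference population against the reference.

    Both features (membrane mean, MMR) are tested per population;
    ``alpha_corrected = alpha / n_comparisons`` with the denominator equal
    to the total number of tests in this batch (Bonferroni).
    """
    if reference not in populations:
        raise ValueError(f"unknown reference population {reference!r}")
    if len(populations) < 2:
        raise ValueError("need at least two populations to compare")
    others = [name for name in populations if name != reference]
    tests = []
    for name in others:
        for feature, getter in (("membrane_mean", lambda f: f.membrane_mean),
                                ("mmr", lambda f: f.mmr)):
            ref_vals = [getter(f) for f in populations[reference]]
            vals = [getter(f) for f in populations[name]]
            tests.append((name, feature, vals, ref_vals))
    n_comparisons = len(tests)
    alpha_corrected = alpha / n_comparisons
    results = []
    for name, feature, vals, ref_vals in tests:
        u, p = mann_whitney(vals, ref_vals, exact_max_n=exact_max_n)
        results.append(ComparisonResult(population=name, reference=reference, feature=feature,
                                        statistic=u, p_raw=p, alpha_corrected=alpha_corrected,
                                        n_comparisons=n_comparisons,
                                        significant=bool(p < alpha_corrected)))
    return results


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Corrected per-test significance threshold alpha / n_comparisons."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons
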