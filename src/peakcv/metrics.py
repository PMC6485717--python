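"""Group-level statistics on LOOCV scores: discrimination p-values,
label-randomization nulls, SD-based diagnostic cutoffs, sensitivity and
specificity, Cohen's d, noncentral-t power, and covariate R².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .loocv import LoocvConfig, LoocvScores, run_loocv, two_sample_t
from .spectra_io import CohortTable

__all__ = [
    "MetricsConfig",
    "ConfusionCounts",
    "TestMetrics",
    "group_discrimination_p",
    "randomize_labels",
    "randomization_test",
    "classification_cutoff",
    "compute_test_metrics",
    "cohens_d",
    "power_from_d",
    "covariate_r2",
]


@dataclass
class MetricsConfig:
    """Diagnostic-metric settings.

    sd_multiplier    SD multiple k for the score cutoff (default 2.28):
                     candidates mean_target - k*SD_target and
                     mean_other + k*SD_other, combined at their midpoint
    alpha            significance level for power computations
    n_randomizations number of label permutations in the randomization test
    seed             RNG seed for label permutations
    age_bins         optional bin edges; permutation is stratified within bins
    """

    sd_multiplier: float = 2.28
    alpha: float = 0.05
    n_randomizations: int = 1
    seed: int = 0
    age_bins: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class TestMetrics:
    """Diagnostic summary of a binary LOOCV score comparison at one cutoff."""

    cutoff: float
    counts: ConfusionCounts
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "cutoff": self.cutoff,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


# ---------------------------------------------------------------------------
# group-level discrimination
# ---------------------------------------------------------------------------

def group_discrimination_p(
    scores: LoocvScores, pooled: bool = False, two_tailed: bool = False
) -> float:
    """P-value for separating the two groups' per-sample LOOCV scores.

    One-tailed Welch t-test by default, tail in the direction of the observed
    mean difference (0.5 when the group means coincide).
    """
    t_vals = scores.group_values(scores.target_group)
    o_vals = scores.group_values(scores.other_group)
    if len(t_vals) < 2 or len(o_vals) < 2:
        raise ValueError("each group needs at least 2 scores")
    t, _, p_one = two_sample_t(t_vals[:, None], o_vals[:, None], pooled=pooled)
    p_one = float(p_one[0])
    if math.isnan(p_one):  # identical constant scores in both groups
        if float(t_vals.mean()) == float(o_vals.mean()):
            return 0.5 if not two_tailed else 1.0
        return 0.0
    return min(1.0, 2.0 * p_one) if two_tailed else p_one


# ---------------------------------------------------------------------------
# randomization null
# ---------------------------------------------------------------------------

def randomize_labels(
    table: CohortTable,
    seed: int | np.random.Generator,
    age_bins: Sequence[float] | None = None,
) -> CohortTable:
    """Permute group labels uniformly over size-preserving assignments.

    With ``age_bins`` (bin edges in years) the permutation is stratified:
    labels are shuffled only within each age bin, preserving the group/age
    composition of the cohort.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = table.samples["group"].to_numpy().copy()
    if age_bins is None:
        labels = labels[rng.permutation(len(labels))]
    else:
        ages = table.samples["age"].to_numpy(dtype=float)
        if np.isnan(ages).any():
            raise ValueError("age-stratified randomization requires ages for all samples")
        bins = np.digitize(ages, np.asarray(age_bins, dtype=float))
        for b in np.unique(bins):
            idx = np.flatnonzero(bins == b)
            labels[idx] = labels[idx[rng.permutation(idx.size)]]
    return table.with_groups(labels)


def randomization_test(
    table: CohortTable,
    config: LoocvConfig,
    metrics: MetricsConfig,
) -> np.ndarray:
    """Group p-values after label randomization.

    Each of ``metrics.n_randomizations`` permutations gets the identical
    LOOCV analysis (per-iteration peak selection, PCV scoring) followed by
    :func:`group_discrimination_p`; the array of randomized-label p-values is
    returned.  A non-significant randomized p alongside a significant
    true-label p argues against over-fitting.
    """
    rng = np.random.default_rng(metrics.seed)
    out = np.empty(metrics.n_randomizations, dtype=float)
    for k in range(metrics.n_randomizations):
        shuffled = randomize_labels(table, rng, age_bins=metrics.age_bins)
        out[k] = group_discrimination_p(run_loocv(shuffled, config))
    return out


# ---------------------------------------------------------------------------
# diagnostic cutoff and confusion counts
# ---------------------------------------------------------------------------

def classification_cutoff(scores: LoocvScores, metrics: MetricsConfig) -> float:
    """Single score cutoff from the two SD-based candidates.

    candidate_high = mean_target − k·SD_target and
    candidate_low  = mean_other  + k·SD_other (k = ``sd_multiplier``);
    the cutoff drawn as one line is their midpoint.
    """
    s = scores.summary()
    k = metrics.sd_multiplier
    cand_high = s["mean_target"] - k * s["sd_target"]
    cand_low = s["mean_other"] + k * s["sd_other"]
    return 0.5 * (cand_high + cand_low)


def compute_test_metrics(scores: LoocvScores, cutoff: float) -> TestMetrics:
    """Confusion counts, sensitivity and specificity at a score cutoff.

    Target-group samples scoring strictly above the cutoff are true
    positives; other-group samples at or below it are true negatives.
    """
    t_vals = scores.group_values(scores.target_group)
    o_vals = scores.group_values(scores.other_group)
    tp = int((t_vals > cutoff).sum())
    fn = len(t_vals) - tp
    fp = int((o_vals > cutoff).sum())
    tn = len(o_vals) - fp
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return TestMetrics(
        cutoff=float(cutoff),
        counts=counts,
        sensitivity=tp / counts.n_positive,
        specificity=tn / counts.n_negative,
    )


# ---------------------------------------------------------------------------
# effect size, power, covariates
# ---------------------------------------------------------------------------

def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Cohen's d with the (n−1)-weighted pooled standard deviation."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both standard deviations are zero")
    pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return (mean1 - mean2) / pooled


def power_from_d(
    d: float, n1: int, n2: int, alpha: float = 0.05, two_tailed: bool = True
) -> float:
    """Two-sample t-test power at effect size ``d`` via the noncentral t.

    Noncentrality d·sqrt(n1·n2/(n1+n2)) on n1+n2−2 degrees of freedom; at
    d = 0 the power equals alpha by construction.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    nc = d * math.sqrt(n1 * n2 / (n1 + n2))

    def _tail(v: float) -> float:
        # scipy's noncentral t returns NaN in the far tail at large |nc|,
        # where the true mass is numerically zero
        return 0.0 if math.isnan(v) else float(v)

    if two_tailed:
        crit = stats.t.ppf(1 - alpha / 2, df)
        return _tail(stats.nct.sf(crit, df, nc)) + _tail(stats.nct.cdf(-crit, df, nc))
    crit = stats.t.ppf(1 - alpha, df)
    return _tail(stats.nct.sf(crit, df, nc))


def scores_cohens_d(scores: LoocvScores) -> float:
    """Cohen's d of the two per-sample LOOCV score distributions."""
    t = scores.group_values(scores.target_group)
    o = scores.group_values(scores.other_group)
    return cohens_d(
        float(t.mean()), float(t.std(ddof=1)), len(t),
        float(o.mean()), float(o.std(ddof=1)), len(o),
    )


def covariate_r2(scores: LoocvScores, covariate: str) -> float:
    """R² of the OLS regression of per-sample scores on one covariate.

    ``covariate`` names a column of the score frame (``age`` or a
    ``covariate:*`` column carried over from the cohort table).
    """
    frame = scores.scores
    if covariate not in frame.columns:
        raise KeyError(f"covariate {covariate!r} not in score frame")
    x = pd.to_numeric(frame[covariate], errors="raise").to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError(f"covariate {covariate!r} missing for some samples")
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    y = frame["pct_target"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return 0.0
    return float(stats.linregress(x, y).rvalue ** 2)
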