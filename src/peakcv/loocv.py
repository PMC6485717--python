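"""Leave-one-sample-out cross-validated mass-peak classification.

For each left-out serum sample, every integer m/Z peak is tested for a group
difference on the left-in samples with a one-tailed unequal-variance (Welch)
t-test at p < alpha; each significant peak gets a Peak Classification Value
(PCV) at the midpoint of the two left-in group mean areas.  The left-out
sample's area at that m/Z is assigned to the higher-mean group if it exceeds
the PCV, otherwise (ties included) to the lower-mean group, and the sample's
score is the percentage of significant peaks assigned to the designated
target group.  Selection and PCVs are recomputed from scratch for every
left-out sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import CohortTable, DegenerateAnalysisError, SampleProfile

__all__ = [
    "PeakRule",
    "LoocvConfig",
    "LoocvScores",
    "two_sample_t",
    "select_significant_peaks",
    "classify_peak",
    "score_sample",
    "run_loocv",
]


@dataclass(frozen=True)
class PeakRule:
    """Decision rule for one significant m/Z peak.

    ``pcv`` is the area midpoint between the two group means; an area strictly
    above it classifies as ``higher_group``, at or below as ``lower_group``.
    """

    mz: int
    p_value: float
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    higher_group: str

    @property
    def pcv(self) -> float:
        return 0.5 * (self.mean_a + self.mean_b)

    @property
    def lower_group(self) -> str:
        return self.group_b if self.higher_group == self.group_a else self.group_a


@dataclass
class LoocvConfig:
    """Peak-selection settings.

    alpha         per-peak significance level for the one-tailed test
    target_group  group whose classified-peak percentage is reported
    pooled        use pooled-variance instead of Welch (unequal-variance) t
    two_tailed    select on the two-tailed p instead of the directed one-tailed p
    """

    target_group: str
    alpha: float = 0.05
    pooled: bool = False
    two_tailed: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class LoocvScores:
    """Per-sample LOOCV scores: % of rules classified to the target group."""

    scores: pd.DataFrame  # index sample_id; true_group, n_rules, pct_target (+covariates)
    target_group: str
    other_group: str

    def group_values(self, group: str) -> np.ndarray:
        return self.scores.loc[
            self.scores["true_group"] == group, "pct_target"
        ].to_numpy()

    def summary(self) -> dict[str, float]:
        t = self.group_values(self.target_group)
        o = self.group_values(self.other_group)
        return {
            "mean_target": float(t.mean()),
            "sd_target": float(t.std(ddof=1)),
            "mean_other": float(o.mean()),
            "sd_other": float(o.std(ddof=1)),
        }


# ---------------------------------------------------------------------------
# the per-peak test
# ---------------------------------------------------------------------------

def two_sample_t(
    xa: np.ndarray, xb: np.ndarray, pooled: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise two-sample t test of ``xa`` (n_a x m) vs ``xb`` (n_b x m).

    Returns ``(t, df, p_one)`` where ``p_one`` is the one-tailed p in the
    direction of the observed mean difference (half the two-tailed p whenever
    the means differ).  Welch-Satterthwaite degrees of freedom by default;
    ``pooled=True`` gives the equal-variance Student test.  Columns with zero
    standard error yield NaN.
    """
    xa = np.atleast_2d(np.asarray(xa, dtype=float))
    xb = np.atleast_2d(np.asarray(xb, dtype=float))
    na, nb = xa.shape[0], xb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va, vb = xa.var(axis=0, ddof=1), xb.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if pooled:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se2 = sp2 * (1.0 / na + 1.0 / nb)
            df = np.full(se2.shape, float(na + nb - 2))
        else:
            ua, ub = va / na, vb / nb
            se2 = ua + ub
            df = se2**2 / (ua**2 / (na - 1) + ub**2 / (nb - 1))
        t = (ma - mb) / np.sqrt(se2)
        p_one = stats.t.sf(np.abs(t), df)
    p_one = np.where(se2 > 0, p_one, np.nan)
    return t, df, p_one


def _rule_arrays(
    xa: np.ndarray, xb: np.ndarray, config: LoocvConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized peak selection.

    Returns ``(cols, pcv, higher_is_a, p)`` over the selected column indices.
    Peaks with equal group means or zero pooled variability are excluded.
    """
    t, _, p_one = two_sample_t(xa, xb, pooled=config.pooled)
    p = 2.0 * p_one if config.two_tailed else p_one
    ma, mb = np.atleast_2d(xa).mean(axis=0), np.atleast_2d(xb).mean(axis=0)
    with np.errstate(invalid="ignore"):
        sig = np.isfinite(p) & (p < config.alpha) & (ma != mb)
    cols = np.flatnonzero(sig)
    return cols, 0.5 * (ma[cols] + mb[cols]), ma[cols] > mb[cols], p[cols]


def _binary_split(
    table: CohortTable, config: LoocvConfig
) -> tuple[str, str, np.ndarray, np.ndarray]:
    a, b = table.require_binary()
    if config.target_group not in (a, b):
        raise ValueError(
            f"target_group {config.target_group!r} not among groups {(a, b)}"
        )
    if config.target_group == b:
        a, b = b, a  # group A is always the target for internal bookkeeping
    labels = table.samples["group"].to_numpy()
    return a, b, labels, table.areas.to_numpy(dtype=float)


def select_significant_peaks(
    table: CohortTable,
    exclude: str | None = None,
    config: LoocvConfig | None = None,
) -> list[PeakRule]:
    """Significant-peak rules on the cohort, optionally excluding one sample.

    One :class:`PeakRule` per m/Z whose one-tailed Welch p on the left-in
    samples falls below ``config.alpha``; its PCV is the midpoint of the two
    left-in group means.
    """
    if config is None:
        raise ValueError("config with target_group is required")
    a, b, labels, X = _binary_split(table, config)
    keep = np.ones(len(labels), dtype=bool)
    if exclude is not None:
        keep = table.samples.index.to_numpy() != exclude
        if keep.all():
            raise KeyError(f"sample {exclude!r} not in table")
    xa, xb = X[keep & (labels == a)], X[keep & (labels == b)]
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each group must retain at least 2 samples after exclusion")
    cols, pcv, higher_a, p = _rule_arrays(xa, xb, config)
    mz = np.asarray(table.areas.columns)
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    return [
        PeakRule(
            mz=int(mz[c]),
            p_value=float(p[i]),
            group_a=a,
            group_b=b,
            mean_a=float(ma[c]),
            mean_b=float(mb[c]),
            higher_group=a if higher_a[i] else b,
        )
        for i, c in enumerate(cols)
    ]


def classify_peak(area: float, rule: PeakRule) -> str:
    """Assign one peak area: above the PCV -> higher-mean group, else lower."""
    return rule.higher_group if area > rule.pcv else rule.lower_group


def score_sample(
    profile: SampleProfile | pd.Series,
    rules: Sequence[PeakRule],
    target_group: str,
) -> float:
    """% of rules whose PCV classification assigns this sample to the target group."""
    if len(rules) == 0:
        sid = getattr(profile, "sample_id", getattr(profile, "name", "<sample>"))
        raise DegenerateAnalysisError(f"no significant peaks to score sample {sid!r}")
    areas = profile.areas if isinstance(profile, SampleProfile) else profile
    hits = sum(
        1 for r in rules if classify_peak(float(areas.loc[r.mz]), r) == target_group
    )
    return 100.0 * hits / len(rules)


def run_loocv(table: CohortTable, config: LoocvConfig) -> LoocvScores:
    """Strict leave-one-sample-out loop over a binary cohort.

    For every sample, significant peaks and their PCVs are recomputed on the
    remaining samples and the left-out sample is scored against those rules.
    """
    a, b, labels, X = _binary_split(table, config)
    is_a = labels == a
    n = len(labels)
    n_rules = np.empty(n, dtype=np.int64)
    pct = np.empty(n, dtype=float)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        xa, xb = X[keep & is_a], X[keep & ~is_a]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(
                "each group must retain at least 2 samples after exclusion"
            )
        cols, pcv, higher_a, _ = _rule_arrays(xa, xb, config)
        if cols.size == 0:
            raise DegenerateAnalysisError(
                f"no significant peaks when leaving out {table.samples.index[i]!r}"
            )
        assigned_target = (X[i, cols] > pcv) == higher_a
        n_rules[i] = cols.size
        pct[i] = 100.0 * int(assigned_target.sum()) / cols.size
    frame = pd.DataFrame(
        {"true_group": labels, "n_rules": n_rules, "pct_target": pct},
        index=table.samples.index.copy(),
    )
    extra = [c for c in table.samples.columns if c != "group"]
    frame = frame.join(table.samples[extra])
    return LoocvScores(scores=frame, target_group=a, other_group=b)
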