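"""Synthetic two-group spectra cohorts with known discriminatory structure.

The generator emulates the study design end to end: two groups of subjects
(default 21 vs 20, matching the size of the most-affected vs control
comparison), triplicate spectra per subject on the integer m/Z grid 400-2000,
log-normal peak areas with a configurable subset of group-discriminatory
peaks whose log-mean is shifted in one group, and multiplicative replicate
noise.  Truth (which m/Z are discriminatory) is recorded so that peak
recovery can be measured.

The model: a baseline log-area is drawn once per m/Z; each subject's log-area
is baseline + group shift (``effect_delta * between_sample_sigma`` at
discriminatory m/Z, group B only) + N(0, between_sample_sigma) subject noise;
each replicate scales the whole spectrum by a log-normal per-acquisition
intensity factor (instrument response drift — the thing segment normalization
is there to cancel) and multiplies each area by (1 + replicate_cv * N(0,1)),
truncated at zero.  A dominant high-abundance envelope — a contiguous block
of very large, low-variance peaks standing in for the serum albumin /
immunoglobulin charge-state envelope — pins the maximum 10-m/Z segment, so
the normalizer is a stable reference.  Everything is deterministic for a
given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import spectra_io
from .loocv import PeakRule
from .spectra_io import CohortTable, mz_grid

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "TruthMetrics",
    "simulate_cohort",
    "cohort_to_table",
    "simulate_table",
    "truth_metrics",
]


@dataclass
class SimConfig:
    """Cohort-generator settings (defaults mirror the study conditions).

    n_group_a/n_group_b   subjects per group (21 control vs 20 is the scale
                          of the main most-affected vs control comparison)
    n_discriminatory      m/Z bins whose group-B log-mean is shifted
    effect_delta          shift in units of between_sample_sigma
    between_sample_sigma  SD of log peak area across subjects
    replicate_cv          multiplicative noise across the triplicates
    acquisition_scale_sd  log-SD of the per-acquisition global intensity
                          factor that segment normalization removes
    n_dominant            width (bins) of the dominant high-abundance
                          envelope; 0 disables it
    dominant_log_boost    log-area excess of dominant over ordinary peaks
    dominant_sigma        between-subject log-SD of dominant peaks
    baseline_log_mean/sd  distribution of per-m/Z baseline log areas
    age_range             uniform age draw, years
    """

    n_group_a: int = 21
    n_group_b: int = 20
    mz_min: int = spectra_io.MZ_MIN
    mz_max: int = spectra_io.MZ_MAX
    n_discriminatory: int = 200
    effect_delta: float = 1.5
    between_sample_sigma: float = 0.5
    replicate_cv: float = 0.1
    acquisition_scale_sd: float = 0.3
    n_replicates: int = 3
    n_dominant: int = 12
    dominant_log_boost: float = 4.0
    dominant_sigma: float = 0.1
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    age_range: tuple[float, float] = (22.0, 62.0)
    group_a: str = "control"
    group_b: str = "case"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.mz_max <= self.mz_min:
            raise ValueError("mz_max must exceed mz_min")
        n_bins = self.mz_max - self.mz_min + 1
        if not 0 <= self.n_discriminatory <= n_bins - self.n_dominant:
            raise ValueError("n_discriminatory outside [0, number of free m/Z bins]")
        if self.effect_delta < 0:
            raise ValueError("effect_delta must be >= 0")
        if self.between_sample_sigma <= 0:
            raise ValueError("between_sample_sigma must be > 0")
        if self.replicate_cv < 0 or self.n_replicates < 1:
            raise ValueError("invalid replicate settings")
        if self.acquisition_scale_sd < 0 or self.dominant_sigma < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 <= self.n_dominant <= n_bins:
            raise ValueError("n_dominant outside [0, number of m/Z bins]")


@dataclass
class SimulatedCohort:
    """Generated replicate spectra plus ground truth."""

    config: SimConfig
    sample_ids: list[str]
    groups: list[str]
    ages: np.ndarray
    replicates: np.ndarray  # (n_samples, n_replicates, n_bins) binned intensities
    true_discriminatory_mz: set[int]

    @property
    def grid(self) -> np.ndarray:
        return mz_grid(self.config.mz_min, self.config.mz_max)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw one synthetic cohort of triplicate binned spectra."""
    rng = np.random.default_rng(config.seed)
    grid = mz_grid(config.mz_min, config.mz_max)
    n_bins = grid.size
    n = config.n_group_a + config.n_group_b
    groups = [config.group_a] * config.n_group_a + [config.group_b] * config.n_group_b
    sample_ids = [f"{g}{i + 1:02d}" for i, g in enumerate(groups)]

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_bins)
    sigma = np.full(n_bins, config.between_sample_sigma)
    if config.n_dominant:
        # dominant envelope on a segment-aligned block so it always pins
        # (at least) one full 10-m/Z segment of the normalizer
        n_starts = max(1, (n_bins - config.n_dominant) // spectra_io.SEGMENT_WIDTH + 1)
        d0 = int(rng.integers(n_starts)) * spectra_io.SEGMENT_WIDTH
        dom = slice(d0, d0 + config.n_dominant)
        baseline[dom] = config.baseline_log_mean + config.dominant_log_boost
        sigma[dom] = config.dominant_sigma
        free = np.concatenate([np.arange(d0), np.arange(d0 + config.n_dominant, n_bins)])
    else:
        free = np.arange(n_bins)
    disc_idx = rng.choice(free, size=config.n_discriminatory, replace=False)
    shift = np.zeros(n_bins)
    shift[disc_idx] = config.effect_delta * config.between_sample_sigma

    is_b = np.array([g == config.group_b for g in groups])
    log_areas = (
        baseline[None, :]
        + np.where(is_b[:, None], shift[None, :], 0.0)
        + sigma[None, :] * rng.normal(0.0, 1.0, size=(n, n_bins))
    )
    areas = np.exp(log_areas)
    acq = np.exp(
        rng.normal(0.0, config.acquisition_scale_sd, size=(n, config.n_replicates))
    )
    noise = rng.normal(0.0, 1.0, size=(n, config.n_replicates, n_bins))
    replicates = np.clip(
        areas[:, None, :] * acq[:, :, None] * (1.0 + config.replicate_cv * noise),
        0.0,
        None,
    )
    ages = rng.uniform(*config.age_range, size=n)
    return SimulatedCohort(
        config=config,
        sample_ids=sample_ids,
        groups=groups,
        ages=ages,
        replicates=replicates,
        true_discriminatory_mz={int(m) for m in grid[disc_idx]},
    )


def cohort_to_table(
    cohort: SimulatedCohort,
    normalize: bool = True,
    segment_width: int = spectra_io.SEGMENT_WIDTH,
    norm_mode: str = "global",
) -> CohortTable:
    """Normalize each replicate spectrum, average per subject, assemble a table.

    Mirrors the processing order applied to acquisitions: segment
    normalization of every replicate first, replicate averaging second.
    """
    cfg = cohort.config
    profiles = []
    for i, sid in enumerate(cohort.sample_ids):
        reps = cohort.replicates[i]
        if normalize:
            reps = [
                spectra_io.normalize_segments(r, segment_width, mode=norm_mode)
                for r in reps
            ]
        mean_areas = spectra_io.average_replicates(list(reps))
        profiles.append(
            spectra_io.SampleProfile(
                sample_id=sid,
                group=cohort.groups[i],
                areas=pd.Series(mean_areas, index=cohort.grid),
                age=float(cohort.ages[i]),
            )
        )
    return spectra_io.cohort_from_profiles(profiles)


def simulate_table(config: SimConfig, normalize: bool = True) -> CohortTable:
    """Convenience: :func:`simulate_cohort` followed by :func:`cohort_to_table`."""
    return cohort_to_table(simulate_cohort(config), normalize=normalize)


@dataclass(frozen=True)
class TruthMetrics:
    """Recovery of the planted discriminatory peaks by a rule set."""

    n_true: int
    n_selected: int
    n_overlap: int
    recall: float | None    # None when no peaks were planted
    precision: float | None  # None when no rules were selected


def truth_metrics(
    cohort: SimulatedCohort, rules: Sequence[PeakRule]
) -> TruthMetrics:
    """Recall and precision of discriminatory-peak recovery by ``rules``."""
    selected = {r.mz for r in rules}
    true = cohort.true_discriminatory_mz
    overlap = len(selected & true)
    return TruthMetrics(
        n_true=len(true),
        n_selected=len(selected),
        n_overlap=overlap,
        recall=overlap / len(true) if true else None,
        precision=overlap / len(selected) if selected else None,
    )
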