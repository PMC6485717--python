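"""Blinded validation: fit rules and a cutoff on a training cohort, then
score held-out (blinded) samples against that fixed model.

The training rules come from significant-peak selection on *all* training
samples (no exclusion); the score cutoff comes from the SD-based
classification cutoff of the training cohort's own LOOCV scores.  Blind
samples never influence rule selection or the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .loocv import (
    LoocvConfig,
    LoocvScores,
    PeakRule,
    run_loocv,
    score_sample,
    select_significant_peaks,
)
from .metrics import MetricsConfig, classification_cutoff
from .spectra_io import CohortTable, DegenerateAnalysisError, SampleProfile

__all__ = ["TrainedModel", "BlindResult", "hold_out", "fit_trained_model", "score_blinds"]


@dataclass
class TrainedModel:
    rules: list[PeakRule]
    target_group: str
    other_group: str
    cutoff: float
    training_scores: LoocvScores


@dataclass
class BlindResult:
    """Scores and verdicts for blinded samples against a trained model."""

    results: pd.DataFrame  # index sample_id; pct_target, predicted_group [, true_group, correct]
    cutoff: float
    n_correct: int | None = None
    n_total: int | None = None


def hold_out(
    table: CohortTable,
    blind_ids: Sequence[str] | None = None,
    n_per_group: dict[str, int] | None = None,
    seed: int | None = None,
) -> tuple[CohortTable, CohortTable]:
    """Split a cohort into disjoint training and blinded sets.

    Either name the blinded samples explicitly (``blind_ids``) or request a
    random draw of ``n_per_group`` samples per group with a ``seed``.
    """
    all_ids = list(table.samples.index)
    if blind_ids is not None:
        blind = list(blind_ids)
        unknown = set(blind) - set(all_ids)
        if unknown:
            raise KeyError(f"blind_ids not in table: {sorted(unknown)}")
    elif n_per_group is not None:
        rng = np.random.default_rng(seed)
        blind = []
        groups = table.samples["group"]
        for g, k in n_per_group.items():
            members = list(groups.index[groups == g])
            if k > len(members):
                raise ValueError(
                    f"requested {k} blinds from group {g!r} with only {len(members)} samples"
                )
            blind.extend(rng.choice(members, size=k, replace=False))
    else:
        blind = []
    train_ids = [s for s in all_ids if s not in set(blind)]
    return table.subset(train_ids), table.subset(blind)


def fit_trained_model(
    training: CohortTable, config: LoocvConfig, metrics: MetricsConfig
) -> TrainedModel:
    """Select rules on the full training table and place the score cutoff.

    Rules use PCVs from the training group means; the cutoff comes from the
    training table's own LOOCV score distributions.
    """
    rules = select_significant_peaks(training, exclude=None, config=config)
    if not rules:
        raise DegenerateAnalysisError("no significant peaks in training table")
    training_scores = run_loocv(training, config)
    cutoff = classification_cutoff(training_scores, metrics)
    return TrainedModel(
        rules=rules,
        target_group=config.target_group,
        other_group=training_scores.other_group,
        cutoff=float(cutoff),
        training_scores=training_scores,
    )


def score_blinds(
    model: TrainedModel,
    blinds: CohortTable | Sequence[SampleProfile],
    truth: dict[str, str] | None = None,
    cutoff: float | None = None,
) -> BlindResult:
    """Score blinded samples against fixed training rules and cutoff.

    Each blind sample's % of target-classified rules is compared with the
    cutoff: strictly above predicts the target group.  When true labels are
    supplied (directly, or present in a blind cohort table), correctness is
    tallied.
    """
    if isinstance(blinds, CohortTable):
        profiles = list(blinds.profiles())
        if truth is None and blinds.samples["group"].notna().all():
            truth = blinds.samples["group"].to_dict()
    else:
        profiles = list(blinds)
    use_cutoff = model.cutoff if cutoff is None else float(cutoff)
    rows = {}
    for p in profiles:
        pct = score_sample(p, model.rules, model.target_group)
        pred = model.target_group if pct > use_cutoff else model.other_group
        rows[p.sample_id] = {"pct_target": pct, "predicted_group": pred}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    n_correct = n_total = None
    if truth is not None and len(frame):
        frame["true_group"] = [truth.get(s) for s in frame.index]
        frame["correct"] = frame["true_group"] == frame["predicted_group"]
        n_correct = int(frame["correct"].sum())
        n_total = int(len(frame))
    return BlindResult(results=frame, cutoff=use_cutoff, n_correct=n_correct, n_total=n_total)
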