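"""Evaluation of predicted against observed QTc triplets.

A study is summarised by a triplet of mean QTc values — baseline (BL),
victim drug alone (T) and victim plus inhibitor (T+I) — on the observed
side and on the predicted side (one triplet per interaction model).  With
within-source baseline subtraction, ΔT = T − BL and ΔTI = (T+I) − BL, the
goodness of fit is the distance

    D = sqrt( (ΔT_pred − ΔT_obs)²
            + (ΔTI_pred − ΔTI_obs)²
            + ((ΔTI_pred − ΔT_pred) − (ΔTI_obs − ΔT_obs))² )   [ms]

which weighs the two treatment effects and the incremental effect of
adding the inhibitor.  The layer also provides a Welch unequal-variance
t-test for observed-vs-predicted ΔQTcB comparisons, model ranking by D,
and counting of subjects for whom the choice of interaction model flips
the 5-ms regulatory-threshold verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interaction import InteractionModel

__all__ = [
    "ThresholdPolicy",
    "StudyComparison",
    "distance",
    "distance_from_deltas",
    "welch_t",
    "count_flips",
    "best_model",
    "evaluate_table",
]

#: Fixed model order used for reporting and tie-breaking.
MODEL_ORDER = (InteractionModel.SUM, InteractionModel.BLISS, InteractionModel.LOEWE)


@dataclass(frozen=True)
class ThresholdPolicy:
    """QTc-prolongation level of regulatory concern; default 5 ms."""

    threshold_ms: float = 5.0

    def __post_init__(self) -> None:
        if not self.threshold_ms > 0:
            raise ValueError("threshold must be > 0 ms")


def distance_from_deltas(
    d_t_obs: float, d_ti_obs: float, d_t_pred: float, d_ti_pred: float
) -> float:
    """Distance D from already baseline-subtracted ΔT and ΔT+I values (ms)."""
    vals = (d_t_obs, d_ti_obs, d_t_pred, d_ti_pred)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"all deltas must be finite, got {vals}")
    term1 = d_t_pred - d_t_obs
    term2 = d_ti_pred - d_ti_obs
    term3 = (d_ti_pred - d_t_pred) - (d_ti_obs - d_t_obs)
    return math.sqrt(term1 * term1 + term2 * term2 + term3 * term3)


def distance(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Distance D between an observed and a predicted (BL, T, T+I) triplet.

    Deltas are taken within each source (predicted deltas against the
    predicted baseline, observed against the observed), so D is invariant
    to adding a constant to either whole triplet.
    """
    obs = tuple(float(v) for v in obs)
    pred = tuple(float(v) for v in pred)
    if len(obs) != 3 or len(pred) != 3:
        raise ValueError("triplets must be (BL, T, T+I)")
    if not all(math.isfinite(v) for v in obs + pred):
        raise ValueError("all six triplet values must be finite")
    return distance_from_deltas(
        obs[1] - obs[0], obs[2] - obs[0], pred[1] - pred[0], pred[2] - pred[0]
    )


@dataclass(frozen=True)
class StudyComparison:
    """Observed vs per-model predicted triplets for one study, with D."""

    study: str
    obs_triplet: tuple[float, float, float]
    pred_triplets: Mapping[InteractionModel, tuple[float, float, float]]

    @property
    def distances(self) -> dict[InteractionModel, float]:
        return {m: distance(self.obs_triplet, p) for m, p in self.pred_triplets.items()}


def welch_t(obs_deltas: Sequence[float], pred_deltas: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided).

    Returns (t statistic, p value) with Welch–Satterthwaite degrees of
    freedom.  Requires at least two values per group and a nonzero pooled
    variance; fully degenerate input is rejected.
    """
    a = np.asarray(obs_deltas, dtype=float)
    b = np.asarray(pred_deltas, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("degenerate input: both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def count_flips(
    per_subject: pd.DataFrame | Mapping[str, Sequence[float]],
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> float:
    """Percentage of subjects for whom model choice flips the threshold verdict.

    ``per_subject``: one row per subject, one column per interaction model,
    values ΔQTcB (ms).  A subject is a case iff the models straddle the
    threshold: min over models < threshold <= max over models.  Returns
    100 · cases / subjects.
    """
    df = pd.DataFrame(per_subject)
    if df.empty:
        raise ValueError("no subjects provided")
    if df.isna().any().any():
        raise ValueError("every subject needs a ΔQTcB for every model")
    lo = df.min(axis=1)
    hi = df.max(axis=1)
    cases = (lo < policy.threshold_ms) & (hi >= policy.threshold_ms)
    return float(100.0 * cases.sum() / len(df))


def best_model(distances: Mapping[InteractionModel | str, float]) -> list[InteractionModel]:
    """Models sorted by ascending D; ties broken SUM, BLISS, LOEWE."""
    norm: dict[InteractionModel, float] = {}
    for key, val in distances.items():
        model = key if isinstance(key, InteractionModel) else InteractionModel(key)
        norm[model] = float(val)
    if not norm:
        raise ValueError("need at least one model distance")
    return sorted(norm, key=lambda m: (norm[m], MODEL_ORDER.index(m)))


def evaluate_table(table2: pd.DataFrame) -> pd.DataFrame:
    """Recompute D for every study/model in a bundled observed-vs-predicted table.

    Expects the tidy layout written by :func:`qtddi.fixtures.make_fixtures`
    (columns: study, arm, observed, pred_sum, pred_bliss, pred_loewe,
    delta_only).  Studies whose observations were published only as QT
    changes (delta_only flag) use those changes directly as ΔT and ΔT+I.
    Returns one row per study with recomputed distances and the best model.
    """
    rows = []
    for study, g in table2.groupby("study", sort=False):
        g = g.set_index("arm")
        delta_only = bool(g["delta_only"].any())
        pred_cols = {"sum": "pred_sum", "bliss": "pred_bliss", "loewe": "pred_loewe"}
        dists: dict[str, float] = {}
        for model, col in pred_cols.items():
            pred = (g.loc["BL", col], g.loc["T", col], g.loc["T+I", col])
            if delta_only:
                d = distance_from_deltas(
                    g.loc["T", "observed"],
                    g.loc["T+I", "observed"],
                    pred[1] - pred[0],
                    pred[2] - pred[0],
                )
            else:
                obs = (g.loc["BL", "observed"], g.loc["T", "observed"], g.loc["T+I", "observed"])
                d = distance(obs, pred)
            dists[model] = d
        ranked = best_model(dists)
        rows.append(
            {
                "study": study,
                "D_sum": dists["sum"],
                "D_bliss": dists["bliss"],
                "D_loewe": dists["loewe"],
                "best_model": ranked[0].value,
            }
        )
    return pd.DataFrame(rows)
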