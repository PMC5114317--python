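"""Replicate virtual QT trials.

One trial replicate: sample a virtual population's PK parameters, generate
per-subject heart-tissue exposure for each arm (BL, victim alone T,
inhibitor alone I, combination T+I), convert the concentration at the
victim's Tmax to per-channel block via the Hill model, combine the two
drugs' block per interaction model for the T+I arm, run the transmural
strand for each distinct block vector and read off QTcB from the
pseudoECG.  ΔQTcB is baseline-subtracted per subject; the same subject
(same PK draw) is carried across all arms and models, so differences are
paired.  Replicates re-draw the population from seeds derived from the
master seed by a fixed increment, making every run reproducible.

Strand simulations are memoized on the (rounded) block vector within a
run — arms or models that induce identical block do not pay for a second
simulation, and a drug-free arm is simulated exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interaction import (
    ChannelInhibitionVector,
    HillParams,
    InteractionModel,
    block_from_concentration,
    combine_channels,
)
from .pk import ExposureModifier, PKParams, apply_interaction, pk_profile, sample_population
from .strand import StrandConfig, strand_qtcb
from .units import ngml_to_um

logger = logging.getLogger(__name__)

__all__ = ["TrialDesign", "TrialResult", "run_trial", "summarize"]

ALL_ARMS = ("BL", "T", "I", "T+I")

#: seeds are split master + _SEED_STRIDE * replicate (kept below 2**31)
_SEED_STRIDE = 1009


@dataclass(frozen=True)
class TrialDesign:
    """Design of one replicated virtual study.

    ``conc_sampling`` selects the representative concentration driving the
    block: 'tmax' (concentration at the victim's Tmax — the default,
    worst-case static coupling) or 'profile_max' (maximum of the sampled
    grid, equivalent for closed-form profiles).
    """

    study: str
    n_subjects: int = 6
    n_replicates: int = 10
    arms: tuple[str, ...] = ("BL", "T", "I", "T+I")
    models: tuple[InteractionModel, ...] = (
        InteractionModel.SUM,
        InteractionModel.BLISS,
        InteractionModel.LOEWE,
    )
    population_cv: float = 0.3
    conc_sampling: str = "tmax"
    master_seed: int = 0
    strand: StrandConfig = field(default_factory=StrandConfig.scaled_down)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_replicates < 1:
            raise ValueError("need at least one subject and one replicate")
        unknown = set(self.arms) - set(ALL_ARMS)
        if unknown:
            raise ValueError(f"unknown arms {sorted(unknown)}")
        if not {"BL", "T+I"} <= set(self.arms):
            raise ValueError("arms must include BL and T+I")
        if self.conc_sampling not in ("tmax", "profile_max"):
            raise ValueError("conc_sampling must be 'tmax' or 'profile_max'")
        if not self.models:
            raise ValueError("at least one interaction model is required")


@dataclass(frozen=True)
class TrialResult:
    """Tidy per-(replicate, subject, arm, model) QTcB and ΔQTcB in ms.

    ``model`` is the interaction-model name for the T+I arm and 'none' for
    the single-drug and baseline arms (whose block does not depend on it).
    """

    design: TrialDesign
    data: pd.DataFrame

    def pivot_models(self, arm: str = "T+I") -> pd.DataFrame:
        """Per-(replicate, subject) ΔQTcB with one column per model."""
        sub = self.data[self.data["arm"] == arm]
        return sub.pivot_table(
            index=["replicate", "subject"], columns="model", values="dqtcb_ms"
        )


class _StrandCache:
    """Memoizes strand QTcB on the rounded block vector."""

    def __init__(self, config: StrandConfig):
        self.config = config
        self._cache: dict[tuple, float] = {}

    def qtcb(self, block: ChannelInhibitionVector) -> float:
        key = tuple(np.round(block.as_array(), 9))
        if key not in self._cache:
            self._cache[key] = strand_qtcb(self.config, block).qtcb_ms
        return self._cache[key]


def _representative_conc_um(profile, design: TrialDesign) -> float:
    conc = profile.conc_uM
    if design.conc_sampling == "tmax":
        return float(conc[int(np.argmax(profile.conc_ngml))])
    return float(conc.max())


def run_trial(
    design: TrialDesign,
    victim_pk: PKParams,
    victim_channels: Mapping[str, HillParams],
    perpetrator_pk: PKParams,
    perpetrator_channels: Mapping[str, HillParams],
    modifier: ExposureModifier,
    time_grid_h: np.ndarray | None = None,
) -> TrialResult:
    """Run every replicate of the study described by ``design``.

    The victim and perpetrator need complete PK parameters; per-channel
    Hill parameters may be sparse (missing channel = no block).  Raises on
    conduction failure with the offending replicate/subject identified.
    """
    times = np.linspace(0.0, 48.0, 481) if time_grid_h is None else np.asarray(time_grid_h)
    rows = []
    # the strand is deterministic given a block vector, so the memo is
    # shared across replicates and subjects
    cache = _StrandCache(design.strand)
    try:
        baseline_qtcb = cache.qtcb(ChannelInhibitionVector())
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"baseline strand simulation failed: {exc}") from exc
    for rep in range(design.n_replicates):
        seed = design.master_seed + _SEED_STRIDE * rep
        rng = np.random.default_rng(seed)
        victims = sample_population(victim_pk, design.n_subjects, design.population_cv, rng)
        perps = sample_population(perpetrator_pk, design.n_subjects, design.population_cv, rng)
        for subj in range(design.n_subjects):
            profile_t = pk_profile(victims[subj], times, subject=subj, arm="T")
            profile_ti = apply_interaction(profile_t, modifier)
            profile_i = pk_profile(perps[subj], times, subject=subj, arm="I")
            conc_t = _representative_conc_um(profile_t, design)
            conc_ti = _representative_conc_um(profile_ti, design)
            conc_i = _representative_conc_um(profile_i, design)
            block_t = block_from_concentration(conc_t, victim_channels)
            block_ti_victim = block_from_concentration(conc_ti, victim_channels)
            block_i = block_from_concentration(conc_i, perpetrator_channels)
            arm_blocks: list[tuple[str, str, ChannelInhibitionVector]] = []
            if "BL" in design.arms:
                arm_blocks.append(("BL", "none", ChannelInhibitionVector()))
            if "T" in design.arms:
                arm_blocks.append(("T", "none", block_t))
            if "I" in design.arms:
                arm_blocks.append(("I", "none", block_i))
            for model in design.models:
                combined = combine_channels(block_ti_victim, block_i, model)
                arm_blocks.append(("T+I", model.value, combined))
            for arm, model_name, block in arm_blocks:
                try:
                    qtcb = cache.qtcb(block)
                except Exception as exc:
                    raise RuntimeError(
                        f"replicate {rep}, subject {subj}, arm {arm}: strand failed: {exc}"
                    ) from exc
                rows.append(
                    {
                        "replicate": rep,
                        "subject": subj,
                        "arm": arm,
                        "model": model_name,
                        "qtcb_ms": qtcb,
                        "dqtcb_ms": qtcb - baseline_qtcb,
                    }
                )
        logger.info("replicate %d/%d done (%d strand runs)",
                    rep + 1, design.n_replicates, len(cache._cache))
    return TrialResult(design=design, data=pd.DataFrame(rows))


def summarize(result: TrialResult, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-(arm, model) mean QTcB and ΔQTcB with a t-distribution CI.

    Means are taken over subjects within each replicate, then over
    replicates; the CI is computed across replicate means (zero width when
    every replicate agrees or only one replicate was run).
    """
    if result.data.empty:
        raise ValueError("empty trial result")
    rep_means = (
        result.data.groupby(["arm", "model", "replicate"])[["qtcb_ms", "dqtcb_ms"]]
        .mean()
        .reset_index()
    )
    out_rows = []
    for (arm, model), g in rep_means.groupby(["arm", "model"]):
        n = len(g)
        mean_qt = g["qtcb_ms"].mean()
        mean_dqt = g["dqtcb_ms"].mean()
        if n > 1 and g["dqtcb_ms"].std(ddof=1) > 0:
            half = stats.t.ppf(0.5 + ci_level / 2, n - 1) * g["dqtcb_ms"].std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
        out_rows.append(
            {
                "arm": arm,
                "model": model,
                "mean_qtcb_ms": mean_qt,
                "mean_dqtcb_ms": mean_dqt,
                "ci_low_ms": mean_dqt - half,
                "ci_high_ms": mean_dqt + half,
                "n_replicates": n,
            }
        )
    return pd.DataFrame(out_rows)
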