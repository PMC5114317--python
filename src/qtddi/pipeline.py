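"""End-to-end study pipeline: exposure → block → strand trials → evaluation.

Drives one of the eight bundled study designs (or a user-supplied one)
through the full chain and writes tidy CSV outputs: per-subject trial
results, arm/model summaries, the per-subject model-flip report, and the
observed-vs-predicted comparison with the distance metric and Welch test.
All randomness flows from the single master seed in the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures
from .evaluation import ThresholdPolicy, count_flips, distance, welch_t
from .interaction import HillParams, load_drug_table
from .pk import ExposureModifier, calibrate_pk
from .strand import StrandConfig
from .trial import TrialDesign, TrialResult, run_trial, summarize

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

#: default absorption half-life driven victim ka (1/h) used by study designs
_DEFAULT_KA = 1.0


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    ``drug_table`` optionally points at a CSV of per-channel Hill
    parameters (defaults to the bundled illustrative table).  The
    scaled-down flag selects the fast 50-cell strand with short
    pre-pacing; full scale uses the 100-cell strand defaults.
    """

    study: str
    out_dir: str
    master_seed: int
    n_subjects: int | None = None
    n_replicates: int = 2
    population_cv: float = 0.3
    scaled_down: bool = True
    drug_table: str | None = None
    threshold_ms: float = 5.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "master_seed" not in raw:
            raise ValueError(f"config {path} must set master_seed")
        return cls(**raw)


def _study_setup(config: PipelineConfig):
    designs = fixtures.study_designs().set_index("study")
    if config.study not in designs.index:
        raise ValueError(
            f"unknown study {config.study!r}; bundled studies: {list(designs.index)}"
        )
    row = designs.loc[config.study]
    if config.drug_table is not None:
        path = Path(config.drug_table)
        if not path.exists():
            raise FileNotFoundError(f"drug table not found: {path}")
        blocks = load_drug_table(path)
    else:
        import io

        blocks = load_drug_table(io.StringIO(fixtures._DRUG_BLOCKS_CSV))
    victim_channels = blocks["terfenadine"]
    inhibitor = str(row["inhibitor"])
    perpetrator_channels = blocks.get(inhibitor, {})

    victim_pk = calibrate_pk(
        target_cmax_ngml=float(row["victim_cmax_ngml"]),
        target_auc_nghml=float(row["victim_auc_nghml"]),
        ka_per_h=_DEFAULT_KA,
    )
    # inhibitor PK: illustrative exposure hitting the fixture Cmax with the
    # same absorption kinetics as the victim
    perp_cmax = float(row["inhibitor_cmax_ngml"])
    perp_pk = calibrate_pk(
        target_cmax_ngml=perp_cmax,
        target_auc_nghml=perp_cmax * 10.0,
        ka_per_h=_DEFAULT_KA,
        mw_g_mol=float(row["inhibitor_mw"]),
    )
    modifier = ExposureModifier(
        auc_ratio=max(1.0, float(row["auc_ratio"])),
        cmax_ratio=max(1.0, float(row["cmax_ratio"])),
    )
    n_subjects = config.n_subjects if config.n_subjects is not None else int(row["n_subjects"])
    strand = StrandConfig.scaled_down() if config.scaled_down else StrandConfig()
    design = TrialDesign(
        study=config.study,
        n_subjects=n_subjects,
        n_replicates=config.n_replicates,
        population_cv=config.population_cv,
        master_seed=config.master_seed,
        strand=strand,
    )
    return design, victim_pk, victim_channels, perp_pk, perpetrator_channels, modifier


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full study pipeline; returns the written output paths."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    try:
        design, victim_pk, victim_ch, perp_pk, perp_ch, modifier = _study_setup(config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'setup' failed: {exc}") from exc

    logger.info("running study %s: %d subjects x %d replicates",
                design.study, design.n_subjects, design.n_replicates)
    try:
        result: TrialResult = run_trial(design, victim_pk, victim_ch, perp_pk, perp_ch, modifier)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'trial' failed: {exc}") from exc

    result.data.to_csv(out / "trial_results.csv", index=False, float_format="%.6f")
    written["trial_results"] = out / "trial_results.csv"

    summary = summarize(result)
    summary.to_csv(out / "summary.csv", index=False, float_format="%.6f")
    written["summary"] = out / "summary.csv"

    # per-subject flip analysis at the regulatory threshold
    flips = count_flips(result.pivot_models(), ThresholdPolicy(config.threshold_ms))
    pd.DataFrame([{"study": design.study, "pct_cases": flips}]).to_csv(
        out / "flip_report.csv", index=False
    )
    written["flip_report"] = out / "flip_report.csv"

    # observed-vs-predicted evaluation against the bundled clinical table
    eval_rows = _evaluate_against_observed(design.study, result, summary)
    if eval_rows is not None:
        eval_rows.to_csv(out / "evaluation.csv", index=False, float_format="%.6f")
        written["evaluation"] = out / "evaluation.csv"

    logger.info("pipeline outputs written to %s", out)
    return written


def _evaluate_against_observed(study: str, result: TrialResult, summary: pd.DataFrame):
    t2 = fixtures.table2()
    g = t2[t2["study"] == study].set_index("arm")
    if g.empty or bool(g["delta_only"].any()):
        return None
    obs = (g.loc["BL", "observed"], g.loc["T", "observed"], g.loc["T+I", "observed"])
    if any(pd.isna(v) for v in obs):
        return None
    s = summary.set_index(["arm", "model"])
    rows = []
    bl = s.loc[("BL", "none"), "mean_qtcb_ms"]
    t_arm = s.loc[("T", "none"), "mean_qtcb_ms"]
    for model in ("sum", "bliss", "loewe"):
        if ("T+I", model) not in s.index:
            continue
        ti = s.loc[("T+I", model), "mean_qtcb_ms"]
        d = distance(obs, (bl, t_arm, ti))
        # Welch test of per-replicate predicted ΔQTcB vs the observed deltas
        pred_deltas = (
            result.data.query("arm == 'T+I' and model == @model")
            .groupby("replicate")["dqtcb_ms"]
            .mean()
            .to_numpy()
        )
        obs_deltas = [obs[1] - obs[0], obs[2] - obs[0]]
        try:
            t_stat, p_val = welch_t(obs_deltas, pred_deltas)
        except ValueError:
            t_stat, p_val = float("nan"), float("nan")
        rows.append(
            {
                "study": study,
                "model": model,
                "pred_bl_ms": bl,
                "pred_t_ms": t_arm,
                "pred_ti_ms": ti,
                "distance_ms": d,
                "welch_t": t_stat,
                "welch_p": p_val,
            }
        )
    return pd.DataFrame(rows)
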