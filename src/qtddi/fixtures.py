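"""Bundled clinical reference tables and illustrative drug parameters.

Three tables are shipped, transcribed from the published terfenadine
drug–drug-interaction QT study this pipeline re-implements:

* table1 — observed vs PBPK-predicted terfenadine Cmax (ng/ml) and AUC
  (ng·h/ml) for each of the eight clinical studies, arms T (terfenadine
  alone) and T+I (terfenadine + inhibitor).  Several observed cells are
  censored ("<5 ng/ml") or carry footnotes (subset of subjects, read off
  a graph); these are flagged, never imputed.
* table2 — observed and per-interaction-model predicted mean QTc triplets
  (BL, T, T+I, plus the inhibitor-alone arm where reported) and the
  published distance values.
* table3 — published percentage of subjects per study for whom the choice
  of interaction model changes the 5-ms-threshold safety verdict.

The channel-block (IC50, Hill n) and inhibitor PK parameter tables are
ILLUSTRATIVE: the original in vitro inputs were not published, so these
are plausible literature-scale values intended for demonstrations and
synthetic trials, not a reproduction of the source study's inputs.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

__all__ = [
    "table1",
    "table2",
    "table3",
    "drug_blocks",
    "study_designs",
    "make_fixtures",
]

# observed columns are strings to preserve censoring ("<5") and footnote flags
_TABLE1_CSV = """\
study,arm,obs_cmax_ngml,pred_cmax_ngml,obs_auc_nghml,pred_auc_nghml,flag
fluoxetine,T,2,2.3,24.6,15.3,
fluoxetine,T+I,1.4,2.3,14.2,15.3,
erythromycin_cr15,T,<5,2.71,NA,NA,censored
erythromycin_cr15,T+I,20.3,9.74,NA,NA,subset_3_of_9
fluconazole,T,<5,2.48,NA,NA,censored
fluconazole,T+I,<5,4.11,NA,NA,censored
itraconazole,T,7.63,4.9,NA,NA,subset_3_of_6
itraconazole,T+I,14.97,14.6,NA,NA,subset_3_of_6
ketoconazole,T,7,2.23,NA,NA,subset_1_of_6
ketoconazole,T+I,49.3,19.67,NA,NA,graph_5_of_6
clarithromycin,T,<5,9,NA,NA,censored;subset_4_of_6
clarithromycin,T+I,2.39,7.03,NA,NA,
erythromycin_cr19,T,<5,2.47,NA,NA,censored
erythromycin_cr19,T+I,7.6,8.98,NA,NA,subset_3_of_6
paroxetine,T,3.68,2.31,30.8,20.5,
paroxetine,T+I,3.64,2.48,30.0,27.5,
"""

# delta_only: observations published as QT changes, not absolute intervals.
# Predicted BL/T/I are shared by the three models; only the T+I prediction
# depends on the interaction model.
_TABLE2_CSV = """\
study,arm,observed,pred_sum,pred_bliss,pred_loewe,delta_only
fluoxetine,BL,372.4,396.0,396.0,396.0,0
fluoxetine,T,374.9,398.5,398.5,398.5,0
fluoxetine,I,NA,400.9,400.9,400.9,0
fluoxetine,T+I,379,401.6,400.8,400.2,0
erythromycin_cr15,BL,NA,392.8,392.8,392.8,1
erythromycin_cr15,T,8,398.5,398.5,398.5,1
erythromycin_cr15,I,21,403.7,403.7,403.7,1
erythromycin_cr15,T+I,39,418.2,413.6,411.4,1
fluconazole,BL,398.5,395.2,395.2,395.2,0
fluconazole,T,398.4,401.3,401.3,401.3,0
fluconazole,I,NA,414.3,414.3,414.3,0
fluconazole,T+I,411,422.6,418.6,416.8,0
itraconazole,BL,376,430.5,430.5,430.5,0
itraconazole,T,390,438,438,438,0
itraconazole,I,NA,486.9,486.9,486.9,0
itraconazole,T+I,417,452.2,448.9,447.3,0
ketoconazole,BL,408,394.5,394.5,394.5,0
ketoconazole,T,416,395,395,395,0
ketoconazole,I,NA,415.4,415.4,415.4,0
ketoconazole,T+I,490,439,427.9,423.6,0
clarithromycin,BL,409,395.5,395.5,395.5,0
clarithromycin,T,410,401.4,401.4,401.4,0
clarithromycin,I,407,393.9,393.9,393.9,0
clarithromycin,T+I,430,404.4,403.8,402.7,0
erythromycin_cr19,BL,394,397.5,397.5,397.5,0
erythromycin_cr19,T,408,403.7,403.7,403.7,0
erythromycin_cr19,I,409,405.8,405.8,405.8,0
erythromycin_cr19,T+I,428,420.1,415.6,413.5,0
paroxetine,BL,381,392.0,392.0,392.0,0
paroxetine,T,387,394.5,394.5,394.5,0
paroxetine,I,NA,393.5,393.5,393.5,0
paroxetine,T+I,386,396.6,393.6,396.8,0
"""

_TABLE2_PRINTED_D_CSV = """\
study,model,printed_distance,best
fluoxetine,sum,1.49,1
fluoxetine,bliss,2.59,0
fluoxetine,loewe,3.34,0
erythromycin_cr15,sum,18.38,1
erythromycin_cr15,bliss,22.75,0
erythromycin_cr15,loewe,25.13,0
fluconazole,sum,31.28,0
fluconazole,bliss,26.02,0
fluconazole,loewe,23.65,1
itraconazole,sum,24.05,1
itraconazole,bliss,28.50,0
itraconazole,loewe,30.68,0
ketoconazole,sum,48.61,1
ketoconazole,bliss,64.03,0
ketoconazole,loewe,70.14,0
clarithromycin,sum,21.43,1
clarithromycin,bliss,22.96,0
clarithromycin,loewe,23.79,0
erythromycin_cr19,sum,14.27,1
erythromycin_cr19,bliss,19.46,0
erythromycin_cr19,loewe,22.17,0
paroxetine,sum,4.69,1
paroxetine,bliss,4.86,0
paroxetine,loewe,4.78,0
"""

_TABLE3_CSV = """\
study,pct_cases
fluoxetine,0.1
erythromycin_cr15,2.8
fluconazole,3.8
itraconazole,2.3
ketoconazole,5.6
clarithromycin,0.2
erythromycin_cr19,3.3
paroxetine,0
"""

# ILLUSTRATIVE channel-block parameters (µM). The source study's in vitro
# inputs were not published; these are literature-scale stand-ins.
_DRUG_BLOCKS_CSV = """\
drug,channel,ic50_uM,hill_n
terfenadine,IKr,0.035,1.0
terfenadine,INa,1.0,1.0
terfenadine,ICaL,2.0,1.0
fluoxetine,IKr,1.5,1.0
fluoxetine,ICaL,3.0,1.0
erythromycin,IKr,72.0,1.0
fluconazole,IKr,48.0,1.0
itraconazole,IKr,5.0,1.0
ketoconazole,IKr,2.0,1.0
ketoconazole,ICaL,10.0,1.0
clarithromycin,IKr,33.0,1.0
paroxetine,IKr,2.5,1.0
"""

# Study design table for the synthetic trials. Victim exposure targets are
# the PBPK-predicted terfenadine Cmax values of table1; AUC targets use the
# printed value where available, otherwise Cmax x a default mean residence
# time (ILLUSTRATIVE, half-life ~ 8.5 h for terfenadine). Exposure
# multipliers are ratios of predicted T+I to T values, clamped at 1 (the
# clarithromycin row implies a ratio < 1, inconsistent with metabolic
# inhibition, and is treated as no PK interaction). Inhibitor heart-tissue
# Cmax values (ng/ml) are ILLUSTRATIVE plausible exposures.
_STUDY_DESIGNS_CSV = """\
study,inhibitor,n_subjects,victim_cmax_ngml,victim_auc_nghml,cmax_ratio,auc_ratio,inhibitor_cmax_ngml,inhibitor_mw
fluoxetine,fluoxetine,6,2.3,15.3,1.0,1.0,100,309.3
erythromycin_cr15,erythromycin,9,2.71,33.2,3.594,3.594,1500,733.9
fluconazole,fluconazole,6,2.48,30.4,1.657,1.657,9000,306.3
itraconazole,itraconazole,6,4.9,60.0,2.980,2.980,400,705.6
ketoconazole,ketoconazole,6,2.23,27.3,8.821,8.821,3500,531.4
clarithromycin,clarithromycin,6,9,110.2,1.0,1.0,2500,748.0
erythromycin_cr19,erythromycin,6,2.47,30.3,3.636,3.636,1500,733.9
paroxetine,paroxetine,6,2.31,20.5,1.074,1.341,60,329.4
"""

_FILES = {
    "table1.csv": _TABLE1_CSV,
    "table2.csv": _TABLE2_CSV,
    "table2_distances.csv": _TABLE2_PRINTED_D_CSV,
    "table3.csv": _TABLE3_CSV,
    "drug_blocks.csv": _DRUG_BLOCKS_CSV,
    "study_designs.csv": _STUDY_DESIGNS_CSV,
}


def _read(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text), na_values=["NA"], keep_default_na=False)


def table1() -> pd.DataFrame:
    """Observed vs predicted victim-drug Cmax/AUC (censored cells as strings)."""
    return _read(_TABLE1_CSV)


def table2() -> pd.DataFrame:
    """Observed vs per-model predicted mean QTc per study and arm (ms)."""
    df = _read(_TABLE2_CSV)
    df["delta_only"] = df["delta_only"].astype(bool)
    return df


def table2_printed_distances() -> pd.DataFrame:
    """The distance values printed alongside table2, with best-model flags."""
    return _read(_TABLE2_PRINTED_D_CSV)


def table3() -> pd.DataFrame:
    """Published per-study percentage of model-flip cases at the 5-ms threshold."""
    return _read(_TABLE3_CSV)


def drug_blocks() -> pd.DataFrame:
    """Illustrative per-drug per-channel Hill parameters (see module docstring)."""
    return _read(_DRUG_BLOCKS_CSV)


def study_designs() -> pd.DataFrame:
    """Per-study synthetic-trial design: exposure targets and multipliers."""
    return _read(_STUDY_DESIGNS_CSV)


def make_fixtures(out_dir) -> list[Path]:
    """Write every bundled table to ``out_dir`` as CSV; idempotent byte-wise."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, text in _FILES.items():
        path = out / name
        path.write_text(text)
        paths.append(path)
    return paths
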