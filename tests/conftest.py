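"""Shared fixtures.

The cardiac simulations dominate the suite's runtime, so every strand or
paced-cell result that more than one test needs is computed once per
session here, at the scaled-down problem sizes (50-cell strand, 20
pre-pacing beats, dt = 0.02 ms).
"""

from __future__ import annotations

import numpy as np
import pytest

from qtddi.cell import CellParameters, PacingProtocol, scale_conductances, simulate_ap
from qtddi.interaction import ChannelInhibitionVector, HillParams
from qtddi.pk import ExposureModifier, calibrate_pk
from qtddi.strand import StrandConfig, compute_pseudoecg, simulate_strand, strand_qtcb
from qtddi.trial import TrialDesign, run_trial


@pytest.fixture(scope="session")
def scaled_config() -> StrandConfig:
    return StrandConfig.scaled_down()


@pytest.fixture(scope="session")
def baseline_field(scaled_config):
    """Drug-free strand V(x,t) of the final beat."""
    return simulate_strand(scaled_config)


@pytest.fixture(scope="session")
def baseline_trace(baseline_field):
    return compute_pseudoecg(baseline_field)


@pytest.fixture(scope="session")
def ikr_block_qtcb(scaled_config, baseline_trace):
    """Strand QTcB under pure IKr block E in {0, 0.25, 0.5}."""
    from qtddi.strand import measure_qt

    out = {0.0: measure_qt(baseline_trace)}
    for e in (0.25, 0.5):
        out[e] = strand_qtcb(scaled_config, ChannelInhibitionVector(IKr=e)).qtcb_ms
    return out


@pytest.fixture(scope="session")
def apd_vs_ikr_block():
    """Single-cell APD90 for IKr block E in {0, 0.25, 0.5, 0.75}."""
    proto = PacingProtocol(n_beats=20)
    base = CellParameters.for_subtype("epi")
    return {
        e: simulate_ap(scale_conductances(base, ChannelInhibitionVector(IKr=e)), proto).apd90_ms
        for e in (0.0, 0.25, 0.5, 0.75)
    }


def _pure_ikr_trial(n_subjects=2, n_replicates=1, seed=11, cv=0.3,
                    perp_ic50=0.5, victim_ic50=0.05, modifier=None):
    """Trial with two pure-IKr blockers (no INa/ICaL confounders)."""
    victim_pk = calibrate_pk(8.0, 90.0)
    perp_pk = calibrate_pk(400.0, 4500.0, mw_g_mol=500.0)
    victim_ch = {"IKr": HillParams(victim_ic50)}
    perp_ch = {"IKr": HillParams(perp_ic50)}
    modifier = modifier or ExposureModifier(auc_ratio=2.0, cmax_ratio=2.0)
    design = TrialDesign(
        study="synthetic-two-ikr-blockers",
        n_subjects=n_subjects,
        n_replicates=n_replicates,
        population_cv=cv,
        master_seed=seed,
    )
    return design, run_trial(design, victim_pk, victim_ch, perp_pk, perp_ch, modifier)


@pytest.fixture(scope="session")
def two_ikr_blocker_trial():
    """Paired-subject trial where both drugs block only IKr."""
    return _pure_ikr_trial()
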