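"""Unit conversions used across the pipeline.

Policy: time in ms for electrophysiology and hours for PK, QT intervals in
ms, block-driving concentrations in µM, PK tables in ng/ml.  All mass/molar
conversions go through this module so the ng/ml <-> µM chain is defined in
exactly one place.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ngml_to_um", "um_to_ngml"]


def ngml_to_um(conc_ngml, mw_g_per_mol):
    """Convert a mass concentration (ng/ml == µg/L) to molarity (µM).

    µg/L divided by the molecular weight in g/mol gives µmol/L.
    """
    mw = float(mw_g_per_mol)
    if not np.isfinite(mw) or mw <= 0:
        raise ValueError(f"molecular weight must be positive and finite, got {mw_g_per_mol!r}")
    return np.asarray(conc_ngml, dtype=float) / mw


def um_to_ngml(conc_um, mw_g_per_mol):
    """Inverse of :func:`ngml_to_um`; round-trips exactly up to float division."""
    mw = float(mw_g_per_mol)
    if not np.isfinite(mw) or mw <= 0:
        raise ValueError(f"molecular weight must be positive and finite, got {mw_g_per_mol!r}")
    return np.asarray(conc_um, dtype=float) * mw
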