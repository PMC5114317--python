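"""Single-cell simulation harness: drug-scaled conductances, pacing, APD90.

Drug action is tonic conductance scaling: a block fraction E on a current
multiplies its maximal conductance by (1 - E).  Only IKr, IKs, INa and
ICaL are drug-sensitive here; the model's remaining currents are never
touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import tp06
from .interaction import ChannelInhibitionVector

__all__ = [
    "CellParameters",
    "PacingProtocol",
    "APResult",
    "scale_conductances",
    "step_cell",
    "simulate_ap",
    "apd90",
]

_SUBTYPES = {"endo": tp06.ENDO, "M": tp06.MID, "epi": tp06.EPI}


@dataclass(frozen=True)
class CellParameters:
    """Maximal conductances of the drug-sensitive currents plus subtype.

    Conductances in nS/pF (the published model's units).  ``subtype``
    selects the transmural variant: 'endo', 'M' or 'epi' (differing in
    Ito and IKs density and Ito inactivation kinetics).
    """

    subtype: str = "epi"
    gNa: float = tp06.GNA_BASE
    gKr: float = tp06.GKR_BASE
    gKs: float = field(default=tp06.GKS_EPI)
    gCaL: float = tp06.GCAL_BASE
    gto: float = field(default=tp06.GTO_EPI)

    def __post_init__(self) -> None:
        if self.subtype not in _SUBTYPES:
            raise ValueError(f"subtype must be one of {sorted(_SUBTYPES)}, got {self.subtype!r}")
        for name in ("gNa", "gKr", "gKs", "gCaL", "gto"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def for_subtype(cls, subtype: str) -> "CellParameters":
        """Published drug-free parameter set for a transmural subtype."""
        g = tp06.base_conductances(_SUBTYPES[subtype])
        return cls(subtype=subtype, gNa=g[0], gKr=g[1], gKs=g[2], gCaL=g[3], gto=g[4])

    @property
    def celltype_code(self) -> int:
        return _SUBTYPES[self.subtype]

    def conductance_array(self) -> np.ndarray:
        return np.array([self.gNa, self.gKr, self.gKs, self.gCaL, self.gto], dtype=float)


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic current-clamp pacing.

    cycle length ms; stimulus amplitude in pA/pF (positive number, applied
    as an inward/depolarising current); duration ms; number of beats;
    integration time step ms (<= 0.05 for stability of the explicit parts).
    """

    cl_ms: float = 1000.0
    stim_amplitude: float = 52.0
    stim_duration_ms: float = 1.0
    n_beats: int = 50
    dt_ms: float = 0.02

    def __post_init__(self) -> None:
        if self.cl_ms <= 0:
            raise ValueError("cycle length must be > 0")
        if self.n_beats < 1:
            raise ValueError("at least one beat is required")
        if not (0 < self.dt_ms <= 0.05):
            raise ValueError("dt must be in (0, 0.05] ms")
        if self.stim_duration_ms <= 0 or self.stim_amplitude <= 0:
            raise ValueError("stimulus amplitude and duration must be > 0")


@dataclass(frozen=True)
class APResult:
    """Last-beat voltage trace with its APD90 (ms)."""

    t_ms: np.ndarray
    v_mV: np.ndarray
    apd90_ms: float
    repolarized: bool
    final_state: np.ndarray


def scale_conductances(base: CellParameters, block: ChannelInhibitionVector) -> CellParameters:
    """Apply fractional block: g' = g * (1 - E) for IKr, IKs, INa, ICaL."""
    return replace(
        base,
        gKr=base.gKr * (1.0 - block.IKr),
        gKs=base.gKs * (1.0 - block.IKs),
        gNa=base.gNa * (1.0 - block.INa),
        gCaL=base.gCaL * (1.0 - block.ICaL),
    )


def step_cell(state: np.ndarray, params: CellParameters, dt_ms: float, stim: float = 0.0) -> np.ndarray:
    """One integration step; returns the new state (input not modified).

    ``stim`` is the depolarising stimulus magnitude in pA/pF (>= 0).
    Raises on a non-finite result (numerical instability).
    """
    out = np.array(state, dtype=float)
    tp06.step_cell(out, params.conductance_array(), params.celltype_code, dt_ms, -float(stim))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("cell state became non-finite; reduce dt or check parameters")
    return out


def apd90(t_ms: np.ndarray, v_mV: np.ndarray) -> tuple[float, bool]:
    """Action-potential duration at 90 % repolarisation for one beat.

    Measured from the time of maximal dV/dt to the first subsequent
    downward crossing of V90 = Vmax - 0.9 * (Vmax - Vrest), with Vrest the
    pre-upstroke minimum. Returns (apd90, repolarized); when the AP never
    reaches V90 within the trace the full remaining interval is returned
    with ``repolarized=False``.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mV, dtype=float)
    dvdt = np.gradient(v, t)
    i_up = int(np.argmax(dvdt))
    v_rest = float(v[: i_up + 1].min()) if i_up > 0 else float(v[0])
    v_max = float(v[i_up:].max())
    v90 = v_max - 0.9 * (v_max - v_rest)
    i_peak = i_up + int(np.argmax(v[i_up:]))
    below = np.nonzero(v[i_peak:] <= v90)[0]
    if below.size == 0:
        return float(t[-1] - t[i_up]), False
    i_cross = i_peak + below[0]
    # linear interpolation between the bracketing samples
    if i_cross > 0 and v[i_cross - 1] > v90:
        t0, t1 = t[i_cross - 1], t[i_cross]
        v0, v1 = v[i_cross - 1], v[i_cross]
        t_cross = t0 + (v90 - v0) * (t1 - t0) / (v1 - v0)
    else:
        t_cross = t[i_cross]
    return float(t_cross - t[i_up]), True


def simulate_ap(
    params: CellParameters,
    protocol: PacingProtocol,
    initial_state: np.ndarray | None = None,
    sample_ms: float = 0.1,
) -> APResult:
    """Pace a single cell to the end of ``protocol`` and analyse the last beat.

    ``sample_ms`` sets the recording resolution of the returned trace; the
    integration step is always ``protocol.dt_ms``.
    """
    state = np.array(tp06.initial_state() if initial_state is None else initial_state, dtype=float)
    if state.shape != (tp06.N_STATE,):
        raise ValueError(f"state must have shape ({tp06.N_STATE},)")
    sample_every = max(1, int(round(sample_ms / protocol.dt_ms)))
    t, v = tp06.run_single_cell(
        state,
        params.conductance_array(),
        params.celltype_code,
        protocol.cl_ms,
        protocol.n_beats,
        protocol.dt_ms,
        -protocol.stim_amplitude,
        protocol.stim_duration_ms,
        sample_every,
    )
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(state))):
        raise FloatingPointError("simulation diverged (non-finite voltage); reduce dt")
    dur, repol = apd90(t, v)
    if not repol:
        warnings.warn(
            "action potential failed to repolarize to 90% within the cycle; "
            "APD90 reported as the remaining interval",
            RuntimeWarning,
            stacklevel=2,
        )
    return APResult(t_ms=t, v_mV=v, apd90_ms=dur, repolarized=repol, final_state=state)
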