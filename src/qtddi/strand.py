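"""Transmural 1D strand, pseudoECG, QT detection and Bazett correction.

A heterogeneous endo → M → epi cable is paced from the endocardial end;
the monodomain equation is solved by operator splitting (cellular reaction
step, then explicit diffusion with no-flux boundaries).  The pseudoECG is
the extracellular potential of a unipolar electrode placed on the fiber
axis beyond the epicardial end,

    Φe(t) ∝ Σ_x (-∂V/∂x) · ∂(1/r)/∂x · Δx ,      r = |x_e - x| ,

which yields a positive QRS for propagation toward the electrode and —
because epicardial cells repolarise first while M cells repolarise last —
a positive T wave.  QT is read off the trace as (T-wave end) - (QRS
onset): QRS onset is the first time |dΦ/dt| exceeds 5 % of its global
maximum, T-wave end is located by the tangent method (steepest-descent
tangent of the T wave intersected with the isoelectric baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tp06
from .cell import CellParameters, PacingProtocol, scale_conductances
from .interaction import ChannelInhibitionVector

__all__ = [
    "StrandConfig",
    "StrandField",
    "PseudoECGTrace",
    "QTMeasurement",
    "ConductionFailure",
    "simulate_strand",
    "compute_pseudoecg",
    "measure_qt",
    "bazett",
    "strand_qtcb",
]


class ConductionFailure(RuntimeError):
    """The paced wave did not reach the epicardial end of the strand."""


@dataclass(frozen=True)
class StrandConfig:
    """Geometry, coupling and pacing of the transmural strand.

    Defaults are the full-size strand (100 cells); ``scaled_down()`` gives
    the 50-cell fast variant used throughout the test suite.  Diffusion
    coefficient in mm²/ms, spacing in mm; the electrode sits
    ``electrode_mm`` beyond the epicardial end on the strand axis.
    """

    n_endo: int = 25
    n_mid: int = 35
    n_epi: int = 40
    dx_mm: float = 0.15
    diffusion_mm2_ms: float = 0.154
    electrode_mm: float = 20.0
    pacing: PacingProtocol = field(default_factory=lambda: PacingProtocol(n_beats=3))
    pre_beats: int = 50
    n_stim_cells: int = 3
    sample_ms: float = 0.25

    def __post_init__(self) -> None:
        if self.n_cells < 20:
            raise ValueError("strand needs at least 20 cells")
        if self.dx_mm <= 0:
            raise ValueError("cell spacing must be > 0")
        if self.diffusion_mm2_ms < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.electrode_mm <= 0:
            raise ValueError("electrode must sit off the strand (distance > 0)")
        if self.pre_beats < 0:
            raise ValueError("pre_beats must be >= 0")
        # explicit diffusion stability bound
        if self.diffusion_mm2_ms > 0:
            dt_max = self.dx_mm**2 / (2.0 * self.diffusion_mm2_ms)
            if self.pacing.dt_ms > dt_max:
                raise ValueError(
                    f"dt={self.pacing.dt_ms} ms unstable for D={self.diffusion_mm2_ms}, "
                    f"dx={self.dx_mm} (need dt <= {dt_max:.4f} ms)"
                )

    @property
    def n_cells(self) -> int:
        return self.n_endo + self.n_mid + self.n_epi

    def subtypes(self) -> list[str]:
        return ["endo"] * self.n_endo + ["M"] * self.n_mid + ["epi"] * self.n_epi

    @classmethod
    def scaled_down(cls, **overrides) -> "StrandConfig":
        """Fast 50-cell strand with reduced pre-pacing, for tests and demos."""
        kwargs = dict(
            n_endo=12,
            n_mid=18,
            n_epi=20,
            pre_beats=20,
            pacing=PacingProtocol(n_beats=2),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class StrandField:
    """V(x, t) of the final paced beat plus per-cell activation times."""

    t_ms: np.ndarray          # (nt,)
    v_mV: np.ndarray          # (nt, n_cells)
    x_mm: np.ndarray          # (n_cells,)
    activation_ms: np.ndarray  # (n_cells,), NaN where the cell never fired
    config: StrandConfig


@dataclass(frozen=True)
class PseudoECGTrace:
    """Uniformly sampled extracellular potential (arbitrary units)."""

    t_ms: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        dt = np.diff(self.t_ms)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
            raise ValueError("pseudoECG trace must be uniformly sampled")
        if not (np.all(np.isfinite(self.t_ms)) and np.all(np.isfinite(self.phi))):
            raise ValueError("pseudoECG trace contains non-finite values")


@dataclass(frozen=True)
class QTMeasurement:
    """QT and RR of one beat with the Bazett-corrected interval."""

    qt_ms: float
    rr_ms: float

    def __post_init__(self) -> None:
        if not (0 < self.qt_ms < self.rr_ms):
            raise ValueError(f"need 0 < QT < RR, got QT={self.qt_ms}, RR={self.rr_ms}")

    @property
    def qtcb_ms(self) -> float:
        return bazett(self.qt_ms, self.rr_ms)


def bazett(qt_ms: float, rr_ms: float) -> float:
    """Bazett heart-rate correction: QTcB = QT / sqrt(RR / 1000)."""
    if not (qt_ms > 0 and rr_ms > 0):
        raise ValueError("QT and RR must both be positive")
    return float(qt_ms / np.sqrt(rr_ms / 1000.0))


def _prepace_states(config: StrandConfig, block: ChannelInhibitionVector) -> dict[str, np.ndarray]:
    """Steady-ish single-cell states per subtype, used to seed the strand.

    Pre-pacing is done on uncoupled cells (cheap) rather than on the full
    cable; the strand then runs ``config.pacing.n_beats`` coupled beats.
    """
    out: dict[str, np.ndarray] = {}
    for subtype in ("endo", "M", "epi"):
        params = scale_conductances(CellParameters.for_subtype(subtype), block)
        state = tp06.initial_state()
        if config.pre_beats > 0:
            proto = config.pacing
            tp06.run_single_cell(
                state,
                params.conductance_array(),
                params.celltype_code,
                proto.cl_ms,
                config.pre_beats,
                proto.dt_ms,
                -proto.stim_amplitude,
                proto.stim_duration_ms,
                10**6,  # no need to record
            )
        out[subtype] = state
    return out


def simulate_strand(
    config: StrandConfig,
    block: ChannelInhibitionVector | None = None,
    check_conduction: bool = True,
) -> StrandField:
    """Pace the strand and return the space–time voltage of the last beat.

    The block vector is applied uniformly to every cell. Raises
    :class:`ConductionFailure` when the wave does not reach the epicardial
    end (unless ``check_conduction`` is off, e.g. for the zero-diffusion
    decoupled limit).
    """
    block = block or ChannelInhibitionVector()
    seeds = _prepace_states(config, block)
    subtypes = config.subtypes()
    n = config.n_cells
    states = np.empty((n, tp06.N_STATE))
    cond = np.empty((n, 5))
    ctypes = np.empty(n, dtype=np.int64)
    for i, sub in enumerate(subtypes):
        states[i] = seeds[sub]
        params = scale_conductances(CellParameters.for_subtype(sub), block)
        cond[i] = params.conductance_array()
        ctypes[i] = params.celltype_code
    proto = config.pacing
    sample_every = max(1, int(round(config.sample_ms / proto.dt_ms)))
    t, field, act = tp06.run_strand(
        states,
        cond,
        ctypes,
        config.diffusion_mm2_ms,
        config.dx_mm,
        proto.cl_ms,
        proto.n_beats,
        proto.dt_ms,
        -proto.stim_amplitude,
        proto.stim_duration_ms,
        config.n_stim_cells,
        sample_every,
    )
    if not np.all(np.isfinite(field)):
        raise FloatingPointError("strand simulation diverged (non-finite voltage)")
    if check_conduction and np.isnan(act[-1]):
        raise ConductionFailure(
            "activation wave did not reach the epicardial end of the strand"
        )
    x = np.arange(n) * config.dx_mm
    return StrandField(t_ms=t, v_mV=field, x_mm=x, activation_ms=act, config=config)


def compute_pseudoecg(field: StrandField, config: StrandConfig | None = None) -> PseudoECGTrace:
    """Unipolar pseudoECG at the configured electrode position.

    Discrete form of Φe ∝ ∫ (-∂V/∂x)(∂/∂x)(1/r) dx over the strand, with
    the electrode on the axis ``electrode_mm`` beyond the epicardial end.
    """
    cfg = config or field.config
    v = field.v_mV
    if np.ptp(v) == 0.0:
        # spatially and temporally uniform field has no dipole source
        return PseudoECGTrace(t_ms=field.t_ms, phi=np.zeros_like(field.t_ms))
    if np.allclose(v, v[:, [0]]):
        return PseudoECGTrace(t_ms=field.t_ms, phi=np.zeros(v.shape[0]))
    x = field.x_mm
    x_e = x[-1] + cfg.electrode_mm
    r = x_e - x
    dvdx = np.gradient(v, x, axis=1)
    d_invr_dx = 1.0 / r**2  # d(1/(x_e - x))/dx
    phi = np.sum(-dvdx * d_invr_dx * cfg.dx_mm, axis=1)
    return PseudoECGTrace(t_ms=field.t_ms, phi=phi)


def measure_qt(trace: PseudoECGTrace, t_window_ms: float | None = None) -> float:
    """QT interval (ms) of the single beat in ``trace``.

    QRS onset: first sample where |dΦ/dt| exceeds 5 % of its global
    maximum.  T-wave end: tangent method — the steepest-descent tangent of
    the dominant T deflection intersected with the isoelectric baseline
    (taken from the tail of the trace).  Invariant to time translation and
    amplitude scaling.
    """
    t = np.asarray(trace.t_ms, dtype=float)
    phi = np.asarray(trace.phi, dtype=float)
    if t.size < 10:
        raise ValueError("trace too short to measure QT")
    dphi = np.gradient(phi, t)
    peak_slope = np.max(np.abs(dphi))
    if peak_slope == 0.0:
        raise ValueError("flat trace: no QRS deflection detectable")
    onset_idx = int(np.argmax(np.abs(dphi) >= 0.05 * peak_slope))
    t_onset = t[onset_idx]

    # isoelectric baseline from the final 10 % of the beat (diastole)
    tail = max(int(0.9 * t.size), t.size - 2)
    baseline = float(np.median(phi[tail:]))

    # T wave: dominant deflection after the QRS complex has ended
    t_search0 = t_onset + (0.12 * (t[-1] - t[0]) if t_window_ms is None else t_window_ms)
    mask = t >= t_search0
    if not np.any(mask):
        raise ValueError("no samples beyond the QRS window; cannot locate T wave")
    seg = phi[mask] - baseline
    seg_t = t[mask]
    i_tpeak = int(np.argmax(np.abs(seg)))
    if np.abs(seg[i_tpeak]) < 1e-12 * np.max(np.abs(phi - baseline)):
        raise ValueError("no detectable T wave")
    sign = np.sign(seg[i_tpeak])
    # steepest return-to-baseline slope after the T peak
    dseg = np.gradient(seg, seg_t)
    after = slice(i_tpeak, None)
    rel = dseg[after] * sign  # descending limb has negative sign-adjusted slope
    i_steep = i_tpeak + int(np.argmin(rel))
    slope = dseg[i_steep]
    if sign * slope >= 0:
        raise ValueError("T wave has no descending limb; cannot apply tangent method")
    t_end = seg_t[i_steep] - seg[i_steep] / slope
    qt = float(t_end - t_onset)
    if qt <= 0:
        raise ValueError("QT detection produced a non-positive interval")
    return qt


def strand_qtcb(
    config: StrandConfig,
    block: ChannelInhibitionVector | None = None,
) -> QTMeasurement:
    """End-to-end: strand simulation → pseudoECG → QT → Bazett.

    RR is the pacing cycle length (no heart-rate model), so at the default
    1000 ms pacing QTcB equals QT.
    """
    field = simulate_strand(config, block)
    trace = compute_pseudoecg(field)
    qt = measure_qt(trace)
    return QTMeasurement(qt_ms=qt, rr_ms=config.pacing.cl_ms)


def trace_to_csv(trace: PseudoECGTrace, path) -> None:
    pd.DataFrame({"time_ms": trace.t_ms, "phi": trace.phi}).to_csv(path, index=False)
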