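"""Synthetic heart-tissue exposure generator.

Stands in for a full physiologically based pharmacokinetic engine: the
contract is fidelity of the exposure magnitudes (Cmax, AUC), not
mechanism.  Plasma concentration follows the one-compartment model with
first-order absorption,

    C(t) = F·D·ka / (V·(ka − ke)) · (exp(−ke·t) − exp(−ka·t)) ,

(ka = ke handled by the analytic limit C(t) = F·D·ka·t·exp(−ka·t)/V) and
heart tissue concentration is plasma times a constant partition ratio.
Closed forms: AUC(0→∞) = F·D/(ke·V); Tmax = ln(ka/ke)/(ka − ke).

Inter-individual variability is log-normal on ka, ke and V.  A metabolic
drug–drug interaction enters purely as an exposure modifier on the victim
drug: the profile is amplitude-scaled and time-stretched so that Cmax and
AUC hit the prescribed multipliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .units import ngml_to_um

__all__ = [
    "PKParams",
    "ExposureModifier",
    "ConcentrationProfile",
    "pk_profile",
    "cmax_tmax",
    "auc_infinity",
    "calibrate_pk",
    "sample_population",
    "apply_interaction",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class PKParams:
    """One-compartment oral-dose parameters for a drug.

    dose mg; F bioavailability fraction; ka, ke 1/h; V litres; mw g/mol;
    heart:plasma partition ratio dimensionless (default 1).
    """

    dose_mg: float
    f_bio: float
    ka_per_h: float
    ke_per_h: float
    v_L: float
    mw_g_mol: float
    partition_heart: float = 1.0

    def __post_init__(self) -> None:
        for name in ("dose_mg", "f_bio", "ka_per_h", "ke_per_h", "v_L", "mw_g_mol", "partition_heart"):
            val = getattr(self, name)
            if not (math.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be finite and > 0, got {val!r}")


@dataclass(frozen=True)
class ExposureModifier:
    """Multipliers applied to the victim drug's exposure when the
    perpetrator is co-dosed.  Both >= 1 for inhibitors of metabolism."""

    auc_ratio: float = 1.0
    cmax_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.auc_ratio < 1.0 or self.cmax_ratio < 1.0:
            raise ValueError("exposure multipliers must be >= 1 for metabolic inhibitors")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Heart-tissue concentration–time series for one subject and arm."""

    time_h: np.ndarray
    conc_ngml: np.ndarray
    mw_g_mol: float
    subject: int = 0
    arm: str = "T"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        c = np.asarray(self.conc_ngml, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("time and concentration must be matching 1-D arrays")
        if np.any(np.diff(t) < 0) or np.any(t < 0):
            raise ValueError("time grid must be sorted and non-negative")
        if np.any(c < -1e-12):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "conc_ngml", np.maximum(c, 0.0))

    @property
    def conc_uM(self) -> np.ndarray:
        return ngml_to_um(self.conc_ngml, self.mw_g_mol)

    @property
    def cmax_ngml(self) -> float:
        return float(self.conc_ngml.max())

    @property
    def tmax_h(self) -> float:
        return float(self.time_h[int(np.argmax(self.conc_ngml))])

    def auc_trapezoid(self) -> float:
        """AUC over the profile's grid (ng·h/ml) by the trapezoid rule."""
        return float(np.trapezoid(self.conc_ngml, self.time_h))


def _conc_mg_per_L(params: PKParams, t_h: np.ndarray) -> np.ndarray:
    d, f, ka, ke, v = params.dose_mg, params.f_bio, params.ka_per_h, params.ke_per_h, params.v_L
    if abs(ka - ke) <= _REL_TOL * max(ka, ke):
        # flip-flop degenerate limit
        return f * d * ka * t_h * np.exp(-ka * t_h) / v
    return f * d * ka / (v * (ka - ke)) * (np.exp(-ke * t_h) - np.exp(-ka * t_h))


def pk_profile(params: PKParams, times_h, subject: int = 0, arm: str = "T") -> ConcentrationProfile:
    """Closed-form heart-tissue profile on the given time grid (hours).

    mg/L of plasma equals µg/ml, i.e. 1000 ng/ml; heart tissue applies the
    constant partition ratio on top.
    """
    t = np.asarray(times_h, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0) or np.any(t < 0):
        raise ValueError("times must be a sorted non-negative 1-D grid")
    conc_ngml = _conc_mg_per_L(params, t) * 1000.0 * params.partition_heart
    return ConcentrationProfile(
        time_h=t, conc_ngml=conc_ngml, mw_g_mol=params.mw_g_mol, subject=subject, arm=arm
    )


def cmax_tmax(params: PKParams) -> tuple[float, float]:
    """Analytic (Cmax in ng/ml of heart tissue, Tmax in h)."""
    ka, ke = params.ka_per_h, params.ke_per_h
    if abs(ka - ke) <= _REL_TOL * max(ka, ke):
        tmax = 1.0 / ka
    else:
        tmax = math.log(ka / ke) / (ka - ke)
    cmax = _conc_mg_per_L(params, np.array([tmax]))[0] * 1000.0 * params.partition_heart
    return float(cmax), float(tmax)


def auc_infinity(params: PKParams) -> float:
    """AUC(0→∞) = F·D/(ke·V), in ng·h/ml of heart tissue."""
    return params.f_bio * params.dose_mg / (params.ke_per_h * params.v_L) * 1000.0 * params.partition_heart


def calibrate_pk(
    target_cmax_ngml: float,
    target_auc_nghml: float,
    dose_mg: float = 60.0,
    f_bio: float = 1.0,
    ka_per_h: float = 1.0,
    mw_g_mol: float = 471.7,
    partition_heart: float = 1.0,
) -> PKParams:
    """Solve for (ke, V) so the profile hits the target Cmax and AUC.

    With ka fixed, AUC pins the product ke·V and Cmax then determines ke;
    the root is bracketed on ke ∈ (0, ka) and found with Brent's method,
    so the result is deterministic.  The achievable ratio Cmax/AUC on that
    branch is bounded above by ka/e; an infeasible pair raises ValueError.
    """
    if not (target_cmax_ngml > 0 and target_auc_nghml > 0):
        raise ValueError("targets must be positive")
    ratio = target_cmax_ngml / target_auc_nghml  # 1/h
    if ratio >= ka_per_h / math.e * (1.0 - 1e-9):
        raise ValueError(
            f"infeasible targets: Cmax/AUC = {ratio:.4g}/h exceeds the attainable "
            f"bound ka/e = {ka_per_h / math.e:.4g}/h for ka = {ka_per_h}/h"
        )

    keV = f_bio * dose_mg * 1000.0 * partition_heart / target_auc_nghml  # ke*V in L/h

    def cmax_err(ke: float) -> float:
        p = PKParams(
            dose_mg=dose_mg, f_bio=f_bio, ka_per_h=ka_per_h, ke_per_h=ke,
            v_L=keV / ke, mw_g_mol=mw_g_mol, partition_heart=partition_heart,
        )
        return cmax_tmax(p)[0] - target_cmax_ngml

    lo = 1e-8 * ka_per_h
    hi = ka_per_h * (1.0 - 1e-9)
    if cmax_err(lo) > 0 or cmax_err(hi) < 0:
        raise ValueError("infeasible Cmax/AUC pair: no absorption-limited solution brackets the target")
    ke = brentq(cmax_err, lo, hi, xtol=1e-12, rtol=1e-12)
    return PKParams(
        dose_mg=dose_mg, f_bio=f_bio, ka_per_h=ka_per_h, ke_per_h=float(ke),
        v_L=float(keV / ke), mw_g_mol=mw_g_mol, partition_heart=partition_heart,
    )


def sample_population(
    base: PKParams, n: int, cv: float, seed: int | np.random.Generator
) -> list[PKParams]:
    """Independent log-normal inter-individual variability on ka, ke, V.

    ``cv`` is the coefficient of variation of each perturbed parameter
    (sigma² = ln(1 + cv²)); the median equals the base value. cv = 0 gives
    n copies of ``base``.  Reproducible given a fixed seed.
    """
    if n < 1:
        raise ValueError("need at least one subject")
    if cv < 0:
        raise ValueError("coefficient of variation must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cv == 0:
        return [base] * n
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    out = []
    for _ in range(n):
        mult = np.exp(rng.normal(0.0, sigma, size=3))
        out.append(
            replace(base, ka_per_h=base.ka_per_h * mult[0],
                    ke_per_h=base.ke_per_h * mult[1], v_L=base.v_L * mult[2])
        )
    return out


def apply_interaction(victim: ConcentrationProfile, mod: ExposureModifier) -> ConcentrationProfile:
    """Rescale a victim profile so Cmax and AUC hit the modifier's ratios.

    Deterministic scheme: amplitude × cmax_ratio combined with a time
    stretch by auc_ratio/cmax_ratio, i.e. C'(t) = cmax_ratio · C(t ·
    cmax_ratio/auc_ratio), evaluated on the original grid by linear
    interpolation (zero beyond the grid).  Cmax scales exactly by
    cmax_ratio and AUC by auc_ratio (up to interpolation error on the
    stretched tail).
    """
    stretch = mod.cmax_ratio / mod.auc_ratio
    if stretch == 1.0 and mod.cmax_ratio == 1.0:
        return replace(victim, arm="T+I")
    t_src = victim.time_h * stretch
    conc = mod.cmax_ratio * np.interp(t_src, victim.time_h, victim.conc_ngml, right=0.0)
    return replace(victim, conc_ngml=conc, arm="T+I")
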