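"""ten Tusscher–Panfilov (2006) human ventricular myocyte model — numba kernels.

State layout (length 19, float64), shared by the single-cell and strand
integrators:

    0  V      membrane potential            mV
    1  Ki     intracellular K+              mM
    2  Nai    intracellular Na+             mM
    3  Cai    cytosolic free Ca2+           mM
    4  CaSS   subspace free Ca2+            mM
    5  CaSR   SR free Ca2+                  mM
    6  m, 7 h, 8 j        INa gates
    9  xr1, 10 xr2        IKr gates
    11 xs                 IKs gate
    12 r, 13 s            Ito gates
    14 d, 15 f, 16 f2, 17 fcass   ICaL gates
    18 Rq                 ryanodine-receptor closed-state fraction

Conductance vector ``cond`` (length 5): gNa, gKr, gKs, gCaL, gto — the
currents a drug may scale plus the two subtype-dependent conductances.
``celltype``: 0 = endocardial, 1 = mid-myocardial (M), 2 = epicardial;
it selects the Ito s-gate kinetics (endo differs) — gKs/gto differences
enter through ``cond``.

Integration is hybrid: Hodgkin–Huxley gates by the exponential
(Rush–Larsen) update, Ca2+ buffering by the analytic steady-state
quadratic, everything else forward Euler.  Currents in pA/pF, time in ms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---- physical constants and fixed model parameters ----
R_GAS = 8314.472       # mJ/(mol K)
TEMP = 310.0           # K
FARADAY = 96485.3415   # C/mol
RTONF = R_GAS * TEMP / FARADAY

CM = 0.185             # µF membrane capacitance (per cell scaling factor)
VC = 0.016404          # cytoplasm volume, µm^3 scale units of the source model
VSR = 0.001094
VSS = 0.00005468

KO = 5.4
NAO = 140.0
CAO = 2.0
PKNA = 0.03

GK1 = 5.405
GBNA = 0.00029
GBCA = 0.000592
PNAK = 2.724
KMK = 1.0
KMNA = 40.0
KNACA = 1000.0
KMNAI = 87.5
KMCA = 1.38
KSAT = 0.1
N_GAMMA = 0.35
ALPHA_NACA = 2.5
GPCA = 0.1238
KPCA = 0.0005
GPK = 0.0146

VMAXUP = 0.006375
KUP = 0.00025
VREL = 0.102
K1P = 0.15
K2P = 0.045
K3 = 0.060
K4 = 0.005
EC = 1.5
MAXSR = 2.5
MINSR = 1.0
VLEAK = 0.00036
VXFER = 0.0038
BUFC = 0.2
KBUFC = 0.001
BUFSR = 10.0
KBUFSR = 0.3
BUFSS = 0.4
KBUFSS = 0.00025

# baseline maximal conductances (nS/pF)
GNA_BASE = 14.838
GKR_BASE = 0.153
GCAL_BASE = 0.0000398
GKS_EPI = 0.392
GKS_ENDO = 0.392
GKS_M = 0.098
GTO_EPI = 0.294
GTO_ENDO = 0.073
GTO_M = 0.294

N_STATE = 19

ENDO, MID, EPI = 0, 1, 2


def base_conductances(celltype: int) -> np.ndarray:
    """Drug-free [gNa, gKr, gKs, gCaL, gto] for a cell subtype."""
    if celltype == ENDO:
        gks, gto = GKS_ENDO, GTO_ENDO
    elif celltype == MID:
        gks, gto = GKS_M, GTO_M
    elif celltype == EPI:
        gks, gto = GKS_EPI, GTO_EPI
    else:
        raise ValueError(f"celltype must be 0 (endo), 1 (M) or 2 (epi), got {celltype}")
    return np.array([GNA_BASE, GKR_BASE, gks, GCAL_BASE, gto], dtype=float)


def initial_state() -> np.ndarray:
    """Published resting initial conditions (approximate steady state at rest)."""
    s = np.empty(N_STATE)
    s[0] = -86.2      # V
    s[1] = 138.3      # Ki
    s[2] = 7.67       # Nai
    s[3] = 0.00007    # Cai
    s[4] = 0.00007    # CaSS
    s[5] = 1.3        # CaSR
    s[6] = 0.0        # m
    s[7] = 0.75       # h
    s[8] = 0.75       # j
    s[9] = 0.0        # xr1
    s[10] = 1.0       # xr2
    s[11] = 0.0       # xs
    s[12] = 0.0       # r
    s[13] = 1.0       # s
    s[14] = 0.0       # d
    s[15] = 1.0       # f
    s[16] = 1.0       # f2
    s[17] = 1.0       # fcass
    s[18] = 1.0       # Rq
    return s


@njit(cache=True)
def step_cell(state, cond, celltype, dt, istim):
    """Advance one cell one time step in place. ``istim`` in pA/pF (negative
    depolarises, matching the source model's sign convention)."""
    V = state[0]
    Ki = state[1]
    Nai = state[2]
    Cai = state[3]
    CaSS = state[4]
    CaSR = state[5]
    m = state[6]
    h = state[7]
    j = state[8]
    xr1 = state[9]
    xr2 = state[10]
    xs = state[11]
    r = state[12]
    s = state[13]
    d = state[14]
    f = state[15]
    f2 = state[16]
    fcass = state[17]
    Rq = state[18]

    gNa = cond[0]
    gKr = cond[1]
    gKs = cond[2]
    gCaL = cond[3]
    gto = cond[4]

    # reversal potentials
    EK = RTONF * np.log(KO / Ki)
    ENa = RTONF * np.log(NAO / Nai)
    EKs = RTONF * np.log((KO + PKNA * NAO) / (Ki + PKNA * Nai))
    ECa = 0.5 * RTONF * np.log(CAO / Cai)

    # currents
    INa = gNa * m * m * m * h * j * (V - ENa)

    alpha_k1 = 0.1 / (1.0 + np.exp(0.06 * (V - EK - 200.0)))
    beta_k1 = (3.0 * np.exp(0.0002 * (V - EK + 100.0)) + np.exp(0.1 * (V - EK - 10.0))) / (
        1.0 + np.exp(-0.5 * (V - EK))
    )
    xk1 = alpha_k1 / (alpha_k1 + beta_k1)
    IK1 = GK1 * np.sqrt(KO / 5.4) * xk1 * (V - EK)

    Ito = gto * r * s * (V - EK)
    IKr = gKr * np.sqrt(KO / 5.4) * xr1 * xr2 * (V - EK)
    IKs = gKs * xs * xs * (V - EKs)

    vf = (V - 15.0) * FARADAY / (R_GAS * TEMP)
    if np.abs(V - 15.0) < 1e-6:
        # L'Hopital limit of the GHG-type driving term at V = 15 mV
        ICaL = gCaL * d * f * f2 * fcass * 2.0 * FARADAY * (0.25 * CaSS - CAO)
    else:
        e2vf = np.exp(2.0 * vf)
        ICaL = (
            gCaL * d * f * f2 * fcass * 4.0 * (V - 15.0) * FARADAY * FARADAY / (R_GAS * TEMP)
            * (0.25 * CaSS * e2vf - CAO) / (e2vf - 1.0)
        )

    INaK = (
        PNAK * (KO / (KO + KMK)) * (Nai / (Nai + KMNA))
        / (1.0 + 0.1245 * np.exp(-0.1 * V / RTONF) + 0.0353 * np.exp(-V / RTONF))
    )

    eg = np.exp(N_GAMMA * V / RTONF)
    eg1 = np.exp((N_GAMMA - 1.0) * V / RTONF)
    INaCa = (
        KNACA
        * (eg * Nai * Nai * Nai * CAO - eg1 * NAO * NAO * NAO * Cai * ALPHA_NACA)
        / ((KMNAI ** 3 + NAO ** 3) * (KMCA + CAO) * (1.0 + KSAT * eg1))
    )

    IpCa = GPCA * Cai / (KPCA + Cai)
    IpK = GPK * (V - EK) / (1.0 + np.exp((25.0 - V) / 5.98))
    IbNa = GBNA * (V - ENa)
    IbCa = GBCA * (V - ECa)

    # --- calcium dynamics ---
    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / CaSR) * (EC / CaSR))
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    dRq = K4 * (1.0 - Rq) - k2 * CaSS * Rq
    Rq = Rq + dt * dRq
    OO = k1 * CaSS * CaSS * Rq / (K3 + k1 * CaSS * CaSS)
    Irel = VREL * OO * (CaSR - CaSS)
    Ileak = VLEAK * (CaSR - Cai)
    Iup = VMAXUP / (1.0 + (KUP / Cai) * (KUP / Cai))
    Ixfer = VXFER * (CaSS - Cai)

    # SR Ca, analytic buffering
    ca_csqn = BUFSR * CaSR / (CaSR + KBUFSR)
    d_casr = dt * (Iup - Irel - Ileak)
    bjsr = BUFSR - ca_csqn - d_casr - CaSR + KBUFSR
    cjsr = KBUFSR * (ca_csqn + d_casr + CaSR)
    CaSR = (np.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

    # subspace Ca
    ca_ssbuf = BUFSS * CaSS / (CaSS + KBUFSS)
    d_cass = dt * (
        -Ixfer * (VC / VSS)
        + Irel * (VSR / VSS)
        + (-ICaL * CM / (2.0 * VSS * FARADAY))
    )
    bcss = BUFSS - ca_ssbuf - d_cass - CaSS + KBUFSS
    ccss = KBUFSS * (ca_ssbuf + d_cass + CaSS)
    CaSS = (np.sqrt(bcss * bcss + 4.0 * ccss) - bcss) / 2.0

    # cytosolic Ca
    ca_buf = BUFC * Cai / (Cai + KBUFC)
    d_cai = dt * (
        -(IbCa + IpCa - 2.0 * INaCa) * CM / (2.0 * VC * FARADAY)
        - (Iup - Ileak) * (VSR / VC)
        + Ixfer
    )
    bc = BUFC - ca_buf - d_cai - Cai + KBUFC
    cc = KBUFC * (ca_buf + d_cai + Cai)
    Cai = (np.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

    # ion concentrations
    Nai = Nai + dt * (-(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * CM / (VC * FARADAY))
    Ki = Ki + dt * (
        -(istim + IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK) * CM / (VC * FARADAY)
    )

    # --- gates (Rush-Larsen) ---
    m_inf = 1.0 / ((1.0 + np.exp((-56.86 - V) / 9.03)) ** 2)
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.10 / (1.0 + np.exp((V - 50.0) / 200.0))
    tau_m = am * bm

    h_inf = 1.0 / ((1.0 + np.exp((V + 71.55) / 7.43)) ** 2)
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    tau_h = 1.0 / (ah + bh)

    j_inf = h_inf
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        aj = (
            (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + np.exp(0.311 * (V + 79.23)))
        )
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    tau_j = 1.0 / (aj + bj)

    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tau_xr1 = axr1 * bxr1

    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau_xr2 = axr2 * bxr2

    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    tau_xs = axs * bxs + 80.0

    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-(V + 40.0) * (V + 40.0) / 1800.0) + 0.8

    if celltype == ENDO:
        s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau_s = 1000.0 * np.exp(-(V + 67.0) * (V + 67.0) / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau_s = (
            85.0 * np.exp(-(V + 45.0) * (V + 45.0) / 320.0)
            + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0))
            + 3.0
        )

    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tau_d = ad * bd + gd

    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (
        1102.5 * np.exp(-(V + 27.0) * (V + 27.0) / 225.0)
        + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
        + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0))
        + 20.0
    )

    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (
        562.0 * np.exp(-(V + 27.0) * (V + 27.0) / 240.0)
        + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
        + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0))
    )

    fcass_inf = 0.6 / (1.0 + (CaSS / 0.05) * (CaSS / 0.05)) + 0.4
    tau_fcass = 80.0 / (1.0 + (CaSS / 0.05) * (CaSS / 0.05)) + 2.0

    m = m_inf - (m_inf - m) * np.exp(-dt / tau_m)
    h = h_inf - (h_inf - h) * np.exp(-dt / tau_h)
    j = j_inf - (j_inf - j) * np.exp(-dt / tau_j)
    xr1 = xr1_inf - (xr1_inf - xr1) * np.exp(-dt / tau_xr1)
    xr2 = xr2_inf - (xr2_inf - xr2) * np.exp(-dt / tau_xr2)
    xs = xs_inf - (xs_inf - xs) * np.exp(-dt / tau_xs)
    r = r_inf - (r_inf - r) * np.exp(-dt / tau_r)
    s = s_inf - (s_inf - s) * np.exp(-dt / tau_s)
    d = d_inf - (d_inf - d) * np.exp(-dt / tau_d)
    f = f_inf - (f_inf - f) * np.exp(-dt / tau_f)
    f2 = f2_inf - (f2_inf - f2) * np.exp(-dt / tau_f2)
    fcass = fcass_inf - (fcass_inf - fcass) * np.exp(-dt / tau_fcass)

    # membrane potential
    itot = IKr + IKs + IK1 + Ito + INa + IbNa + ICaL + IbCa + INaK + INaCa + IpCa + IpK + istim
    V = V - dt * itot

    state[0] = V
    state[1] = Ki
    state[2] = Nai
    state[3] = Cai
    state[4] = CaSS
    state[5] = CaSR
    state[6] = m
    state[7] = h
    state[8] = j
    state[9] = xr1
    state[10] = xr2
    state[11] = xs
    state[12] = r
    state[13] = s
    state[14] = d
    state[15] = f
    state[16] = f2
    state[17] = fcass
    state[18] = Rq


@njit(cache=True)
def run_single_cell(state, cond, celltype, cl_ms, n_beats, dt, stim_amp, stim_dur, sample_every):
    """Pace one cell for ``n_beats`` at cycle length ``cl_ms``; record the
    final beat.

    Returns (t, V) for the last beat sampled every ``sample_every`` steps;
    ``state`` is advanced in place. Stimulus at the start of each cycle.
    """
    steps_per_beat = int(round(cl_ms / dt))
    stim_steps = int(round(stim_dur / dt))
    n_samples = steps_per_beat // sample_every + 1
    t_out = np.empty(n_samples)
    v_out = np.empty(n_samples)
    k = 0
    for beat in range(n_beats):
        last = beat == n_beats - 1
        for istep in range(steps_per_beat):
            if last and istep % sample_every == 0:
                t_out[k] = istep * dt
                v_out[k] = state[0]
                k += 1
            istim = stim_amp if istep < stim_steps else 0.0
            step_cell(state, cond, celltype, dt, istim)
        if last and k < n_samples:
            t_out[k] = steps_per_beat * dt
            v_out[k] = state[0]
            k += 1
    return t_out[:k], v_out[:k]


@njit(cache=True)
def run_strand(states, cond, celltypes, diff_coeff, dx, cl_ms, n_beats, dt,
               stim_amp, stim_dur, n_stim_cells, sample_every):
    """Monodomain 1D cable paced from cell 0; record V(x, t) of the last beat.

    Operator splitting: per-cell reaction step (``step_cell``) then explicit
    diffusion with no-flux ends.  ``diff_coeff`` in mm^2/ms, ``dx`` in mm.
    Also returns per-cell activation time (first upward crossing of 0 mV
    during the last beat, at full dt resolution; NaN if never).
    """
    n_cells = states.shape[0]
    steps_per_beat = int(round(cl_ms / dt))
    stim_steps = int(round(stim_dur / dt))
    n_samples = steps_per_beat // sample_every + 1
    field = np.empty((n_samples, n_cells))
    t_out = np.empty(n_samples)
    act = np.full(n_cells, np.nan)
    lam = diff_coeff * dt / (dx * dx)
    vnew = np.empty(n_cells)
    vprev = np.empty(n_cells)
    k = 0
    for beat in range(n_beats):
        last = beat == n_beats - 1
        for istep in range(steps_per_beat):
            if last and istep % sample_every == 0:
                t_out[k] = istep * dt
                for i in range(n_cells):
                    field[k, i] = states[i, 0]
                k += 1
            for i in range(n_cells):
                vprev[i] = states[i, 0]
            # reaction
            for i in range(n_cells):
                istim = stim_amp if (istep < stim_steps and i < n_stim_cells) else 0.0
                step_cell(states[i], cond[i], celltypes[i], dt, istim)
            # diffusion, no-flux boundaries
            for i in range(n_cells):
                vm = states[i - 1, 0] if i > 0 else states[1, 0]
                vp = states[i + 1, 0] if i < n_cells - 1 else states[n_cells - 2, 0]
                vnew[i] = states[i, 0] + lam * (vm - 2.0 * states[i, 0] + vp)
            for i in range(n_cells):
                states[i, 0] = vnew[i]
                if last and np.isnan(act[i]) and vprev[i] <= 0.0 and vnew[i] > 0.0:
                    # sub-step linear interpolation of the upward 0 mV crossing
                    act[i] = istep * dt + dt * (-vprev[i]) / (vnew[i] - vprev[i])
    return t_out[:k], field[:k], act
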