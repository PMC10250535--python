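"""Single-cell mouse LV epicardial action-potential model.

The ionic model is the Bondarenko-group mouse ventricular myocyte model in
its apical (LV epicardial) parameterization: Hodgkin-Huxley K+ currents
(I_Kto,f, I_Kto,s, I_Kur, I_Kss, I_Ks, I_K1), Markov schemes for the fast
Na+ channel (9 states), the L-type Ca2+ channel (8 states) and I_Kr
(5 states), Na+/K+ pump, Na+/Ca2+ exchanger, sarcolemmal Ca2+ pump,
background currents, a Ca2+-activated Cl- current, and a full intracellular
Ca2+ handling system (subspace, junctional and network SR, ryanodine
receptor, SERCA uptake, troponin/calmodulin/calsequestrin buffering).

Units: mV, ms, pA/pF, uM (concentrations), mS/uF (conductances).
Temperature and extracellular ion concentrations are the published model
values and are not exposed as tunables.

The three perturbations used by the scan protocols enter here:

* ``scale_g*``    - multipliers on maximal K+ conductances;
* ``k_reopen``    - multiplier on the single IF_Na -> O_Na transition rate
  of the Na_v Markov scheme (late Na+ current);
* ``dV_half_CaL`` - additive shift of the I_CaL *activation* rate
  voltage-dependence (activation rates evaluated at ``V - dV``),
  inactivation untouched.

Markov occupancy conservation is enforced exactly by carrying one state of
each scheme as the dependent complement (1 minus the sum of the others).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import ModelParameters

# ---------------------------------------------------------------------------
# physical constants and cell geometry
# ---------------------------------------------------------------------------
F = 96.5          # C/mmol
T = 298.0         # K
R = 8.314         # J/(mol K)
RT_F = R * T / F  # mV

ACAP = 1.534e-4   # capacitive membrane area, cm^2
CM = 1.0          # specific membrane capacitance, uF/cm^2
V_MYO = 25.84e-6  # myoplasm volume, uL
V_JSR = 0.12e-6   # junctional SR volume, uL
V_NSR = 2.098e-6  # network SR volume, uL
V_SS = 1.485e-9   # subspace volume, uL

KO = 5400.0       # uM
NAO = 140000.0    # uM
CAO = 1800.0      # uM

# maximal conductances / fluxes (apical = LV epicardial variant)
G_NA = 13.0
G_NAB = 0.0026
G_CAL = 0.1729
E_CAL = 63.0
G_CAB = 0.000367
G_KTOF = 0.4067
G_KTOS = 0.0
G_KUR = 0.160
G_KSS = 0.050
G_KS = 0.00575
G_KR = 0.078
G_CLCA = 10.0
G_K1_MAX = 0.2938
I_NAK_MAX = 0.88
KM_NAI = 21000.0
KM_KO = 1500.0
K_NACA = 292.8
KM_NA = 87500.0
KM_CA = 1380.0
K_SAT = 0.1
ETA = 0.35
I_PCA_MAX = 1.0
KM_PCA = 0.5
KM_CL = 10.0
E_CL = -40.0
I_CAL_MAX = 7.0   # normalization of I_CaL in the RyR modulation term

# Ca handling
V1_REL = 4.5
V2_LEAK = 1.74e-5
V3_UP = 0.45
KM_UP = 0.5
TAU_TR = 20.0
TAU_XFER = 8.0
LTRPN_TOT = 70.0
HTRPN_TOT = 140.0
K_P_HTRPN = 0.00237
K_M_HTRPN = 3.2e-5
K_P_LTRPN = 0.0327
K_M_LTRPN = 0.0196
CMDN_TOT = 50.0
KM_CMDN = 0.238
CSQN_TOT = 15000.0
KM_CSQN = 800.0
K_PA_RYR = 0.006075
K_MA_RYR = 0.07125
K_PB_RYR = 0.00405
K_MB_RYR = 0.965
K_PC_RYR = 0.009
K_MC_RYR = 0.0008

# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------
STATE_NAMES = (
    "V",
    "Cai", "Cass", "CaJSR", "CaNSR",
    "LTRPN_Ca", "HTRPN_Ca",
    "P_RyR", "P_O1", "P_O2", "P_C2",
    "O_CaL", "C2_CaL", "C3_CaL", "C4_CaL", "I1_CaL", "I2_CaL", "I3_CaL",
    "C_Na2", "C_Na1", "O_Na", "IF_Na", "I1_Na", "I2_Na", "IC_Na2", "IC_Na3",
    "Nai", "Ki",
    "ato_f", "ito_f", "ato_s", "ito_s", "nKs", "aur", "iur", "aKss", "iKss",
    "C_K1", "C_K2", "O_K", "I_K",
)
N_STATES = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: the nine Na_v Markov states, in scan/diagram order; C_Na3 is carried as
#: the dependent complement so occupancy conservation is exact.
NA_MARKOV_STATES = (
    "C_Na3", "C_Na2", "C_Na1", "O_Na", "IF_Na",
    "I1_Na", "I2_Na", "IC_Na2", "IC_Na3",
)
_NA_EXPLICIT = ("C_Na2", "C_Na1", "O_Na", "IF_Na", "I1_Na", "I2_Na",
                "IC_Na2", "IC_Na3")
NA_SLICE = slice(IDX["C_Na2"], IDX["IC_Na3"] + 1)

#: initial conditions of the published apical model (quiescent cell)
INITIAL_STATE = np.array([
    -82.4202,                       # V
    0.115001, 0.115001,             # Cai, Cass
    1299.5, 1299.5,                 # CaJSR, CaNSR
    11.2684, 125.290,               # LTRPN_Ca, HTRPN_Ca
    0.0, 0.149102e-4, 0.951726e-10, 0.16774e-3,   # P_RyR, P_O1, P_O2, P_C2
    0.930308e-18, 0.124216e-3, 0.578679e-8, 0.119816e-12,  # O,C2,C3,C4 CaL
    0.497923e-18, 0.345847e-13, 0.185106e-13,              # I1,I2,I3 CaL
    0.020752, 0.279132e-3, 0.713483e-6, 0.153176e-3,       # CNa2,CNa1,ONa,IF
    0.673345e-6, 0.155787e-8, 0.0113879, 0.34278,          # I1,I2,IC2,IC3
    14237.1, 143720.0,              # Nai, Ki
    0.265563e-2, 0.999977,          # ato_f, ito_f
    0.417069e-3, 0.998543,          # ato_s, ito_s
    0.262753e-3,                    # nKs
    0.417069e-3, 0.998543,          # aur, iur
    0.417069e-3, 1.0,               # aKss, iKss
    0.992513e-3, 0.641229e-3, 0.175298e-3, 0.319129e-4,    # C_K1,C_K2,O_K,I_K
])


def initial_state() -> np.ndarray:
    """Return a copy of the published quiescent initial state vector."""
    return INITIAL_STATE.copy()


# ---------------------------------------------------------------------------
# parameter packing for the compiled right-hand side
# ---------------------------------------------------------------------------
def pack_params(params: ModelParameters, i_stim: float = 0.0) -> np.ndarray:
    """Pack perturbation multipliers and stimulus into the RHS vector."""
    return np.array([
        params.scale_gKtof, params.scale_gKtos, params.scale_gKur,
        params.scale_gKss, params.scale_gK1, params.scale_gKr,
        params.scale_gKs, params.k_reopen_scale, params.dV_half_CaL,
        i_stim,
    ])


# ---------------------------------------------------------------------------
# transition-rate helpers (shared by the RHS and the labelled wrappers)
# ---------------------------------------------------------------------------
@njit(cache=True)
def _na_rate_values(V, k_reopen):
    """The 13 distinct Na_v Markov transition rates at voltage V (1/ms)."""
    a11 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 17.0)
                   + 0.20 * np.exp(-(V + 2.5) / 150.0))
    a12 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 15.0)
                   + 0.23 * np.exp(-(V + 2.5) / 150.0))
    a13 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 12.0)
                   + 0.25 * np.exp(-(V + 2.5) / 150.0))
    b11 = 0.1917 * np.exp(-(V + 2.5) / 20.3)
    b12 = 0.20 * np.exp(-(V - 2.5) / 20.3)
    b13 = 0.22 * np.exp(-(V - 7.5) / 20.3)
    a3 = 7.0e-7 * np.exp(-(V + 7.0) / 7.7)
    b3 = 0.0084 + 0.00002 * (V + 7.0)
    a2 = 1.0 / (0.188495 * np.exp(-(V + 7.0) / 16.6) + 0.393956)
    # microscopic reversibility; this is the re-opening rate IF_Na -> O_Na
    b2 = k_reopen * a13 * a2 * a3 / (b13 * b3)
    a4 = a2 / 1000.0
    b4 = a3
    a5 = a2 / 95000.0
    b5 = a3 / 50.0
    return a11, a12, a13, b11, b12, b13, a2, b2, a3, b3, a4, b4, a5, b5


@njit(cache=True)
def _cal_activation_rates(V_act):
    """I_CaL activation rates alpha/beta, evaluated at the (shifted) voltage."""
    alpha = (0.4 * np.exp((V_act + 12.0) / 10.0)
             * (1.0 + 0.7 * np.exp(-(V_act + 40.0) ** 2 / 10.0)
                - 0.75 * np.exp(-(V_act + 20.0) ** 2 / 400.0))
             / (1.0 + 0.12 * np.exp((V_act + 12.0) / 10.0)))
    beta = 0.05 * np.exp(-(V_act + 12.0) / 13.0)
    return alpha, beta


@njit(cache=True)
def _cal_inactivation_rates(V, Cass):
    gamma = 0.23324 * Cass / (20.0 + Cass)
    Kpcf = 13.0 * (1.0 - np.exp(-(V + 14.5) ** 2 / 100.0))
    Kpcb = 0.0005
    return gamma, Kpcf, Kpcb


def na_markov_rates(V: float, k_reopen_scale: float = 1.0) -> dict:
    """Labelled Na_v Markov transition rates (1/ms) at voltage ``V``.

    Exactly one rate -- the IF_Na -> O_Na re-opening transition that
    generates the late Na+ current -- is multiplied by ``k_reopen_scale``;
    all others keep their baseline values.
    """
    if not np.isfinite(V):
        raise ValueError(f"membrane potential must be finite, got {V}")
    if not k_reopen_scale > 0:
        raise ValueError(
            f"k_reopen_scale must be positive, got {k_reopen_scale}"
        )
    (a11, a12, a13, b11, b12, b13,
     a2, b2, a3, b3, a4, b4, a5, b5) = _na_rate_values(
        float(V), float(k_reopen_scale))
    return {
        "C_Na3->C_Na2": a11, "C_Na2->C_Na3": b11,
        "C_Na2->C_Na1": a12, "C_Na1->C_Na2": b12,
        "C_Na1->O_Na": a13, "O_Na->C_Na1": b13,
        "O_Na->IF_Na": a2, "IF_Na->O_Na": b2,
        "IF_Na->C_Na1": a3, "C_Na1->IF_Na": b3,
        "IF_Na->I1_Na": a4, "I1_Na->IF_Na": b4,
        "I1_Na->I2_Na": a5, "I2_Na->I1_Na": b5,
        "IC_Na2->IF_Na": a12, "IF_Na->IC_Na2": b12,
        "IC_Na3->IC_Na2": a11, "IC_Na2->IC_Na3": b11,
        "IC_Na2->C_Na2": a3, "C_Na2->IC_Na2": b3,
        "IC_Na3->C_Na3": a3, "C_Na3->IC_Na3": b3,
    }


def na_rate_matrix(V: float, k_reopen_scale: float = 1.0) -> np.ndarray:
    """9x9 generator matrix Q with dp/dt = Q @ p over ``NA_MARKOV_STATES``."""
    rates = na_markov_rates(V, k_reopen_scale)
    index = {s: i for i, s in enumerate(NA_MARKOV_STATES)}
    Q = np.zeros((9, 9))
    for edge, rate in rates.items():
        src, dst = edge.split("->")
        Q[index[dst], index[src]] += rate
        Q[index[src], index[src]] -= rate
    return Q


def ical_activation_rates(V: float, dV_half_CaL: float = 0.0) -> tuple:
    """(alpha, beta) activation rates of I_CaL with the voltage shift applied."""
    return _cal_activation_rates(float(V) - float(dV_half_CaL))


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------
@njit(cache=True)
def rhs(t, y, p):
    """Time-derivative of the 41-component state vector.

    ``p`` is the packed perturbation vector from :func:`pack_params`;
    ``p[9]`` is the stimulus current density (pA/pF, magnitude of the
    inward pulse) active for the whole call -- pacing is integrated
    piecewise so each segment sees a constant stimulus.
    """
    d = np.empty(y.shape[0])

    V = y[0]
    Cai = y[1]
    Cass = y[2]
    CaJSR = y[3]
    CaNSR = y[4]
    LTRPN_Ca = y[5]
    HTRPN_Ca = y[6]
    P_RyR = y[7]
    P_O1 = y[8]
    P_O2 = y[9]
    P_C2 = y[10]
    O_CaL = y[11]
    C2 = y[12]
    C3 = y[13]
    C4 = y[14]
    I1 = y[15]
    I2 = y[16]
    I3 = y[17]
    C_Na2 = y[18]
    C_Na1 = y[19]
    O_Na = y[20]
    IF_Na = y[21]
    I1_Na = y[22]
    I2_Na = y[23]
    IC_Na2 = y[24]
    IC_Na3 = y[25]
    Nai = y[26]
    Ki = y[27]
    ato_f = y[28]
    ito_f = y[29]
    ato_s = y[30]
    ito_s = y[31]
    nKs = y[32]
    aur = y[33]
    iur = y[34]
    aKss = y[35]
    iKss = y[36]
    C_K1 = y[37]
    C_K2 = y[38]
    O_K = y[39]
    I_K = y[40]

    s_gKtof = p[0]
    s_gKtos = p[1]
    s_gKur = p[2]
    s_gKss = p[3]
    s_gK1 = p[4]
    s_gKr = p[5]
    s_gKs = p[6]
    k_reopen = p[7]
    dV_caL = p[8]
    i_stim = p[9]

    # dependent Markov states (exact conservation)
    C1_CaL = 1.0 - (O_CaL + C2 + C3 + C4 + I1 + I2 + I3)
    C_Na3 = 1.0 - (C_Na2 + C_Na1 + O_Na + IF_Na + I1_Na + I2_Na
                   + IC_Na2 + IC_Na3)
    P_C1 = 1.0 - (P_O1 + P_O2 + P_C2)
    C_K0 = 1.0 - (C_K1 + C_K2 + O_K + I_K)

    # reversal potentials
    E_Na = RT_F * np.log((0.9 * NAO + 0.1 * KO) / (0.9 * Nai + 0.1 * Ki))
    E_K = RT_F * np.log(KO / Ki)
    E_CaN = 0.5 * RT_F * np.log(CAO / Cai)

    # ---- fast Na+ current (Markov) ----
    (a11, a12, a13, b11, b12, b13,
     a2, b2, a3, b3, a4, b4, a5, b5) = _na_rate_values(V, k_reopen)
    I_Na = G_NA * O_Na * (V - E_Na)

    d[18] = (a11 * C_Na3 - b11 * C_Na2 + b12 * C_Na1 - a12 * C_Na2
             + a3 * IC_Na2 - b3 * C_Na2)
    d[19] = (a12 * C_Na2 - b12 * C_Na1 + b13 * O_Na - a13 * C_Na1
             + a3 * IF_Na - b3 * C_Na1)
    d[20] = a13 * C_Na1 - b13 * O_Na + b2 * IF_Na - a2 * O_Na
    d[21] = (a2 * O_Na - b2 * IF_Na + b3 * C_Na1 - a3 * IF_Na
             + b4 * I1_Na - a4 * IF_Na + a12 * IC_Na2 - b12 * IF_Na)
    d[22] = a4 * IF_Na - b4 * I1_Na + b5 * I2_Na - a5 * I1_Na
    d[23] = a5 * I1_Na - b5 * I2_Na
    d[24] = (a11 * IC_Na3 - b11 * IC_Na2 + b12 * IF_Na - a12 * IC_Na2
             + b3 * C_Na2 - a3 * IC_Na2)
    d[25] = b11 * IC_Na2 - a11 * IC_Na3 + b3 * C_Na3 - a3 * IC_Na3

    # ---- L-type Ca2+ current (Markov); activation shifted by dV_caL ----
    alpha, beta = _cal_activation_rates(V - dV_caL)
    gamma, Kpcf, Kpcb = _cal_inactivation_rates(V, Cass)
    I_CaL = G_CAL * O_CaL * (V - E_CAL)

    d[11] = (alpha * C4 - 4.0 * beta * O_CaL + Kpcb * I1 - gamma * O_CaL
             + 0.001 * (alpha * I2 - Kpcf * O_CaL))
    d[12] = 4.0 * alpha * C1_CaL - beta * C2 + 2.0 * beta * C3 - 3.0 * alpha * C2
    d[13] = 3.0 * alpha * C2 - 2.0 * beta * C3 + 3.0 * beta * C4 - 2.0 * alpha * C3
    d[14] = (2.0 * alpha * C3 - 3.0 * beta * C4 + 4.0 * beta * O_CaL
             - alpha * C4
             + 0.01 * (4.0 * Kpcb * beta * I1 - alpha * gamma * C4)
             + 0.002 * (4.0 * beta * I2 - Kpcf * C4)
             + 4.0 * beta * Kpcb * I3 - gamma * Kpcf * C4)
    d[15] = (gamma * O_CaL - Kpcb * I1
             + 0.001 * (Kpcf * I3 - alpha * I1)
             + 0.01 * (alpha * gamma * C4 - 4.0 * beta * Kpcb * I1))
    d[16] = (0.001 * (Kpcf * O_CaL - alpha * I2) + Kpcb * I3 - gamma * I2
             + 0.002 * (Kpcf * C4 - 4.0 * beta * I2))
    d[17] = (0.001 * (alpha * I1 - Kpcf * I3) + gamma * I2 - Kpcb * I3
             + gamma * Kpcf * C4 - 4.0 * beta * Kpcb * I3)

    # ---- K+ currents ----
    I_Ktof = s_gKtof * G_KTOF * ato_f ** 3 * ito_f * (V - E_K)
    I_Ktos = s_gKtos * G_KTOS * ato_s * ito_s * (V - E_K)
    I_Kur = s_gKur * G_KUR * aur * iur * (V - E_K)
    I_Kss = s_gKss * G_KSS * aKss * iKss * (V - E_K)
    I_K1 = (s_gK1 * G_K1_MAX * (KO / (KO + 210.0))
            * (V - E_K) / (1.0 + np.exp(0.0896 * (V - E_K))))
    I_Ks = s_gKs * G_KS * nKs * nKs * (V - E_K)
    E_Kr = RT_F * np.log((0.98 * KO + 0.02 * NAO) / (0.98 * Ki + 0.02 * Nai))
    I_Kr = s_gKr * G_KR * O_K * (V - E_Kr)

    # I_Kto,f gates
    aa = 0.18064 * np.exp(0.03577 * (V + 30.0))
    ba = 0.3956 * np.exp(-0.06237 * (V + 30.0))
    ai = (0.000152 * np.exp(-(V + 13.5) / 7.0)
          / (0.067083 * np.exp(-(V + 33.5) / 7.0) + 1.0))
    bi = (0.00095 * np.exp((V + 33.5) / 7.0)
          / (0.051335 * np.exp((V + 33.5) / 7.0) + 1.0))
    d[28] = aa * (1.0 - ato_f) - ba * ato_f
    d[29] = ai * (1.0 - ito_f) - bi * ito_f

    # slow Ito / IKur / IKss gates share steady-state curves
    a_ss = 1.0 / (1.0 + np.exp(-(V + 22.5) / 7.7))
    i_ss = 1.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    tau_tas = 0.493 * np.exp(-0.0629 * V) + 2.058
    tau_tis = 270.0 + 1050.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    d[30] = (a_ss - ato_s) / tau_tas
    d[31] = (i_ss - ito_s) / tau_tis
    tau_iur = 1200.0 - 170.0 / (1.0 + np.exp((V + 45.2) / 5.7))
    d[33] = (a_ss - aur) / tau_tas
    d[34] = (i_ss - iur) / tau_iur
    tau_Kss = 39.3 * np.exp(-0.0862 * V) + 13.17
    d[35] = (a_ss - aKss) / tau_Kss
    d[36] = 0.0

    # IKs gate
    an = (4.81333e-6 * (V + 26.5)
          / (1.0 - np.exp(-0.128 * (V + 26.5))))
    bn = 9.53333e-5 * np.exp(-0.038 * (V + 26.5))
    d[32] = an * (1.0 - nKs) - bn * nKs

    # IKr Markov
    aa0 = 0.022348 * np.exp(0.01176 * V)
    ba0 = 0.047002 * np.exp(-0.0631 * V)
    aa1 = 0.013733 * np.exp(0.038198 * V)
    ba1 = 6.89e-5 * np.exp(-0.04178 * V)
    ai_kr = 0.090821 * np.exp(0.023391 * (V + 5.0))
    bi_kr = 0.006497 * np.exp(-0.03268 * (V + 5.0))
    kf = 0.023761
    kb = 0.036778
    d[37] = aa0 * C_K0 - ba0 * C_K1 + kb * C_K2 - kf * C_K1
    d[38] = kf * C_K1 - kb * C_K2 + ba1 * O_K - aa1 * C_K2
    d[39] = aa1 * C_K2 - ba1 * O_K + bi_kr * I_K - ai_kr * O_K
    d[40] = ai_kr * O_K - bi_kr * I_K

    # ---- pumps, exchangers, background ----
    sigma = (np.exp(NAO / 67300.0) - 1.0) / 7.0
    f_NaK = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / RT_F)
                   + 0.0365 * sigma * np.exp(-V / RT_F))
    I_NaK = (I_NAK_MAX * f_NaK * (KO / (KO + KM_KO))
             / (1.0 + (KM_NAI / Nai) ** 1.5))
    expEta = np.exp(ETA * V / RT_F)
    expEta1 = np.exp((ETA - 1.0) * V / RT_F)
    I_NaCa = (K_NACA / (KM_NA ** 3 + NAO ** 3) / (KM_CA + CAO)
              / (1.0 + K_SAT * expEta1)
              * (expEta * Nai ** 3 * CAO - expEta1 * NAO ** 3 * Cai))
    I_pCa = I_PCA_MAX * Cai * Cai / (KM_PCA * KM_PCA + Cai * Cai)
    I_Cab = G_CAB * (V - E_CaN)
    I_Nab = G_NAB * (V - E_Na)
    O_ClCa = 0.2 / (1.0 + np.exp(-(V - 46.7) / 7.8))
    I_ClCa = G_CLCA * O_ClCa * (Cai / (Cai + KM_CL)) * (V - E_CL)

    # ---- Ca2+ handling ----
    J_rel = V1_REL * (P_O1 + P_O2) * (CaJSR - Cass) * P_RyR
    J_tr = (CaNSR - CaJSR) / TAU_TR
    J_xfer = (Cass - Cai) / TAU_XFER
    J_leak = V2_LEAK * (CaNSR - Cai)
    J_up = V3_UP * Cai * Cai / (KM_UP * KM_UP + Cai * Cai)
    J_trpn = (K_P_HTRPN * Cai * (HTRPN_TOT - HTRPN_Ca)
              - K_M_HTRPN * HTRPN_Ca
              + K_P_LTRPN * Cai * (LTRPN_TOT - LTRPN_Ca)
              - K_M_LTRPN * LTRPN_Ca)

    B_i = 1.0 / (1.0 + CMDN_TOT * KM_CMDN / (KM_CMDN + Cai) ** 2)
    B_ss = 1.0 / (1.0 + CMDN_TOT * KM_CMDN / (KM_CMDN + Cass) ** 2)
    B_JSR = 1.0 / (1.0 + CSQN_TOT * KM_CSQN / (KM_CSQN + CaJSR) ** 2)

    conv_myo = ACAP * CM / (2.0 * V_MYO * F)
    d[1] = B_i * (J_leak + J_xfer - J_up - J_trpn
                  - (I_Cab + I_pCa - 2.0 * I_NaCa) * conv_myo)
    d[2] = B_ss * (J_rel * V_JSR / V_SS - J_xfer * V_MYO / V_SS
                   - I_CaL * ACAP * CM / (2.0 * V_SS * F))
    d[3] = B_JSR * (J_tr - J_rel)
    d[4] = (J_up - J_leak) * V_MYO / V_NSR - J_tr * V_JSR / V_NSR
    d[5] = K_P_LTRPN * Cai * (LTRPN_TOT - LTRPN_Ca) - K_M_LTRPN * LTRPN_Ca
    d[6] = K_P_HTRPN * Cai * (HTRPN_TOT - HTRPN_Ca) - K_M_HTRPN * HTRPN_Ca

    # RyR
    Cass2 = Cass * Cass
    Cass3 = Cass2 * Cass
    Cass4 = Cass2 * Cass2
    d[8] = (K_PA_RYR * Cass4 * P_C1 - K_MA_RYR * P_O1
            - K_PB_RYR * Cass3 * P_O1 + K_MB_RYR * P_O2
            - K_PC_RYR * P_O1 + K_MC_RYR * P_C2)
    d[9] = K_PB_RYR * Cass3 * P_O1 - K_MB_RYR * P_O2
    d[10] = K_PC_RYR * P_O1 - K_MC_RYR * P_C2
    d[7] = (-0.04 * P_RyR
            - 0.1 * (I_CaL / I_CAL_MAX) * np.exp(-(V - 5.0) ** 2 / 648.0))

    # ---- ion concentrations ----
    conv = ACAP * CM / (V_MYO * F)
    d[26] = -(I_Na + I_Nab + 3.0 * I_NaCa + 3.0 * I_NaK) * conv
    d[27] = -(I_Ktof + I_Ktos + I_K1 + I_Ks + I_Kss + I_Kur + I_Kr
              - 2.0 * I_NaK) * conv

    # ---- membrane potential; i_stim applied as an inward current ----
    I_ion = (I_CaL + I_pCa + I_NaCa + I_Cab + I_Na + I_Nab + I_NaK
             + I_Ktof + I_Ktos + I_K1 + I_Ks + I_Kur + I_Kss + I_Kr
             + I_ClCa)
    d[0] = -(I_ion - i_stim)

    return d


# ---------------------------------------------------------------------------
# membrane currents at a state (diagnostics; mirrors the RHS expressions)
# ---------------------------------------------------------------------------
def currents(state: np.ndarray, params: ModelParameters) -> dict:
    """Individual membrane current densities (pA/pF) at ``state``."""
    y = np.asarray(state, dtype=float)
    V, Cai, Cass, Nai, Ki = (y[IDX["V"]], y[IDX["Cai"]], y[IDX["Cass"]],
                             y[IDX["Nai"]], y[IDX["Ki"]])
    E_Na = RT_F * np.log((0.9 * NAO + 0.1 * KO) / (0.9 * Nai + 0.1 * Ki))
    E_K = RT_F * np.log(KO / Ki)
    E_Kr = RT_F * np.log((0.98 * KO + 0.02 * NAO) / (0.98 * Ki + 0.02 * Nai))
    expEta = np.exp(ETA * V / RT_F)
    expEta1 = np.exp((ETA - 1.0) * V / RT_F)
    sigma = (np.exp(NAO / 67300.0) - 1.0) / 7.0
    f_NaK = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / RT_F)
                   + 0.0365 * sigma * np.exp(-V / RT_F))
    out = {
        "I_Na": G_NA * y[IDX["O_Na"]] * (V - E_Na),
        "I_CaL": G_CAL * y[IDX["O_CaL"]] * (V - E_CAL),
        "I_Ktof": params.scale_gKtof * G_KTOF
                  * y[IDX["ato_f"]] ** 3 * y[IDX["ito_f"]] * (V - E_K),
        "I_Ktos": params.scale_gKtos * G_KTOS
                  * y[IDX["ato_s"]] * y[IDX["ito_s"]] * (V - E_K),
        "I_Kur": params.scale_gKur * G_KUR
                 * y[IDX["aur"]] * y[IDX["iur"]] * (V - E_K),
        "I_Kss": params.scale_gKss * G_KSS
                 * y[IDX["aKss"]] * y[IDX["iKss"]] * (V - E_K),
        "I_K1": params.scale_gK1 * G_K1_MAX * (KO / (KO + 210.0))
                * (V - E_K) / (1.0 + np.exp(0.0896 * (V - E_K))),
        "I_Ks": params.scale_gKs * G_KS * y[IDX["nKs"]] ** 2 * (V - E_K),
        "I_Kr": params.scale_gKr * G_KR * y[IDX["O_K"]] * (V - E_Kr),
        "I_NaK": I_NAK_MAX * f_NaK * (KO / (KO + KM_KO))
                 / (1.0 + (KM_NAI / Nai) ** 1.5),
        "I_NaCa": K_NACA / (KM_NA ** 3 + NAO ** 3) / (KM_CA + CAO)
                  / (1.0 + K_SAT * expEta1)
                  * (expEta * Nai ** 3 * CAO - expEta1 * NAO ** 3 * Cai),
        "I_pCa": I_PCA_MAX * Cai ** 2 / (KM_PCA ** 2 + Cai ** 2),
        "I_Cab": G_CAB * (V - 0.5 * RT_F * np.log(CAO / Cai)),
        "I_Nab": G_NAB * (V - E_Na),
        "I_ClCa": G_CLCA * (0.2 / (1.0 + np.exp(-(V - 46.7) / 7.8)))
                  * (Cai / (Cai + KM_CL)) * (V - E_CL),
    }
    return out


# ---------------------------------------------------------------------------
# validated state container and public derivative evaluation
# ---------------------------------------------------------------------------
HH_GATE_NAMES = ("ato_f", "ito_f", "ato_s", "ito_s", "nKs", "aur", "iur",
                 "aKss", "iKss")
CONCENTRATION_NAMES = ("Cai", "Cass", "CaJSR", "CaNSR", "Nai", "Ki")


@dataclass
class ModelState:
    """Named view of the model state vector with invariant checks."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (N_STATES,):
            raise ValueError(
                f"state vector must have {N_STATES} entries, got {self.y.shape}"
            )

    def __getitem__(self, name: str) -> float:
        return float(self.y[IDX[name]])

    @property
    def V_m(self) -> float:
        return float(self.y[0])

    @property
    def na_markov(self) -> np.ndarray:
        """The 9 Na_v occupancies in ``NA_MARKOV_STATES`` order."""
        explicit = self.y[NA_SLICE]
        c_na3 = 1.0 - explicit.sum()
        return np.concatenate(([c_na3], explicit))

    @property
    def hh_gates(self) -> np.ndarray:
        return np.array([self[g] for g in HH_GATE_NAMES])

    @property
    def concentrations(self) -> dict:
        return {c: self[c] for c in CONCENTRATION_NAMES}

    def validate(self) -> None:
        for i, name in enumerate(STATE_NAMES):
            if not np.isfinite(self.y[i]):
                raise ValueError(f"non-finite state variable {name!r}: {self.y[i]}")
        if abs(self.na_markov.sum() - 1.0) > 1e-8:
            raise ValueError("Na_v Markov occupancies do not sum to 1")
        for g in HH_GATE_NAMES:
            if not -1e-9 <= self[g] <= 1.0 + 1e-9:
                raise ValueError(f"gating variable {g!r} outside [0, 1]")
        for c in CONCENTRATION_NAMES:
            if not self[c] > 0:
                raise ValueError(f"concentration {c!r} must be positive")


def derivatives(
    state: ModelState | np.ndarray,
    params: ModelParameters,
    i_stim: float = 0.0,
) -> dict:
    """Named time-derivatives of every state variable (per ms).

    The derivative of the dependent Markov state of each scheme (C_Na3,
    C1 of I_CaL, the closed RyR state, the deepest closed I_Kr state) is
    the negative sum of its partners, so each Markov sub-block is exactly
    conservative.
    """
    y = state.y if isinstance(state, ModelState) else np.asarray(state, float)
    for i, name in enumerate(STATE_NAMES):
        if not np.isfinite(y[i]):
            raise ValueError(f"non-finite state variable {name!r}: {y[i]}")
    d = rhs(0.0, y, pack_params(params, i_stim))
    out = {name: float(d[i]) for i, name in enumerate(STATE_NAMES)}
    out["C_Na3"] = -float(d[NA_SLICE].sum())
    out["C1_CaL"] = -float(d[IDX["O_CaL"]:IDX["I3_CaL"] + 1].sum())
    out["P_C1"] = -float(d[IDX["P_O1"]:IDX["P_C2"] + 1].sum())
    out["C_K0"] = -float(d[IDX["C_K1"]:IDX["I_K"] + 1].sum())
    return out
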