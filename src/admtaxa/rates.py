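"""Process rates and inhibition functions.

Uptake follows Monod kinetics per population.  Inhibition products:

* acetoclastic (per population i):  I = I_pH,ac * I_IN,lim * I_nh3,i
* propionate   (per population i):  I = I_pH,aa * I_IN,lim * I_h2 * I_nh3,i
* butyrate/valerate, LCFA:          I = I_pH,aa * I_IN,lim * I_h2
* hydrogenotrophic:                 I = I_pH,h2 * I_IN,lim

The free-ammonia term on propionate uptake is the extension; butyrate
oxidation and hydrogenotrophic methanogenesis keep their classical
forms.  All inhibition factors lie in (0, 1].
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet
from .state import IDX, N_STATES, IonSpeciation, ReactorState
from .stoichiometry import N_PROCESSES, PIDX

_EPS = 1e-12


def ammonia_inhibition(S_nh3: float, K_I: float) -> float:
    """Non-competitive free-ammonia inhibition factor 1/(1 + S_nh3/K_I).

    Parameters
    ----------
    S_nh3 : free ammonia concentration, M (>= 0)
    K_I : inhibition constant, M (> 0)
    """
    if K_I <= 0.0:
        raise ValueError(f"ammonia inhibition constant must be positive, got {K_I}")
    if S_nh3 < 0.0:
        raise ValueError(f"free ammonia concentration must be non-negative, got {S_nh3}")
    return 1.0 / (1.0 + S_nh3 / K_I)


def ph_inhibition(S_h: float, pH_UL: float, pH_LL: float) -> float:
    """Low-pH inhibition (Hill form of the benchmark implementation)."""
    n = 3.0 / (pH_UL - pH_LL)
    K_pH = 10.0 ** (-(pH_UL + pH_LL) / 2.0)
    return K_pH ** n / (S_h ** n + K_pH ** n)


def nitrogen_limitation(S_IN: float, K_S_IN: float) -> float:
    """Growth ceases when inorganic nitrogen is exhausted."""
    return S_IN / (S_IN + K_S_IN) if S_IN > 0.0 else 0.0


def hydrogen_inhibition(S_h2: float, K_I_h2: float) -> float:
    return 1.0 / (1.0 + max(S_h2, 0.0) / K_I_h2)


def _monod(S: float, K_S: float) -> float:
    return S / (S + K_S) if S > 0.0 else 0.0


def process_rates(state, spec: IonSpeciation, params: ParameterSet) -> np.ndarray:
    """Rate of every biochemical process, gCOD/L/d on the substrate basis.

    Negative concentrations (integrator excursions) are clipped to zero
    inside this evaluation only; the raw state is never modified.
    """
    y = state.y if isinstance(state, ReactorState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to process_rates")
    c = np.maximum(y, 0.0)
    p = params

    S_su, S_aa, S_fa = c[IDX["S_su"]], c[IDX["S_aa"]], c[IDX["S_fa"]]
    S_va, S_bu, S_pro, S_ac = c[IDX["S_va"]], c[IDX["S_bu"]], c[IDX["S_pro"]], c[IDX["S_ac"]]
    S_h2, S_IN = c[IDX["S_h2"]], c[IDX["S_IN"]]

    I_ph_aa = ph_inhibition(spec.S_h, p.pH_UL_aa, p.pH_LL_aa)
    I_ph_ac = ph_inhibition(spec.S_h, p.pH_UL_ac, p.pH_LL_ac)
    I_ph_h2 = ph_inhibition(spec.S_h, p.pH_UL_h2, p.pH_LL_h2)
    I_in = nitrogen_limitation(S_IN, p.K_S_IN)
    I_h2_fa = hydrogen_inhibition(S_h2, p.K_I_h2_fa)
    I_h2_c4 = hydrogen_inhibition(S_h2, p.K_I_h2_c4)
    I_h2_pro = hydrogen_inhibition(S_h2, p.K_I_h2_pro)
    S_nh3 = max(spec.S_nh3, 0.0)
    I_nh3_ac1 = ammonia_inhibition(S_nh3, p.K_I_nh3_ac1)
    I_nh3_ac2 = ammonia_inhibition(S_nh3, p.K_I_nh3_ac2)
    I_nh3_pro1 = ammonia_inhibition(S_nh3, p.K_I_nh3_pro1)
    I_nh3_pro2 = ammonia_inhibition(S_nh3, p.K_I_nh3_pro2)

    rho = np.zeros(N_PROCESSES)
    rho[PIDX["disintegration"]] = p.k_dis * c[IDX["X_c"]]
    rho[PIDX["hydrolysis_ch"]] = p.k_hyd_ch * c[IDX["X_ch"]]
    rho[PIDX["hydrolysis_pr"]] = p.k_hyd_pr * c[IDX["X_pr"]]
    rho[PIDX["hydrolysis_li"]] = p.k_hyd_li * c[IDX["X_li"]]

    I_ferm = I_ph_aa * I_in
    rho[PIDX["uptake_su"]] = p.k_m_su * _monod(S_su, p.K_S_su) * c[IDX["X_su"]] * I_ferm
    rho[PIDX["uptake_aa"]] = p.k_m_aa * _monod(S_aa, p.K_S_aa) * c[IDX["X_aa"]] * I_ferm
    rho[PIDX["uptake_fa"]] = p.k_m_fa * _monod(S_fa, p.K_S_fa) * c[IDX["X_fa"]] * I_ferm * I_h2_fa
    # valerate and butyrate compete for the same degrader
    frac_va = S_va / (S_va + S_bu + _EPS)
    frac_bu = S_bu / (S_va + S_bu + _EPS)
    rho[PIDX["uptake_va"]] = (
        p.k_m_c4 * _monod(S_va, p.K_S_c4) * c[IDX["X_c4"]] * frac_va * I_ferm * I_h2_c4
    )
    rho[PIDX["uptake_bu"]] = (
        p.k_m_c4 * _monod(S_bu, p.K_S_c4) * c[IDX["X_c4"]] * frac_bu * I_ferm * I_h2_c4
    )
    rho[PIDX["uptake_pro1"]] = (
        p.k_m_pro * _monod(S_pro, p.K_S_pro1) * c[IDX["X_pro1"]]
        * I_ferm * I_h2_pro * I_nh3_pro1
    )
    rho[PIDX["uptake_pro2"]] = (
        p.k_m_pro * _monod(S_pro, p.K_S_pro2) * c[IDX["X_pro2"]]
        * I_ferm * I_h2_pro * I_nh3_pro2
    )
    rho[PIDX["uptake_ac1"]] = (
        p.k_m_ac * _monod(S_ac, p.K_S_ac1) * c[IDX["X_ac1"]] * I_ph_ac * I_in * I_nh3_ac1
    )
    rho[PIDX["uptake_ac2"]] = (
        p.k_m_ac * _monod(S_ac, p.K_S_ac2) * c[IDX["X_ac2"]] * I_ph_ac * I_in * I_nh3_ac2
    )
    rho[PIDX["uptake_h2"]] = (
        p.k_m_h2 * _monod(S_h2, p.K_S_h2) * c[IDX["X_h2"]] * I_ph_h2 * I_in
    )

    for pop in ("su", "aa", "fa", "c4", "pro1", "pro2", "ac1", "ac2", "h2"):
        rho[PIDX[f"decay_{pop}"]] = p.k_dec * c[IDX[f"X_{pop}"]]
    return rho


def partial_pressures(state, params: ParameterSet, eq) -> tuple[float, float, float, float]:
    """(p_h2, p_ch4, p_co2, P_total) in bar, including water vapour."""
    from .chemistry import R_GAS

    y = state.y if isinstance(state, ReactorState) else np.asarray(state, dtype=float)
    RT = R_GAS * params.T_op
    p_h2 = max(y[IDX["S_gas_h2"]], 0.0) * RT / 16.0
    p_ch4 = max(y[IDX["S_gas_ch4"]], 0.0) * RT / 64.0
    p_co2 = max(y[IDX["S_gas_co2"]], 0.0) * RT
    return p_h2, p_ch4, p_co2, p_h2 + p_ch4 + p_co2 + eq.p_gas_h2o


def gas_flow(state, params: ParameterSet, eq=None) -> tuple[float, dict[str, float]]:
    """Biogas volumetric flow (L/d) and dry composition.

    Linear overpressure law ``q = k_p * (P_headspace - P_atm)``,
    clipped at zero (no backflow through the gas line).
    """
    from .chemistry import equilibrium_constants

    if eq is None:
        eq = equilibrium_constants(params)
    p_h2, p_ch4, p_co2, P = partial_pressures(state, params, eq)
    q = max(params.k_p * (P - params.P_atm), 0.0)
    dry = p_h2 + p_ch4 + p_co2
    comp = {
        "h2": p_h2 / dry if dry > 0 else 0.0,
        "ch4": p_ch4 / dry if dry > 0 else 0.0,
        "co2": p_co2 / dry if dry > 0 else 0.0,
    }
    return q, comp
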