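"""Acid-base speciation and pH.

The pH is treated as a fast algebraic variable: at every right-hand-side
evaluation the proton concentration is obtained by scalar root-finding
on the charge balance

    S_cat + S_nh4 + S_h  =  S_an + S_hco3 + S_ac- + S_pro- + S_bu- + S_va- + S_oh

with the VFA anions converted from gCOD/L to M by their COD-per-mole
(64, 112, 160, 208 gCOD/mol for C2..C5).  Equilibrium constants are
given at 298.15 K and corrected to the operating temperature with the
van 't Hoff relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .parameters import ParameterSet
from .state import IonSpeciation, ReactorState

R_GAS = 8.3145e-2      # bar L / (mol K) == bar M^-1 K^-1

# gCOD per mole of acid (theoretical oxygen demand)
COD_AC = 64.0
COD_PRO = 112.0
COD_BU = 160.0
COD_VA = 208.0

# reaction enthalpies for van 't Hoff correction, J/mol
DH_KW = 55900.0
DH_KA_CO2 = 7646.0
DH_KA_IN = 51965.0
DH_KH_CO2 = -19410.0
DH_KH_CH4 = -14240.0
DH_KH_H2 = -4180.0


def _vant_hoff(K_ref: float, dH: float, T_base: float, T_op: float) -> float:
    return K_ref * math.exp((dH / 8.3145) * (1.0 / T_base - 1.0 / T_op))


@dataclass(frozen=True)
class EquilibriumConstants:
    K_w: float        # M^2
    K_a_va: float     # M
    K_a_bu: float
    K_a_pro: float
    K_a_ac: float
    K_a_co2: float
    K_a_IN: float
    K_H_co2: float    # M/bar
    K_H_ch4: float
    K_H_h2: float
    p_gas_h2o: float  # bar


def equilibrium_constants(params: ParameterSet) -> EquilibriumConstants:
    """Temperature-corrected equilibrium and Henry constants."""
    Tb = params.T_base
    T = params.T_op if params.temperature_correction else params.T_base
    return EquilibriumConstants(
        K_w=_vant_hoff(1e-14, DH_KW, Tb, T),
        K_a_va=10.0 ** -4.86,
        K_a_bu=10.0 ** -4.82,
        K_a_pro=10.0 ** -4.88,
        K_a_ac=10.0 ** -4.76,
        K_a_co2=_vant_hoff(10.0 ** -6.35, DH_KA_CO2, Tb, T),
        K_a_IN=_vant_hoff(10.0 ** -9.25, DH_KA_IN, Tb, T),
        K_H_co2=_vant_hoff(0.035, DH_KH_CO2, Tb, T),
        K_H_ch4=_vant_hoff(0.0014, DH_KH_CH4, Tb, T),
        K_H_h2=_vant_hoff(7.8e-4, DH_KH_H2, Tb, T),
        # Antoine-type water vapour pressure anchored at 0.0313 bar, 298.15 K
        p_gas_h2o=0.0313 * math.exp(5290.0 * (1.0 / 298.15 - 1.0 / params.T_op)),
    )


def free_ammonia_fraction(pH: float, params: ParameterSet) -> float:
    """Fraction of total ammonia nitrogen present as free NH3 at ``pH``."""
    eq = equilibrium_constants(params)
    S_h = 10.0 ** -pH
    return eq.K_a_IN / (eq.K_a_IN + S_h)


def _charge_balance(S_h, S_cat, S_an, S_IC, S_IN, vfa, eq):
    """Signed net charge (M) at proton concentration ``S_h``."""
    S_ac, S_pro, S_bu, S_va = vfa
    pos = S_cat + S_IN * S_h / (eq.K_a_IN + S_h) + S_h
    neg = (
        S_an
        + S_IC * eq.K_a_co2 / (eq.K_a_co2 + S_h)
        + (S_ac / COD_AC) * eq.K_a_ac / (eq.K_a_ac + S_h)
        + (S_pro / COD_PRO) * eq.K_a_pro / (eq.K_a_pro + S_h)
        + (S_bu / COD_BU) * eq.K_a_bu / (eq.K_a_bu + S_h)
        + (S_va / COD_VA) * eq.K_a_va / (eq.K_a_va + S_h)
        + eq.K_w / S_h
    )
    return pos - neg


class SpeciationError(RuntimeError):
    """Charge balance has no root in the admissible pH window."""


PH_LO, PH_HI = 2.0, 12.0


def _charge_balance_prime(S_h, S_IC, S_IN, vfa, eq):
    """d(charge balance)/d(S_h); the balance is strictly increasing."""
    S_ac, S_pro, S_bu, S_va = vfa
    return (
        1.0
        + S_IN * eq.K_a_IN / (eq.K_a_IN + S_h) ** 2
        + S_IC * eq.K_a_co2 / (eq.K_a_co2 + S_h) ** 2
        + (S_ac / COD_AC) * eq.K_a_ac / (eq.K_a_ac + S_h) ** 2
        + (S_pro / COD_PRO) * eq.K_a_pro / (eq.K_a_pro + S_h) ** 2
        + (S_bu / COD_BU) * eq.K_a_bu / (eq.K_a_bu + S_h) ** 2
        + (S_va / COD_VA) * eq.K_a_va / (eq.K_a_va + S_h) ** 2
        + eq.K_w / S_h ** 2
    )


def solve_ph(S_cat, S_an, S_IC, S_IN, vfa, eq, ph_guess: float | None = None) -> float:
    """Root of the charge balance as pH in (2, 12).

    Warm-started Newton iteration on S_h (the balance is monotone in
    S_h, so Newton from a decent guess converges quadratically); falls
    back to bracketing if the guess is poor.
    """
    if ph_guess is not None and PH_LO < ph_guess < PH_HI:
        S_h = 10.0 ** -ph_guess
        for _ in range(30):
            f = _charge_balance(S_h, S_cat, S_an, S_IC, S_IN, vfa, eq)
            step = f / _charge_balance_prime(S_h, S_IC, S_IN, vfa, eq)
            S_h_new = S_h - step
            if not (10.0 ** -PH_HI < S_h_new < 10.0 ** -PH_LO):
                break
            if abs(S_h_new - S_h) <= 1e-16 + 1e-12 * S_h_new:
                S_h = S_h_new
                f_final = _charge_balance(S_h, S_cat, S_an, S_IC, S_IN, vfa, eq)
                if abs(f_final) < 1e-10:
                    return -math.log10(S_h)
                break
            S_h = S_h_new

    f = lambda pH: _charge_balance(10.0 ** -pH, S_cat, S_an, S_IC, S_IN, vfa, eq)
    f_lo, f_hi = f(PH_LO), f(PH_HI)
    if f_lo * f_hi > 0.0:
        raise SpeciationError(
            f"charge balance has no sign change on pH ({PH_LO}, {PH_HI}): "
            f"f({PH_LO})={f_lo:.3e}, f({PH_HI})={f_hi:.3e}"
        )
    return brentq(f, PH_LO, PH_HI, xtol=1e-12, rtol=8.9e-16, maxiter=200)


def speciate(state: ReactorState, params: ParameterSet, eq: EquilibriumConstants | None = None,
             ph_guess: float | None = None) -> IonSpeciation:
    """Full ion speciation for a reactor state.

    Negative concentrations (transient integrator excursions) are
    clipped to zero before solving.  ``eq`` may be passed to reuse
    precomputed equilibrium constants in hot loops, and ``ph_guess``
    warm-starts the root solve.
    """
    if eq is None:
        eq = equilibrium_constants(params)
    S_cat = max(state.S_cat, 0.0)
    S_an = max(state.S_an, 0.0)
    S_IC = max(state.S_IC, 0.0)
    S_IN = max(state.S_IN, 0.0)
    vfa = (max(state.S_ac, 0.0), max(state.S_pro, 0.0),
           max(state.S_bu, 0.0), max(state.S_va, 0.0))
    for v in (S_cat, S_an, S_IC, S_IN, *vfa):
        if not math.isfinite(v):
            raise SpeciationError("non-finite concentration in speciation input")
    pH = solve_ph(S_cat, S_an, S_IC, S_IN, vfa, eq, ph_guess=ph_guess)
    S_h = 10.0 ** -pH
    S_nh4 = S_IN * S_h / (eq.K_a_IN + S_h)
    S_hco3 = S_IC * eq.K_a_co2 / (eq.K_a_co2 + S_h)
    spec = IonSpeciation(
        pH=pH,
        S_h=S_h,
        S_oh=eq.K_w / S_h,
        S_nh3=S_IN - S_nh4,
        S_nh4=S_nh4,
        S_hco3=S_hco3,
        S_co2=S_IC - S_hco3,
        S_ac_ion=vfa[0] / COD_AC * eq.K_a_ac / (eq.K_a_ac + S_h),
        S_pro_ion=vfa[1] / COD_PRO * eq.K_a_pro / (eq.K_a_pro + S_h),
        S_bu_ion=vfa[2] / COD_BU * eq.K_a_bu / (eq.K_a_bu + S_h),
        S_va_ion=vfa[3] / COD_VA * eq.K_a_va / (eq.K_a_va + S_h),
        residual=_charge_balance(S_h, S_cat, S_an, S_IC, S_IN, vfa, eq),
    )
    return spec
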