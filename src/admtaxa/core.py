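"""Full right-hand side of the extended CSTR model.

Every liquid component carries a dilution term ``D * (c_in - c)``;
biological conversions enter through the Petersen matrix; H2, CH4 and
CO2 are exchanged with the headspace via two-film transfer; the
headspace is vented through a linear overpressure law.  The pH is
solved algebraically at every evaluation.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .chemistry import equilibrium_constants, speciate
from .parameters import ParameterSet
from .rates import gas_flow, partial_pressures, process_rates
from .state import GAS_NAMES, IDX, N_STATES, ReactorState
from .stoichiometry import build_petersen_matrix, carbon_content, cod_content, nitrogen_content


class Model:
    """Precompiled reaction system for one parameter set."""

    def __init__(self, params: ParameterSet):
        self.params = params
        self.eq = equilibrium_constants(params)
        self.nu = build_petersen_matrix(params)
        self.carbon = carbon_content(params)
        self.nitrogen = nitrogen_content(params)
        self.cod = cod_content()
        self._i_h2 = IDX["S_h2"]
        self._i_ch4 = IDX["S_ch4"]
        self._i_ic = IDX["S_IC"]
        self._gas_idx = np.array([IDX[n] for n in GAS_NAMES])
        self._liquid = np.ones(N_STATES, dtype=bool)
        self._liquid[self._gas_idx] = False
        self._ph_guess: float | None = None

    def speciate(self, y: np.ndarray):
        spec = speciate(ReactorState(y), self.params, self.eq, ph_guess=self._ph_guess)
        self._ph_guess = spec.pH
        return spec

    def transfer_rates(self, y: np.ndarray, spec) -> np.ndarray:
        """Liquid->gas transfer of (h2, ch4, co2), per liquid volume."""
        from .chemistry import R_GAS

        p = self.params
        p_h2, p_ch4, p_co2, _ = partial_pressures(y, p, self.eq)
        return np.array([
            p.k_L_a * (max(y[self._i_h2], 0.0) - 16.0 * self.eq.K_H_h2 * p_h2),
            p.k_L_a * (max(y[self._i_ch4], 0.0) - 64.0 * self.eq.K_H_ch4 * p_ch4),
            p.k_L_a * (spec.S_co2 - self.eq.K_H_co2 * p_co2),
        ])

    def rhs(self, t: float, y: np.ndarray, s_in: np.ndarray, dilution: float) -> np.ndarray:
        """Time derivative of the full state vector.

        ``s_in`` is the influent composition (gas entries ignored) and
        ``dilution`` the current dilution rate 1/HRT (0 while feeding
        is suspended).
        """
        p = self.params
        spec = self.speciate(y)
        rho = process_rates(y, spec, p)

        dy = self.nu @ rho
        if dilution != 0.0:
            dy[self._liquid] += dilution * (s_in[self._liquid] - y[self._liquid])

        rT = self.transfer_rates(y, spec)
        dy[self._i_h2] -= rT[0]
        dy[self._i_ch4] -= rT[1]
        dy[self._i_ic] -= rT[2]

        q, _ = gas_flow(y, p, self.eq)
        conv = np.array([1.0, 1.0, 1.0])  # COD-equiv for h2/ch4, molar for co2
        dy[self._gas_idx] = (
            -y[self._gas_idx] * q / p.V_gas + rT * conv * p.V_liq / p.V_gas
        )
        return dy

    def make_rhs(self, influent: Callable[[float], np.ndarray],
                 dilution: Callable[[float], float]) -> Callable[[float, np.ndarray], np.ndarray]:
        def f(t: float, y: np.ndarray) -> np.ndarray:
            return self.rhs(t, y, influent(t), dilution(t))
        return f

    # --- audit helpers ------------------------------------------------
    def total_cod(self, y: np.ndarray) -> float:
        """Liquid-phase COD inventory, gCOD/L."""
        liq = self.cod.copy()
        liq[self._gas_idx] = 0.0
        return float(liq @ y)

    def total_nitrogen(self, y: np.ndarray) -> float:
        """Liquid-phase nitrogen inventory, M."""
        return float(self.nitrogen @ np.where(self._liquid, y, 0.0))

    def gas_cod_export(self, y: np.ndarray) -> float:
        """COD leaving through the gas line, gCOD per liquid volume per day."""
        q, _ = gas_flow(y, self.params, self.eq)
        cod_gas = y[IDX["S_gas_h2"]] + y[IDX["S_gas_ch4"]]
        return q * cod_gas / self.params.V_liq


def rhs(t: float, state, influent, params: ParameterSet, dilution: float | None = None) -> np.ndarray:
    """Convenience single-shot evaluation of the model derivative.

    ``influent`` may be a full-length vector or a mapping from state
    names to influent concentrations.  For repeated evaluation use
    :class:`Model` directly.
    """
    y = state.y if isinstance(state, ReactorState) else np.asarray(state, dtype=float)
    if isinstance(influent, dict):
        s_in = np.zeros(N_STATES)
        for name, v in influent.items():
            s_in[IDX[name]] = v
    else:
        s_in = np.asarray(influent, dtype=float)
    if dilution is None:
        dilution = 1.0 / params.HRT
    return Model(params).rhs(t, y, s_in, dilution)
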