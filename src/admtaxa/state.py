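"""State vector layout and typed views.

Units follow ADM1 benchmark conventions: gCOD/L (== kgCOD/m3) for all
organic solubles and particulates, M (kmole/m3) for inorganic carbon,
inorganic nitrogen, cations and anions.  Gas-phase components are kept
as COD- (resp. mole-) equivalent concentrations in the headspace, from
which partial pressures follow via the ideal gas law.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

#: Ordered component names of the liquid + gas state vector.
STATE_NAMES: tuple[str, ...] = (
    # soluble organics, gCOD/L
    "S_su", "S_aa", "S_fa", "S_va", "S_bu", "S_pro", "S_ac", "S_h2", "S_ch4",
    # inorganic carbon / nitrogen, M
    "S_IC", "S_IN",
    # soluble inerts, gCOD/L
    "S_I",
    # particulates, gCOD/L
    "X_c", "X_ch", "X_pr", "X_li",
    "X_su", "X_aa", "X_fa", "X_c4",
    "X_pro1", "X_pro2", "X_ac1", "X_ac2", "X_h2",
    "X_I",
    # ions, M
    "S_cat", "S_an",
    # gas phase (headspace concentrations; h2/ch4 in gCOD/L, co2 in M)
    "S_gas_h2", "S_gas_ch4", "S_gas_co2",
)

IDX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}

N_STATES = len(STATE_NAMES)

#: Names of the biomass (active particulate) components.
BIOMASS_NAMES: tuple[str, ...] = (
    "X_su", "X_aa", "X_fa", "X_c4", "X_pro1", "X_pro2", "X_ac1", "X_ac2", "X_h2",
)

#: Denominator convention for "methanogen" relative abundance.
METHANOGEN_NAMES: tuple[str, ...] = ("X_ac1", "X_ac2", "X_h2")

#: Denominator convention for "bacteria" relative abundance.
BACTERIA_NAMES: tuple[str, ...] = ("X_su", "X_aa", "X_fa", "X_c4", "X_pro1", "X_pro2")

GAS_NAMES: tuple[str, ...] = ("S_gas_h2", "S_gas_ch4", "S_gas_co2")


class ReactorState:
    """Thin named view over a reactor state vector.

    Behaves like a mutable mapping from component name to value while
    holding the underlying ``numpy`` vector used by the integrator.
    """

    __slots__ = ("y",)

    def __init__(self, y=None, **components: float):
        if y is None:
            y = np.zeros(N_STATES)
        else:
            y = np.asarray(y, dtype=float).copy()
            if y.shape != (N_STATES,):
                raise ValueError(f"state vector must have length {N_STATES}, got {y.shape}")
        self.y = y
        for name, value in components.items():
            self[name] = value

    def __getitem__(self, name: str) -> float:
        return float(self.y[IDX[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.y[IDX[name]] = value

    def __getattr__(self, name: str) -> float:
        try:
            return float(self.y[IDX[name]])
        except KeyError:
            raise AttributeError(name) from None

    def __iter__(self) -> Iterator[str]:
        return iter(STATE_NAMES)

    def copy(self) -> "ReactorState":
        return ReactorState(self.y)

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(STATE_NAMES, self.y)}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(f"{k}={v:.4g}" for k, v in self.as_dict().items() if v != 0.0)
        return f"ReactorState({parts})"


@dataclass(frozen=True)
class IonSpeciation:
    """Algebraic acid-base state at one instant.

    All concentrations in M.  ``residual`` is the signed charge-balance
    defect at the returned pH and must be below the solver tolerance.
    """

    pH: float
    S_h: float
    S_oh: float
    S_nh3: float
    S_nh4: float
    S_hco3: float
    S_co2: float
    S_ac_ion: float
    S_pro_ion: float
    S_bu_ion: float
    S_va_ion: float
    residual: float
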