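"""Petersen matrix of the extended reaction network.

Twenty-three biochemical processes map onto the 31 state components.
Relative to the classical network, propionate and acetate uptake each
appear twice (once per competing population).  The inorganic-carbon and
inorganic-nitrogen rows are not taken from tabulated values but are
computed as closure terms so that every process column conserves
elemental C and N exactly; COD conservation holds by construction of
the product fractions.

Acetate-producing processes (the summation feeding the acetate balance)
are the uptakes of sugars, amino acids, LCFA, valerate, butyrate and
propionate (both populations).
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet
from .state import IDX, N_STATES, STATE_NAMES

PROCESS_NAMES: tuple[str, ...] = (
    "disintegration",
    "hydrolysis_ch", "hydrolysis_pr", "hydrolysis_li",
    "uptake_su", "uptake_aa", "uptake_fa",
    "uptake_va", "uptake_bu",
    "uptake_pro1", "uptake_pro2",
    "uptake_ac1", "uptake_ac2",
    "uptake_h2",
    "decay_su", "decay_aa", "decay_fa", "decay_c4",
    "decay_pro1", "decay_pro2", "decay_ac1", "decay_ac2", "decay_h2",
)

N_PROCESSES = len(PROCESS_NAMES)

PIDX: dict[str, int] = {name: j for j, name in enumerate(PROCESS_NAMES)}

#: Processes whose stoichiometry produces acetate.
ACETATE_PRODUCING: tuple[str, ...] = (
    "uptake_su", "uptake_aa", "uptake_fa", "uptake_va", "uptake_bu",
    "uptake_pro1", "uptake_pro2",
)

_DECAY_OF = {
    "decay_su": "X_su", "decay_aa": "X_aa", "decay_fa": "X_fa",
    "decay_c4": "X_c4", "decay_pro1": "X_pro1", "decay_pro2": "X_pro2",
    "decay_ac1": "X_ac1", "decay_ac2": "X_ac2", "decay_h2": "X_h2",
}


def carbon_content(params: ParameterSet) -> np.ndarray:
    """kmole C per unit of each state component (per gCOD or per M)."""
    c = np.zeros(N_STATES)
    p = params
    values = {
        "S_su": p.C_su, "S_aa": p.C_aa, "S_fa": p.C_fa, "S_va": p.C_va,
        "S_bu": p.C_bu, "S_pro": p.C_pro, "S_ac": p.C_ac, "S_ch4": p.C_ch4,
        "S_IC": 1.0, "S_I": p.C_sI,
        "X_c": p.C_xc, "X_ch": p.C_ch, "X_pr": p.C_pr, "X_li": p.C_li,
        "X_su": p.C_bac, "X_aa": p.C_bac, "X_fa": p.C_bac, "X_c4": p.C_bac,
        "X_pro1": p.C_bac, "X_pro2": p.C_bac, "X_ac1": p.C_bac,
        "X_ac2": p.C_bac, "X_h2": p.C_bac, "X_I": p.C_xI,
        "S_gas_ch4": p.C_ch4, "S_gas_co2": 1.0,
    }
    for name, v in values.items():
        c[IDX[name]] = v
    return c


def nitrogen_content(params: ParameterSet) -> np.ndarray:
    """kmole N per unit of each state component."""
    n = np.zeros(N_STATES)
    p = params
    values = {
        "S_aa": p.N_aa, "S_IN": 1.0, "S_I": p.N_I,
        "X_c": p.N_xc, "X_pr": p.N_aa, "X_I": p.N_I,
        "X_su": p.N_bac, "X_aa": p.N_bac, "X_fa": p.N_bac, "X_c4": p.N_bac,
        "X_pro1": p.N_bac, "X_pro2": p.N_bac, "X_ac1": p.N_bac,
        "X_ac2": p.N_bac, "X_h2": p.N_bac,
    }
    for name, v in values.items():
        n[IDX[name]] = v
    return n


def cod_content() -> np.ndarray:
    """COD weight of each component (1 for organics incl. inerts, else 0)."""
    cod = np.zeros(N_STATES)
    for name in STATE_NAMES:
        if name.startswith(("X_",)) or name in (
            "S_su", "S_aa", "S_fa", "S_va", "S_bu", "S_pro", "S_ac",
            "S_h2", "S_ch4", "S_I", "S_gas_h2", "S_gas_ch4",
        ):
            cod[IDX[name]] = 1.0
    return cod


def build_petersen_matrix(params: ParameterSet) -> np.ndarray:
    """Yield-coefficient matrix ``nu`` of shape (N_STATES, N_PROCESSES).

    ``d(state)/dt |_bio = nu @ rho``.  Gas transfer is handled outside
    the matrix.  The S_IC and S_IN rows are closure terms.
    """
    p = params
    nu = np.zeros((N_STATES, N_PROCESSES))

    def set_col(process: str, entries: dict[str, float]) -> None:
        j = PIDX[process]
        for name, v in entries.items():
            nu[IDX[name], j] = v

    set_col("disintegration", {
        "X_c": -1.0, "S_I": p.f_sI_xc, "X_ch": p.f_ch_xc,
        "X_pr": p.f_pr_xc, "X_li": p.f_li_xc, "X_I": p.f_xI_xc,
    })
    set_col("hydrolysis_ch", {"X_ch": -1.0, "S_su": 1.0})
    set_col("hydrolysis_pr", {"X_pr": -1.0, "S_aa": 1.0})
    set_col("hydrolysis_li", {"X_li": -1.0, "S_fa": p.f_fa_li, "S_su": 1.0 - p.f_fa_li})

    set_col("uptake_su", {
        "S_su": -1.0,
        "S_bu": (1 - p.Y_su) * p.f_bu_su, "S_pro": (1 - p.Y_su) * p.f_pro_su,
        "S_ac": (1 - p.Y_su) * p.f_ac_su, "S_h2": (1 - p.Y_su) * p.f_h2_su,
        "X_su": p.Y_su,
    })
    set_col("uptake_aa", {
        "S_aa": -1.0,
        "S_va": (1 - p.Y_aa) * p.f_va_aa, "S_bu": (1 - p.Y_aa) * p.f_bu_aa,
        "S_pro": (1 - p.Y_aa) * p.f_pro_aa, "S_ac": (1 - p.Y_aa) * p.f_ac_aa,
        "S_h2": (1 - p.Y_aa) * p.f_h2_aa,
        "X_aa": p.Y_aa,
    })
    set_col("uptake_fa", {
        "S_fa": -1.0,
        "S_ac": (1 - p.Y_fa) * 0.7, "S_h2": (1 - p.Y_fa) * 0.3,
        "X_fa": p.Y_fa,
    })
    set_col("uptake_va", {
        "S_va": -1.0,
        "S_pro": (1 - p.Y_c4) * 0.54, "S_ac": (1 - p.Y_c4) * 0.31,
        "S_h2": (1 - p.Y_c4) * 0.15,
        "X_c4": p.Y_c4,
    })
    set_col("uptake_bu", {
        "S_bu": -1.0,
        "S_ac": (1 - p.Y_c4) * 0.8, "S_h2": (1 - p.Y_c4) * 0.2,
        "X_c4": p.Y_c4,
    })
    for proc, pop in (("uptake_pro1", "X_pro1"), ("uptake_pro2", "X_pro2")):
        set_col(proc, {
            "S_pro": -1.0,
            "S_ac": (1 - p.Y_pro) * 0.57, "S_h2": (1 - p.Y_pro) * 0.43,
            pop: p.Y_pro,
        })
    for proc, pop in (("uptake_ac1", "X_ac1"), ("uptake_ac2", "X_ac2")):
        set_col(proc, {"S_ac": -1.0, "S_ch4": 1 - p.Y_ac, pop: p.Y_ac})
    set_col("uptake_h2", {"S_h2": -1.0, "S_ch4": 1 - p.Y_h2, "X_h2": p.Y_h2})

    for proc, pop in _DECAY_OF.items():
        set_col(proc, {pop: -1.0, "X_c": 1.0})

    # --- elemental closure: S_IC and S_IN absorb the per-column C/N
    # imbalance of the organic species so that every process conserves
    # carbon and nitrogen exactly.
    carbon = carbon_content(params)
    nitrogen = nitrogen_content(params)
    i_ic, i_in = IDX["S_IC"], IDX["S_IN"]
    assert np.all(nu[i_ic] == 0.0) and np.all(nu[i_in] == 0.0)
    nu[i_ic, :] = -carbon @ nu
    nu[i_in, :] = -nitrogen @ nu
    return nu
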