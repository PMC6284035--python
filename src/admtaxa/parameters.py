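"""Model parameters.

Defaults combine the widely used ADM1 benchmark parameterisation
(mesophilic, high-rate) with the two-population extension for
acetoclastic methanogens and propionate oxidizers:

* ``X_ac1`` — ammonia-tolerant acetoclast (*Methanosarcina*-like):
  K_S = 0.34 gCOD/L, K_I,nh3 = 0.3387 M
* ``X_ac2`` — ammonia-sensitive acetoclast (*Methanosaeta*-like):
  K_S = 0.15 gCOD/L, K_I,nh3 = 0.0052 M
* ``X_pro1`` — ammonia-tolerant propionate oxidizer (unknown taxon):
  K_S = 0.34 gCOD/L, K_I,nh3 = 0.4887 M
* ``X_pro2`` — ammonia-sensitive propionate oxidizer
  (*Syntrophobacter*-like): K_S = 0.10 gCOD/L, K_I,nh3 = 0.0036 M

Both populations of a guild share yield, maximum uptake rate and decay
rate; they differ only in substrate affinity and ammonia sensitivity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


@dataclass
class ParameterSet:
    """Stoichiometric, kinetic, physico-chemical and reactor parameters.

    Units: rates 1/d or gCOD_S/gCOD_X/d, half-saturation gCOD/L,
    inhibition constants M, carbon/nitrogen contents kmole per kgCOD,
    volumes L, temperature K, pressure bar.
    """

    # --- reactor geometry / operation -------------------------------
    V_liq: float = 6.0            # working volume, L
    V_gas: float = 0.5            # headspace volume, L (not reported; configurable)
    HRT: float = 5.5              # hydraulic retention time, d
    T_op: float = 310.15          # operating temperature, K (37 degC)
    T_base: float = 298.15        # reference temperature of equilibrium constants, K
    P_atm: float = 1.013          # ambient pressure, bar
    k_p: float = 5.0e4            # pipe-resistance coefficient, L/d/bar (linear law)
    k_L_a: float = 200.0          # gas-liquid transfer coefficient, 1/d
    temperature_correction: bool = True  # van 't Hoff correction of equilibria to T_op

    # --- disintegration / hydrolysis --------------------------------
    k_dis: float = 0.5
    k_hyd_ch: float = 10.0
    k_hyd_pr: float = 10.0
    k_hyd_li: float = 10.0

    # --- composite disintegration fractions -------------------------
    f_sI_xc: float = 0.1
    f_xI_xc: float = 0.2
    f_ch_xc: float = 0.2
    f_pr_xc: float = 0.2
    f_li_xc: float = 0.3
    f_fa_li: float = 0.95

    # --- fermentation product fractions -----------------------------
    f_h2_su: float = 0.19
    f_bu_su: float = 0.13
    f_pro_su: float = 0.27
    f_ac_su: float = 0.41
    f_h2_aa: float = 0.06
    f_va_aa: float = 0.23
    f_bu_aa: float = 0.26
    f_pro_aa: float = 0.05
    f_ac_aa: float = 0.40

    # --- yields (gCOD_X / gCOD_S) -----------------------------------
    Y_su: float = 0.10
    Y_aa: float = 0.08
    Y_fa: float = 0.06
    Y_c4: float = 0.06
    Y_pro: float = 0.04
    Y_ac: float = 0.05
    Y_h2: float = 0.06

    # --- uptake kinetics --------------------------------------------
    k_m_su: float = 30.0
    K_S_su: float = 0.5
    k_m_aa: float = 50.0
    K_S_aa: float = 0.3
    k_m_fa: float = 6.0
    K_S_fa: float = 0.4
    K_I_h2_fa: float = 5.0e-6
    k_m_c4: float = 20.0
    K_S_c4: float = 0.2
    K_I_h2_c4: float = 1.0e-5
    k_m_pro: float = 13.0
    K_S_pro1: float = 0.34
    K_S_pro2: float = 0.10
    K_I_h2_pro: float = 3.5e-6
    k_m_ac: float = 8.0
    K_S_ac1: float = 0.34
    K_S_ac2: float = 0.15
    k_m_h2: float = 35.0
    K_S_h2: float = 7.0e-6
    k_dec: float = 0.02
    K_S_IN: float = 1.0e-4        # nitrogen-limitation constant, M

    # --- free-ammonia inhibition constants, M -----------------------
    K_I_nh3_ac1: float = 0.3387
    K_I_nh3_ac2: float = 0.0052
    K_I_nh3_pro1: float = 0.4887
    K_I_nh3_pro2: float = 0.0036

    # --- pH inhibition ranges ---------------------------------------
    pH_UL_aa: float = 5.5
    pH_LL_aa: float = 4.0
    pH_UL_ac: float = 7.0
    pH_LL_ac: float = 6.0
    pH_UL_h2: float = 6.0
    pH_LL_h2: float = 5.0

    # --- carbon contents, kmole C / kgCOD ---------------------------
    C_su: float = 0.0313
    C_aa: float = 0.03
    C_fa: float = 0.0217
    C_va: float = 0.024
    C_bu: float = 0.025
    C_pro: float = 0.0268
    C_ac: float = 0.0313
    C_ch4: float = 0.0156
    C_xc: float = 0.02786
    C_sI: float = 0.03
    C_ch: float = 0.0313
    C_pr: float = 0.03
    C_li: float = 0.022
    C_xI: float = 0.03
    C_bac: float = 0.0313

    # --- nitrogen contents, kmole N / kgCOD -------------------------
    N_xc: float = 0.0376 / 14.0
    N_I: float = 0.06 / 14.0
    N_aa: float = 0.007
    N_bac: float = 0.08 / 14.0

    # --- initial concentrations of the ammonia-tolerant taxa --------
    # The tolerant populations are competitively excluded at the
    # pre-shock steady state, so their t=0 concentrations are free
    # inputs of every simulation (estimated against reactor data in
    # the original study; defaults reconstructed to reproduce the
    # reported trajectory).
    X_ac1_init: float = 0.06      # gCOD/L
    X_pro1_init: float = 0.004    # gCOD/L

    # ------------------------------------------------------------------
    _STRICTLY_POSITIVE = (
        "V_liq", "V_gas", "HRT", "T_op", "T_base", "P_atm", "k_p", "k_L_a",
        "k_dis", "k_hyd_ch", "k_hyd_pr", "k_hyd_li",
        "Y_su", "Y_aa", "Y_fa", "Y_c4", "Y_pro", "Y_ac", "Y_h2",
        "k_m_su", "K_S_su", "k_m_aa", "K_S_aa", "k_m_fa", "K_S_fa",
        "K_I_h2_fa", "k_m_c4", "K_S_c4", "K_I_h2_c4", "k_m_pro",
        "K_S_pro1", "K_S_pro2", "K_I_h2_pro", "k_m_ac", "K_S_ac1",
        "K_S_ac2", "k_m_h2", "K_S_h2", "k_dec", "K_S_IN",
        "K_I_nh3_ac1", "K_I_nh3_ac2", "K_I_nh3_pro1", "K_I_nh3_pro2",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._STRICTLY_POSITIVE:
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value}")
        for name in ("X_ac1_init", "X_pro1_init"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"parameter {name!r} must be non-negative")

    # --- serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **changes: float) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)


def default_parameters() -> ParameterSet:
    """Packaged defaults: benchmark ADM1 values plus the two-population rows."""
    with resources.files("admtaxa.data").joinpath("default_params.yaml").open() as fh:
        data = yaml.safe_load(fh)
    return ParameterSet.from_dict(data)


def original_structure_parameters(K_I_nh3_ac: float = 0.008) -> ParameterSet:
    """Single-population (classical) ADM1 parameterisation.

    The single acetoclast and single propionate oxidizer occupy the
    ``*2`` slots with their benchmark affinities (K_S,ac = 0.15,
    K_S,pro = 0.10 gCOD/L); the ``*1`` slots are never inoculated.
    Propionate uptake carries no ammonia term (K_I set far above any
    attainable free-ammonia level).  The benchmark acetoclastic
    K_I,nh3 of 0.0018 M collapses the process entirely under the
    ammonia shock; 0.008 M is the adjusted value that yields a
    persistently elevated, non-recovering acetate plateau.
    """
    base = default_parameters()
    return base.replace(
        K_S_ac2=0.15,
        K_I_nh3_ac2=K_I_nh3_ac,
        K_S_pro2=0.10,
        K_I_nh3_pro2=1.0e9,        # no propionate ammonia inhibition
        K_I_nh3_ac1=K_I_nh3_ac,    # unused (X_ac1 never inoculated)
        K_I_nh3_pro1=1.0e9,
        X_ac1_init=0.0,
        X_pro1_init=0.0,
    )
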