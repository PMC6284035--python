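"""Per-acid degradation efficiencies from VFA time series.

For each sampling time t the efficiency of acid i over the preceding
window of length dt is the ratio of mass degraded to mass supplied plus
mass produced (per reactor volume):

    E_i(t) = [S_i,in/HRT*dt - dS_i,out(t) + dS_i,p(t) - dS_i(t)]
             / [S_i,in/HRT*dt + dS_i,p(t)]

    dS_i,out(t) = (S_i(t) + S_i(t-dt)) / 2 / HRT * dt     (mean outflow)
    dS_i(t)     = S_i(t) - S_i(t-dt)                      (storage change)

Only acetate has a production credit, fed by same-window propionate and
butyrate oxidation:

    dS_ac,p(t) = S_pro,in/HRT*dt * E_pro(t) * f_ac,pro
               + S_bu,in/HRT*dt  * E_bu(t)  * f_ac,bu

with stoichiometric conversion factors of 1 mol acetate per mol
propionate and 2 mol acetate per mol butyrate, expressed on the
declared concentration basis.  E_pro and E_bu are computed first (their
production terms are zero), then E_ac; no iteration is needed because
acetate does not feed back.  Concentrations between sampling dates are
linearly interpolated.  E = 1 means complete degradation at steady
state; values above 1 occur when stored acid is drawn down and values
below 0 when an acid accumulates faster than it is supplied.  Values
are reported unclipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ACIDS = ("ac", "pro", "bu")

# molar masses (g/mol) and theoretical oxygen demands (gCOD/mol)
_MOLAR_MASS = {"ac": 60.05, "pro": 74.08, "bu": 88.11}
_COD_PER_MOL = {"ac": 64.0, "pro": 112.0, "bu": 160.0}


def conversion_factors(basis: str) -> tuple[float, float]:
    """(f_ac_pro, f_ac_bu): acetate produced per propionate / butyrate
    oxidized, on the declared concentration basis.

    Molar stoichiometry: 1 mol acetate per mol propionate, 2 mol per
    mol butyrate.
    """
    if basis == "molar":
        return 1.0, 2.0
    if basis == "COD":
        return (1.0 * _COD_PER_MOL["ac"] / _COD_PER_MOL["pro"],
                2.0 * _COD_PER_MOL["ac"] / _COD_PER_MOL["bu"])
    if basis == "mass":
        return (1.0 * _MOLAR_MASS["ac"] / _MOLAR_MASS["pro"],
                2.0 * _MOLAR_MASS["ac"] / _MOLAR_MASS["bu"])
    raise ValueError(f"unknown concentration basis {basis!r}; expected molar, mass or COD")


@dataclass
class VfaSeries:
    """Sampled reactor VFA concentrations plus influent and operation.

    ``concentrations`` maps acid name ('ac', 'pro', 'bu') to an array
    aligned with ``times``; ``influent`` maps acid name to the constant
    feed concentration.  All concentrations share one declared basis
    ('molar', 'mass' or 'COD').
    """

    times: np.ndarray
    concentrations: dict[str, np.ndarray]
    influent: dict[str, float]
    HRT: float
    basis: str = "COD"
    dt: float = 1.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.HRT <= 0:
            raise ValueError("HRT must be positive")
        if self.dt <= 0 or self.dt > self.times[-1] - self.times[0]:
            raise ValueError("dt must be positive and not exceed the series span")
        conversion_factors(self.basis)  # validates basis
        for acid in ACIDS:
            if acid not in self.concentrations or acid not in self.influent:
                raise KeyError(f"series must provide concentrations and influent for {acid!r}")
            self.concentrations[acid] = np.asarray(self.concentrations[acid], dtype=float)
            if self.concentrations[acid].shape != self.times.shape:
                raise ValueError(f"concentration series for {acid!r} does not match times")

    def interp(self, acid: str, t: float) -> float:
        return float(np.interp(t, self.times, self.concentrations[acid]))


def degradation_efficiency(series: VfaSeries) -> pd.DataFrame:
    """Efficiency records for every sampling time with a full window.

    Returns a frame indexed by time with columns E_ac, E_pro, E_bu and
    the acetate production credit dS_ac_p.  Sampling times whose
    look-back window starts before the first sample are skipped with a
    warning.  An acid with zero influent concentration has undefined
    efficiency (NaN, flagged via the ``undefined_<acid>`` column).
    """
    f_ac_pro, f_ac_bu = conversion_factors(series.basis)
    t0 = series.times[0]
    rows = []
    skipped = 0
    for t in series.times:
        if t - series.dt < t0 - 1e-12:
            skipped += 1
            continue
        rec: dict[str, float] = {"time": t}
        window_in = {a: series.influent[a] / series.HRT * series.dt for a in ACIDS}

        def efficiency(acid: str, dS_p: float) -> float:
            s_t = series.interp(acid, t)
            s_prev = series.interp(acid, t - series.dt)
            dS_out = (s_t + s_prev) / 2.0 / series.HRT * series.dt
            dS = s_t - s_prev
            supplied = window_in[acid] + dS_p
            if supplied <= 0.0:
                return np.nan
            return (window_in[acid] - dS_out + dS_p - dS) / supplied

        E_pro = efficiency("pro", 0.0)
        E_bu = efficiency("bu", 0.0)
        dS_ac_p = 0.0
        if np.isfinite(E_pro):
            dS_ac_p += window_in["pro"] * E_pro * f_ac_pro
        if np.isfinite(E_bu):
            dS_ac_p += window_in["bu"] * E_bu * f_ac_bu
        E_ac = efficiency("ac", dS_ac_p)
        rec.update(E_ac=E_ac, E_pro=E_pro, E_bu=E_bu, dS_ac_p=dS_ac_p)
        for acid, E in (("ac", E_ac), ("pro", E_pro), ("bu", E_bu)):
            rec[f"undefined_{acid}"] = not np.isfinite(E)
        rows.append(rec)
    if skipped:
        warnings.warn(f"skipped {skipped} sampling time(s) with incomplete look-back window",
                      stacklevel=2)
    if not rows:
        raise ValueError("no sampling time has a complete look-back window")
    return pd.DataFrame(rows).set_index("time")


def efficiency_from_simulation(result, basis: str = "COD",
                               times: np.ndarray | None = None) -> pd.DataFrame:
    """Apply the efficiency calculus to a noise-free simulated run.

    Samples the dense output daily by default.  Reactor and influent
    concentrations are taken on the requested basis (the simulation is
    COD-based; mass and molar bases are converted per acid).
    """
    from .state import IDX

    if times is None:
        t_end = result.segments[-1].t1
        times = np.arange(0.0, t_end + 1e-9, 1.0)
    conv = {a: 1.0 for a in ACIDS}
    if basis == "mass":
        conv = {a: _MOLAR_MASS[a] / _COD_PER_MOL[a] for a in ACIDS}
    elif basis == "molar":
        conv = {a: 1.0 / _COD_PER_MOL[a] for a in ACIDS}
    name = {"ac": "S_ac", "pro": "S_pro", "bu": "S_bu"}
    conc = {
        a: np.array([result.value_at(name[a], float(t)) for t in times]) * conv[a]
        for a in ACIDS
    }
    s_in0 = result.schedule.influent(0.0)
    influent = {a: float(s_in0[IDX[name[a]]]) * conv[a] for a in ACIDS}
    series = VfaSeries(times=times, concentrations=conc, influent=influent,
                       HRT=result.params.HRT, basis=basis)
    return degradation_efficiency(series)
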