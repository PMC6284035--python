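"""Influent schedules and initial conditions for the CSTR experiment.

Three reactor variants are encoded:

* ``ctrl``     — 52 mM ammonium bicarbonate in the feed throughout.
* ``NH3``      — feed ammonia stepped from 52 to 277 mM on day 21.
* ``NH3_HCl``  — as ``NH3`` plus 100 mM HCl in the feed from day 38
  (a ``hcl_start=36`` preset exists) until day 73.

The feed is a synthetic VFA mixture of 37.2 gCOD/L split 45/10/45
(acetic/propionic/butyric, COD basis) in mineral medium; lumped other
cations 78.3 mM and anions 19.8 mM.  Feed inorganic carbon equals feed
inorganic nitrogen (ammonium bicarbonate).  The inhibited variants
receive pulse disturbances on days 55, 62 and 69: one daily feed volume
delivered at once, with continuous feeding suspended for the following
24 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import Model
from .parameters import ParameterSet
from .state import IDX, N_STATES, STATE_NAMES, ReactorState

VARIANTS = ("ctrl", "NH3", "NH3_HCl")

TOTAL_VFA_COD = 37.2            # gCOD/L
VFA_SPLIT = {"S_ac": 0.45, "S_pro": 0.10, "S_bu": 0.45}
SIN_LOW = 0.052                 # M, feed TAN before the step
SIN_HIGH = 0.277                # M, feed TAN after day 21
AMMONIA_STEP_DAY = 21.0
SCAT_IN = 0.0783                # M
SAN_IN = 0.0198                 # M
HCL_EXTRA = 0.100               # M added to feed anions in the HCl window
HCL_START_DEFAULT = 38.0        # methods value; a day-36 preset also exists
HCL_END = 73.0
PULSE_DAYS = (55.0, 62.0, 69.0)
T_END_DEFAULT = 79.0


@dataclass(frozen=True)
class PulseEvent:
    """One deliberate disturbance: a daily feed volume delivered at once."""

    day: float
    volume: float                       # L of influent fed
    mode: str = "instantaneous"         # or "high_rate" (20-minute delivery)
    duration: float = 20.0 / 1440.0     # d, used by "high_rate" mode

    def __post_init__(self):
        if self.mode not in ("instantaneous", "high_rate"):
            raise ValueError(f"unknown pulse mode {self.mode!r}")


@dataclass
class InfluentSchedule:
    """Piecewise-constant influent composition plus pulse events.

    ``breaks`` holds the interior discontinuity times; evaluation is
    right-continuous (a query at a breakpoint returns the post-step
    composition).
    """

    variant: str
    params: ParameterSet
    hcl_start: float = HCL_START_DEFAULT
    pulse_mode: str = "instantaneous"
    t_end: float = T_END_DEFAULT
    pulses: tuple[PulseEvent, ...] = field(init=False)
    breaks: tuple[float, ...] = field(init=False)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.variant == "ctrl":
            self.pulses = ()
        else:
            v_pulse = self.params.V_liq / self.params.HRT  # one daily feed volume
            self.pulses = tuple(
                PulseEvent(day=d, volume=v_pulse, mode=self.pulse_mode)
                for d in PULSE_DAYS if d < self.t_end
            )
        breaks: set[float] = set()
        if self.variant in ("NH3", "NH3_HCl"):
            breaks.add(AMMONIA_STEP_DAY)
        if self.variant == "NH3_HCl":
            breaks.update((self.hcl_start, HCL_END))
        for ev in self.pulses:
            breaks.add(ev.day)
            if ev.mode == "high_rate":
                breaks.add(ev.day + ev.duration)
            breaks.add(ev.day + 1.0)   # feeding resumes
        self.breaks = tuple(sorted(b for b in breaks if 0.0 < b < self.t_end))

    # --- influent composition ---------------------------------------
    def influent(self, t: float) -> np.ndarray:
        """Feed concentration vector at time ``t`` (right-continuous)."""
        s = np.zeros(N_STATES)
        for name, frac in VFA_SPLIT.items():
            s[IDX[name]] = frac * TOTAL_VFA_COD
        if self.variant == "ctrl":
            sin = SIN_LOW
        else:
            sin = SIN_HIGH if t >= AMMONIA_STEP_DAY else SIN_LOW
        s[IDX["S_IN"]] = sin
        s[IDX["S_IC"]] = sin               # feed IC equals feed IN
        s[IDX["S_cat"]] = SCAT_IN
        san = SAN_IN
        if self.variant == "NH3_HCl" and self.hcl_start <= t < HCL_END:
            san += HCL_EXTRA
        s[IDX["S_an"]] = san
        return s

    def dilution(self, t: float) -> float:
        """Dilution rate 1/HRT, zero while continuous feeding is suspended."""
        for ev in self.pulses:
            if ev.mode == "instantaneous":
                if ev.day <= t < ev.day + 1.0:
                    return 0.0
            else:
                if ev.day <= t < ev.day + ev.duration:
                    # whole daily volume within the delivery window
                    return ev.volume / (self.params.V_liq * ev.duration)
                if ev.day + ev.duration <= t < ev.day + 1.0:
                    return 0.0
        return 1.0 / self.params.HRT

    def pulse_jump(self, y: np.ndarray, ev: PulseEvent) -> np.ndarray:
        """Instantaneous perfectly-mixed pulse at constant liquid volume.

        ``ev.volume`` litres of influent are mixed into the reactor and
        the same volume of mixed content withdrawn, so each liquid
        component ends at ``(c*V + c_in*V_p) / (V + V_p)``.
        """
        V, Vp = self.params.V_liq, ev.volume
        s_in = self.influent(ev.day)
        y_new = y.copy()
        liquid = np.ones(N_STATES, dtype=bool)
        for name in ("S_gas_h2", "S_gas_ch4", "S_gas_co2"):
            liquid[IDX[name]] = False
        y_new[liquid] = (y[liquid] * V + s_in[liquid] * Vp) / (V + Vp)
        return y_new

    # --- serialisation ----------------------------------------------
    def to_breakpoint_table(self) -> pd.DataFrame:
        """Tabular form: one row per (t_start, component, value)."""
        times = [0.0, *self.breaks]
        rows = []
        for t in times:
            s = self.influent(t)
            for name in STATE_NAMES:
                v = s[IDX[name]]
                if v != 0.0:
                    rows.append({"t_start": t, "component": name, "value": v})
            rows.append({"t_start": t, "component": "dilution", "value": self.dilution(t)})
        return pd.DataFrame(rows)


def experiment_schedule(variant: str, params: ParameterSet | None = None,
                        hcl_start: float = HCL_START_DEFAULT,
                        pulse_mode: str = "instantaneous",
                        t_end: float = T_END_DEFAULT) -> InfluentSchedule:
    """Influent schedule of one experimental reactor variant."""
    if params is None:
        from .parameters import default_parameters
        params = default_parameters()
    return InfluentSchedule(variant=variant, params=params, hcl_start=hcl_start,
                            pulse_mode=pulse_mode, t_end=t_end)


#: Documented spin-up seed (gCOD/L, M).  The ammonia-tolerant
#: populations are deliberately absent: they are competitively excluded
#: at the pre-shock steady state and their t=0 values are configured
#: inputs layered on top of the converged state.
SEED_STATE: dict[str, float] = {
    "S_su": 0.01, "S_aa": 0.005, "S_fa": 0.1, "S_va": 0.02, "S_bu": 0.2,
    "S_pro": 0.1, "S_ac": 0.2, "S_h2": 2e-7, "S_ch4": 0.05,
    "S_IC": 0.1, "S_IN": 0.05, "S_I": 0.1,
    "X_c": 0.1, "X_ch": 0.01, "X_pr": 0.01, "X_li": 0.01,
    "X_su": 0.02, "X_aa": 0.02, "X_fa": 0.02, "X_c4": 0.8,
    "X_pro1": 0.0, "X_pro2": 0.15, "X_ac1": 0.0, "X_ac2": 1.0, "X_h2": 0.3,
    "X_I": 0.5, "S_cat": 0.0783, "S_an": 0.0198,
    "S_gas_h2": 1e-5, "S_gas_ch4": 1.3, "S_gas_co2": 0.016,
}


class InitializationError(RuntimeError):
    """Spin-up failed to reach a steady state within the horizon."""


def steady_state_init(params: ParameterSet, schedule: InfluentSchedule | None = None,
                      tol: float = 1e-6, floor: float = 1e-6,
                      chunk: float = 100.0, max_horizon: float = 1200.0,
                      apply_overrides: bool = True,
                      rtol: float = 1e-8, atol: float = 1e-12) -> ReactorState:
    """Pre-disturbance steady state under the low-ammonia feed.

    Integrates the model from the documented seed with the influent
    frozen at its pre-step (t < 21 d) composition until every
    component's derivative satisfies ``|dy_i/dt| <= tol * max(|y_i|,
    floor)``.  The ammonia-tolerant populations are held at zero during
    spin-up and, if ``apply_overrides``, set to their configured
    initial values afterwards.
    """
    if schedule is None:
        schedule = experiment_schedule("ctrl", params)
    model = Model(params)
    s_in = schedule.influent(min(10.0, AMMONIA_STEP_DAY / 2))
    D = 1.0 / params.HRT

    y = np.zeros(N_STATES)
    for name, v in SEED_STATE.items():
        y[IDX[name]] = v
    y[IDX["X_ac1"]] = 0.0
    y[IDX["X_pro1"]] = 0.0

    def f(t, yy):
        return model.rhs(t, yy, s_in, D)

    elapsed = 0.0
    while elapsed < max_horizon:
        sol = solve_ivp(f, (0.0, chunk), y, method="BDF", rtol=rtol, atol=atol)
        if not sol.success:
            raise InitializationError(f"spin-up integration failed: {sol.message}")
        y = sol.y[:, -1]
        elapsed += chunk
        dy = f(0.0, y)
        scale = np.maximum(np.abs(y), floor)
        if np.max(np.abs(dy) / scale) < tol:
            break
    else:
        raise InitializationError(
            f"no steady state within {max_horizon} d "
            f"(max relative derivative {np.max(np.abs(f(0.0, y)) / np.maximum(np.abs(y), floor)):.2e})"
        )
    state = ReactorState(y)
    if apply_overrides:
        state["X_ac1"] = params.X_ac1_init
        state["X_pro1"] = params.X_pro1_init
    return state
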