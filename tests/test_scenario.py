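"""Influent schedules, pulses and steady-state initialization."""

import numpy as np
import pytest

from admtaxa import default_parameters, experiment_schedule, steady_state_init
from admtaxa.core import Model
from admtaxa.scenario import SEED_STATE, InfluentSchedule
from admtaxa.state import IDX, N_STATES


@pytest.fixture(scope="module")
def p():
    return default_parameters()


def test_unknown_variant_rejected(p):
    with pytest.raises(ValueError):
        experiment_schedule("high_ammonia", p)


def test_feed_composition_before_and_after_step(p):
    sched = experiment_schedule("NH3", p)
    early = sched.influent(10.0)
    assert early[IDX["S_IN"]] == pytest.approx(0.052)
    late = sched.influent(30.0)
    assert late[IDX["S_IN"]] == pytest.approx(0.277)
    assert late[IDX["S_IC"]] == pytest.approx(0.277)
    # 45/10/45 COD split of 37.2 gCOD/L, constant over time
    for t in (10.0, 30.0, 75.0):
        s = sched.influent(t)
        assert s[IDX["S_ac"]] == pytest.approx(16.74)
        assert s[IDX["S_pro"]] == pytest.approx(3.72)
        assert s[IDX["S_bu"]] == pytest.approx(16.74)
    assert late[IDX["S_cat"]] == pytest.approx(0.0783)
    assert late[IDX["S_an"]] == pytest.approx(0.0198)


def test_step_is_right_continuous(p):
    sched = experiment_schedule("NH3", p)
    assert sched.influent(21.0)[IDX["S_IN"]] == pytest.approx(0.277)
    assert sched.influent(21.0 - 1e-9)[IDX["S_IN"]] == pytest.approx(0.052)


def test_hcl_window_only_for_hcl_variant(p):
    nh3 = experiment_schedule("NH3", p)
    hcl = experiment_schedule("NH3_HCl", p)
    assert nh3.influent(50.0)[IDX["S_an"]] == pytest.approx(0.0198)
    assert hcl.influent(38.0)[IDX["S_an"]] == pytest.approx(0.1198)
    assert hcl.influent(72.9)[IDX["S_an"]] == pytest.approx(0.1198)
    assert hcl.influent(73.0)[IDX["S_an"]] == pytest.approx(0.0198)
    # the day-36 reading of the HCl start is available as a preset
    hcl36 = experiment_schedule("NH3_HCl", p, hcl_start=36.0)
    assert hcl36.influent(37.0)[IDX["S_an"]] == pytest.approx(0.1198)


def test_control_has_no_pulses_inhibited_have_three(p):
    assert experiment_schedule("ctrl", p).pulses == ()
    pulses = experiment_schedule("NH3", p).pulses
    assert [ev.day for ev in pulses] == [55.0, 62.0, 69.0]
    for ev in pulses:
        assert ev.volume == pytest.approx(p.V_liq / p.HRT)


def test_feeding_suspended_for_a_day_after_pulse(p):
    sched = experiment_schedule("NH3", p)
    assert sched.dilution(54.9) == pytest.approx(1 / p.HRT)
    assert sched.dilution(55.0) == 0.0
    assert sched.dilution(55.9) == 0.0
    assert sched.dilution(56.0) == pytest.approx(1 / p.HRT)


def test_pulse_mass_conservation(p):
    """Mixed mass before + fed mass equals mass after + withdrawn mass."""
    sched = experiment_schedule("NH3", p)
    ev = sched.pulses[0]
    rng = np.random.default_rng(3)
    y = np.abs(rng.normal(0.5, 0.5, N_STATES))
    y_new = sched.pulse_jump(y, ev)
    s_in = sched.influent(ev.day)
    V, Vp = p.V_liq, ev.volume
    for i in range(N_STATES):
        name = __import__("admtaxa.state", fromlist=["STATE_NAMES"]).STATE_NAMES[i]
        if name.startswith("S_gas"):
            assert y_new[i] == y[i]
            continue
        # mass balance of the mix-then-withdraw rule
        assert y[i] * V + s_in[i] * Vp == pytest.approx(
            y_new[i] * V + y_new[i] * Vp, rel=1e-12)


def test_high_rate_pulse_mode_feeds_same_volume(p):
    sched = experiment_schedule("NH3", p, pulse_mode="high_rate")
    ev = sched.pulses[0]
    # integrated dilution over the delivery window equals Vp/V
    dt = ev.duration
    assert sched.dilution(ev.day) * dt == pytest.approx(ev.volume / p.V_liq)
    assert sched.dilution(ev.day + dt) == 0.0


def test_breakpoint_table_round_trips_values(p):
    sched = experiment_schedule("NH3_HCl", p)
    table = sched.to_breakpoint_table()
    row = table[(table.t_start == 38.0) & (table.component == "S_an")]
    assert row.value.iloc[0] == pytest.approx(0.1198)


# --- steady state --------------------------------------------------------

def test_steady_state_derivative_norm(params, ctrl_schedule):
    """Per-component relative derivative below 1e-6 at the fixed point
    (before the tolerant-population inocula are layered on)."""
    converged = steady_state_init(params, ctrl_schedule, apply_overrides=False)
    m = Model(params)
    s_in = ctrl_schedule.influent(10.0)
    dy = m.rhs(0.0, converged.y, s_in, 1 / params.HRT)
    rel = np.abs(dy) / np.maximum(np.abs(converged.y), 1e-6)
    assert np.max(rel) < 1e-6


def test_steady_state_idempotent_under_longer_spinup(params, ctrl_schedule):
    """Doubling the spin-up horizon moves no component by > 0.1%."""
    a = steady_state_init(params, ctrl_schedule, chunk=150.0, max_horizon=150.0,
                          tol=np.inf)  # exactly one chunk
    b = steady_state_init(params, ctrl_schedule, chunk=300.0, max_horizon=300.0,
                          tol=np.inf)
    scale = np.maximum(np.abs(b.y), 1e-6)
    assert np.max(np.abs(a.y - b.y) / scale) < 1e-3


def test_steady_state_total_vfa_plausible(steady_state):
    """Pre-disturbance total VFA stays within the observed ~1.5 g/L."""
    total = sum(steady_state[n] for n in ("S_ac", "S_pro", "S_bu", "S_va"))
    assert total < 1.5


def test_tolerant_populations_overridden(steady_state, params):
    assert steady_state["X_ac1"] == pytest.approx(params.X_ac1_init)
    assert steady_state["X_pro1"] == pytest.approx(params.X_pro1_init)
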