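"""Petersen-matrix conservation and process-rate arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from admtaxa import ReactorState, ammonia_inhibition, default_parameters, process_rates, speciate
from admtaxa.core import Model
from admtaxa.state import IDX, N_STATES
from admtaxa.stoichiometry import PIDX, PROCESS_NAMES, build_petersen_matrix, cod_content


@pytest.fixture(scope="module")
def model():
    return Model(default_parameters())


# --- inhibition function -------------------------------------------------

@pytest.mark.parametrize("s_nh3, k_i, expected", [
    (0.0, 0.0052, 1.0),            # no inhibitor, no inhibition
    (0.0052, 0.0052, 0.5),         # midpoint of the hyperbola
    (0.3387, 0.3387, 0.5),
    (0.0104, 0.0052, 1.0 / 3.0),   # twice the constant -> one third
])
def test_ammonia_inhibition_values(s_nh3, k_i, expected):
    assert ammonia_inhibition(s_nh3, k_i) == pytest.approx(expected, rel=1e-12)


def test_ammonia_inhibition_rejects_bad_parameters():
    with pytest.raises(ValueError):
        ammonia_inhibition(0.01, 0.0)
    with pytest.raises(ValueError):
        ammonia_inhibition(-0.01, 0.005)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.floats(0, 1.0), st.floats(1e-6, 1.0), st.floats(1e-6, 0.5))
def test_ammonia_inhibition_monotone_decreasing(s, k_i, ds):
    """The factor lies in (0, 1] and strictly decreases with NH3."""
    lo, hi = ammonia_inhibition(s, k_i), ammonia_inhibition(s + ds, k_i)
    assert 0.0 < hi < lo <= 1.0


# --- stoichiometry -------------------------------------------------------

def test_every_column_conserves_cod_carbon_nitrogen(model):
    """Organic COD, elemental C and N close per process to 1e-8."""
    cod = model.cod.copy()
    for n in ("S_gas_h2", "S_gas_ch4", "S_gas_co2"):
        cod[IDX[n]] = 0.0
    for j, name in enumerate(PROCESS_NAMES):
        assert abs(cod @ model.nu[:, j]) < 1e-8, f"COD leak in {name}"
        assert abs(model.carbon @ model.nu[:, j]) < 1e-8, f"C leak in {name}"
        assert abs(model.nitrogen @ model.nu[:, j]) < 1e-8, f"N leak in {name}"


def test_acetoclastic_column_releases_co2(model):
    """Acetate (high C density) to CH4 (low) must release inorganic C."""
    j = PIDX["uptake_ac1"]
    assert model.nu[IDX["S_IC"], j] > 0
    assert model.nu[IDX["S_IN"], j] < 0  # biomass growth takes up N


def test_decay_column_releases_nitrogen(model):
    """Biomass is N-richer than composite, so decay must free IN."""
    j = PIDX["decay_ac1"]
    assert model.nu[IDX["S_IN"], j] > 0


# --- process rates -------------------------------------------------------

def _spec_of(y, params):
    return speciate(ReactorState(np.asarray(y)), params)


def test_zero_biomass_means_zero_rates():
    p = default_parameters()
    y = np.zeros(N_STATES)
    y[IDX["S_ac"]] = 1.0
    y[IDX["S_cat"]] = 0.05
    y[IDX["S_an"]] = 0.01
    y[IDX["S_IC"]] = 0.05
    rho = process_rates(y, _spec_of(y, p), p)
    assert np.all(rho == 0.0)


def test_half_saturation_rates_match_table_values():
    """At S = K_S and unit inhibition the uptake rate is k_m * X / 2.

    A synthetic uninhibited speciation (pH 9, no free ammonia) isolates
    the Monod arithmetic from the acid-base subsystem.
    """
    from admtaxa.state import IonSpeciation

    p = default_parameters()
    spec = IonSpeciation(pH=9.0, S_h=1e-9, S_oh=1e-5, S_nh3=0.0, S_nh4=0.0,
                         S_hco3=0.0, S_co2=0.0, S_ac_ion=0.0, S_pro_ion=0.0,
                         S_bu_ion=0.0, S_va_ion=0.0, residual=0.0)

    y = np.zeros(N_STATES)
    y[IDX["S_IN"]] = 1.0                  # nitrogen limitation fully lifted
    y[IDX["S_ac"]] = p.K_S_ac1            # 0.34 gCOD/L
    y[IDX["X_ac1"]] = 0.7
    rho = process_rates(y, spec, p)
    # k_m_ac = 8 -> rho = 0.5 * 8 * X = 4 X
    assert rho[PIDX["uptake_ac1"]] == pytest.approx(4.0 * 0.7, rel=1e-3)

    y2 = np.zeros(N_STATES)
    y2[IDX["S_IN"]] = 1.0
    y2[IDX["S_pro"]] = p.K_S_pro2         # 0.10 gCOD/L
    y2[IDX["X_pro2"]] = 0.3
    rho2 = process_rates(y2, spec, p)
    # k_m_pro = 13 -> rho = 0.5 * 13 * X
    assert rho2[PIDX["uptake_pro2"]] == pytest.approx(0.5 * 13.0 * 0.3, rel=1e-3)


def test_rates_nonnegative_for_random_states():
    p = default_parameters()
    rng = np.random.default_rng(7)
    for _ in range(20):
        y = np.abs(rng.normal(0.2, 0.5, N_STATES))
        y[IDX["S_an"]] = 0.02 * rng.random()
        y[IDX["S_cat"]] = y[IDX["S_an"]] + 0.05 * rng.random()
        y[IDX["S_IC"]] = 0.05 + 0.2 * rng.random()
        y[IDX["S_IN"]] = 0.05 + 0.2 * rng.random()
        y[IDX["S_h2"]] = abs(rng.normal(0, 1e-6))
        rho = process_rates(y, _spec_of(y, p), p)
        assert np.all(rho >= 0.0)


def test_negative_concentrations_clip_not_propagate():
    """A slightly negative substrate behaves as zero inside the rates."""
    p = default_parameters()
    y = np.zeros(N_STATES)
    y[IDX["S_cat"]] = 0.05
    y[IDX["S_IC"]] = 0.05
    y[IDX["S_ac"]] = -1e-9
    y[IDX["X_ac1"]] = 1.0
    rho = process_rates(y, _spec_of(y, p), p)
    assert rho[PIDX["uptake_ac1"]] == 0.0
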