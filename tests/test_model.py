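"""Core ODE engine: rate law, integration, steady states, fold changes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stressnet import (
    InvalidStateError,
    KineticParameters,
    SpeciesState,
    fold_change,
    healthy_state_array,
    rhs,
    simulate,
    steady_state,
)
from stressnet.parameters import EdgeKinetics, PoolKinetics, SpeciesRates, StressGains
from stressnet.species import IDX, N_SPECIES, SPECIES


def _plain_params(basal=0.0, deg=1.0):
    """Interaction-free parameter set (every species basal/deg only)."""
    species = {n: SpeciesRates(basal=basal, deg=deg) for n in SPECIES}
    return KineticParameters(species=species, edges={}, pools={})


def test_zero_system_fixed_point():
    """All-zero state with zero production has zero derivative."""
    p = _plain_params(basal=0.0)
    d = rhs(np.zeros(N_SPECIES), p)
    assert np.all(d == 0.0)


def test_isolated_species_linear_steady_state():
    """An uncoupled species with production k and decay d is stationary
    at k/d."""
    p = _plain_params(basal=0.8, deg=2.0)
    x = np.full(N_SPECIES, 0.4)
    d = rhs(x, p)
    assert np.allclose(d, 0.0, atol=1e-14)


def test_rhs_matches_finite_difference_of_trajectory(healthy_params, healthy_state):
    """The reported derivative agrees with a central finite difference of
    the integrated trajectory (independent integrator oracle)."""
    x0 = healthy_state.to_array() * 1.1  # off steady state so rhs != 0
    h = 1e-4
    traj = simulate(x0, healthy_params, duration=2 * h, output_grid=[0.0, h, 2 * h],
                    rtol=1e-10, atol=1e-13)
    fd = (traj.states[2] - traj.states[0]) / (2 * h)
    analytic = rhs(x0, healthy_params)
    scale = np.maximum(np.abs(analytic), 1e-6 * np.abs(analytic).max())
    assert np.all(np.abs(fd - analytic) / scale < 5e-3)


def test_simulate_matches_linear_decay_closed_form():
    """With no interactions the trajectory is x0 * exp(-d t) exactly."""
    p = _plain_params(basal=0.0, deg=0.7)
    x0 = np.linspace(0.5, 2.0, N_SPECIES)
    ts = [0.0, 1.0, 3.0, 5.0]
    traj = simulate(x0, p, duration=5.0, output_grid=ts, rtol=1e-10, atol=1e-14)
    for i, t in enumerate(ts):
        expected = x0 * np.exp(-0.7 * t)
        assert np.allclose(traj.states[i], expected, rtol=1e-6)


def test_simulate_rejects_bad_inputs(healthy_params, healthy_state):
    with pytest.raises(ValueError):
        simulate(healthy_state, healthy_params, duration=-1.0)
    with pytest.raises(ValueError):
        simulate(healthy_state, healthy_params, duration=1.0, output_grid=[0.0, 2.0])
    with pytest.raises(InvalidStateError, match="nfkb"):
        bad = healthy_state.replace(nfkb=float("nan"))
        simulate(bad, healthy_params, duration=1.0)


def test_steady_state_single_species_exact():
    p = _plain_params(basal=0.8, deg=2.0)
    ss = steady_state(p)
    assert ss.to_array() == pytest.approx(np.full(N_SPECIES, 0.4), abs=1e-10)


def test_healthy_steady_state_is_stationary(healthy_params, healthy_state):
    d = rhs(healthy_state, healthy_params)
    assert np.abs(d).max() < 1e-8


def test_steady_state_deterministic(healthy_params, healthy_state):
    """Repeated calls with identical parameters are bit-stable."""
    a = steady_state(healthy_params, guess=healthy_state).to_array()
    b = steady_state(healthy_params, guess=healthy_state).to_array()
    assert np.array_equal(a, b)


def test_healthy_steady_state_is_locally_stable(healthy_params, healthy_state):
    """A 1 % perturbation of the healthy steady state relaxes back."""
    from stressnet.species import IDX

    x0 = healthy_state.to_array() * 1.01
    for pool_species in ("irs", "pirs", "akt", "pakt"):
        x0[IDX[pool_species]] = healthy_state.to_array()[IDX[pool_species]]
    traj = simulate(x0, healthy_params, duration=60.0, output_grid=[0.0, 60.0])
    rel = np.abs(traj.states[-1] - healthy_state.to_array()) / np.maximum(
        healthy_state.to_array(), 1e-12)
    assert rel.max() < 1e-4


def test_intervention_trajectory_reaches_steady_state(
        stressed_ss, combined_params, combined_ss):
    """A 35-day intervention run ends within 0.5 % of the intervened
    steady state."""
    traj = simulate(stressed_ss, combined_params, duration=35.0,
                    output_grid=[0.0, 35.0])
    final = traj.states[-1]
    target = combined_ss.to_array()
    rel = np.abs(final - target) / np.maximum(np.abs(target), 1e-12)
    assert rel.max() < 5e-3


def test_stressed_cortisol_approaches_steady_state_monotonically(
        healthy_state, stressed_params, stressed_ss):
    """Cortisol rises towards the stressed steady state without sustained
    oscillation after the initial transient."""
    traj = simulate(healthy_state, stressed_params, duration=60.0,
                    output_grid=np.linspace(0, 60, 121))
    cort = traj.column("cortisol")
    target = stressed_ss.cortisol
    # monotone rise through the approach phase
    assert np.all(np.diff(cort[:20]) > 0)
    # no sustained oscillation: any overshoot stays below 0.5 % and the
    # distance to the steady state shrinks over the tail
    assert cort.max() < target * 1.005
    dev = np.abs(cort - target)
    assert dev[120] <= dev[80] <= dev[40]
    assert cort[-1] == pytest.approx(target, rel=1e-4)


def test_pool_conservation_along_trajectory(healthy_state, stressed_params):
    """irs+pirs and akt+pakt stay constant to 1e-8 relative."""
    x0 = healthy_state.to_array()
    traj = simulate(x0, stressed_params, duration=40.0,
                    output_grid=np.linspace(0, 40, 41))
    for a, b in (("irs", "pirs"), ("akt", "pakt")):
        total = traj.column(a) + traj.column(b)
        assert np.all(np.abs(total - total[0]) / total[0] < 1e-8)


def test_nonnegativity_preserving_rhs(healthy_params):
    """Species at zero with non-negative regulators never get negative
    derivatives."""
    x = healthy_state_array()
    for name in ("ros", "tnfa", "cortisol", "nfkb", "aldosterone"):
        xz = x.copy()
        xz[IDX[name]] = 0.0
        d = rhs(xz, healthy_params)
        assert d[IDX[name]] >= 0.0


@settings(max_examples=60, derandomize=True, deadline=None)
@given(pre=st.floats(1e-6, 1e6), post=st.floats(1e-6, 1e6))
def test_fold_change_is_ratio(pre, post):
    assert fold_change(pre, post) == pytest.approx(pre / post)
    assert fold_change(pre, pre) == pytest.approx(1.0)


def test_fold_change_examples_and_errors():
    assert fold_change(171.92, 5.58) == pytest.approx(30.81, abs=0.01)
    assert fold_change(106.7, 8.57) == pytest.approx(12.45, abs=0.01)
    with pytest.raises(ZeroDivisionError):
        fold_change(1.0, 0.0)
    with pytest.raises(ValueError):
        fold_change(-1.0, 1.0)


def test_parameter_validation_names_offender(healthy_params):
    bad = healthy_params.copy()
    bad.species["ros"].deg = -1.0
    with pytest.raises(Exception, match="ros"):
        rhs(healthy_state_array(), bad)
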