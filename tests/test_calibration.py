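"""Calibration machinery: objective semantics, reproducibility,
parameter recovery."""

import numpy as np
import pytest

from stressnet import (
    CalibrationProblem,
    CalibrationTarget,
    calibrate,
    default_targets,
    objective,
)
from stressnet.calibration import _residuals, LITERATURE_FIXTURES

FREE = ["stress.beta_ros", "stress.alpha_inf"]


@pytest.fixture(scope="module")
def problem(healthy_params):
    return CalibrationProblem(healthy_params, FREE)


@pytest.fixture(scope="module")
def self_targets(problem):
    """Targets generated by the model itself at the identity multipliers."""
    markers = problem.evaluate(problem.base_params, "stressed")
    return [
        CalibrationTarget("ros_percent", "stressed", markers["ros_percent"]),
        CalibrationTarget("tnfa", "stressed", markers["tnfa"]),
    ]


def test_objective_zero_iff_targets_met(problem, self_targets):
    assert objective(np.zeros(2), self_targets, problem) == pytest.approx(0.0, abs=1e-16)


def test_objective_positive_after_perturbation(problem, self_targets):
    loss = objective(np.log([1.1, 1.0]), self_targets, problem)
    assert loss > 0.0


def test_objective_requires_targets(problem):
    with pytest.raises(ValueError):
        objective(np.zeros(2), [], problem)


def test_objective_matches_independent_residual_formula(problem, self_targets):
    """The optimizer's loss equals a hand-computed weighted sum of squared
    relative residuals on the same simulation outputs."""
    x = np.log([1.05, 0.95])
    loss = objective(x, self_targets, problem)
    params = problem.realise(x)
    by_hand = 0.0
    for t in self_targets:
        got = problem.evaluate(params, t.condition)[t.marker]
        by_hand += t.weight * ((got - t.value) / t.value) ** 2
    assert loss == pytest.approx(by_hand, rel=1e-12)


def test_parameter_recovery(healthy_params, problem):
    """Targets generated from a perturbed parameter set are recovered by
    the optimiser started nearby (loss < 1e-4)."""
    true = healthy_params.scaled({"stress.beta_ros": 1.2, "stress.alpha_inf": 0.85})
    truth = CalibrationProblem(true, FREE)
    markers = truth.evaluate(true, "stressed")
    targets = [
        CalibrationTarget("ros_percent", "stressed", markers["ros_percent"], 0.01),
        CalibrationTarget("tnfa", "stressed", markers["tnfa"], 0.01),
    ]
    result = calibrate(healthy_params, targets, budget=400, free_paths=FREE, seed=0)
    assert result.loss < 1e-4
    assert result.all_passed
    # residual report reproducible from the returned parameters
    rep = _residuals(CalibrationProblem(healthy_params, FREE),
                     result.log_multipliers, targets)
    for t, r in rep.items():
        assert result.residuals[t] == pytest.approx(float(r), abs=1e-12)


def test_calibrate_deterministic_given_seed(healthy_params, self_targets):
    a = calibrate(healthy_params, self_targets, budget=60, free_paths=FREE, seed=3)
    b = calibrate(healthy_params, self_targets, budget=60, free_paths=FREE, seed=3)
    assert np.array_equal(a.log_multipliers, b.log_multipliers)
    assert a.loss == b.loss


def test_calibrate_best_effort_on_unreachable_target(healthy_params):
    """An impossible target returns a failure report, not an exception."""
    impossible = [CalibrationTarget("ros_percent", "healthy", 500.0, 0.01)]
    result = calibrate(healthy_params, impossible, budget=40,
                       free_paths=["species.mda.basal"], seed=0)
    assert not result.all_passed
    assert np.isfinite(result.loss)


def test_calibrate_rejects_bad_inputs(healthy_params, self_targets):
    with pytest.raises(ValueError):
        calibrate(healthy_params, [], budget=10)
    with pytest.raises(ValueError):
        calibrate(healthy_params, self_targets, budget=0)


def test_shipped_targets_table_loads():
    targets = default_targets()
    assert len(targets) >= 7
    conditions = {t.condition for t in targets}
    assert {"stressed", "combined"} <= conditions
    assert all(t.tolerance > 0 for t in targets)


def test_literature_fixtures_well_formed():
    assert len(LITERATURE_FIXTURES) == 5
    sources = {f.source for f in LITERATURE_FIXTURES}
    assert sources == {"gotukola", "elderberry", "purple_carrot"}
    assert all(f.dose_ug_per_ml > 0 for f in LITERATURE_FIXTURES)
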