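"""Population synthesis: determinism, demographics, structure,
responder computation."""

import numpy as np
import pytest

from stressnet import (
    GeneratorConfig,
    Individual,
    StressScenario,
    derive_panel,
    generate_population,
    responder_fraction,
    simulate_population,
    steady_state,
)


def test_empty_population():
    pop = generate_population(0, 1)
    assert len(pop) == 0


def test_negative_n_rejected():
    with pytest.raises(ValueError):
        generate_population(-1, 1)


def test_seed_determinism_exact():
    """Two generations with the same seed are identical in every field."""
    a = generate_population(60, 42)
    b = generate_population(60, 42)
    for ia, ib in zip(a.individuals, b.individuals):
        assert ia == ib
    c = generate_population(60, 43)
    assert any(ia != ic for ia, ic in zip(a.individuals, c.individuals))


def test_demographics():
    pop = generate_population(201, 5)
    ages = np.array([i.age for i in pop.individuals])
    assert ages.min() >= 20.0 and ages.max() <= 80.0
    males = sum(i.sex == "male" for i in pop.individuals)
    assert abs(males - (201 - males)) <= 1  # 1:1 ratio up to odd n


def test_severities_and_multipliers_valid():
    pop = generate_population(150, 9)
    for ind in pop.individuals:
        for axis in ("inflammatory", "oxidative", "insulin"):
            assert 0.0 <= getattr(ind.severities, axis) <= 1.0
        assert all(m > 0 for m in ind.multipliers.values())
        assert all(0 < q <= 1 for q in ind.response.values())


def test_generated_moments_converge_with_n():
    """Sample means of the generator's draws approach the configured
    values as n grows (Monte-Carlo consistency of the generator)."""
    cfg = GeneratorConfig()
    small = generate_population(200, 11, cfg)
    big = generate_population(2000, 11, cfg)

    def age_mean(pop):
        return np.mean([i.age for i in pop.individuals])

    assert abs(age_mean(big) - 50.0) < abs(age_mean(small) - 50.0) + 1.0
    assert age_mean(big) == pytest.approx(50.0, abs=1.5)
    frac_all4_big = np.mean([i.pattern == "all_four" for i in big.individuals])
    assert frac_all4_big == pytest.approx(cfg.pattern_probs["all_four"], abs=0.04)


def test_unstressed_individual_recovers_healthy_panel(healthy_params, healthy_state):
    """A no-stress, no-intervention individual reproduces the healthy
    baseline panel within solver tolerance."""
    ind = Individual(id=0, age=40.0, sex="female",
                     severities=StressScenario(), multipliers={})
    ss = steady_state(ind.params(healthy_params), guess=healthy_state)
    panel = derive_panel(ss, healthy_state)
    ref = derive_panel(healthy_state, healthy_state)
    assert panel.ros_percent == pytest.approx(ref.ros_percent, abs=1e-6)
    assert panel.cortisol == pytest.approx(ref.cortisol, rel=1e-6)
    assert panel.sbp == pytest.approx(ref.sbp, rel=1e-6)


def test_simulation_is_paired_and_deterministic(healthy_params, formulation):
    """Arms share individuals and a repeated run gives identical panels."""
    pop = generate_population(40, 3)
    arms = [("stressed", None), ("combined", formulation)]
    r1 = simulate_population(pop, arms, params=healthy_params)
    r2 = simulate_population(pop, arms, params=healthy_params)
    for arm in ("stressed", "combined"):
        a = np.array([[p.ros_percent, p.tnfa, p.sbp, p.pss] for p in r1.panels(arm)])
        b = np.array([[p.ros_percent, p.tnfa, p.sbp, p.pss] for p in r2.panels(arm)])
        assert np.array_equal(a, b)
        assert len(r1.panels(arm)) == len(pop)
    pre, post = r1.paired_panels("stressed", "combined")
    assert len(pre) == len(post) == len(pop)


def test_empty_arms_rejected(healthy_params):
    pop = generate_population(3, 1)
    with pytest.raises(ValueError):
        simulate_population(pop, arms=[], params=healthy_params)


def test_responder_fraction_identity_and_errors(study):
    pre = study["result"].panels("stressed")
    assert responder_fraction(pre, pre, "ros") == 0.0
    assert responder_fraction(pre, pre, "pss") == 0.0
    with pytest.raises(ValueError):
        responder_fraction([], [], "ros")
    with pytest.raises(KeyError):
        responder_fraction(pre, pre, "unknown")


def test_population_csv_roundtrip(tmp_path):
    pop = generate_population(25, 2)
    path = tmp_path / "pop.csv"
    pop.to_csv(path)
    text = path.read_text()
    assert text.startswith("# stressnet population, seed=2")
    assert text.count("\n") == 27  # header comment + column row + 25 rows
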