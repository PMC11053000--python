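"""Intervention engine: composition algebra, formulation contents,
efficacy operations."""

import itertools

import numpy as np
import pytest

from stressnet import (
    ConfigurationError,
    Formulation,
    Ingredient,
    apply_intervention,
    single_ingredient_efficacy,
    steady_state,
)
from stressnet.intervention import Target


def test_empty_formulation_is_identity(healthy_params):
    out = apply_intervention(healthy_params, Formulation())
    assert out == healthy_params


def test_unknown_target_node_names_ingredient(healthy_params):
    bad = Ingredient("mystery", "botanical", (Target("notaspecies", "down", 0.1),))
    with pytest.raises(ConfigurationError, match="mystery"):
        apply_intervention(healthy_params, Formulation((bad,)))


def test_potency_bounds():
    with pytest.raises(ValueError):
        Target("ros", "down", 1.0)
    with pytest.raises(ValueError):
        Target("ros", "sideways", 0.1)


def test_order_independence(healthy_params, formulation):
    """Any ingredient ordering yields identical parameters."""
    base = apply_intervention(healthy_params, formulation)
    shuffled = Formulation(tuple(reversed(formulation.ingredients)),
                           name="reversed")
    assert apply_intervention(healthy_params, shuffled) == base


def test_shared_node_composes_multiplicatively(healthy_params):
    a = Ingredient("a", "vitamin", (Target("ros", "down", 0.2),))
    b = Ingredient("b", "mineral", (Target("ros", "down", 0.3),))
    joint = apply_intervention(healthy_params, Formulation((a, b)))
    assert joint.species["ros"].basal == pytest.approx(
        healthy_params.species["ros"].basal * 0.8 * 0.7)


def test_default_formulation_composition(formulation):
    """4 botanicals + 13 vitamins + 11 minerals, unique names, and the
    named principals present."""
    counts = {"botanical": 0, "vitamin": 0, "mineral": 0}
    names = set()
    for ing in formulation:
        counts[ing.klass] += 1
        names.add(ing.name)
    assert counts == {"botanical": 4, "vitamin": 13, "mineral": 11}
    assert len(names) == 28
    for required in ("gotukola", "acerola", "elderberry", "purple_carrot",
                     "vitamin_a", "vitamin_c", "zinc", "iodine", "magnesium",
                     "selenium", "chromium", "phosphorus"):
        assert required in names


def test_formulation_json_roundtrip(tmp_path, formulation):
    path = tmp_path / "form.json"
    formulation.to_json(path)
    assert Formulation.from_json(path) == formulation


def test_inert_ingredient_has_zero_efficacy(stressed_params, stressed_ss, healthy_state):
    inert = Ingredient("placebo", "mineral", (Target("ros", "down", 0.0),))
    eff = single_ingredient_efficacy(stressed_params, inert, "ros", healthy_state,
                                     stressed_state=stressed_ss)
    assert eff == pytest.approx(0.0, abs=1e-6)


def test_unknown_marker_rejected(stressed_params, stressed_ss, healthy_state, formulation):
    with pytest.raises(KeyError, match="marker"):
        single_ingredient_efficacy(stressed_params, formulation.get("zinc"),
                                   "cholesterol", healthy_state,
                                   stressed_state=stressed_ss)


def test_efficacy_monotone_in_potency_scale(stressed_params, stressed_ss,
                                            healthy_state, formulation):
    """Scaling all potencies by lambda in [0, 1] weakly decreases the
    ROS efficacy of an antioxidant botanical."""
    ing = formulation.get("acerola")
    effs = []
    for lam in (0.0, 0.5, 1.0):
        eff = single_ingredient_efficacy(stressed_params, ing.scaled(lam), "ros",
                                         healthy_state, stressed_state=stressed_ss)
        effs.append(eff)
    assert effs[0] == pytest.approx(0.0, abs=1e-6)
    assert effs[0] < effs[1] < effs[2]


def test_subset_selects_classes(formulation):
    micron = formulation.subset({"vitamin", "mineral"})
    assert len(micron) == 24
    assert all(i.klass in ("vitamin", "mineral") for i in micron)
    bot = formulation.subset({"botanical"})
    assert len(bot) == 4
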