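"""Ingredients, formulations and intervention application.

An ingredient (botanical extract, vitamin or mineral) carries a list of
node-level targets, each with a direction (up/down) and a potency — the
fractional modulation of the target node's production rate at the
formulation's dose.  Applying an intervention multiplies every rate
feeding a down-regulated node by ``(1 - potency)`` and every rate
feeding an up-regulated node by ``(1 + potency)``.  Ingredients sharing
a node compose multiplicatively, hence order-independently.

The packaged default formulation contains the four botanicals
(Gotukola / Centella asiatica with 15 % triterpenoids, acerola cherry,
elderberry, purple carrot), thirteen vitamins (A, D, E, K, C and eight
B vitamins) and eleven minerals (iodine, copper, manganese, molybdenum,
selenium, zinc, chromium, iron, magnesium, calcium, phosphorus), with
potencies calibrated to the printed single-ingredient efficacies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .biomarkers import SBP_FLOOR, derive_panel
from .model import simulate, steady_state
from .parameters import KineticParameters, _defaults_dir
from .species import SpeciesState

__all__ = [
    "Target",
    "Ingredient",
    "Formulation",
    "ConfigurationError",
    "apply_intervention",
    "single_ingredient_efficacy",
    "combined_efficacy",
    "default_formulation",
    "MARKERS",
]

INGREDIENT_CLASSES = ("botanical", "vitamin", "mineral")

#: markers accepted by the efficacy operations
MARKERS = ("ros", "tnfa", "cortisol", "sbp", "pss")


class ConfigurationError(ValueError):
    """An ingredient refers to an unknown target node."""


@dataclass(frozen=True)
class Target:
    node: str
    direction: str  # "up" | "down"
    potency: float

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"target direction must be up/down, got {self.direction!r}")
        if not 0.0 <= self.potency < 1.0:
            raise ValueError(f"potency must be in [0, 1), got {self.potency!r}")


@dataclass(frozen=True)
class Ingredient:
    name: str
    klass: str
    targets: tuple[Target, ...]

    def __post_init__(self) -> None:
        if self.klass not in INGREDIENT_CLASSES:
            raise ValueError(f"ingredient class must be one of {INGREDIENT_CLASSES}")

    def scaled(self, lam: float) -> "Ingredient":
        """Copy with every potency scaled by ``lam`` in [0, 1]."""
        if not 0.0 <= lam <= 1.0:
            raise ValueError("potency scale must be in [0, 1]")
        return Ingredient(
            self.name, self.klass,
            tuple(Target(t.node, t.direction, t.potency * lam) for t in self.targets),
        )


@dataclass(frozen=True)
class Formulation:
    """A named set of ingredients with multiplicative combination."""

    ingredients: tuple[Ingredient, ...] = ()
    name: str = "formulation"
    combination_rule: str = "multiplicative"

    def __post_init__(self) -> None:
        names = [i.name for i in self.ingredients]
        if len(names) != len(set(names)):
            raise ValueError("ingredient names must be unique")

    def __len__(self) -> int:
        return len(self.ingredients)

    def __iter__(self):
        return iter(self.ingredients)

    def subset(self, classes: Iterable[str], name: str | None = None) -> "Formulation":
        classes = set(classes)
        return Formulation(
            tuple(i for i in self.ingredients if i.klass in classes),
            name=name or "+".join(sorted(classes)),
        )

    def scaled(self, lam: float) -> "Formulation":
        return Formulation(tuple(i.scaled(lam) for i in self.ingredients),
                           name=self.name, combination_rule=self.combination_rule)

    def get(self, name: str) -> Ingredient:
        for i in self.ingredients:
            if i.name == name:
                return i
        raise KeyError(f"no ingredient '{name}'")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "combination_rule": self.combination_rule,
            "ingredients": [
                {
                    "name": i.name,
                    "class": i.klass,
                    "targets": [[t.node, t.direction, t.potency] for t in i.targets],
                }
                for i in self.ingredients
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Formulation":
        ings = tuple(
            Ingredient(
                e["name"], e["class"],
                tuple(Target(n, dr, p) for n, dr, p in e["targets"]),
            )
            for e in d["ingredients"]
        )
        return cls(ings, name=d.get("name", "formulation"),
                   combination_rule=d.get("combination_rule", "multiplicative"))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Formulation":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_formulation() -> Formulation:
    """The packaged calibrated multi-nutrient botanical formulation."""
    return Formulation.from_json(_defaults_dir() / "formulation.json")


# ---------------------------------------------------------------------------

def _production_paths(node: str, params: KineticParameters, ingredient: str) -> list[str]:
    """Parameter paths that together constitute a node's production rate."""
    if node in ("pakt", "pirs"):
        return [f"pool.{node[1:]}.kph"]
    if node not in params.species:
        raise ConfigurationError(
            f"ingredient '{ingredient}' targets unknown node '{node}'"
        )
    paths = [f"species.{node}.basal"]
    for (src, tgt), ek in params.edges.items():
        if tgt == node and ek.sign == "activate":
            paths.append(f"edge.{src}->{tgt}.w")
    return paths


def apply_intervention(params: KineticParameters, formulation: Formulation) -> KineticParameters:
    """Apply a formulation to a parameter set; pure, order-independent.

    Because every targeted rate is scaled multiplicatively, the
    production of a down-target is scaled by exactly
    ``prod_i (1 - p_i)`` over the ingredients hitting it.
    """
    params.validate()
    factor_lists: dict[str, list[float]] = {}
    for ing in formulation:
        for t in ing.targets:
            f = (1.0 - t.potency) if t.direction == "down" else (1.0 + t.potency)
            for path in _production_paths(t.node, params, ing.name):
                factor_lists.setdefault(path, []).append(f)
    if not factor_lists:
        return params.copy()
    # reduce in sorted order so the composition is exactly permutation
    # invariant in floating point
    factors = {path: float(np.prod(sorted(fs))) for path, fs in factor_lists.items()}
    return params.scaled(factors)


# ---------------------------------------------------------------------------

def _marker_value(panel, marker: str) -> float:
    """Marker on its stress-relevant scale.

    SBP is measured as excess over the hemodynamic floor of the
    aldosterone map (the mmHg scale has an arbitrary zero); all other
    markers are on their natural panel scale (ROS as % production).
    """
    if marker == "ros":
        return panel.ros_percent
    if marker == "tnfa":
        return panel.tnfa
    if marker == "cortisol":
        return panel.cortisol
    if marker == "sbp":
        return panel.sbp - SBP_FLOOR
    if marker == "pss":
        return panel.pss
    raise KeyError(f"unknown marker '{marker}'; expected one of {MARKERS}")


def _percent_reduction(pre: float, post: float) -> float:
    if pre <= 0:
        return 0.0
    return 100.0 * (pre - post) / pre


def single_ingredient_efficacy(
    params_stressed: KineticParameters,
    ingredient: Ingredient,
    marker: str,
    healthy_baseline: SpeciesState,
    duration: float = 35.0,
    stressed_state: SpeciesState | None = None,
) -> float:
    """Percent reduction of a marker's stressed steady state by one
    ingredient after a 35-day simulated intervention."""
    if marker not in MARKERS:
        raise KeyError(f"unknown marker '{marker}'; expected one of {MARKERS}")
    pre = stressed_state or steady_state(params_stressed, guess=healthy_baseline)
    p_int = apply_intervention(params_stressed, Formulation((ingredient,), name=ingredient.name))
    traj = simulate(pre, p_int, duration=duration,
                    output_grid=[0.0, duration], rtol=1e-8, atol=1e-12)
    post = traj.final
    m_pre = _marker_value(derive_panel(pre, healthy_baseline), marker)
    m_post = _marker_value(derive_panel(post, healthy_baseline), marker)
    return _percent_reduction(m_pre, m_post)


def combined_efficacy(
    params_healthy: KineticParameters,
    formulation: Formulation,
    marker: str,
    n: int = 1000,
    seed: int = 7,
    population=None,
    result=None,
) -> float:
    """Population-level percent reduction of a marker under the full
    formulation.

    The stress-mitigating effect of the combined formulation is
    quantified on the in-silico population: the marker's mean over the
    stressed arm is compared with its mean over the combined-intervention
    arm (paired design).  Exceeds the best single-ingredient efficacy for
    every marker under the calibrated potencies (synergy).
    """
    if marker not in MARKERS:
        raise KeyError(f"unknown marker '{marker}'; expected one of {MARKERS}")
    from .population import generate_population, simulate_population  # lazy: avoid cycle

    if result is not None:
        res = result
    else:
        pop = population or generate_population(n, seed)
        res = simulate_population(pop, arms=[("stressed", None), ("combined", formulation)],
                                  params=params_healthy)
    pre_mean = float(np.mean([_marker_value(p, marker) for p in res.panels("stressed")]))
    post_mean = float(np.mean([_marker_value(p, marker) for p in res.panels("combined")]))
    return _percent_reduction(pre_mean, post_mean)
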