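"""In-silico population synthesis and simulation.

Generates a virtual adult population (default 1000 individuals, ages
20-80, equal male:female ratio) with heterogeneous stress severities and
kinetic-parameter multipliers, then simulates each individual through
the study arms (stressed / micronutrients-only / botanicals-only /
combined) to steady state and derives the biomarker panels.

Heterogeneity has three layers:

* **stress-pattern mixture** — each individual is assigned one of a
  small set of intended stress-phenotype patterns (all four axes, three
  axes, two, one, none), which sets which severity axes are "on";
* **severity draws** — "on" axes get a severity close to one
  (1 - Beta(1, 9)); "off" axes are mostly zero with a minority of mild
  sub-threshold severities;
* **parameter multipliers** — lognormal multipliers on stress-response
  gains and on basal HPA / renin-angiotensin tone, partially correlated
  through a shared latent factor, plus a per-individual responsiveness
  factor for the antioxidant arm of the intervention (bioavailability
  variation).

Individuals are shared across arms (paired design), so per-individual
pre/post differences are well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .biomarkers import SBP_FLOOR, BiomarkerPanel, classify, derive_panel
from .intervention import Formulation, apply_intervention
from .model import SteadyStateError, steady_state
from .parameters import KineticParameters, healthy_parameters, healthy_state_array
from .species import SpeciesState
from .stress import StressScenario, apply_stress

__all__ = [
    "GeneratorConfig",
    "Individual",
    "Population",
    "PopulationResult",
    "generate_population",
    "simulate_population",
    "responder_fraction",
    "DEFAULT_RESPONDER_CUTOFF",
]

#: minimal relative decline that counts as a response; a smaller change
#: is within intra-individual variability of these markers
DEFAULT_RESPONDER_CUTOFF = 0.55

#: node groups whose intervention potency scales with the individual
#: per-arm responsiveness factors (bioavailability variation)
_RESPONSE_GROUPS: dict[str, frozenset] = {
    "antiox": frozenset({"ros", "sod", "nrf2", "gsh", "cat", "gpx"}),
    "infl": frozenset({"nfkb", "tnfa", "il6", "pakt", "pirs"}),
}

#: intended-phenotype patterns: (oxidative, inflammatory, physical, mental)
_PATTERNS: dict[str, tuple[bool, bool, bool, bool]] = {
    "all_four": (True, True, True, True),
    "no_oxidative": (False, True, True, True),
    "no_inflammatory": (True, False, True, True),
    "sbp_pss": (False, False, True, True),
    "sbp_only": (False, False, True, False),
    "pss_only": (False, False, False, True),
    "none": (False, False, False, False),
}


@dataclass
class GeneratorConfig:
    """Distributional knobs of the population generator.

    The defaults are the calibrated study conditions: they put ~90 % of
    the pre-intervention population on three or more stress axes, ~98 %
    above the SBP and PSS thresholds, and reproduce the pre-intervention
    phenotype mix (about two thirds with all four stress types).
    """

    pattern_probs: dict = field(default_factory=lambda: {
        "all_four": 0.66,
        "no_oxidative": 0.135,
        "no_inflammatory": 0.135,
        "sbp_pss": 0.055,
        "sbp_only": 0.01,
        "pss_only": 0.005,
        "none": 0.0,
    })
    # severity draws
    eps_beta_a: float = 1.0
    eps_beta_b: float = 9.0
    off_zero_prob: float = 0.80
    off_low: float = 0.01
    off_high: float = 0.05
    # multiplier distributions (lognormal; means are arithmetic means)
    # oxidative constitution: tight core plus a severe upper mode that
    # responds incompletely to the antioxidant arm
    m_ox_core_mean: float = 1.0
    m_ox_core_sigma: float = 0.05
    m_ox_tail_prob: float = 0.26
    m_ox_tail_mean: float = 1.95
    m_ox_tail_sigma: float = 0.15
    m_inf_mean: float = 1.60
    m_inf_sigma: float = 0.14
    h_sigma: float = 0.32
    g_cort_sigma: float = 0.25
    g_cort_forced: tuple = (1.8, 2.1)
    g_cort_forced_phys: tuple = (2.5, 2.95)
    g_cort_cap: float = 1.5
    g_ras_sigma: float = 0.06
    g_ras_forced: tuple = (1.9, 2.4)
    g_ras_cap: float = 1.15
    # shared latent correlation across heterogeneity channels
    rho: float = 0.6
    # per-arm response mixtures: fraction of partial responders and the
    # range of their potency scale
    q_ox_partial_prob: float = 0.0
    q_ox_partial_range: tuple = (0.30, 0.45)
    q_inf_partial_prob: float = 0.02
    q_inf_partial_range: tuple = (0.35, 0.55)
    responder_cutoff: float = DEFAULT_RESPONDER_CUTOFF

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Individual:
    """One virtual subject: demographics, severities, multipliers."""

    id: int
    age: float
    sex: str  # "male" | "female"
    severities: StressScenario
    multipliers: dict[str, float]
    response: dict[str, float] = field(default_factory=dict)
    pattern: str = "all_four"

    def params(self, healthy: KineticParameters) -> KineticParameters:
        """This individual's stressed parameter set."""
        return apply_stress(healthy.scaled(self.multipliers), self.severities)

    def formulation(self, formulation: Formulation) -> Formulation:
        """Formulation with per-arm potencies scaled by this individual's
        responsiveness factors."""
        if all(v >= 1.0 for v in self.response.values()):
            return formulation
        from .intervention import Ingredient, Target

        scale = {}
        for arm, q in self.response.items():
            for node in _RESPONSE_GROUPS[arm]:
                scale[node] = q
        ings = []
        for ing in formulation:
            targets = tuple(
                Target(t.node, t.direction, t.potency * scale.get(t.node, 1.0))
                for t in ing.targets
            )
            ings.append(Ingredient(ing.name, ing.klass, targets))
        return Formulation(tuple(ings), name=formulation.name)


@dataclass
class Population:
    """Seeded collection of individuals; regeneration with the same seed
    reproduces the population exactly."""

    individuals: list[Individual]
    seed: int
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.individuals)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for ind in self.individuals:
            row = {
                "id": ind.id, "age": ind.age, "sex": ind.sex,
                "pattern": ind.pattern,
                "severity_inflammatory": ind.severities.inflammatory,
                "severity_oxidative": ind.severities.oxidative,
                "severity_insulin": ind.severities.insulin,
                "antiox_response": ind.response.get("antiox", 1.0),
                "infl_response": ind.response.get("infl", 1.0),
            }
            row.update(ind.multipliers)
            rows.append(row)
        df = pd.DataFrame(rows)
        with open(path, "w") as fh:
            fh.write(f"# stressnet population, seed={self.seed}, n={len(self)}\n")
            df.to_csv(fh, index=False)


def _lognormal(rng, mean_or_median: float, sigma: float, size: int,
               z: np.ndarray | None = None, median: bool = False) -> np.ndarray:
    """Lognormal draws; ``mean_or_median`` is the arithmetic mean unless
    ``median`` is set.  Optionally driven by provided standard normals."""
    if z is None:
        z = rng.standard_normal(size)
    mu = np.log(mean_or_median) - (0.0 if median else 0.5 * sigma**2)
    return np.exp(mu + sigma * z)


def generate_population(
    n: int,
    seed: int,
    config: GeneratorConfig | None = None,
) -> Population:
    """Generate the in-silico population (deterministic for fixed
    ``(n, seed, config)``)."""
    if n < 0:
        raise ValueError("population size must be non-negative")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    names = list(cfg.pattern_probs)
    probs = np.array([cfg.pattern_probs[k] for k in names], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("pattern probabilities must sum to 1")

    ages = rng.uniform(20.0, 80.0, size=n)
    sexes = np.array(["male", "female"] * ((n + 1) // 2))[:n]
    sexes = rng.permutation(sexes)
    patterns = rng.choice(names, size=n, p=probs)

    # severities
    eps = rng.beta(cfg.eps_beta_a, cfg.eps_beta_b, size=(n, 3))
    on_sev = 1.0 - eps
    off_zero = rng.random(size=(n, 3)) < cfg.off_zero_prob
    off_sev = np.where(off_zero, 0.0, rng.uniform(cfg.off_low, cfg.off_high, size=(n, 3)))

    # correlated latent heterogeneity
    z0 = rng.standard_normal(n)
    def _corr(zi):
        return cfg.rho * z0 + np.sqrt(1.0 - cfg.rho**2) * zi

    # oxidative constitution mixture, tail membership tied to the latent
    from scipy.stats import norm

    u_mox = norm.cdf(_corr(rng.standard_normal(n)))
    m_ox_core = _lognormal(rng, cfg.m_ox_core_mean, cfg.m_ox_core_sigma, n)
    m_ox_tail = _lognormal(rng, cfg.m_ox_tail_mean, cfg.m_ox_tail_sigma, n)
    m_ox = np.where(u_mox > 1.0 - cfg.m_ox_tail_prob, m_ox_tail, m_ox_core)
    m_inf = _lognormal(rng, cfg.m_inf_mean, cfg.m_inf_sigma, n)
    h = _lognormal(rng, 1.0, cfg.h_sigma, n, z=_corr(rng.standard_normal(n)), median=True)
    g_cort = _lognormal(rng, 1.0, cfg.g_cort_sigma, n,
                        z=_corr(rng.standard_normal(n)), median=True)
    g_ras = _lognormal(rng, 1.0, cfg.g_ras_sigma, n, median=True)
    g_cort_u = rng.random(size=n)
    g_ras_forced = rng.uniform(*cfg.g_ras_forced, size=n)

    # per-arm responsiveness (partial-responder mixtures, correlated
    # with the latent factor so residual stress clusters post-intervention)
    u_ox = norm.cdf(_corr(rng.standard_normal(n)))
    u_inf = norm.cdf(_corr(rng.standard_normal(n)))
    q_ox = np.where(u_ox > 1.0 - cfg.q_ox_partial_prob,
                    rng.uniform(*cfg.q_ox_partial_range, size=n), 1.0)
    q_inf = np.where(u_inf > 1.0 - cfg.q_inf_partial_prob,
                     rng.uniform(*cfg.q_inf_partial_range, size=n), 1.0)

    individuals: list[Individual] = []
    for i in range(n):
        ox, inf, phys, mental = _PATTERNS[str(patterns[i])]
        s_oxi = on_sev[i, 0] if ox else off_sev[i, 0]
        s_inf = on_sev[i, 1] if inf else off_sev[i, 1]
        s_ins = on_sev[i, 2] if inf else off_sev[i, 2]

        gc = g_cort[i]
        if mental and not (ox or inf):
            # basal HPA tone carries the mental flag when both the IL-6
            # and the ROS routes are quiet; where glucocorticoid
            # hypertension is also intended the tone sits higher
            lo, hi = cfg.g_cort_forced_phys if phys else cfg.g_cort_forced
            gc = lo + (hi - lo) * g_cort_u[i]
        elif not mental and not (ox or inf):
            gc = min(gc, cfg.g_cort_cap)
        gr = g_ras[i]
        if phys and not (inf or mental):
            gr = g_ras_forced[i]  # basal RAS tone carries the physical flag
        elif not phys:
            gr = min(gr, cfg.g_ras_cap)

        mult = {
            "stress.beta_keap1": m_ox[i],
            "stress.beta_sod": m_ox[i],
            "stress.beta_ros": m_ox[i],
            "stress.alpha_inf": m_inf[i],
            "stress.gamma_irs": h[i],
            "stress.gamma_akt": h[i],
            "species.cortisol.basal": gc,
            "species.renin.basal": gr,
        }
        individuals.append(Individual(
            id=i,
            age=float(ages[i]),
            sex=str(sexes[i]),
            severities=StressScenario(
                inflammatory=float(s_inf), oxidative=float(s_oxi), insulin=float(s_ins)
            ),
            multipliers={k: float(v) for k, v in mult.items()},
            response={"antiox": float(q_ox[i]), "infl": float(q_inf[i])},
            pattern=str(patterns[i]),
        ))
    return Population(individuals=individuals, seed=seed, config=cfg)


@dataclass
class PopulationResult:
    """Per-arm, per-individual biomarker panels from one population run."""

    population: Population
    arm_labels: list[str]
    _panels: dict[str, list[BiomarkerPanel | None]]
    failed: dict[str, list[int]]

    def panels(self, arm: str) -> list[BiomarkerPanel]:
        return [p for p in self._panels[arm] if p is not None]

    def paired_panels(self, pre: str, post: str) -> tuple[list[BiomarkerPanel], list[BiomarkerPanel]]:
        a, b = [], []
        for pa, pb in zip(self._panels[pre], self._panels[post]):
            if pa is not None and pb is not None:
                a.append(pa)
                b.append(pb)
        return a, b

    def classifications(self, arm: str, thresholds=None):
        return [classify(p, thresholds) for p in self.panels(arm)]

    def summary(self, arm: str) -> dict[str, dict[str, float]]:
        import pandas as pd

        rows = {}
        panels = self.panels(arm)
        for attr in ("ros_percent", "tnfa", "sbp", "dbp", "cortisol", "pss"):
            v = np.array([p.marker(attr) for p in panels])
            rows[attr] = {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
        return rows

    def to_csv(self, arm: str, path: str | Path) -> None:
        import pandas as pd

        panels = self._panels[arm]
        rows = []
        for ind, p in zip(self.population.individuals, panels):
            row = {"id": ind.id, "arm": arm}
            if p is None:
                row["failed"] = True
            else:
                row.update({
                    "ros_percent": p.ros_percent, "tnfa": p.tnfa, "sbp": p.sbp,
                    "dbp": p.dbp, "cortisol": p.cortisol, "pss": p.pss,
                    "pss_score": p.pss_score, "failed": False,
                })
            rows.append(row)
        with open(path, "w") as fh:
            fh.write(f"# stressnet panels, arm={arm}, seed={self.population.seed}\n")
            pd.DataFrame(rows).to_csv(fh, index=False)


def simulate_population(
    pop: Population,
    arms: Sequence[tuple[str, Formulation | None]],
    params: KineticParameters | None = None,
    healthy_baseline: SpeciesState | None = None,
    max_failure_fraction: float = 0.01,
) -> PopulationResult:
    """Simulate every individual through each arm to steady state.

    Each arm is (label, formulation-or-None); ``None`` means the
    stressed condition without intervention.  A per-individual solver
    failure is recorded as a missing result; the run aborts only if more
    than ``max_failure_fraction`` of individuals fail in any arm.
    """
    if len(arms) == 0:
        raise ValueError("arms must be non-empty")
    healthy = params or healthy_parameters()
    baseline = healthy_baseline or SpeciesState.from_array(healthy_state_array())

    # deterministic reference states per arm as solver guesses
    from .stress import FULL_STRESS

    ref_stressed = apply_stress(healthy, FULL_STRESS)
    guesses: dict[str, np.ndarray] = {}
    for label, formulation in arms:
        p_ref = ref_stressed if formulation is None else apply_intervention(ref_stressed, formulation)
        guesses[label] = steady_state(p_ref, guess=baseline).to_array()

    panels: dict[str, list[BiomarkerPanel | None]] = {label: [] for label, _ in arms}
    failed: dict[str, list[int]] = {label: [] for label, _ in arms}
    for ind in pop.individuals:
        p_stressed = ind.params(healthy)
        for label, formulation in arms:
            if formulation is None:
                p_arm = p_stressed
            else:
                p_arm = apply_intervention(p_stressed, ind.formulation(formulation))
            try:
                ss = steady_state(p_arm, guess=guesses[label])
                panels[label].append(derive_panel(ss, baseline))
            except SteadyStateError:
                panels[label].append(None)
                failed[label].append(ind.id)
    n = max(1, len(pop))
    for label, ids in failed.items():
        if len(ids) / n > max_failure_fraction:
            raise RuntimeError(
                f"arm '{label}': {len(ids)}/{n} individuals failed to converge"
            )
    return PopulationResult(
        population=pop,
        arm_labels=[label for label, _ in arms],
        _panels=panels,
        failed=failed,
    )


def _responder_scale(panel: BiomarkerPanel, marker: str, baseline: BiomarkerPanel) -> float:
    """Marker on its stress-excess scale for responder analysis."""
    if marker == "ros":
        return panel.ros_percent
    if marker == "tnfa":
        return max(panel.tnfa - baseline.tnfa, 0.0)
    if marker == "sbp":
        return panel.sbp - SBP_FLOOR
    if marker == "pss":
        return panel.pss
    if marker == "cortisol":
        return panel.cortisol
    raise KeyError(f"unknown marker '{marker}'")


#: minimum meaningful pre-intervention excess per marker (below this the
#: marker was not elevated and the individual cannot respond on it)
_RESPONDER_ATOL = {"ros": 0.5, "tnfa": 1e-4, "sbp": 0.5, "pss": 0.5, "cortisol": 0.2}


def responder_fraction(
    pre_panels: Sequence[BiomarkerPanel],
    post_panels: Sequence[BiomarkerPanel],
    marker: str,
    criterion: float = DEFAULT_RESPONDER_CUTOFF,
    healthy_baseline: BiomarkerPanel | None = None,
) -> float:
    """Fraction of individuals whose marker declines by more than
    ``criterion`` (relative) between the paired pre and post panels.

    An individual with no pre-intervention excess on the marker cannot
    respond on it and counts in the denominator.
    """
    if len(pre_panels) == 0 or len(pre_panels) != len(post_panels):
        raise ValueError("pre/post panels must be paired and non-empty")
    if healthy_baseline is None:
        healthy = SpeciesState.from_array(healthy_state_array())
        healthy_baseline = derive_panel(healthy, healthy)
    n_resp = 0
    for pre, post in zip(pre_panels, post_panels):
        a = _responder_scale(pre, marker, healthy_baseline)
        b = _responder_scale(post, marker, healthy_baseline)
        if a > _RESPONDER_ATOL[marker] and (a - b) / a > criterion:
            n_resp += 1
    return n_resp / len(pre_panels)
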