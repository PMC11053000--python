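"""Stress induction: severity-parameterised perturbation of the network.

A stress scenario tweaks the key nodes of the inflammatory
(LPS -> NF-kB), oxidative (NRF2-KEAP1 / SOD / ROS) and insulin
(PI3K-AKT -> FOXO1 -> LPS) arms by scaling the corresponding rate
constants.  A severity of zero on every axis is the identity; a
severity of one reproduces the calibrated fully stressed condition.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import KineticParameters
from .species import SpeciesState

__all__ = ["StressScenario", "apply_stress", "confirm_stressed", "FULL_STRESS"]


@dataclass(frozen=True)
class StressScenario:
    """Per-axis stress severities, each in [0, 1].

    * ``inflammatory`` scales the LPS -> NF-kB activation input.
    * ``oxidative`` scales KEAP1-mediated NRF2 suppression, SOD
      suppression and basal ROS generation.
    * ``insulin`` scales the serine-phosphorylation drive on IRS and AKT
      that feeds FOXO1 cytosolic accumulation and LPS activation.
    """

    inflammatory: float = 0.0
    oxidative: float = 0.0
    insulin: float = 0.0

    def __post_init__(self) -> None:
        for axis in ("inflammatory", "oxidative", "insulin"):
            v = getattr(self, axis)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"severity '{axis}' must be in [0, 1], got {v!r}")

    @property
    def is_identity(self) -> bool:
        return self.inflammatory == self.oxidative == self.insulin == 0.0


#: The default fully stressed reference condition.
FULL_STRESS = StressScenario(inflammatory=1.0, oxidative=1.0, insulin=1.0)


def apply_stress(params: KineticParameters, scenario: StressScenario) -> KineticParameters:
    """Return a stressed copy of ``params``; the input is not modified.

    The mechanistic mapping (gains alpha/beta/gamma are calibration
    constants stored in ``params.stress_gains``):

    * inflammatory severity ``s``: LPS -> NF-kB weight x (1 + alpha*s)
    * oxidative severity ``s``: KEAP1 production x (1 + beta_keap1*s),
      SOD production / (1 + beta_sod*s), ROS generation x (1 + beta_ros*s)
    * insulin severity ``s``: IRS and AKT phosphorylation rates
      x (1 + gamma*s)
    """
    params.validate()
    p = params.copy()
    if scenario.is_identity:
        return p
    g = p.stress_gains
    s = scenario.inflammatory
    p.edges[("lps", "nfkb")].w *= 1.0 + g.alpha_inf * s
    s = scenario.oxidative
    p.species["keap1"].basal *= 1.0 + g.beta_keap1 * s
    p.species["sod"].basal /= 1.0 + g.beta_sod * s
    p.species["ros"].basal *= 1.0 + g.beta_ros * s
    s = scenario.insulin
    p.pools["irs"].kph *= 1.0 + g.gamma_irs * s
    p.pools["akt"].kph *= 1.0 + g.gamma_akt * s
    return p


def confirm_stressed(
    state: SpeciesState,
    healthy_baseline: SpeciesState,
    thresholds=None,
) -> dict[str, bool]:
    """Per-axis stressed-vs-healthy elevation flags for a state.

    Delegates the thresholds to the biomarker module: oxidative if ROS
    production exceeds the healthy level by more than 10 %, inflammatory
    if TNF-a exceeds the model-scale threshold, physical if derived
    SBP > 120 mmHg, mental if the PSS score mapped from cortisol
    exceeds 13.
    """
    from .biomarkers import classify, derive_panel

    state.validate()
    healthy_baseline.validate()
    panel = derive_panel(state, healthy_baseline)
    cls = classify(panel, thresholds)
    return {
        "oxidative": cls.oxidative,
        "inflammatory": cls.inflammatory,
        "physical": cls.physical,
        "mental": cls.mental,
    }
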