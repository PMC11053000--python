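"""Clinical read-outs and stress-phenotype classification.

Four clinical outputs are derived from a model state:

* **ROS production %** — elevation of the reactive-oxygen level over the
  healthy baseline, in percent (> 10 % marks oxidative stress).
* **TNF-a** (pg/mL) — inflammatory stress marker, read directly from the
  state.  The clinical normal band is 0-1.5 pg/mL; the model operates on
  a 1e-3 pg/mL scale, so the classifier threshold is a calibrated
  model-scale constant and the clinical band is kept as documentation.
* **SBP** (mmHg) — physical stress marker, derived from aldosterone via
  a saturating (logistic-style) map; > 120 mmHg marks physical stress.
  DBP is reported as 0.65 * SBP but not used for classification.
* **PSS** (0-40) — mental stress score mapped from cortisol through a
  monotone saturating map; > 13 marks mental stress (0-13 low, 14-26
  moderate, 27-40 high perceived stress).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .species import SpeciesState

__all__ = [
    "BiomarkerPanel",
    "StressClassification",
    "Thresholds",
    "derive_panel",
    "cortisol_to_pss",
    "sbp_from_aldosterone",
    "classify",
    "remission_stats",
    "phenotype_distribution",
    "DEFAULT_THRESHOLDS",
    "HEALTHY_BANDS",
]

# --- calibrated map constants -------------------------------------------

#: SBP map: sbp = SBP_FLOOR + SBP_SPAN * a^2 / (SBP_K^2 + a^2).
#: Floor and span are calibrated so the healthy renin-angiotensin tone
#: (aldosterone = 1 model unit) reads ~115 mmHg and the fully stressed
#: tone ~156 mmHg, with a hemodynamic floor of 106 mmHg and a ceiling
#: of 200 mmHg.
SBP_FLOOR = 106.0
SBP_CEIL = 200.0
SBP_SPAN = SBP_CEIL - SBP_FLOOR
SBP_K = 3.0
SBP_H = 2.0

#: PSS map: pss = 40 * c^h / (K^h + c^h), anchored so that the calibrated
#: stressed cortisol level (106.7 ng/mL) maps into the high band (~32.7)
#: and the post-intervention level (8.57 ng/mL) into the low band (~9.0).
PSS_MAX = 40.0
PSS_K = 23.9
PSS_H = 1.38

#: ratio of diastolic to systolic pressure used for the reported DBP
DBP_RATIO = 0.65

#: Clinical healthy bands kept for reporting (cortisol band in nmol/L is
#: retained as metadata only; classification uses the PSS band).
HEALTHY_BANDS = {
    "ros": (0.0, 10.0),        # % production over baseline
    "tnfa": (0.0, 1.0e-3),     # pg/mL, model scale
    "sbp": (0.0, 120.0),       # mmHg
    "pss": (0.0, 13.0),        # score
    "tnfa_clinical": (0.0, 1.5),   # pg/mL, literature serum band
    "cortisol_nmol_per_L": (140.0, 690.0),
}


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds for the four stress axes."""

    ros_percent: float = 10.0
    tnfa: float = 1.0e-3
    sbp: float = 120.0
    pss: float = 13.0


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class BiomarkerPanel:
    """The four clinical outputs derived from one model state."""

    ros_percent: float
    tnfa: float
    sbp: float
    dbp: float
    cortisol: float
    pss: float

    @property
    def pss_score(self) -> int:
        """PSS rounded half-up to the integer instrument scale."""
        return int(min(40, max(0, np.floor(self.pss + 0.5))))

    def marker(self, name: str) -> float:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown marker '{name}'") from None


@dataclass(frozen=True)
class StressClassification:
    """Per-axis stress flags and their count (0-4)."""

    oxidative: bool
    inflammatory: bool
    physical: bool
    mental: bool

    @property
    def count(self) -> int:
        return int(self.oxidative) + int(self.inflammatory) + int(self.physical) + int(self.mental)

    @property
    def category(self) -> str:
        return ("none", "one", "two", "three", "four")[self.count]


def sbp_from_aldosterone(aldosterone: float) -> float:
    """Monotone saturating aldosterone -> systolic BP map (mmHg)."""
    if aldosterone < 0:
        raise ValueError("aldosterone must be non-negative")
    a = aldosterone ** SBP_H
    return SBP_FLOOR + SBP_SPAN * a / (SBP_K ** SBP_H + a)


def cortisol_to_pss(cortisol: float) -> float:
    """Map cortisol (ng/mL) to a perceived-stress score in [0, 40].

    Monotone non-decreasing and saturating; 0 maps to 0.
    """
    if cortisol < 0:
        raise ValueError("cortisol must be non-negative")
    c = cortisol ** PSS_H
    return PSS_MAX * c / (PSS_K ** PSS_H + c)


def derive_panel(state: SpeciesState, healthy_baseline: SpeciesState) -> BiomarkerPanel:
    """Derive the four clinical outputs from a state.

    ``ros_percent`` is the percent elevation over the healthy baseline,
    clipped at zero; TNF-a and cortisol are copied in their model units;
    SBP comes from the aldosterone map and PSS from the cortisol map.
    """
    state.validate()
    healthy_baseline.validate()
    if healthy_baseline.ros <= 0:
        raise ValueError("healthy baseline ROS must be positive")
    ros_percent = max(0.0, 100.0 * (state.ros - healthy_baseline.ros) / healthy_baseline.ros)
    sbp = sbp_from_aldosterone(state.aldosterone)
    return BiomarkerPanel(
        ros_percent=ros_percent,
        tnfa=state.tnfa,
        sbp=sbp,
        dbp=DBP_RATIO * sbp,
        cortisol=state.cortisol,
        pss=cortisol_to_pss(state.cortisol),
    )


def classify(panel: BiomarkerPanel, thresholds: Thresholds | None = None) -> StressClassification:
    """Deterministic threshold classification of a panel.

    PSS is rounded to the integer instrument scale before banding.
    """
    t = thresholds or DEFAULT_THRESHOLDS
    return StressClassification(
        oxidative=panel.ros_percent > t.ros_percent,
        inflammatory=panel.tnfa > t.tnfa,
        physical=panel.sbp > t.sbp,
        mental=panel.pss_score > t.pss,
    )


#: responder/remission marker scales: name -> (panel attribute, healthy band)
_REMISSION_MARKERS = {
    "ros": ("ros_percent", HEALTHY_BANDS["ros"]),
    "tnfa": ("tnfa", HEALTHY_BANDS["tnfa"]),
    "sbp": ("sbp", HEALTHY_BANDS["sbp"]),
    "pss": ("pss", HEALTHY_BANDS["pss"]),
}


def remission_stats(
    pre_panels: Sequence[BiomarkerPanel],
    post_panels: Sequence[BiomarkerPanel],
    stressed_means: dict[str, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-marker fractions of individuals below the stressed mean and
    within the healthy band after intervention.

    ``stressed_means`` defaults to the means of ``pre_panels``.
    """
    if len(pre_panels) == 0 or len(post_panels) == 0:
        raise ValueError("panel lists must be non-empty")
    if len(pre_panels) != len(post_panels):
        raise ValueError("panel lists must be paired (equal length)")
    out: dict[str, dict[str, float]] = {}
    n = len(post_panels)
    for marker, (attr, band) in _REMISSION_MARKERS.items():
        post = np.array([p.marker(attr) for p in post_panels])
        if stressed_means is not None and marker in stressed_means:
            mean_pre = stressed_means[marker]
        else:
            mean_pre = float(np.mean([p.marker(attr) for p in pre_panels]))
        lo, hi = band
        out[marker] = {
            "below_stressed_mean": float(np.sum(post < mean_pre)) / n,
            "within_healthy_band": float(np.sum((post >= lo) & (post <= hi))) / n,
        }
    return out


def phenotype_distribution(
    classifications: Sequence[StressClassification],
) -> dict[str, Fraction]:
    """Fractions over the five phenotype categories {four..none}.

    Computed with rational arithmetic on counts so the five fractions
    sum to exactly one.
    """
    if len(classifications) == 0:
        raise ValueError("classification list must be non-empty")
    n = len(classifications)
    counts = {"four": 0, "three": 0, "two": 0, "one": 0, "none": 0}
    for c in classifications:
        counts[c.category] += 1
    return {k: Fraction(v, n) for k, v in counts.items()}
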