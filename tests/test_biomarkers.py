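"""Biomarker maps, classification combinatorics, remission and
phenotype statistics."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stressnet import (
    BiomarkerPanel,
    StressClassification,
    Thresholds,
    classify,
    cortisol_to_pss,
    derive_panel,
    phenotype_distribution,
    remission_stats,
    sbp_from_aldosterone,
)


def _panel(ros=0.0, tnfa=1e-4, sbp=110.0, cortisol=10.0, pss=None):
    return BiomarkerPanel(ros_percent=ros, tnfa=tnfa, sbp=sbp, dbp=0.65 * sbp,
                          cortisol=cortisol,
                          pss=pss if pss is not None else cortisol_to_pss(cortisol))


# --- cortisol -> PSS map ---------------------------------------------------

def test_pss_map_floor_and_bands():
    assert cortisol_to_pss(0.0) == 0.0
    assert 27.0 <= cortisol_to_pss(106.7) <= 40.0   # high perceived stress
    assert 0.0 <= cortisol_to_pss(8.57) <= 13.0     # low-stress range
    with pytest.raises(ValueError):
        cortisol_to_pss(-1.0)


def test_pss_map_monotone_and_bounded():
    grid = np.linspace(0.0, 500.0, 400)
    vals = np.array([cortisol_to_pss(c) for c in grid])
    assert np.all(np.diff(vals) >= 0.0)
    assert vals.min() >= 0.0 and vals.max() <= 40.0


def test_sbp_map_monotone():
    """Doubling aldosterone strictly increases derived SBP."""
    a = np.linspace(0.1, 6.0, 50)
    s = np.array([sbp_from_aldosterone(v) for v in a])
    assert np.all(np.diff(s) > 0.0)
    assert sbp_from_aldosterone(2.0) > sbp_from_aldosterone(1.0)


# --- derive_panel ----------------------------------------------------------

def test_panel_at_baseline_is_unstressed(healthy_state):
    panel = derive_panel(healthy_state, healthy_state)
    assert panel.ros_percent == 0.0
    assert panel.sbp < 120.0 and panel.pss < 13.0
    assert panel.dbp == pytest.approx(0.65 * panel.sbp)


def test_stressed_panel_reproduces_calibrated_values(stressed_ss, healthy_state):
    panel = derive_panel(stressed_ss, healthy_state)
    assert panel.ros_percent == pytest.approx(171.92, rel=0.01)
    assert panel.cortisol == pytest.approx(106.7, rel=0.01)
    assert panel.tnfa == pytest.approx(2.2e-3, rel=0.01)


def test_zero_ros_baseline_rejected(healthy_state):
    with pytest.raises(ValueError):
        derive_panel(healthy_state, healthy_state.replace(ros=0.0))


# --- classification --------------------------------------------------------

@settings(max_examples=100, derandomize=True, deadline=None)
@given(ros=st.booleans(), inf=st.booleans(), phys=st.booleans(), men=st.booleans())
def test_classifier_combinatorics(ros, inf, phys, men):
    """Every combination of marker elevations maps to exactly the
    matching flag pattern and count."""
    panel = _panel(
        ros=50.0 if ros else 0.0,
        tnfa=2e-3 if inf else 1e-4,
        sbp=150.0 if phys else 110.0,
        cortisol=80.0 if men else 8.0,
    )
    cls = classify(panel)
    assert (cls.oxidative, cls.inflammatory, cls.physical, cls.mental) == \
        (ros, inf, phys, men)
    assert cls.count == sum((ros, inf, phys, men))
    assert cls.category == ("none", "one", "two", "three", "four")[cls.count]


def test_classifier_threshold_monotone():
    """Raising a marker never clears its flag."""
    lo = classify(_panel(ros=11.0))
    hi = classify(_panel(ros=300.0))
    assert lo.oxidative and hi.oxidative
    assert classify(_panel(sbp=125.0)).physical
    assert not classify(_panel(sbp=120.0)).physical


def test_classifier_pss_integer_banding():
    """PSS is rounded half-up to the instrument scale before banding."""
    assert not classify(_panel(cortisol=0.0, pss=13.4)).mental
    assert classify(_panel(cortisol=0.0, pss=13.5)).mental


def test_custom_thresholds():
    t = Thresholds(ros_percent=50.0, tnfa=1.0, sbp=300.0, pss=39.0)
    assert classify(_panel(ros=20.0, sbp=150.0), t).count == 0


# --- phenotype distribution ------------------------------------------------

def test_phenotype_distribution_exact_rational():
    cls = [StressClassification(True, True, True, True)] * 3 + \
          [StressClassification(False, False, False, False)] * 1
    dist = phenotype_distribution(cls)
    assert dist["four"] == Fraction(3, 4)
    assert dist["none"] == Fraction(1, 4)
    assert sum(dist.values()) == 1  # exactly, in rational arithmetic


def test_phenotype_distribution_all_healthy():
    cls = [StressClassification(False, False, False, False)] * 10
    dist = phenotype_distribution(cls)
    assert dist["none"] == 1 and dist["four"] == 0


def test_phenotype_distribution_empty_rejected():
    with pytest.raises(ValueError):
        phenotype_distribution([])


# --- remission -------------------------------------------------------------

def test_remission_all_healthy_post():
    pre = [_panel(ros=200.0, tnfa=3e-3, sbp=160.0, cortisol=100.0)] * 5
    post = [_panel(ros=0.0, tnfa=0.0, sbp=110.0, cortisol=0.0)] * 5
    out = remission_stats(pre, post)
    for marker in ("ros", "tnfa", "sbp", "pss"):
        assert out[marker]["below_stressed_mean"] == 1.0
        assert out[marker]["within_healthy_band"] == 1.0


def test_remission_no_change_fraction_near_half(study):
    """With post == pre, the below-stressed-mean fraction reflects the
    distribution's balance about its mean: strictly interior, near one
    half only for symmetric markers (the bimodal TNF-a distribution has
    most of its mass above its mean)."""
    pre = study["result"].panels("stressed")
    out = remission_stats(pre, pre)
    for marker in ("ros", "tnfa", "sbp", "pss"):
        frac = out[marker]["below_stressed_mean"]
        assert 0.1 < frac < 0.95


def test_remission_rejects_mismatched_inputs():
    with pytest.raises(ValueError):
        remission_stats([], [])
    with pytest.raises(ValueError):
        remission_stats([_panel()], [_panel(), _panel()])
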