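"""Relative correction factors: both estimators, their aggregation,
robustness across conditions, and the limits in which they coincide."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qams import longan
from qams.errors import PanelError
from qams.rcf import (
    RCFSet,
    aggregate_multipoint,
    multipoint_rcf,
    multipoint_rcf_from_series,
    robustness_summary,
    round_half_up,
    slope_rcf,
    slope_rcf_set,
)
from qams.synthetic import NoiseModel, default_response_model, simulate_standard_series, standard_masses


# -------------------------------------------------------------- multipoint

def test_multipoint_identity():
    assert multipoint_rcf(1.0, 5.0, 1.0, 5.0) == 1.0


def test_multipoint_direct_arithmetic():
    # (m_s·A_i)/(m_i·A_s) = (2·3)/(4·6)
    assert multipoint_rcf(m_s=2.0, A_s=6.0, m_i=4.0, A_i=3.0) == pytest.approx(0.25)


def test_multipoint_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        multipoint_rcf(0.0, 1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        multipoint_rcf(1.0, 1.0, 1.0, -2.0)


def test_multipoint_on_proportional_response_equals_slope_ratio():
    """With A = k·m (no intercept), the multipoint factor is k_i/k_s at any level."""
    ku = {c: longan.calibration_curve("UPLC", c).slope for c in longan.COMPONENT_CODES}
    for m_s, m_i in [(0.1, 0.05), (0.4, 0.02), (0.25, 0.25)]:
        f = multipoint_rcf(m_s, ku["C3"] * m_s, m_i, ku["C1"] * m_i)
        assert f == pytest.approx(ku["C1"] / ku["C3"], rel=1e-12)
    assert round_half_up(ku["C1"] / ku["C3"]) == 0.400


@pytest.mark.parametrize("values,expected_mean", [
    # published per-volume factors: astragalin on UPLC, luteolin on HPLC
    ([0.477, 0.485, 0.487, 0.490, 0.489, 0.490], 0.486),
    ([0.781, 0.797, 0.800, 0.802, 0.804, 0.806], 0.798),
])
def test_aggregate_reproduces_published_means(values, expected_mean):
    mean, rsd = aggregate_multipoint(values)
    assert round_half_up(mean) == expected_mean
    assert rsd > 0


def test_aggregate_constant_vector_has_zero_rsd():
    mean, rsd = aggregate_multipoint([0.4, 0.4, 0.4])
    assert mean == pytest.approx(0.4, rel=1e-15)
    assert rsd == pytest.approx(0.0, abs=1e-10)


def test_aggregate_needs_two_values():
    with pytest.raises(ValueError):
        aggregate_multipoint([0.4])


# -------------------------------------------------------------------- slope

@pytest.mark.parametrize("k_i,k_s,expected", [
    (7794.28, 19503.76, 0.400),   # ethyl gallate / quercetin, UPLC
    (9618.87, 19503.76, 0.493),   # astragalin, UPLC
    (17806.81, 19503.76, 0.913),  # kaempferol, UPLC
    (2903.01, 3574.23, 0.812),    # luteolin, HPLC
    (3249.11, 3574.23, 0.909),    # kaempferol, HPLC
])
def test_slope_rcf_reproduces_published_values(k_i, k_s, expected):
    assert round_half_up(slope_rcf(k_i, k_s)) == expected


def test_slope_rcf_of_equal_slopes_is_one():
    assert slope_rcf(1234.5, 1234.5) == 1.0


def test_slope_rcf_rejects_nonpositive():
    with pytest.raises(ValueError):
        slope_rcf(-1.0, 2.0)


# ----------------------------------------------------- equivalence property

def test_multipoint_equals_slope_in_intercept_free_noiseless_limit():
    """Per level, |multipoint − slope| < 1e-12 when b = 0 and noise = 0."""
    response = default_response_model("UPLC").without_intercepts()
    table = simulate_standard_series(response, standard_masses("UPLC"), NoiseModel())
    curves = {c: longan.calibration_curve("UPLC", c) for c in longan.COMPONENT_CODES}
    sl = slope_rcf_set(curves, "C3")
    levels = sorted({r.sample_id for r in table})
    for level in levels:
        recs = {r.component_code: r for r in table if r.sample_id == level}
        ref = recs["C3"]
        for code in longan.ANALYTE_CODES:
            f = multipoint_rcf(ref.injected_mass, ref.area, recs[code].injected_mass, recs[code].area)
            assert abs(f - sl.values[code]) < 1e-12


def test_multipoint_with_intercepts_drifts_with_level():
    """Published-style intercepts make per-level factors vary monotonically-ish,
    so the aggregated RSD is strictly positive."""
    response = default_response_model("UPLC")
    table = simulate_standard_series(response, standard_masses("UPLC"), NoiseModel())
    mp = multipoint_rcf_from_series(table, "C3")
    for code in longan.ANALYTE_CODES:
        _, rsd = mp.dispersion[code]
        assert rsd > 0


def test_simulated_multipoint_means_near_published_table():
    """The full simulated series reproduces the published per-volume means
    to the tables' own rounding scale."""
    response = default_response_model("UPLC")
    table = simulate_standard_series(response, standard_masses("UPLC"), NoiseModel())
    mp = multipoint_rcf_from_series(table, "C3")
    published_means = {"C1": 0.397, "C2": 0.486, "C4": 0.813, "C5": 0.902}
    for code, expected in published_means.items():
        assert mp.values[code] == pytest.approx(expected, abs=2e-3)


@given(gain=st.floats(min_value=0.01, max_value=100.0),
       mass_scale=st.floats(min_value=0.01, max_value=100.0))
def test_scale_invariance(gain, mass_scale):
    """Detector gain and mass rescaling leave the factor unchanged."""
    base = multipoint_rcf(0.2, 3900.0, 0.05, 390.0)
    assert multipoint_rcf(0.2, 3900.0 * gain, 0.05, 390.0 * gain) == pytest.approx(base, rel=1e-12)
    assert multipoint_rcf(0.2 * mass_scale, 3900.0, 0.05 * mass_scale, 390.0) == pytest.approx(base, rel=1e-12)


def test_structural_ordering_of_factors():
    """Structurally similar analytes (luteolin, kaempferol) sit nearer 1
    than the glycoside and the gallate ester."""
    curves = {c: longan.calibration_curve("UPLC", c) for c in longan.COMPONENT_CODES}
    sl = slope_rcf_set(curves, "C3")
    for close in ("C4", "C5"):
        for far in ("C1", "C2"):
            assert abs(sl.values[close] - 1) < abs(sl.values[far] - 1)


# --------------------------------------------------------------- robustness

def _sets_from_table(table):
    return [
        RCFSet("C3", values, "multipoint", condition=cond)
        for cond, values in table.items()
    ]


def test_robustness_from_published_conditions():
    """Across the nine published conditions the largest per-analyte RSD
    stays at the couple-percent level (recomputed from printed cells)."""
    out = robustness_summary(_sets_from_table(longan.ROBUSTNESS_RCF_TABLE))
    assert out["C1"] == pytest.approx(2.27, abs=0.01)
    assert max(out.values()) == out["C1"]


def test_identical_conditions_have_zero_rsd():
    sets = [RCFSet("C3", {"C1": 0.4}, "multipoint", condition=f"c{i}") for i in range(3)]
    assert robustness_summary(sets)["C1"] == pytest.approx(0.0, abs=1e-10)


def test_robustness_monotonic_in_spread():
    tight = [RCFSet("C3", {"C1": 0.4}, "slope"), RCFSet("C3", {"C1": 0.4}, "slope")]
    wide = [RCFSet("C3", {"C1": 0.4}, "slope"), RCFSet("C3", {"C1": 0.5}, "slope")]
    assert robustness_summary(wide)["C1"] > robustness_summary(tight)["C1"]


def test_mismatched_panels_rejected():
    sets = [RCFSet("C3", {"C1": 0.4}, "slope"), RCFSet("C3", {"C2": 0.5}, "slope")]
    with pytest.raises(PanelError):
        robustness_summary(sets)


def test_rcfset_rejects_reference_among_analytes():
    with pytest.raises(ValueError):
        RCFSet("C3", {"C3": 1.0, "C1": 0.4}, "slope")
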