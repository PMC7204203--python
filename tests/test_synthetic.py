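"""Generator behaviour: exact noiseless responses, unit conversions,
determinism, noise calibration, and the render/integrate round trip."""

import numpy as np
import pytest

from qams import longan
from qams.chromdata import PeakRecord, PeakTable
from qams.synthetic import (
    ExtractionSpec,
    NoiseModel,
    ResponseModel,
    default_content_profile,
    default_noise_model,
    default_response_model,
    default_retention_model,
    injected_mass_ug,
    integrate_chromatogram,
    render_chromatogram,
    simulate_sample_table,
    simulate_standard_series,
    standard_masses,
)


def test_noiseless_standard_area_is_exact():
    """A 0.2 µg quercetin injection gives area k·m + b exactly."""
    response = default_response_model("UPLC")
    table = simulate_standard_series(response, {"C3": [0.2]}, NoiseModel())
    (rec,) = list(table)
    assert rec.area == pytest.approx(19503.76 * 0.2 - 50.67, abs=1e-9)
    assert rec.area == pytest.approx(3850.082, abs=1e-9)
    assert rec.injected_mass == 0.2


def test_zero_mass_zero_intercept_gives_zero_area():
    response = ResponseModel("UPLC", {"C3": (1000.0, 0.0)})
    table = simulate_standard_series(response, {"C3": [0.0]}, NoiseModel())
    assert list(table)[0].area == 0.0


def test_series_record_count():
    response = default_response_model("UPLC")
    table = simulate_standard_series(response, standard_masses("UPLC"), NoiseModel())
    assert len(table) == 6 * 5


def test_negative_mass_rejected():
    response = default_response_model("UPLC")
    with pytest.raises(ValueError, match="non-negative"):
        simulate_standard_series(response, {"C3": [-0.1]}, NoiseModel())


def test_standard_masses_match_published_linear_ranges():
    """Working-solution concentration × volume series spans each linear range."""
    for system in ("UPLC", "HPLC"):
        ladders = standard_masses(system)
        for code, ladder in ladders.items():
            lo, hi = longan.calibration_curve(system, code).linear_range
            assert ladder[0] == pytest.approx(lo, rel=5e-3)
            assert ladder[-1] == pytest.approx(hi, rel=5e-3)


def test_injected_mass_unit_conversion():
    """1.073 mg/g at 4 g / 20 mL injected at 0.5 µL puts 0.1073 µg on column."""
    m = injected_mass_ug(1.073, ExtractionSpec(4.0, 20.0), 0.5)
    assert m == pytest.approx(0.1073, rel=1e-12)


def test_zero_content_gives_intercept_only_peak():
    """A zero-mass injection reads back the response intercept, floored at
    zero detector counts."""
    from qams.synthetic import ContentProfile
    profile_row = {c: 0.0 for c in longan.COMPONENT_CODES}
    for system_id, system in (("UPLC", longan.UPLC_SYSTEM), ("HPLC", longan.HPLC_SYSTEM)):
        response = default_response_model(system_id)
        retention = default_retention_model(system_id)
        table = simulate_sample_table(
            ContentProfile({"blank": profile_row}), ExtractionSpec(),
            system, response, noise=NoiseModel())
        by_rt = {r.retention_time: r.area for r in table}
        for code in longan.COMPONENT_CODES:
            _, b = response.curves[code]
            assert by_rt[retention.rt(code)] == max(0.0, b)


def test_same_seed_gives_identical_tables():
    response = default_response_model("UPLC")
    noise = default_noise_model("UPLC", seed=42)
    kwargs = dict(profile=default_content_profile(), extraction=ExtractionSpec(),
                  system=longan.UPLC_SYSTEM, response=response, noise=noise, replicates=3)
    t1 = simulate_sample_table(**kwargs)
    t2 = simulate_sample_table(**kwargs)
    assert list(t1) == list(t2)
    t3 = simulate_sample_table(**{**kwargs, "noise": default_noise_model("UPLC", seed=43)})
    assert list(t1) != list(t3)


def test_sample_records_are_unlabeled_unknowns():
    table = simulate_sample_table(
        default_content_profile(), ExtractionSpec(), longan.UPLC_SYSTEM,
        default_response_model("UPLC"), noise=NoiseModel())
    assert all(r.component_code is None and r.injected_mass is None for r in table)
    assert len(table) == 10 * 5


def test_area_noise_reproduces_requested_rsd():
    """Empirical area RSD matches the nominal within 3 standard errors."""
    target = 1.5  # percent
    response = ResponseModel("UPLC", {"C3": (10000.0, 0.0)})
    noise = NoiseModel(area_rsd=target, seed=7)
    n = 400
    table = simulate_standard_series(response, {"C3": [0.2] * n}, noise)
    areas = np.array([r.area for r in table])
    empirical = 100.0 * areas.std(ddof=1) / areas.mean()
    se = target / np.sqrt(2 * n)
    assert abs(empirical - target) < 3 * se


# ------------------------------------------------------- render / integrate

def _single_peak_table(area=100.0, rt=5.0):
    return PeakTable(records=[PeakRecord("s", "sim", rt, area, 1.0)])


def test_unit_area_gaussian_integrates_to_one():
    t, y = render_chromatogram(_single_peak_table(area=1.0), peak_width_sd=0.05, sampling_rate=20.0)
    assert np.trapezoid(y, t) == pytest.approx(1.0, rel=5e-3)


def test_undersampling_rejected():
    with pytest.raises(ValueError, match="points per peak sd"):
        render_chromatogram(_single_peak_table(), peak_width_sd=0.01, sampling_rate=2.0)


def test_two_resolved_peaks_give_two_maxima():
    # separation 1.0 min vs sd 0.05 min: resolution far above 1.5
    table = PeakTable(records=[
        PeakRecord("s", "sim", 5.0, 100.0, 1.0),
        PeakRecord("s", "sim", 6.0, 80.0, 1.0),
    ])
    t, y = render_chromatogram(table, peak_width_sd=0.05, sampling_rate=20.0)
    from scipy.signal import find_peaks
    apexes, _ = find_peaks(y, prominence=10.0)
    assert len(apexes) == 2


def test_empty_table_renders_baseline_only():
    t, y = render_chromatogram(PeakTable(), peak_width_sd=0.05, sampling_rate=20.0,
                               baseline_level=3.0)
    assert np.allclose(y, 3.0)


def test_flat_signal_integrates_to_empty_table():
    t = np.linspace(0, 10, 1000)
    y = np.full_like(t, 2.0)
    assert len(integrate_chromatogram(t, y, min_prominence=1.0)) == 0


def test_single_gaussian_area_recovered():
    t, y = render_chromatogram(_single_peak_table(area=100.0), peak_width_sd=0.05,
                               sampling_rate=20.0)
    out = integrate_chromatogram(t, y, min_prominence=10.0)
    assert len(out) == 1
    assert list(out)[0].area == pytest.approx(100.0, rel=5e-3)


def test_render_integrate_round_trip_on_five_peaks():
    """Five well-separated peaks: areas within 0.5%, apexes within one sample."""
    retention = default_retention_model("UPLC")
    areas = {"C1": 1500.0, "C2": 900.0, "C3": 8000.0, "C4": 700.0, "C5": 1200.0}
    table = PeakTable(records=[
        PeakRecord("s", "sim", retention.rt(c), areas[c], 1.0) for c in areas
    ])
    t, y = render_chromatogram(table, peak_width_sd=0.05, sampling_rate=20.0,
                               baseline_level=5.0, baseline_drift=0.2)
    out = integrate_chromatogram(t, y, min_prominence=50.0)
    assert len(out) == 5
    dt = t[1] - t[0]
    truth = sorted(table, key=lambda r: r.retention_time)
    found = sorted(out, key=lambda r: r.retention_time)
    for a, b in zip(truth, found):
        assert b.area == pytest.approx(a.area, rel=5e-3)
        assert abs(b.retention_time - a.retention_time) <= dt
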