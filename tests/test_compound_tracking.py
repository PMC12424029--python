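"""EIC extraction, peak location, ppm deviation and peak-shape factors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import exponnorm

from conftest import make_eic
from lcmsqc import TrackedCompound, extract_eic, find_peak, peak_shape, ppm_deviation
from lcmsqc.compound_tracking import (TrackingParams, integration_bounds,
                                      track_file)
from lcmsqc.errors import EmptyRunError, InputError
from lcmsqc.mzml_io import Spectrum
from lcmsqc.synthetic_data import simulate_run_arrays


def _spec(rt, mz, inten):
    return Spectrum(rt=rt, mz=np.asarray(mz, float), intensity=np.asarray(inten, float))


# -- extract_eic -----------------------------------------------------------

def test_single_centroid_at_target_is_recovered_exactly():
    spectra = [_spec(0.0, [500.0], [1000.0])]
    eic = extract_eic(spectra, 500.0, tol_ppm=20)
    assert eic.intensity.tolist() == [1000.0]
    assert eic.mz_per_scan.tolist() == [500.0]


def test_centroid_outside_ppm_window_contributes_zero():
    mz = 500.0 * (1 + 30e-6)
    eic = extract_eic([_spec(0.0, [mz], [1000.0])], 500.0, tol_ppm=20)
    assert eic.intensity.tolist() == [0.0]
    assert np.isnan(eic.mz_per_scan[0])


def test_upper_window_bound_is_half_open():
    hi = 500.0 * (1 + 20e-6)
    eic = extract_eic([_spec(0.0, [hi], [10.0])], 500.0, tol_ppm=20)
    assert eic.intensity.tolist() == [0.0]


def test_in_window_mz_is_intensity_weighted_mean():
    m1, m2 = 500.000, 500.005
    eic = extract_eic([_spec(0.0, [m1, m2], [100.0, 300.0])], 500.0, tol_ppm=20)
    assert eic.mz_per_scan[0] == pytest.approx((100 * m1 + 300 * m2) / 400)
    assert eic.intensity[0] == 400.0


def test_empty_spectra_raise_empty_run():
    with pytest.raises(EmptyRunError):
        extract_eic([], 500.0, 20.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_eic_conserves_total_in_window_signal(seed):
    """Sum over EIC scans equals a brute-force sum of in-window centroids."""
    rng = np.random.default_rng(seed)
    target, tol = 400.0, 25.0
    lo, hi = target * (1 - tol * 1e-6), target * (1 + tol * 1e-6)
    spectra = []
    brute = 0.0
    for i in range(rng.integers(1, 8)):
        n = int(rng.integers(0, 20))
        mz = np.sort(rng.uniform(399.97, 400.03, n))
        inten = rng.exponential(100.0, n)
        brute += inten[(mz >= lo) & (mz < hi)].sum()
        spectra.append(_spec(0.1 * i, mz, inten))
    eic = extract_eic(spectra, target, tol)
    assert eic.intensity.sum() == pytest.approx(brute, rel=1e-12, abs=1e-9)


# -- find_peak -------------------------------------------------------------

def test_symmetric_peak_apex_found_at_center():
    rt = np.arange(0, 10, 0.02)
    inten = 1000 * np.exp(-0.5 * ((rt - 5.0) / 0.1) ** 2)
    hit = find_peak(make_eic(rt, inten), 5.0, 0.5)
    assert hit is not None
    assert hit[0] == pytest.approx(5.0, abs=0.02)


def test_flat_zero_eic_is_not_found():
    assert find_peak(make_eic([0, 1, 2], [0, 0, 0]), 1.0, 1.0) is None


def test_tie_broken_by_proximity_to_expected_rt():
    rt = np.array([4.8, 4.9, 5.0, 5.1, 5.2])
    inten = np.array([1.0, 9.0, 2.0, 1.0, 9.0])
    hit = find_peak(make_eic(rt, inten), 5.0, 0.5)
    assert hit[0] == pytest.approx(4.9)


def test_isolated_spike_rejected_by_consecutive_scan_rule():
    rt = np.arange(10) * 0.1
    inten = np.zeros(10)
    inten[5] = 100.0
    assert find_peak(make_eic(rt, inten), 0.5, 1.0, min_consecutive_scans=3) is None
    inten[4] = inten[6] = 10.0
    assert find_peak(make_eic(rt, inten), 0.5, 1.0, min_consecutive_scans=3) is not None


# -- ppm_deviation ---------------------------------------------------------

@pytest.mark.parametrize("observed,target,expected", [
    (100.0010, 100.0000, 10.0),
    (123.456, 123.456, 0.0),
    # independent arithmetic: (204.9931 - 205.0972)/205.0972 * 1e6
    (204.9931, 205.0972, (204.9931 - 205.0972) / 205.0972 * 1e6),
])
def test_ppm_deviation_formula(observed, target, expected):
    assert ppm_deviation(observed, target) == pytest.approx(expected, abs=1e-9)
    assert ppm_deviation(204.9931, 205.0972) < 0


def test_ppm_deviation_rejects_nonpositive_target():
    with pytest.raises(InputError):
        ppm_deviation(100.0, 0.0)


# -- peak_shape ------------------------------------------------------------

def _dense_oracle(rt, inten):
    """Independent crossing-based shape factors on a dense grid."""
    apex = int(np.argmax(inten))
    t_apex, h = rt[apex], inten[apex]

    def crossing(level, side):
        i = apex
        while 0 <= i + side < len(inten):
            j = i + side
            if inten[j] <= level:
                frac = (inten[i] - level) / (inten[i] - inten[j])
                return rt[i] + frac * (rt[j] - rt[i])
            i = j
        return None

    l5, r5 = crossing(0.05 * h, -1), crossing(0.05 * h, +1)
    l10, r10 = crossing(0.10 * h, -1), crossing(0.10 * h, +1)
    return (r5 - l5) / (2 * (t_apex - l5)), (r10 - t_apex) / (t_apex - l10)


def test_symmetric_gaussian_has_unit_shape_factors():
    rt = np.linspace(0, 10, 4001)
    inten = np.exp(-0.5 * ((rt - 5.0) / 0.2) ** 2)
    shape = peak_shape(make_eic(rt, inten), int(np.argmax(inten)))
    assert shape.tailing_factor == pytest.approx(1.0, abs=0.02)
    assert shape.asymmetry_factor == pytest.approx(1.0, abs=0.02)


@pytest.mark.parametrize("tau", [0.02, 0.05, 0.1, 0.2])
def test_emg_shape_matches_dense_grid_oracle(tau):
    """Factors agree within 1% with an oracle built on scipy's EMG density."""
    sigma, mu = 0.1, 5.0
    rt = np.linspace(3, 9, 6001)
    inten = exponnorm.pdf(rt, K=tau / sigma, loc=mu, scale=sigma)
    shape = peak_shape(make_eic(rt, inten), int(np.argmax(inten)))
    dense_rt = np.linspace(3, 9, 10001)
    dense = exponnorm.pdf(dense_rt, K=tau / sigma, loc=mu, scale=sigma)
    t_ref, a_ref = _dense_oracle(dense_rt, dense)
    assert shape.tailing_factor == pytest.approx(t_ref, rel=0.01)
    assert shape.asymmetry_factor == pytest.approx(a_ref, rel=0.01)


def test_asymmetry_strictly_increases_with_emg_tau():
    sigma = 0.1
    rt = np.linspace(3, 9, 2401)
    values = []
    for tau in (0.02, 0.05, 0.1, 0.2):
        inten = exponnorm.pdf(rt, K=tau / sigma, loc=5.0, scale=sigma)
        values.append(peak_shape(make_eic(rt, inten),
                                 int(np.argmax(inten))).asymmetry_factor)
    assert all(b > a for a, b in zip(values, values[1:]))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(0.01, 0.15), st.integers(301, 900))
def test_mirrored_eic_has_reciprocal_asymmetry(tau, n_points):
    sigma = 0.1
    rt = np.linspace(3.0, 9.0, n_points)
    inten = exponnorm.pdf(rt, K=tau / sigma, loc=5.0, scale=sigma)
    fwd = peak_shape(make_eic(rt, inten), int(np.argmax(inten)))
    mirrored = inten[::-1].copy()
    rev = peak_shape(make_eic(rt, mirrored), int(np.argmax(mirrored)))
    assert rev.asymmetry_factor == pytest.approx(1.0 / fwd.asymmetry_factor,
                                                 rel=0.02)


def test_truncated_trailing_edge_reports_unbracketed_crossing():
    rt = np.linspace(4, 5.2, 200)
    inten = np.exp(-0.5 * ((rt - 5.0) / 0.2) ** 2)  # cut before 5% decay
    apex = int(np.argmax(inten))
    shape = peak_shape(make_eic(rt, inten), apex)
    assert shape.tailing_factor is None
    assert "unbracketed" in shape.reason or "boundary" in shape.reason


def test_apex_on_boundary_gives_null_metrics():
    shape = peak_shape(make_eic([0.0, 0.1], [5.0, 1.0]), 0)
    assert shape.tailing_factor is None and "boundary" in shape.reason


# -- track_file ------------------------------------------------------------

def _spectra_for(config, run_index):
    rt, mzs, ins = simulate_run_arrays(config, run_index)
    return [_spec(t, m, i) for t, m, i in zip(rt, mzs, ins)]


def test_injected_ppm_offset_is_recovered(batch):
    config = batch["config"]
    targets = [TrackedCompound(c.name, c.mz, c.rt) for c in config.compounds]
    params = TrackingParams(tol_ppm=50.0)
    for run_index, truth in enumerate(batch["manifest"]["runs"]):
        metrics = track_file(_spectra_for(config, run_index), None, targets, params)
        for m in metrics:
            assert m.found
            assert m.mz_dev_ppm == pytest.approx(truth["ppm_offset"], abs=1.0)
            assert abs(m.rt_dev - truth["rt_shift"]) <= config.scan_interval


def test_absent_target_yields_not_found_record(batch):
    config = batch["config"]
    spectra = _spectra_for(config, 0)
    ghost = TrackedCompound("ghost", 777.7777, 1.0)
    rec = track_file(spectra, None, [ghost], TrackingParams())[0]
    assert rec.found is False
    assert rec.mz_observed is None and rec.rt_dev is None


def test_integration_bounds_stop_at_floor_or_local_minimum():
    inten = np.array([0.0, 0.2, 5.0, 60.0, 100.0, 55.0, 8.0, 12.0, 3.0])
    eic = make_eic(np.arange(9) * 0.1, inten)
    lo, hi = integration_bounds(eic, 4, floor_frac=0.01)
    assert lo == 2   # 0.2 < 1% of 100
    assert hi == 6   # local minimum before the 12.0 rebound


def test_compound_scope_filtering():
    c = TrackedCompound("x", 100.0, 1.0, instrument="SYNAPT1", polarity="POS")
    assert c.in_scope("SYNAPT1", "POS")
    assert not c.in_scope("OTHER", "POS")
    assert TrackedCompound("y", 100.0, 1.0).in_scope("anything", "NEG")
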