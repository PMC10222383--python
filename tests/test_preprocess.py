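"""Preprocessing: R-peak detection, windowing, DFT oracle, featurization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecgverify as ev
from ecgverify.errors import InvalidArgumentError
from ecgverify.preprocess import REFRACTORY_S, zscore


def naive_dft(x):
    """O(N^2) double-loop forward transform — the independent oracle."""
    x = np.asarray(x, dtype=np.float64)
    N = x.size
    X = np.zeros(N, dtype=np.complex128)
    for k in range(N):
        for n in range(N):
            X[k] += x[n] * np.exp(-2j * np.pi * k * n / N)
    return X


# ------------------------------------------------------------- detector

def test_detector_finds_noiseless_beats_near_truth():
    from dataclasses import replace

    s = replace(
        ev.sample_subjects(1, seed=14)[0], noise_sd=0.0, baseline_amp=0.0,
        mean_rr=0.9,
    )
    rec = ev.synth_record(s, 10, fs=500, seed=3)
    peaks = ev.detect_r_peaks(rec)
    assert peaks.size == rec.r_peak_truth.size
    assert np.all(np.abs(peaks - rec.r_peak_truth) <= 3)


def test_detector_on_noisy_multisubject_records(small_cohort):
    for rec in small_cohort.records:
        peaks = ev.detect_r_peaks(rec)
        # at least 90% of true beats matched within 3 samples
        hits = sum(np.min(np.abs(peaks - t)) <= 3 for t in rec.r_peak_truth)
        assert hits >= 0.9 * rec.r_peak_truth.size
        gaps = np.diff(peaks)
        assert np.all(gaps >= REFRACTORY_S * rec.fs)


def test_detector_flat_signal_returns_empty():
    rec = ev.ECGRecord(np.zeros(1000) + 0.3, fs=500, subject_id="flat")
    assert ev.detect_r_peaks(rec).size == 0


def test_detector_rejects_subsecond_record():
    rec = ev.ECGRecord(np.sin(np.arange(100)), fs=500, subject_id="short")
    with pytest.raises(InvalidArgumentError):
        ev.detect_r_peaks(rec)


# ---------------------------------------------------------- segmentation

def test_segments_one_window_per_interior_beat():
    from dataclasses import replace

    s = replace(ev.sample_subjects(1, seed=5)[0], noise_sd=0.0)
    rec = ev.synth_record(s, 12, fs=500, seed=6)
    interior = [
        r for r in rec.r_peak_truth
        if r - 102 >= 0 and r - 102 + 256 <= rec.samples.size
    ]
    segs = ev.segment_record(rec, rec.r_peak_truth, 256)
    assert len(segs) == len(interior)
    for seg in segs:
        assert seg.L == 256
        assert seg.r_index == 102  # floor(0.4 * 256)
        assert abs(seg.values.mean()) < 1e-9
        assert abs(seg.values.std() - 1.0) < 1e-6


def test_boundary_windows_are_discarded():
    rec = ev.ECGRecord(
        np.sin(np.arange(600) / 10.0), fs=500, subject_id="edge"
    )
    segs = ev.segment_record(rec, np.array([10, 300]), 256)
    assert len(segs) == 1  # peak at 10 underflows the 102-sample pre-window


def test_segment_normalization_matches_arithmetic_oracle(rng):
    rec = ev.ECGRecord(rng.normal(size=2000), fs=500, subject_id="r")
    segs = ev.segment_record(rec, np.array([500]), 256)
    window = rec.samples[500 - 102 : 500 - 102 + 256]
    expected = (window - window.mean()) / window.std()
    np.testing.assert_allclose(segs[0].values, expected, rtol=1e-12)


def test_segment_rejects_bad_window_length():
    rec = ev.ECGRecord(np.ones(1000), fs=500, subject_id="x")
    for L in (31, 30, 255):
        with pytest.raises(InvalidArgumentError):
            ev.segment_record(rec, np.array([500]), L)


# ------------------------------------------------------------------ DFT

@pytest.mark.parametrize("N", [7, 8, 50, 200, 256])
def test_dft_matches_naive_oracle(N, rng):
    x = rng.normal(size=N)
    np.testing.assert_allclose(
        ev.dft(x), naive_dft(x), rtol=1e-9, atol=1e-9 * N
    )


def test_dft_constant_sequence_is_dc_only():
    c = 1.7
    X = ev.dft(np.full(8, c))
    assert abs(X[0] - 8 * c) < 1e-12 * 8 * c
    assert np.all(np.abs(X[1:]) < 1e-12 * 8 * c)


def test_dft_unit_impulse_is_flat():
    x = np.zeros(16)
    x[0] = 1.0
    np.testing.assert_allclose(ev.dft(x), np.ones(16), atol=1e-12)


def test_dft_rejects_nonfinite():
    with pytest.raises(InvalidArgumentError):
        ev.dft(np.array([1.0, np.nan]))
    with pytest.raises(InvalidArgumentError):
        ev.dft(np.array([]))


@given(st.integers(min_value=1, max_value=64), st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_idft_inverts_dft_at_any_length(N, seed):
    x = np.random.default_rng(seed).normal(size=N)
    np.testing.assert_allclose(ev.idft(ev.dft(x)), x, atol=1e-9)


def test_idft_roundtrip_odd_length(rng):
    x = rng.normal(size=33)
    np.testing.assert_allclose(ev.idft(ev.dft(x)), x, atol=1e-9)


def test_parseval_energy_conservation(rng):
    x = rng.normal(size=200)
    X = ev.dft(x)
    lhs = np.sum(np.abs(x) ** 2)
    rhs = np.sum(np.abs(X) ** 2) / x.size
    assert abs(lhs - rhs) < 1e-9 * lhs


# ------------------------------------------------------------- featurize

@pytest.mark.parametrize("L", [200, 256])
def test_featurize_shape_L_by_2(L, rng):
    seg = ev.Segment(
        values=zscore(rng.normal(size=L)), subject_id="s", r_index=L // 2
    )
    fm = ev.featurize(seg)
    assert fm.data.shape == (L, 2)
    np.testing.assert_array_equal(fm.data[:, 0], seg.values)
    assert np.all(np.isfinite(fm.data))


def test_featurize_spectrum_channel_has_conjugate_symmetry(rng):
    L = 64
    seg = ev.Segment(
        values=zscore(rng.normal(size=L)), subject_id="s", r_index=32
    )
    mag = np.abs(ev.dft(seg.values))
    for k in range(1, L):
        assert abs(mag[k] - mag[L - k]) < 1e-9


def test_featurize_is_pure_and_deterministic(rng):
    seg = ev.Segment(
        values=zscore(rng.normal(size=256)), subject_id="s", r_index=102
    )
    a = ev.featurize(seg)
    b = ev.featurize(seg)
    np.testing.assert_array_equal(a.data, b.data)


def test_end_to_end_preprocess_one_matrix_per_interior_beat():
    from dataclasses import replace

    s = replace(
        ev.sample_subjects(1, seed=20)[0], noise_sd=0.0, baseline_amp=0.0
    )
    rec = ev.synth_record(s, 15, fs=500, seed=21)
    fms = ev.preprocess_record(rec, 256)
    interior = [
        r for r in rec.r_peak_truth
        if r - 102 >= 0 and r - 102 + 256 <= rec.samples.size
    ]
    assert len(fms) == len(interior)
    assert all(fm.data.shape == (256, 2) for fm in fms)
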