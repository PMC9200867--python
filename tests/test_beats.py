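"""Peak detection, windowing, endpoint zeroing, QC and averaging."""

from dataclasses import replace

import numpy as np
import pytest

from vcgdi import (
    PRESETS,
    QCError,
    VCGSignal,
    average_beats,
    compute_speed,
    compute_voltage,
    detect_peaks,
    endpoint_correct,
    extract_windows,
    generate_record,
    kors_transform,
    qc_correlation,
)
from conftest import clean_params


def vcg_from_xyz(xyz, fs=1000.0):
    X, Y, Z = xyz
    return VCGSignal(X=X, Y=Y, Z=Z, voltage=compute_voltage(X, Y, Z),
                     speed=compute_speed(X, Y, Z, fs), sampling_rate=fs)


def pulse_train(centers_ms, amps, n=10_000, half=40):
    """Unimodal cos² bumps on X only."""
    t = np.arange(n, dtype=float)
    x = np.zeros(n)
    for c, a in zip(centers_ms, amps):
        m = np.abs(t - c) < half
        x[m] += a * np.cos(np.pi * (t[m] - c) / (2 * half)) ** 2
    return np.vstack([x, np.zeros(n), np.zeros(n)])


class TestDetectPeaks:
    def test_programmed_beats_found_within_5ms(self):
        rec, truth = generate_record(clean_params("normal"))
        vcg = kors_transform(rec)
        peaks = detect_peaks(vcg.voltage, 1000.0)
        programmed = truth["beat_times_ms"]
        # every programmed beat far enough from the edges must be found
        expect = programmed[(programmed >= 110) & (programmed < 9890)]
        assert len(peaks) == len(expect)
        assert np.all(np.abs(peaks - expect) <= 5)

    def test_sixty_bpm_yields_nine_to_ten_peaks(self):
        rec, _ = generate_record(clean_params("normal"))
        peaks = detect_peaks(kors_transform(rec).voltage, 1000.0)
        assert 9 <= len(peaks) <= 10

    def test_flat_signal_raises_qc_error(self):
        with pytest.raises(QCError):
            detect_peaks(np.zeros(5000), 1000.0)

    def test_refractory_rule_keeps_larger_of_close_pair(self):
        xyz = pulse_train([1000, 1250, 2000, 3000, 4000],
                          [1.0, 0.6, 1.0, 1.0, 1.0])
        peaks = detect_peaks(compute_voltage(*xyz), 1000.0,
                             min_separation_ms=300.0)
        assert 1000 in peaks and 1250 not in peaks

    def test_low_peaks_below_height_fraction_dropped(self):
        xyz = pulse_train([1000, 2000, 3000], [1.0, 0.3, 1.0])
        peaks = detect_peaks(compute_voltage(*xyz), 1000.0)
        assert list(peaks) == [1000, 3000]


class TestExtractWindows:
    def test_window_indices_and_length(self):
        xyz = pulse_train([2000, 5000], [1.0, 1.0])
        ens = extract_windows(vcg_from_xyz(xyz), np.array([2000, 5000]))
        assert ens.window_len == 221
        assert ens.peak_offset == 110
        # window of the second beat covers samples 4890..5110 inclusive
        src = xyz[0][4890:5111]
        corrected = endpoint_correct(src)
        assert np.allclose(ens.xyz[1, 0], corrected)

    def test_edge_peak_excluded(self):
        xyz = pulse_train([100, 3000, 6000], [1.0, 1.0, 1.0])
        ens = extract_windows(vcg_from_xyz(xyz), np.array([100, 3000, 6000]))
        assert ens.n_beats == 2

    def test_identical_beats_give_identical_windows(self):
        xyz = pulse_train([2000, 3000, 4000], [1.0, 1.0, 1.0])
        ens = extract_windows(vcg_from_xyz(xyz), np.array([2000, 3000, 4000]))
        assert np.allclose(ens.xyz[0], ens.xyz[1])
        assert np.allclose(ens.voltage[1], ens.voltage[2])

    def test_voltage_windows_are_endpoint_zero(self):
        rec, _ = generate_record(replace(clean_params("normal"), seed=7))
        vcg = kors_transform(rec)
        ens = extract_windows(vcg, detect_peaks(vcg.voltage, 1000.0))
        assert np.allclose(ens.voltage[:, 0], 0.0, atol=1e-12)
        assert np.allclose(ens.voltage[:, -1], 0.0, atol=1e-12)


class TestEndpointCorrect:
    def test_already_zero_unchanged(self, rng):
        w = rng.normal(size=(3, 51))
        w[:, 0] = 0.0
        w[:, -1] = 0.0
        assert np.allclose(endpoint_correct(w), w)

    def test_constant_offset_removed(self):
        w = np.full((3, 21), 0.3)
        assert np.allclose(endpoint_correct(w), 0.0)

    def test_linear_ramp_annihilated(self):
        w = np.vstack([np.linspace(-1, 2, 31)] * 3)
        assert np.allclose(endpoint_correct(w), 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        w = rng.normal(size=(3, 41))
        once = endpoint_correct(w)
        assert np.allclose(endpoint_correct(once), once)


class TestQcCorrelation:
    def _ensemble(self, windows):
        from vcgdi.beats import BeatEnsemble
        xyz = np.stack([np.vstack([w, np.zeros_like(w), np.zeros_like(w)])
                        for w in windows])
        return BeatEnsemble(xyz=xyz, voltage=np.abs(np.stack(windows)),
                            peak_indices=np.arange(len(windows)),
                            sampling_rate=1000.0)

    def test_identical_beats_pass_with_unit_correlation(self):
        w = np.hanning(221)
        qc = qc_correlation(self._ensemble([w, w, w]))
        assert qc.passed and qc.min_correlation == pytest.approx(1.0)

    def test_noise_beat_fails(self, rng):
        w = np.hanning(221)
        noise = rng.normal(0.0, w.std(), 221)
        qc = qc_correlation(self._ensemble([w, w, noise]))
        assert not qc.passed and qc.min_correlation < 0.9

    def test_threshold_is_inclusive(self, rng):
        w = np.hanning(221)
        ens = self._ensemble([w, w + rng.normal(0.0, 0.05, 221)])
        r = qc_correlation(ens).min_correlation
        assert qc_correlation(ens, threshold=r).passed  # r == threshold passes


class TestAverageBeats:
    def test_mean_of_identical_beats_is_any_member(self):
        xyz = pulse_train([2000, 3000, 4000], [1.0, 1.0, 1.0])
        ens = extract_windows(vcg_from_xyz(xyz), np.array([2000, 3000, 4000]))
        avg = average_beats(ens)
        assert np.allclose(avg.voltage, ens.voltage[0], atol=1e-12)
        assert avg.n_beats == 3

    def test_refuses_failed_qc(self, rng):
        xyz = pulse_train([2000, 3000], [1.0, 1.0])
        xyz[:, 2900:3100] += rng.normal(0.0, 0.5, (3, 200))
        ens = extract_windows(vcg_from_xyz(xyz), np.array([2000, 3000]))
        with pytest.raises(QCError):
            average_beats(ens)

    def test_opposite_x_cancels_in_average(self):
        n = 10_000
        x = pulse_train([2000], [1.0])[0] - pulse_train([5000], [1.0])[0]
        y = pulse_train([2000], [0.5])[0] + pulse_train([5000], [0.5])[0]
        xyz = np.vstack([x, y, np.zeros(n)])
        ens = extract_windows(vcg_from_xyz(xyz), np.array([2000, 5000]))
        avg = average_beats(ens, enforce_qc=False)
        assert np.allclose(avg.X, 0.0, atol=1e-12)
        assert np.max(avg.Y) > 0.4

    def test_averaging_suppresses_noise_like_sqrt_n(self, rng):
        n_beats, centers = 10, np.arange(1000, 10_000, 900)
        clean = pulse_train(centers, np.ones(n_beats))
        noisy = clean + rng.normal(0.0, 0.05, clean.shape)
        ens = extract_windows(vcg_from_xyz(noisy), centers)
        avg = average_beats(ens, enforce_qc=False)
        template = endpoint_correct(clean[:, centers[0] - 110:centers[0] + 111])
        tmpl_v = np.sqrt((template**2).sum(axis=0))
        err_avg = np.sqrt(np.mean((avg.voltage - tmpl_v) ** 2))
        err_single = np.sqrt(np.mean((ens.voltage[0] - tmpl_v) ** 2))
        assert err_avg < err_single / 2.0  # ~1/sqrt(10) in theory

    def test_average_voltage_recomputed_from_averaged_axes(self):
        # voltage of the mean, not mean of voltages: with cancelling X the
        # two differ and the implementation must give the former
        x = pulse_train([2000], [1.0])[0] - pulse_train([5000], [1.0])[0]
        xyz = np.vstack([x, np.zeros_like(x), np.zeros_like(x)])
        ens = extract_windows(vcg_from_xyz(xyz), np.array([2000, 5000]))
        avg = average_beats(ens, enforce_qc=False)
        mean_of_voltages = ens.voltage.mean(axis=0)
        assert np.allclose(avg.voltage, 0.0, atol=1e-12)
        assert np.max(mean_of_voltages) > 0.4
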