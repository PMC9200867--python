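"""Integrals, control line, dyssynchrony index, cutoff, TPS-SD."""

import numpy as np
import pytest

from vcgdi import (
    AverageBeat,
    ControlLine,
    ControlLineResults,
    ParameterError,
    StrainTable,
    YoudenCutoff,
    compute_integrals,
    compute_speed,
    compute_voltage,
    dyssynchrony_index,
    generate_control_points,
    generate_strain_table,
    simulate_vcg_beat,
    tps_sd,
)
from vcgdi.io import SEGMENT_18
from vcgdi.limits import DepolarizationSegment
from vcgdi.simulate import PRESETS, BeatTemplate


def beat_from_xyz(xyz, fs=1000.0):
    X, Y, Z = xyz
    return AverageBeat(X=X, Y=Y, Z=Z, voltage=compute_voltage(X, Y, Z),
                       speed=compute_speed(X, Y, Z, fs), n_beats=1,
                       sampling_rate=fs)


class TestComputeIntegrals:
    def test_rectangular_pulse_area(self):
        x = np.zeros(221)
        x[60:161] = 1.0  # 1 mV across 100 ms
        beat = beat_from_xyz(np.vstack([x, np.zeros(221), np.zeros(221)]))
        seg = DepolarizationSegment(onset_ms=60.0, offset_ms=160.0,
                                    threshold_mv=0.5)
        vti, _ = compute_integrals(beat, seg)
        assert vti == pytest.approx(100.0)

    def test_triangular_pulse_area(self):
        t = np.arange(221, dtype=float)
        x = np.clip(1.0 - np.abs(t - 110.0) / 50.0, 0.0, None)
        beat = beat_from_xyz(np.vstack([x, np.zeros(221), np.zeros(221)]))
        seg = DepolarizationSegment(onset_ms=60.0, offset_ms=160.0,
                                    threshold_mv=0.0)
        vti, _ = compute_integrals(beat, seg)
        assert vti == pytest.approx(50.0)

    def test_template_integrals_match_fine_quadrature(self):
        # sampled template integrated at 1 kHz vs the generator's 0.02-ms
        # quadrature of the closed-form loop
        for name in ("normal", "lbbb"):
            xyz, gt_vti, gt_sti = simulate_vcg_beat(PRESETS[name])
            beat = beat_from_xyz(xyz)
            thr, half = BeatTemplate(PRESETS[name]).analytic_limits()
            mid = 110.0
            seg = DepolarizationSegment(onset_ms=mid - half,
                                        offset_ms=mid + half,
                                        threshold_mv=thr)
            vti, sti = compute_integrals(beat, seg)
            assert vti == pytest.approx(gt_vti, rel=0.01)
            assert sti == pytest.approx(gt_sti, rel=0.01)

    def test_zero_length_segment_rejected(self):
        beat = beat_from_xyz(np.ones((3, 221)))
        with pytest.raises(ParameterError):
            compute_integrals(beat, DepolarizationSegment(50.0, 50.0, 0.1))


class TestControlLine:
    def test_three_collinear_points_exact(self):
        res = ControlLine([100.0, 200.0, 300.0],
                          [10_000.0, 20_000.0, 30_000.0]).fit()
        assert res.m_norm == pytest.approx(1.0)
        assert res.k_norm == pytest.approx(0.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope_raw == pytest.approx(100.0)

    def test_slope_raw_consistent_with_normalization(self):
        vti = np.array([30.0, 45.0, 60.0, 75.0])
        res = ControlLine(vti, 70.28 * vti).fit()
        assert res.m_norm == pytest.approx(0.7028, abs=1e-12)
        assert res.slope_raw == pytest.approx(70.28, abs=1e-9)

    def test_parameter_recovery_within_standard_error(self):
        # |error|/SE is pivotal (~|N(0,1)|): assert typical recovery via
        # the median over independent cohorts rather than one draw
        ratios = []
        for seed in range(11):
            vti, sti = generate_control_points(n=90, m_norm=0.7028,
                                               k_norm=0.0, seed=seed)
            res = ControlLine(vti, sti).fit()
            ratios.append(abs(res.m_norm - 0.7028) / res.m_se)
        assert np.median(ratios) <= 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            ControlLine([100.0, 100.0, 100.0], [1.0, 2.0, 3.0]).fit()
        with pytest.raises(ParameterError):
            ControlLine([1.0, 2.0], [1.0, 2.0]).fit()

    def test_json_round_trip(self, tmp_path):
        vti, sti = generate_control_points(seed=1)
        res = ControlLine(vti, sti).fit()
        res.to_json(tmp_path / "model.json")
        back = ControlLineResults.from_json(tmp_path / "model.json")
        assert back.m_norm == res.m_norm
        assert back.index(50.0, 4000.0) == res.index(50.0, 4000.0)


class TestDyssynchronyIndex:
    def test_point_on_line_is_zero(self):
        assert dyssynchrony_index(50.0, 0.7028 * 50.0 * 100.0,
                                  k_norm=0.0, m_norm=0.7028) \
            == pytest.approx(0.0, abs=1e-12)

    def test_unit_slope_closed_form(self):
        # k=0, m=1, point (1, 0) in normalized units -> 1/sqrt(2)
        idx = dyssynchrony_index(100.0, 0.0, k_norm=0.0, m_norm=1.0)
        assert idx == pytest.approx(0.7071068, abs=1e-7)

    def test_general_closed_form(self):
        # k=1, m=2, point (1, 0) -> 3/sqrt(5)
        idx = dyssynchrony_index(100.0, 0.0, k_norm=1.0, m_norm=2.0)
        assert idx == pytest.approx(1.3416408, abs=1e-7)

    def test_scale_invariance(self, rng):
        vti, sti = generate_control_points(n=40, seed=3)
        res = ControlLine(vti, sti).fit()
        res_scaled = ControlLine(vti * 3.7, sti * 3.7,
                                 norm_vti=100.0 * 3.7,
                                 norm_sti=10_000.0 * 3.7).fit()
        p = (55.0, 3000.0)
        assert res_scaled.index(p[0] * 3.7, p[1] * 3.7) \
            == pytest.approx(res.index(*p))

    def test_linear_growth_with_perpendicular_displacement(self):
        m, k = 0.7028, 0.1
        norm = np.sqrt(1 + m**2)
        for d in (0.1, 0.2, 0.5, 1.0):
            # displace a point on the line by d along the unit normal
            vti_n, sti_n = 0.5, k + m * 0.5
            vti = (vti_n - d * m / norm) * 100.0
            sti = (sti_n + d / norm) * 10_000.0
            assert dyssynchrony_index(vti, sti, k, m) == pytest.approx(d)


class TestYoudenCutoff:
    def test_separable_toy_example(self):
        res = YoudenCutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).fit()
        assert res.max_youden == pytest.approx(1.0)
        assert res.cutoff_lo == pytest.approx(0.2)
        assert res.cutoff_hi == pytest.approx(0.8)
        assert res.cutoff_mean == pytest.approx(0.5)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_cutoff_mean_is_midpoint(self, rng):
        idx = rng.normal(0.5, 0.3, 200)
        labels = (idx + rng.normal(0, 0.3, 200) > 0.6).astype(int)
        res = YoudenCutoff(idx, labels).fit()
        assert res.cutoff_mean == pytest.approx(
            (res.cutoff_lo + res.cutoff_hi) / 2)
        assert -1.0 <= res.max_youden <= 1.0

    def test_uninformative_index_gives_near_zero_youden(self, rng):
        idx = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        res = YoudenCutoff(idx, labels).fit()
        assert res.max_youden < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            YoudenCutoff([0.1, 0.2], [1, 1]).fit()

    def test_logistic_probability_is_monotone(self, rng):
        idx = np.r_[rng.normal(0.1, 0.1, 50), rng.normal(0.9, 0.1, 50)]
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        res = YoudenCutoff(idx, labels).fit()
        p = res.predict_proba([0.0, 0.5, 1.0])
        assert p[0] < p[1] < p[2]


class TestTpsSd:
    @staticmethod
    def _table_from_times(times_ms, dt=5.0, duration=600.0):
        t = np.arange(0.0, duration + dt / 2, dt)
        curves = np.empty((18, t.size))
        for j, tau in enumerate(times_ms):
            u = (t - tau) / (1.1 * duration)
            dip = np.where(np.abs(u) < 0.5, np.cos(np.pi * u) ** 2, 0.0)
            curves[j] = -17.0 * dip
        return StrainTable(SEGMENT_18, t, curves)

    def test_synchronous_segments_give_zero(self):
        table = self._table_from_times(np.full(18, 250.0))
        assert tps_sd(table).sd_ms == pytest.approx(0.0)

    def test_closed_form_sample_sd(self):
        times = np.tile([100.0, 120.0, 140.0], 6)
        result = tps_sd(self._table_from_times(times))
        # sample SD with n-1: sqrt(12*400/17)
        assert result.sd_ms == pytest.approx(np.sqrt(4800.0 / 17.0), abs=1e-9)

    def test_programmed_dispersion_recovered(self):
        table, taus = generate_strain_table(tps_sd_ms=60.0, seed=5)
        result = tps_sd(table)
        # exact against the programmed times (5-ms grid), and within
        # sampling error of the population value
        assert result.sd_ms == pytest.approx(np.std(taus, ddof=1), abs=4.0)
        assert abs(result.sd_ms - 60.0) <= 2 * 60.0 / np.sqrt(2 * 17)

    def test_flat_segment_named_in_error(self):
        table = self._table_from_times(np.full(18, 250.0))
        table.curves[4] = 0.0
        with pytest.raises(ParameterError, match=SEGMENT_18[4]):
            tps_sd(table)
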