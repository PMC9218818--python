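import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmscan.rhythm import (
    FAIL_AMPLITUDE,
    FAIL_CORRELATION,
    RhythmParams,
    absolute_change_criterion,
    best_phase_correlation,
    build_template_bank,
    circadian_time,
    classify_all,
    classify_gene,
    correlation_pvalue,
    critical_r,
    nearest_extremum_samples,
    predicted_fold_change,
)
from rhythmscan.simulate import SCHEDULES, SyntheticDatasetSpec, simulate_expression

from conftest import cosine_series

PARAMS = RhythmParams(abs_change_multiplier=0.0)
WHITE = SCHEDULES["white"]
RED = SCHEDULES["red"]


def dense_phase_argmax(series, times, period=24.0, grid_step=0.01):
    """Brute-force oracle: best phase over a dense phase grid."""
    phases = np.arange(0.0, period, grid_step)
    templates = np.cos(2 * np.pi * (np.asarray(times)[None, :] - phases[:, None]) / period)
    zs = (series - np.mean(series)) / np.std(series)
    zt = (templates - templates.mean(axis=1, keepdims=True)) / templates.std(axis=1, keepdims=True)
    r = zt @ zs / len(series)
    return phases[np.argmax(r)]


class TestCircadianTime:
    @pytest.mark.parametrize("t,expected", [(24, 0), (32, 8), (68, 20), (0, 0), (47.5, 23.5)])
    def test_values(self, t, expected):
        assert circadian_time(t) == expected


class TestTemplateBank:
    def test_shape(self):
        bank = build_template_bank(RED, PARAMS)
        assert bank.template_values.shape == (24, 4)
        assert len(bank.phases) == 24

    def test_peak_and_trough_values(self):
        bank = build_template_bank(RED, PARAMS)
        # phase-0 template peaks (mean + amplitude) at t = 24
        assert bank.template(0.0)[0] == pytest.approx(120.0)
        # phase-12 template is at its trough (mean - amplitude) at t = 24
        assert bank.template(12.0)[0] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_circadian_times(self):
        with pytest.raises(ValueError, match="distinct circadian times"):
            build_template_bank([24.0, 48.0, 36.0, 60.0], PARAMS)


class TestBestPhaseCorrelation:
    def test_exact_template_series(self):
        times = [0, 6, 12, 18]
        series = 100 + 20 * np.cos(2 * np.pi * (np.array(times, dtype=float) - 8) / 24)
        np.testing.assert_allclose(series, [90.0, 117.3205, 110.0, 82.6795], atol=1e-4)
        bank = build_template_bank(times, PARAMS)
        phase, r = best_phase_correlation(series, bank)
        assert phase == 8.0
        assert r == pytest.approx(1.0)

    def test_constant_series(self):
        bank = build_template_bank(RED, PARAMS)
        phase, r = best_phase_correlation([5.0, 5.0, 5.0, 5.0], bank)
        assert r == 0.0

    def test_scale_and_shift_invariance_of_r(self):
        rng = np.random.default_rng(0)
        series = rng.uniform(10, 100, size=12)
        bank = build_template_bank(WHITE, PARAMS)
        p1, r1 = best_phase_correlation(series, bank)
        p2, r2 = best_phase_correlation(3.7 * series + 55.0, bank)
        assert (p1, r1) == (p2, pytest.approx(r1))

    def test_template_constants_are_cosmetic(self):
        rng = np.random.default_rng(1)
        tiny = RhythmParams(abs_change_multiplier=0.0, template_mean=0.001,
                            template_amplitude=0.001)
        bank60 = build_template_bank(WHITE, PARAMS)
        bank_tiny = build_template_bank(WHITE, tiny)
        for _ in range(20):
            series = rng.uniform(1, 100, size=12)
            assert best_phase_correlation(series, bank60) == pytest.approx(
                best_phase_correlation(series, bank_tiny))

    @pytest.mark.parametrize("times", [WHITE, RED])
    def test_agrees_with_dense_grid_oracle(self, times):
        rng = np.random.default_rng(42)
        bank = build_template_bank(times, PARAMS)
        for _ in range(200):
            series = rng.uniform(1, 100, size=len(times))
            phase, _ = best_phase_correlation(series, bank)
            dense = dense_phase_argmax(series, times)
            d = abs(phase - dense) % 24
            assert min(d, 24 - d) <= PARAMS.phase_step_h + 0.01


class TestCorrelationPvalue:
    def test_zero_r(self):
        for n in (4, 12, 30):
            assert correlation_pvalue(0.0, n) == 1.0

    def test_perfect_fit(self):
        assert correlation_pvalue(1.0, 4) == 0.0
        assert correlation_pvalue(-1.0, 12) == 0.0

    def test_critical_values_against_tables(self):
        # two-tailed alpha = 0.01 critical r from standard tables
        assert critical_r(12, 0.01) == pytest.approx(0.708, abs=5e-4)
        assert critical_r(4, 0.01) == pytest.approx(0.990, abs=5e-4)

    def test_critical_r_is_the_p_boundary(self):
        for n in (4, 12):
            rc = critical_r(n, 0.01)
            assert correlation_pvalue(rc + 1e-6, n) < 0.01
            assert correlation_pvalue(rc - 1e-6, n) > 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 2)

    def test_monotone_in_r(self):
        ps = [correlation_pvalue(r, 12) for r in np.linspace(0, 0.999, 50)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestNearestExtremum:
    def test_tie_break_earliest(self):
        # trough target CT12 is equidistant from CT8 and CT16
        assert nearest_extremum_samples([0, 8, 16], 0.0) == (0, 1)

    def test_direct_circular_distance(self):
        assert nearest_extremum_samples([0, 6, 12, 18], 8.0) == (1, 3)

    def test_against_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            times = np.sort(rng.uniform(0, 72, size=rng.integers(3, 10)))
            times += np.arange(len(times)) * 1e-3  # enforce strict increase
            phase = float(rng.uniform(0, 24))
            ip, it = nearest_extremum_samples(times, phase)
            ct = times % 24.0
            for idx, target in ((ip, phase % 24), (it, (phase + 12) % 24)):
                d = np.abs(ct - target)
                d = np.minimum(d, 24 - d)
                assert d[idx] == pytest.approx(d.min())
                ties = np.flatnonzero(np.isclose(d, d.min()))
                assert times[idx] == times[ties].min()


class TestPredictedFoldChange:
    def test_boundary_ratio_passes_exactly(self):
        series = cosine_series(RED, phase=8, mean=100, ratio=1.5)
        pfc = predicted_fold_change(series, RED, 8.0, PARAMS)
        assert pfc == pytest.approx(1.5)

    def test_flat_series_fails(self):
        pfc = predicted_fold_change(np.full(4, 50.0), RED, 0.0, PARAMS)
        assert pfc < PARAMS.fold_threshold

    def test_hand_computed_example(self):
        times = [0, 8, 16, 24]
        series = [160.0, 100.0, 100.0, 160.0]
        assert predicted_fold_change(series, times, 0.0, PARAMS) == pytest.approx(1.8)

    def test_nonpositive_extremum(self):
        series = [0.0, 10.0, 10.0, 10.0]
        assert predicted_fold_change(series, RED, 0.0, PARAMS) == 0.0

    @pytest.mark.parametrize("times", [WHITE, RED, [24, 30, 40, 47, 55]])
    def test_monotone_boundary_noiseless(self, times):
        for phase in range(0, 24, 3):
            for ratio, expect_pass in [(1.2, False), (1.4, False), (1.5, True),
                                       (1.6, True), (3.0, True)]:
                series = cosine_series(times, phase=phase, mean=80, ratio=ratio)
                bank = build_template_bank(times, PARAMS)
                best, _ = best_phase_correlation(series, bank)
                pfc = predicted_fold_change(series, times, best, PARAMS)
                assert (pfc >= 1.5 - 1e-9) == expect_pass, (times, phase, ratio, pfc)


class TestAbsoluteChange:
    def test_zero_multiplier_always_true(self):
        assert absolute_change_criterion([1.0, 1.0], 100.0, PARAMS)

    def test_direct_arithmetic(self):
        p = RhythmParams(abs_change_multiplier=2.5)
        assert absolute_change_criterion([100.0, 400.0], 100.0, p)

    def test_literal_reading_fails(self):
        p = RhythmParams(abs_change_multiplier=250.0)
        assert not absolute_change_criterion([100.0, 400.0], 100.0, p)

    def test_units_mode(self):
        p = RhythmParams(abs_change_multiplier=0.0, abs_change_units=250.0)
        assert absolute_change_criterion([0.0, 260.0], 1.0, p)
        assert not absolute_change_criterion([0.0, 240.0], 1.0, p)


class TestClassifyGene:
    def test_noiseless_sine_rhythmic(self):
        series = cosine_series(WHITE, phase=8, mean=100, ratio=2)
        call = classify_gene(series, WHITE, 100.0, PARAMS)
        assert call.rhythmic and call.phase == 8.0 and call.failure_reason == "none"
        assert call.p_value == 0.0

    def test_low_amplitude_sine_fails_amplitude(self):
        series = cosine_series(WHITE, phase=5, mean=100, ratio=1.2)
        call = classify_gene(series, WHITE, 1e6,
                             RhythmParams(abs_change_multiplier=2.5))
        assert not call.rhythmic
        assert call.failure_reason == FAIL_AMPLITUDE
        assert call.r == pytest.approx(1.0)

    def test_constant_series_fails_correlation(self):
        call = classify_gene(np.full(12, 10.0), WHITE, 100.0, PARAMS)
        assert call.failure_reason == FAIL_CORRELATION
        assert call.r == 0.0 and call.p_value == 1.0

    def test_failure_reason_consistency_on_noise(self):
        # DERIVED: reasons recomputed independently from p/fc/abs fields
        rng = np.random.default_rng(99)
        params = RhythmParams(abs_change_multiplier=2.5)
        grand_mean = 50.0
        for _ in range(300):
            series = rng.uniform(10, 90, size=12)
            call = classify_gene(series, WHITE, grand_mean, params)
            sig = call.p_value < params.alpha
            amp = (call.predicted_fc >= params.fold_threshold
                   or call.abs_change >= params.abs_change_multiplier * grand_mean)
            assert call.rhythmic == (sig and amp)
            if not sig:
                assert call.failure_reason == FAIL_CORRELATION
            elif not amp:
                assert call.failure_reason == FAIL_AMPLITUDE
            else:
                assert call.failure_reason == "none"

    @given(shift=st.floats(min_value=1.0, max_value=1000.0),
           seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_additive_shift_changes_fc_not_r(self, shift, seed):
        rng = np.random.default_rng(seed)
        series = rng.uniform(10, 100, size=12)
        a = classify_gene(series, WHITE, 100.0, PARAMS)
        b = classify_gene(series + shift, WHITE, 100.0, PARAMS)
        assert a.r == pytest.approx(b.r, abs=1e-9)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-9)
        assert a.phase == b.phase


class TestClassifyAll:
    def test_noiseless_recovery(self):
        spec = SyntheticDatasetSpec(n_genes=100, seed=2, schedule="white",
                                    fraction_rhythmic=0.5, peak_trough_ratio=2.0)
        ds, truth = simulate_expression(spec)
        calls = classify_all(ds, ("synthetic", "WT"), PARAMS)
        assert int(calls["rhythmic"].sum()) == 50
        rhythmic = truth["rhythmic"]
        pd.testing.assert_series_equal(
            calls.loc[rhythmic[rhythmic].index, "phase"],
            truth.loc[rhythmic, "phase_h"],
            check_names=False,
        )

    def test_empty_rhythmic_set_is_valid(self):
        spec = SyntheticDatasetSpec(n_genes=20, seed=3, fraction_rhythmic=0.0,
                                    noise_sd_frac=0.0)
        ds, _ = simulate_expression(spec)
        calls = classify_all(ds, ("synthetic", "WT"), PARAMS)
        assert int(calls["rhythmic"].sum()) == 0

    def test_deterministic_across_runs(self):
        spec = SyntheticDatasetSpec(n_genes=50, seed=4, noise_sd_frac=0.3)
        ds, _ = simulate_expression(spec)
        c1 = classify_all(ds, ("synthetic", "WT"), PARAMS)
        c2 = classify_all(ds, ("synthetic", "WT"), PARAMS)
        pd.testing.assert_frame_equal(c1, c2)

    def test_unknown_group_rejected(self):
        spec = SyntheticDatasetSpec(n_genes=5, seed=5)
        ds, _ = simulate_expression(spec)
        with pytest.raises(KeyError):
            classify_all(ds, ("red", "fhy3"), PARAMS)
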