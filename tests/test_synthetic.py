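"""Synthetic episode generator: waveform shape, ground truth, determinism."""

import numpy as np
import pytest

from cprfb import (
    Cycle,
    EpisodeScenario,
    WaveformParams,
    annotate_windows,
    compression_displacement_waveform,
    depth_from_segment,
    generate_episode,
    oracle_double_integration,
    paper_like_scenario,
    process_episode,
)
from cprfb.synthetic import compression_intervals, window_ambiguity_mask


class TestWaveform:
    def test_excursion_bounds(self):
        params = WaveformParams(depth_mm=50.0, rate_cpm=110.0)
        t = np.linspace(0.0, 60.0 / 110.0, 5001)
        s = compression_displacement_waveform(params, t)
        assert s.min() == pytest.approx(-50.0, abs=1e-6)
        assert s.max() == pytest.approx(0.0, abs=1e-6)

    def test_leaning_raises_release_level(self):
        params = WaveformParams(depth_mm=50.0, rate_cpm=110.0, leaning_mm=5.0)
        t = np.linspace(0.0, 60.0 / 110.0, 5001)
        s = compression_displacement_waveform(params, t)
        assert s.max() == pytest.approx(-5.0, abs=1e-6)
        assert s.min() == pytest.approx(-50.0, abs=1e-6)

    def test_symmetric_duty_is_pure_cosine(self):
        # duty 0.5, no richness: s(t) = -D/2 (1 - cos(2πt/T)), a single tone
        params = WaveformParams(depth_mm=40.0, rate_cpm=120.0)
        t = np.arange(1000) / 250.0
        s = compression_displacement_waveform(params, t)
        expected = -20.0 * (1.0 - np.cos(2.0 * np.pi * 2.0 * t))
        np.testing.assert_allclose(s, expected, atol=1e-9)

    def test_richness_preserves_range(self):
        params = WaveformParams(
            depth_mm=45.0, rate_cpm=100.0, duty_cycle=0.4, harmonic_richness=0.5
        )
        t = np.linspace(0.0, 0.6, 20001)
        s = compression_displacement_waveform(params, t)
        assert s.min() == pytest.approx(-45.0, abs=1e-4)
        assert s.max() == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"depth_mm": -1.0, "rate_cpm": 100.0},
            {"depth_mm": 40.0, "rate_cpm": 20.0},
            {"depth_mm": 40.0, "rate_cpm": 100.0, "duty_cycle": 1.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WaveformParams(**kwargs)


class TestGenerateEpisode:
    def test_seeded_determinism_is_bitwise(self):
        scenario = paper_like_scenario(duration_s=30.0, seed=42)
        rec1, disp1, gold1 = generate_episode(scenario)
        rec2, disp2, gold2 = generate_episode(scenario)
        assert np.array_equal(rec1.samples, rec2.samples)
        assert np.array_equal(disp1.values, disp2.values)
        assert gold1 == gold2

    def test_different_seeds_differ(self):
        rec1, _, _ = generate_episode(paper_like_scenario(30.0, seed=1))
        rec2, _, _ = generate_episode(paper_like_scenario(30.0, seed=2))
        assert not np.array_equal(rec1.samples, rec2.samples)

    def test_displacement_acceleration_conservation(self):
        # noiseless: double-integrating the generated acceleration must give
        # back the reference displacement within 1 mm peak-to-peak per window
        # (rate 120 cpm -> 4 exact cycles per 2-s window, so each window is
        # periodic and the integration oracle applies)
        from cprfb.windowing import AnalysisWindow

        scenario = EpisodeScenario(
            duration_s=20.0,
            segments=(
                ("compressions", 20.0,
                 WaveformParams(depth_mm=45.0, rate_cpm=120.0, duty_cycle=0.45,
                                harmonic_richness=0.2)),
            ),
        )
        record, reference, _ = generate_episode(scenario)
        for k in range(10):
            sl = slice(k * 500, (k + 1) * 500)
            w = AnalysisWindow(k, k * 2.0, record.samples[sl], 250.0)
            ref_p2p = float(np.ptp(reference.values[sl]))
            oracle_p2p = depth_from_segment(oracle_double_integration(w))
            assert abs(oracle_p2p - ref_p2p) < 1.0

    def test_pause_windows_not_compression(self):
        scenario = EpisodeScenario(
            duration_s=30.0,
            segments=(
                ("compressions", 10.0, WaveformParams(depth_mm=40.0, rate_cpm=120.0)),
                ("pause", 10.0, None),
                ("compressions", 10.0, WaveformParams(depth_mm=40.0, rate_cpm=120.0)),
            ),
        )
        _, _, gold = generate_episode(scenario)
        # windows fully inside the 10-20 s pause
        for g in gold[5:10]:
            assert not g.is_compression
            assert g.gs_depth_mm is None and g.gs_rate_cpm is None

    def test_end_to_end_noiseless_recovery(self):
        scenario = EpisodeScenario(
            duration_s=60.0,
            segments=(
                ("compressions", 60.0,
                 WaveformParams(depth_mm=45.0, rate_cpm=105.0, duty_cycle=0.45,
                                harmonic_richness=0.2)),
            ),
        )
        record, _, gold = generate_episode(scenario)
        estimates, _ = process_episode(record)
        for est, g in zip(estimates, gold):
            assert est.detected and g.is_compression
            assert est.depth_mm == pytest.approx(g.gs_depth_mm, abs=1.0)
            assert est.rate_cpm == pytest.approx(g.gs_rate_cpm, abs=0.5)

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            EpisodeScenario(
                duration_s=30.0,
                segments=(("pause", 10.0, None),),
            )
        with pytest.raises(ValueError, match="kind"):
            EpisodeScenario(duration_s=10.0, segments=(("massage", 10.0, None),))

    def test_quantization_flag_changes_lsb_only(self):
        base = paper_like_scenario(20.0, seed=3)
        quant = EpisodeScenario(
            **{**base.__dict__, "quantize_16bit": True}
        )
        rec_b, _, _ = generate_episode(base)
        rec_q, _, _ = generate_episode(quant)
        assert np.max(np.abs(rec_b.samples - rec_q.samples)) < 2 * 78.4532 / 65536


class TestAnnotateWindows:
    def _cycle(self, trough, depth=40.0, rate=120.0):
        period = 60.0 / rate
        return Cycle(
            t_start=trough - period / 2.0,
            period_s=period,
            depth_mm=depth,
            trough_time=trough,
            nominal_rate_cpm=rate,
            nominal_depth_mm=depth,
        )

    def test_regular_cycles(self):
        cycles = [self._cycle(0.25 + 0.5 * k) for k in range(4)]
        gold = annotate_windows(cycles, [(0.0, 2.0)], 1, 2.0)
        assert gold[0].is_compression
        assert gold[0].gs_depth_mm == pytest.approx(40.0)
        assert gold[0].gs_rate_cpm == pytest.approx(120.0)

    def test_depth_is_mean_of_in_window_troughs(self):
        cycles = [
            self._cycle(0.4, depth=30.0),
            self._cycle(1.0, depth=40.0),
            self._cycle(1.6, depth=50.0),
        ]
        gold = annotate_windows(cycles, [(0.0, 2.0)], 1, 2.0)
        assert gold[0].gs_depth_mm == pytest.approx(40.0)

    def test_rate_from_inter_trough_intervals(self):
        cycles = [self._cycle(t, rate=100.0) for t in (0.3, 0.9, 1.5)]
        gold = annotate_windows(cycles, [(0.0, 2.0)], 1, 2.0)
        assert gold[0].gs_rate_cpm == pytest.approx(100.0)  # 60 / 0.6

    def test_single_trough_falls_back_to_nominal_rate(self):
        cycles = [self._cycle(1.0, rate=115.0)]
        gold = annotate_windows(cycles, [(0.0, 2.0)], 1, 2.0)
        assert gold[0].gs_rate_cpm == pytest.approx(115.0)


class TestScenarioRealism:
    def test_gold_distribution_medians(self):
        """Across many seeded episodes the per-window GS medians sit near
        adult OHCA values (≈42 mm depth, ≈110 cpm rate)."""
        depths, rates = [], []
        for seed in range(12):
            scenario = paper_like_scenario(duration_s=120.0, seed=seed)
            _, _, gold = generate_episode(scenario)
            depths += [g.gs_depth_mm for g in gold if g.gs_depth_mm is not None]
            rates += [g.gs_rate_cpm for g in gold if g.gs_rate_cpm is not None]
        assert len(depths) >= 500
        assert np.median(depths) == pytest.approx(41.6, abs=4.0)
        assert np.median(rates) == pytest.approx(110.3, abs=6.0)

    def test_ambiguity_mask_flags_transitions(self):
        intervals = [(0.0, 5.0)]  # transition inside window 2 (4-6 s)
        mask = window_ambiguity_mask(intervals, 4, 2.0)
        np.testing.assert_array_equal(mask, [True, True, False, True])

    def test_compression_intervals_from_scenario(self):
        scenario = EpisodeScenario(
            duration_s=30.0,
            segments=(
                ("compressions", 12.0, WaveformParams(depth_mm=40.0, rate_cpm=110.0)),
                ("hands_off", 8.0, None),
                ("compressions", 10.0, WaveformParams(depth_mm=40.0, rate_cpm=110.0)),
            ),
        )
        assert compression_intervals(scenario) == [(0.0, 12.0), (20.0, 30.0)]
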