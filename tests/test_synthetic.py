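"""Generator correctness: determinism, geometry, and ground-truth bookkeeping."""

import numpy as np
import pytest

from enskit.synthetic import (
    MotilitySpec,
    WaveSpec,
    generate_motility_video,
    generate_qc_table,
    generate_transit_profile,
    make_width_function,
)
from enskit.scqc import filter_cells

from conftest import FULL_LENGTH_WAVE, small_spec


def silhouette_from_truth(spec, truth, t_s):
    """Reconstruct the exact noiseless band mask for one frame."""
    cols = np.arange(spec.frame_width_px, dtype=float)
    h = np.round(truth.width_function(cols, t_s)).astype(int)
    center = spec.frame_height_px / 2.0
    top = np.round(center - h / 2.0).astype(int)
    rows = np.arange(spec.frame_height_px)[:, None]
    return (rows >= top[None, :]) & (rows < (top + h)[None, :])


class TestMotilityVideo:
    def test_no_dynamics_gives_static_full_width_band(self):
        spec = small_spec(wave_list=(), noise_sd=0.0, duration_s=2.0)
        frames, truth = generate_motility_video(spec)
        assert truth.n_events == 0
        assert all(np.array_equal(frames[0], f) for f in frames)
        heights = (frames[0] > 100).sum(axis=0)
        assert np.all(heights == spec.baseline_width_px)

    def test_ttx_mode_drops_neurogenic_waves_from_ground_truth(self):
        waves = tuple(
            WaveSpec(onset_s=t, origin_fraction=0.5, velocity_px_per_s=50.0,
                     amplitude_fraction=0.3)
            for t in (5.0, 10.0, 15.0)
        )
        spec = small_spec(wave_list=waves, neurogenic_enabled=False, noise_sd=0.0)
        frames, truth = generate_motility_video(spec)
        assert truth.events == ()
        assert all(np.array_equal(frames[0], f) for f in frames)

    def test_myogenic_wave_survives_ttx_mode(self):
        waves = (
            WaveSpec(onset_s=5.0, origin_fraction=0.5, velocity_px_per_s=50.0,
                     amplitude_fraction=0.3, neurogenic=True),
            WaveSpec(onset_s=15.0, origin_fraction=0.5, velocity_px_per_s=50.0,
                     amplitude_fraction=0.3, neurogenic=False),
        )
        _, truth = generate_motility_video(small_spec(wave_list=waves,
                                                      neurogenic_enabled=False))
        assert [w.neurogenic for w in truth.events] == [False]

    def test_protocol_duration_gives_18000_frames(self):
        assert MotilitySpec(duration_s=1200.0, frame_rate_fps=15.0).n_frames == 18000

    def test_seed_determinism_is_byte_identical(self):
        a, _ = generate_motility_video(small_spec(duration_s=3.0))
        b, _ = generate_motility_video(small_spec(duration_s=3.0))
        assert a.tobytes() == b.tobytes()

    def test_noise_free_band_heights_match_width_function(self, ):
        spec = small_spec(noise_sd=0.0, duration_s=6.0)
        frames, truth = generate_motility_video(spec)
        times = np.arange(spec.n_frames) / spec.frame_rate_fps
        cols = np.arange(spec.frame_width_px, dtype=float)
        for t_idx in (0, 40, 75, 89):
            expected = np.round(truth.width_function(cols, times[t_idx]))
            measured = (frames[t_idx] > 100).sum(axis=0)
            assert np.array_equal(measured, expected)

    def test_wave_outside_recording_excluded_from_ground_truth(self):
        far = WaveSpec(onset_s=500.0, origin_fraction=0.5, velocity_px_per_s=50.0,
                       amplitude_fraction=0.3, temporal_halfwidth_s=3.0)
        near_edge = WaveSpec(onset_s=28.0, origin_fraction=0.5, velocity_px_per_s=50.0,
                             amplitude_fraction=0.3, temporal_halfwidth_s=3.0)
        _, truth = generate_motility_video(small_spec(wave_list=(far, near_edge)))
        # 28 s onset overlaps the 24 s recording within 3 halfwidths; 500 s does not
        assert [w.onset_s for w in truth.events] == [28.0]

    def test_width_floor_prevents_vanishing_silhouette(self):
        deep = WaveSpec(onset_s=5.0, origin_fraction=0.5, velocity_px_per_s=30.0,
                        amplitude_fraction=0.95)
        spec = small_spec(wave_list=(deep, deep), noise_sd=0.0, duration_s=10.0)
        w = make_width_function(spec)
        vals = w(np.arange(200.0)[None, :], np.linspace(0, 10, 60)[:, None])
        assert vals.min() >= 0.2 * spec.baseline_width_px - 1e-12

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            small_spec(baseline_width_px=100.0)  # wider than the frame
        with pytest.raises(ValueError):
            small_spec(foreground_intensity=10.0)
        with pytest.raises(ValueError):
            WaveSpec(onset_s=0, origin_fraction=0.5, velocity_px_per_s=1.0,
                     amplitude_fraction=1.5)


class TestTransitGenerator:
    def test_point_mass_center(self):
        raw, gc = generate_transit_profile([(7.0, 0.0, 1.0)], noise_sd=0.0)
        assert gc == 7.0
        assert raw[6] > 0 and np.count_nonzero(raw) == 1

    def test_uniform_center_is_10(self):
        comps = [(float(i), 0.0, 1.0) for i in range(1, 20)]
        _, gc = generate_transit_profile(comps, noise_sd=0.0)
        assert gc == pytest.approx(10.0, abs=1e-12)

    def test_mixture_center_is_weighted_mean(self):
        comps = [(3.0, 0.0, 0.25), (15.0, 0.0, 0.75)]
        _, gc = generate_transit_profile(comps, noise_sd=0.0)
        assert gc == pytest.approx(0.25 * 3 + 0.75 * 15, abs=1e-12)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            generate_transit_profile([(5.0, 1.0, 0.0)])

    def test_noise_keeps_profile_nonnegative_and_seeded(self):
        a, _ = generate_transit_profile(noise_sd=200.0, seed=3)
        b, _ = generate_transit_profile(noise_sd=200.0, seed=3)
        assert np.array_equal(a, b)
        assert np.all(a >= 0)


class TestQCGenerator:
    def test_determinism(self):
        a = generate_qc_table(100, seed=5)
        b = generate_qc_table(100, seed=5)
        assert a.equals(b)

    def test_genes_never_exceed_umis(self):
        t = generate_qc_table(500, seed=1)
        assert (t["n_genes"] <= t["n_umis"]).all()
        assert t["pct_mito"].between(0, 100).all()

    def test_all_cells_inside_cutoffs_pass_filter(self):
        t = generate_qc_table(
            300, umi_mean=10_000, umi_sd=1_000, gene_fraction_mean=0.3,
            mito_mean_pct=3.0, mito_sd_pct=0.5, seed=2,
        )
        kept, _ = filter_cells(t)
        assert len(kept) == len(t)

    def test_mixture_pass_fraction_within_3_binomial_sd(self):
        # Half the cells are built to pass comfortably, half to fail on
        # mitochondrial content: the pass probability is 0.5 by construction.
        n = 2000
        good = generate_qc_table(n // 2, umi_mean=10_000, umi_sd=1_000,
                                 mito_mean_pct=3.0, mito_sd_pct=0.5, seed=11)
        bad = generate_qc_table(n // 2, umi_mean=10_000, umi_sd=1_000,
                                mito_mean_pct=60.0, mito_sd_pct=5.0, seed=12)
        import pandas as pd

        table = pd.concat([good, bad], ignore_index=True)
        kept, _ = filter_cells(table)
        p = 0.5
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(len(kept) / n - p) <= 3 * sd

    def test_gene_fraction_at_least_one_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            generate_qc_table(10, gene_fraction_mean=1.0)
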