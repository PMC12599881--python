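import numpy as np
import pytest

from axoshed import synthetic
from axoshed.config import ConfigurationError, SceneConfig


class TestTrajectories:
    def test_degenerate_fractions_all_stationary(self):
        cfg = SceneConfig(n_particles=50, state_fractions=(1, 0, 0), seed=1)
        parts = synthetic.simulate_trajectories(cfg)
        assert len(parts) == 50
        assert all(p.state == "stationary" for p in parts)

    def test_empirical_fractions_converge(self):
        # law of large numbers at n=4000: within +/-0.03 of the mixture
        cfg = SceneConfig(n_particles=4000, seed=11)
        parts = synthetic.simulate_trajectories(cfg)
        frac = {s: np.mean([p.state == s for p in parts])
                for s in synthetic.STATES}
        assert frac["stationary"] == pytest.approx(0.50, abs=0.03)
        assert frac["anterograde"] == pytest.approx(0.25, abs=0.03)
        assert frac["retrograde"] == pytest.approx(0.25, abs=0.03)

    def test_zero_sd_gives_exact_mean_speeds(self):
        cfg = SceneConfig(n_particles=200, speed_sd_um_s=0.0, seed=2)
        parts = synthetic.simulate_trajectories(cfg)
        for p in parts:
            if p.state == "anterograde":
                assert p.speed_um_s == pytest.approx(0.63)
            elif p.state == "retrograde":
                assert p.speed_um_s == pytest.approx(-0.78)

    def test_stationary_jitter_below_moving_boundary(self):
        cfg = SceneConfig(n_particles=300, state_fractions=(1, 0, 0), seed=3)
        span = (cfg.n_frames - 1) * cfg.frame_interval_s
        for p in synthetic.simulate_trajectories(cfg):
            net_v = abs(p.positions[-1] - p.positions[0]) / span
            assert net_v < 0.09

    def test_moving_speeds_clear_the_boundary_and_sign(self):
        cfg = SceneConfig(n_particles=400, seed=4)
        for p in synthetic.simulate_trajectories(cfg):
            if p.state == "anterograde":
                assert p.speed_um_s >= 0.1
            elif p.state == "retrograde":
                assert p.speed_um_s <= -0.1

    def test_positions_length_matches_frames(self, small_cfg):
        for p in synthetic.simulate_trajectories(small_cfg):
            assert len(p.positions) == small_cfg.n_frames


class TestRenderTimelapse:
    def test_static_spot_argmax_constant(self, one_particle_cfg):
        parts = synthetic.simulate_trajectories(one_particle_cfg)
        stack = synthetic.render_timelapse(parts, one_particle_cfg,
                                           noise=False)
        mito = stack.channel("mito")
        idx = [np.unravel_index(np.argmax(f), f.shape) for f in mito]
        assert len(set(idx)) == 1

    def test_moving_spot_advances_v_over_pixel_size(self):
        cfg = SceneConfig(
            n_particles=1, field_length_um=60.0, n_axons=1, n_frames=20,
            state_fractions=(0, 1, 0), speed_mean_antero_um_s=0.5,
            speed_sd_um_s=0.0, stationary_jitter_um=0.0,
            pixel_size_um=0.25,
            noise_model={"gaussian_sd": 0.0, "poisson_scale": 0.0}, seed=5)
        parts = synthetic.simulate_trajectories(cfg)
        stack = synthetic.render_timelapse(parts, cfg, noise=False)
        mito = stack.channel("mito")
        xs = [np.unravel_index(np.argmax(f), f.shape)[1] for f in mito]
        steps = np.diff(xs)
        assert np.isclose(np.mean(steps), 2.0, atol=0.1)  # 0.5 / 0.25

    def test_partner_channel_only_for_carriers(self, small_cfg):
        cfg = small_cfg.replace(coloc_coupling={
            "stationary": 0.0, "anterograde": 0.0, "retrograde": 0.0})
        parts = synthetic.simulate_trajectories(cfg)
        stack = synthetic.render_timelapse(parts, cfg, noise=False)
        assert stack.channel("optn").max() == 0

    def test_same_seed_bit_identical(self, small_cfg):
        parts = synthetic.simulate_trajectories(small_cfg)
        a = synthetic.render_timelapse(parts, small_cfg)
        b = synthetic.render_timelapse(parts, small_cfg)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_different_seed_differs(self, small_cfg):
        parts = synthetic.simulate_trajectories(small_cfg)
        a = synthetic.render_timelapse(parts, small_cfg)
        b = synthetic.render_timelapse(parts, small_cfg.replace(seed=99))
        assert not np.array_equal(a.intensities, b.intensities)


class TestDrift:
    def test_zero_drift_unchanged(self, one_particle_cfg):
        parts = synthetic.simulate_trajectories(one_particle_cfg)
        stack = synthetic.render_timelapse(parts, one_particle_cfg)
        out, shifts = synthetic.inject_drift(stack, (0.0, 0.0))
        np.testing.assert_array_equal(out.intensities, stack.intensities)
        assert np.all(shifts == 0)

    def test_integer_drift_is_row_translation(self, one_particle_cfg):
        parts = synthetic.simulate_trajectories(one_particle_cfg)
        stack = synthetic.render_timelapse(parts, one_particle_cfg,
                                           noise=False)
        out, _ = synthetic.inject_drift(stack, (1.0, 0.0), order=0)
        f0 = stack.channel("mito")[0]
        for t in range(1, 5):
            ft = out.channel("mito")[t]
            np.testing.assert_allclose(ft[t:], f0[:-t], atol=1e-5)

    def test_excessive_drift_rejected(self, one_particle_cfg):
        parts = synthetic.simulate_trajectories(one_particle_cfg)
        stack = synthetic.render_timelapse(parts, one_particle_cfg)
        ny = stack.intensities.shape[2]
        with pytest.raises(ValueError, match="25%"):
            synthetic.inject_drift(stack, (ny, 0.0))


@pytest.fixture(scope="module")
def particles():
    cfg = SceneConfig(n_particles=200, field_length_um=150, seed=8)
    return cfg, synthetic.simulate_trajectories(cfg)


class TestZstack:
    def test_outside_fraction_allocated_exactly(self, particles):
        cfg, parts = particles
        vol = synthetic.render_zstack(
            parts, cfg.replace(extra_axonal_fraction=0.25))
        frac = (~vol.blob_truth["inside_axon"]).mean()
        assert frac == pytest.approx(0.25, abs=0.03)

    def test_zero_outside_all_axonal(self, particles):
        cfg, parts = particles
        vol = synthetic.render_zstack(
            parts, cfg.replace(extra_axonal_fraction=0.0))
        assert (vol.blob_truth["compartment"] == "axon").all()

    def test_surface_share_one_puts_all_outside_on_surface(self, particles):
        cfg, parts = particles
        vol = synthetic.render_zstack(parts, cfg.replace(
            extra_axonal_fraction=0.2, surface_share_of_outside=1.0))
        outside = vol.blob_truth[~vol.blob_truth["inside_axon"]]
        assert (outside["compartment"] == "surface").all()

    def test_voxel_truth_labels_populated(self, particles):
        cfg, parts = particles
        vol = synthetic.render_zstack(parts, cfg)
        assert vol.voxel_truth is not None
        assert set(np.unique(vol.voxel_truth)) == {0, 1, 2, 3}

    def test_noiseless_blob_supra_voxels_match_truth_side(self, particles):
        # direct voxel-count oracle: supra-threshold voxels outside the true
        # tubes should match the constructed blob allocation
        cfg, parts = particles
        vol = synthetic.render_zstack(
            parts, cfg.replace(extra_axonal_fraction=0.25), noise=False)
        mito = vol.channel("mito")
        tube = vol.voxel_truth == 1
        sig = mito > 0.5 * mito.max()
        measured = (sig & ~tube).sum() / sig.sum()
        assert measured == pytest.approx(0.25, abs=0.04)


class TestProtrusionSeries:
    def test_invalid_schedule_rejected(self):
        with pytest.raises(ConfigurationError, match="interval"):
            synthetic.make_protrusion_series("loading", interval_s=45.0,
                                             duration_s=300.0)
        with pytest.raises(ConfigurationError, match="kind"):
            synthetic.make_protrusion_series("exploding")

    def test_swelling_distance_zero_throughout(self):
        _, _, truth = synthetic.make_protrusion_series("swelling")
        assert np.all(truth.distance_um == 0)

    def test_pinch_truth_distance_transitions(self):
        _, _, truth = synthetic.make_protrusion_series(
            "pinching_off", interval_s=30.0, duration_s=300.0, pinch_index=6)
        assert np.all(truth.distance_um[:7] == 0)
        assert np.all(truth.distance_um[7:] > 0)

    def test_loading_conserves_total_signal(self):
        # bud gain is drawn from the axon beneath: total integrated optn
        # signal is constant over the series
        vols, _, _ = synthetic.make_protrusion_series("loading")
        totals = [float(v.channel("optn").sum()) for v in vols]
        assert np.ptp(totals) / totals[0] < 0.01

    def test_two_minute_schedule_length(self):
        vols, masks, truth = synthetic.make_protrusion_series(
            "detached", interval_s=120.0, duration_s=600.0)
        assert len(vols) == len(masks) == 6
        assert truth.interval_s == 120.0


def test_sparse_axon_flags_validated():
    with pytest.raises(ConfigurationError):
        synthetic.make_sparse_axon_image(100, protrusion_x_um=[50],
                                         mito_flags=[])


def test_object_phantom_volumes():
    sph = synthetic.render_object_volume("sphere", 1.0, 0.05)
    v = sph.sum() * 0.05**3
    assert v == pytest.approx(4 / 3 * np.pi, rel=0.02)
    cap = synthetic.render_object_volume("capsule", 0.5, 0.05, length_um=2.0)
    v_cap = cap.sum() * 0.05**3
    expect = np.pi * 0.25 * 2.0 + 4 / 3 * np.pi * 0.125
    assert v_cap == pytest.approx(expect, rel=0.02)
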