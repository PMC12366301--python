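"""Ground-truthed scene generation: occupancy, growth model, rendering."""

import math

import numpy as np
import pytest

from dropgrowth import (
    GenerationError,
    GrowerParams,
    GrowthModelParams,
    OpticsParams,
    SyntheticDroplet,
    generate_scene,
    generate_series,
    render_scene,
    sample_diameters,
    sample_occupancy,
    simulate_growth,
    simulate_trajectories,
)
from dropgrowth.synthetic import _interior_radius


class TestSampleOccupancy:
    def test_zero_lambda_all_empty(self):
        assert (sample_occupancy(500, 0.0, seed=1) == 0).all()

    def test_sample_mean_near_lambda(self):
        n = 100_000
        counts = sample_occupancy(n, 0.11, seed=3)
        assert abs(counts.mean() - 0.11) < 3 * math.sqrt(0.11 / n)

    def test_deterministic_for_seed(self):
        a = sample_occupancy(1000, 0.11, seed=9)
        b = sample_occupancy(1000, 0.11, seed=9)
        assert (a == b).all()

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            sample_occupancy(10, -0.1, seed=0)


class TestSampleDiameters:
    def test_zero_cv_is_constant(self):
        d = sample_diameters(100, 55.0, 0.0, seed=0)
        assert (d == 55.0).all()

    def test_sample_cv_near_nominal(self):
        d = sample_diameters(1000, 55.0, 0.05, seed=5)
        cv = d.std(ddof=1) / d.mean()
        assert abs(cv - 0.05) < 0.01

    def test_all_positive_and_within_truncation(self):
        d = sample_diameters(5000, 10.0, 0.3, seed=2)
        assert (d > 0).all()
        assert (np.abs(d - 10.0) <= 4 * 3.0 + 1e-9).all()

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            sample_diameters(10, 55.0, -0.01, seed=0)


class TestGrowthModel:
    def test_empty_droplet_never_grows(self):
        frac, cls = simulate_growth(0, GrowthModelParams(), t=100.0, seed=1)
        assert frac == 0.0 and cls == "none"

    def test_saturates_at_capacity(self):
        params = GrowthModelParams(fast_fraction=1.0, jitter_sigma=0.0)
        frac, cls = simulate_growth(1, params, t=1000.0, seed=1)
        assert cls == "fast"
        assert frac == pytest.approx(params.fast.capacity, rel=1e-6)

    def test_matches_closed_form_logistic(self):
        """Jitter-free trajectory equals the lagged-logistic formula."""
        g = GrowerParams(lag=2.0, rate=0.8, capacity=0.5)
        params = GrowthModelParams(fast_fraction=1.0, fast=g, jitter_sigma=0.0)
        b0 = params.seed_fraction
        for t in (0.0, 2.0, 5.0, 10.0, 30.0):
            expected = (
                b0
                if t <= g.lag
                else g.capacity / (1 + ((g.capacity - b0) / b0) * math.exp(-g.rate * (t - g.lag)))
            )
            frac, _ = simulate_growth(1, params, t=t, seed=0)
            assert frac == pytest.approx(expected, abs=1e-12)

    def test_trajectory_consistent_with_pointwise(self):
        params = GrowthModelParams()
        traj, classes = simulate_trajectories([1, 0, 2], params, [0.0, 24.0], seed=11)
        for i, c in enumerate([1, 0, 2]):
            for j, t in enumerate([0.0, 24.0]):
                frac, cls = simulate_growth(c, params, t=t, seed=11, index=i)
                assert traj[i, j] == frac
                assert classes[i] == cls

    def test_slow_faster_rate_rejected(self):
        with pytest.raises(ValueError):
            GrowthModelParams(
                fast=GrowerParams(2.0, 0.1, 0.6), slow=GrowerParams(4.0, 0.5, 0.25)
            )


class TestRenderScene:
    def test_zero_droplets_is_noise_only(self):
        scene = render_scene([], (64, 64), seed=0)
        optics = OpticsParams()
        assert scene.image.shape == (64, 64)
        assert abs(scene.image.mean() / 255 - optics.background) < 0.01

    def test_ground_truth_record_count(self, dense_scene):
        assert len(dense_scene.droplets) == 12

    def test_out_of_bounds_rejected(self):
        d = SyntheticDroplet((5.0, 32.0), 20.0, 0, 0.0, "none")
        with pytest.raises(GenerationError):
            render_scene([d], (64, 64))

    def test_overlapping_rejected(self):
        a = SyntheticDroplet((32.0, 30.0), 12.0, 0, 0.0, "none")
        b = SyntheticDroplet((32.0, 40.0), 12.0, 0, 0.0, "none")
        with pytest.raises(GenerationError):
            render_scene([a, b], (64, 80))

    @pytest.mark.parametrize("style", ["dense", "clumps", "filaments"])
    def test_rendered_coverage_tracks_truth(self, style):
        """Dark pixels cover the requested biomass fraction within ±20% rel."""
        optics = OpticsParams(noise_sd=0.0)
        frac = 0.3
        d = SyntheticDroplet((60.0, 60.0), 50.0, 1, frac, "fast", style=style)
        scene = render_scene([d], (120, 120), optics=optics, seed=3)
        yy, xx = np.mgrid[0:120, 0:120]
        interior = np.hypot(yy - 60, xx - 60) <= _interior_radius(50.0, optics)
        # dark = below the midpoint between biomass and interior levels
        cut = 255 * (optics.biomass + optics.interior) / 2
        covered = (scene.image < cut) & interior
        rendered = covered.sum() / interior.sum()
        assert abs(rendered - frac) / frac <= 0.20

    def test_empty_droplet_truth_is_zero(self):
        with pytest.raises(ValueError):
            SyntheticDroplet((32.0, 32.0), 10.0, 0, 0.5, "none")


class TestSceneAssembly:
    def test_determinism_bit_identical(self):
        a = generate_scene(n_droplets=5, seed=21, shape=(400, 400), pixel_size=1.0)
        b = generate_scene(n_droplets=5, seed=21, shape=(400, 400), pixel_size=1.0)
        assert (a.image == b.image).all()
        assert a.droplets == b.droplets

    def test_droplets_inside_and_disjoint(self, dense_scene):
        h, w = dense_scene.image.shape
        ds = dense_scene.droplets
        for d in ds:
            assert d.radius < d.center[0] < h - d.radius
            assert d.radius < d.center[1] < w - d.radius
        for i, a in enumerate(ds):
            for b in ds[:i]:
                gap = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                assert gap >= a.radius + b.radius

    def test_cohort_identity_across_timepoints(self, two_timepoint_series):
        t0, t48 = two_timepoint_series
        for a, b in zip(t0.droplets, t48.droplets):
            assert a.center == b.center and a.radius == b.radius
            assert a.cell_count == b.cell_count and a.grower_class == b.grower_class
            assert b.true_biomass_fraction >= a.true_biomass_fraction

    def test_occupancy_realism_at_operating_lambda(self):
        """Empty ground-truth fraction within 3 SE of e^(−0.11)."""
        counts = []
        for s in range(30):
            scene = generate_scene(
                n_droplets=20, seed=800 + s, pixel_size=1.0, shape=(640, 640)
            )
            counts += [d.cell_count for d in scene.droplets]
        counts = np.array(counts)
        p = math.exp(-0.11)
        se = math.sqrt(p * (1 - p) / counts.size)
        assert abs(np.mean(counts == 0) - p) < 3 * se


def test_mixture_bimodality_upper_mode_mass():
    """Post-lag non-empty growth is bimodal with upper-mode mass ≈ fast_fraction."""
    params = GrowthModelParams()  # fast_fraction 0.5
    counts = sample_occupancy(4000, 0.11, seed=77)
    traj, classes = simulate_trajectories(counts, params, [24.0], seed=77)
    nonempty = traj[np.array(counts) > 0, 0]
    assert nonempty.size > 100
    # two-mode structure: a wide empty valley separates the modes
    log_v = np.sort(np.log10(nonempty))
    gaps = np.diff(log_v)
    split = log_v[np.argmax(gaps)]
    assert gaps.max() > 0.3  # clearly separated modes
    upper_mass = np.mean(np.log10(nonempty) > split)
    se = math.sqrt(0.5 * 0.5 / nonempty.size)
    assert abs(upper_mass - params.fast_fraction) <= 3 * se
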