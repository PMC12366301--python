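"""Day-0 threshold, normalized growth score, and distribution comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from dropgrowth import (
    ConfigurationError,
    GrowthModelParams,
    InsufficientDataError,
    NormalizationError,
    ThresholdUndefinedError,
    classify_droplets,
    compare_growth_distributions,
    compute_threshold,
    growth_curve,
    measure_population,
    normalized_growth_score,
    per_droplet_normalized,
    sample_occupancy,
    simulate_trajectories,
)
from dropgrowth import generate_series
from tests.conftest import gt_rois


class TestComputeThreshold:
    def test_hand_computed_example(self):
        """{0,0,0.01,0.03}: positives mean 0.02, SD 0.014142 → T = 0.048284."""
        t = compute_threshold([0.0, 0.0, 0.01, 0.03])
        assert t.day0_mean == pytest.approx(0.02)
        assert t.day0_sd == pytest.approx(0.014142, abs=1e-6)
        assert t.value == pytest.approx(0.048284, abs=1e-6)
        assert t.n_nonzero == 2

    def test_single_positive_sd_fallback(self):
        t = compute_threshold([0.05])
        assert t.value == 0.05
        assert t.day0_sd == 0.0

    def test_scale_equivariance(self):
        base = compute_threshold([0.0, 0.01, 0.03, 0.002])
        scaled = compute_threshold([0.0, 0.03, 0.09, 0.006])
        assert scaled.value == pytest.approx(3 * base.value, rel=1e-12)

    def test_all_zero_rejected_with_guidance(self):
        with pytest.raises(ThresholdUndefinedError, match="floor"):
            compute_threshold([0.0, 0.0])


class TestClassifyDroplets:
    def test_direct_comparison(self):
        parts = classify_droplets([0.01, 0.05, 0.5], 0.048)
        assert list(parts["above"]) == [0.05, 0.5]
        assert list(parts["below_or_equal"]) == [0.01]

    def test_tie_at_threshold_counts_as_not_grown(self):
        parts = classify_droplets([0.048, 0.049], 0.048)
        assert list(parts["above"]) == [0.049]

    def test_all_below_gives_empty_above(self):
        parts = classify_droplets([0.01, 0.02], 0.05)
        assert parts["above"].size == 0

    def test_order_invariant_partition(self):
        a = classify_droplets([0.1, 0.9, 0.3], 0.2)
        b = classify_droplets([0.9, 0.3, 0.1], 0.2)
        assert sorted(a["above"]) == sorted(b["above"])


class TestNormalizedGrowthScore:
    def test_hand_computed_example(self):
        """Above-threshold {0.2,0.3,0.5}: G_A=1/3, N=3, max=0.5 → score 2.0."""
        s = normalized_growth_score([0.2, 0.3, 0.5], 0.1)
        assert s.G_A == pytest.approx(1 / 3)
        assert s.N == 3
        assert s.G_A_Max == 0.5
        assert s.score == pytest.approx(2.0)

    def test_equal_values_score_equals_count(self):
        s = normalized_growth_score([0.4, 0.4, 0.4, 0.4], 0.1)
        assert s.score == pytest.approx(4.0)

    def test_scale_invariance(self):
        a = normalized_growth_score([0.2, 0.3, 0.5], 0.1)
        b = normalized_growth_score([0.02, 0.03, 0.05], 0.01)
        assert b.score == pytest.approx(a.score, rel=1e-12)

    def test_no_grown_droplets_scores_zero(self):
        s = normalized_growth_score([0.01, 0.02], 0.05)
        assert s.N == 0 and s.score == 0.0
        assert math.isnan(s.G_A) and math.isnan(s.G_A_Max)

    def test_score_doubles_when_droplets_duplicated(self):
        """Same mean and max, twice the count → twice the score."""
        vals = [0.2, 0.3, 0.5]
        s1 = normalized_growth_score(vals, 0.1)
        s2 = normalized_growth_score(vals * 2, 0.1)
        assert s2.score == pytest.approx(2 * s1.score, rel=1e-12)

    def test_series_scope_uses_global_max(self):
        s = normalized_growth_score([0.2, 0.3], 0.1, scope_values=[0.2, 0.3, 0.8])
        assert s.G_A_Max == 0.8
        assert s.scope == "series-global"


class TestPerDropletNormalized:
    def test_examples(self):
        assert list(per_droplet_normalized([0.5], 0.5)) == [1.0]
        assert list(per_droplet_normalized([0.1, 0.2], 0.5)) == pytest.approx([0.2, 0.4])

    def test_order_preserved(self):
        out = per_droplet_normalized([0.3, 0.1, 0.2], 0.5)
        assert list(out) == pytest.approx([0.6, 0.2, 0.4])

    def test_nonpositive_max_rejected(self):
        with pytest.raises(NormalizationError):
            per_droplet_normalized([0.1], 0.0)


class TestCompareGrowthDistributions:
    def test_identical_samples(self):
        u, p = compare_growth_distributions([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n²/2
        assert p > 0.9

    def test_fully_separated_exact_p(self):
        """{1,2,3} vs {4,5,6}: U=0, exact two-sided p = 2/C(6,3) = 0.1."""
        u, p = compare_growth_distributions([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.1], [2.0, 4.0, 5.5, 6.0]
        u_ab, p_ab = compare_growth_distributions(a, b)
        u_ba, p_ba = compare_growth_distributions(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba)

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_growth_distributions([], [1.0])

    def test_normal_approximation_tracks_exact_enumeration(self):
        """The asymptotic p is within 0.01 of exact for n between 5 and 15."""
        from dropgrowth.scoring import _asymptotic_mwu_pvalue

        rng = np.random.default_rng(12)
        worst = 0.0
        for _ in range(100):
            na, nb = rng.integers(5, 16, size=2)
            a = rng.normal(0, 1, na)
            b = rng.normal(rng.uniform(-1, 1), 1, nb)
            p_exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            u = float(mannwhitneyu(a, b, alternative="two-sided").statistic)
            worst = max(worst, abs(p_exact - _asymptotic_mwu_pvalue(u, a, b)))
        assert worst < 0.01


class TestGrowthCurve:
    @staticmethod
    def _series_df(seed=5, n=400, timepoints=(0.0, 24.0, 48.0, 72.0)):
        counts = sample_occupancy(n, 0.11, seed=seed)
        traj, _ = simulate_trajectories(counts, GrowthModelParams(), timepoints, seed=seed)
        rows = [
            {"timepoint": t, "growth_value": traj[i, j]}
            for j, t in enumerate(timepoints)
            for i in range(n)
        ]
        return pd.DataFrame(rows)

    def test_scores_nondecreasing_through_saturation(self):
        df = self._series_df()
        curve = growth_curve(df)
        assert list(curve.timepoint) == [0.0, 24.0, 48.0, 72.0]
        scores = curve.score.to_numpy()
        assert (np.diff(scores) >= -1e-12).all()
        assert scores[-1] > scores[0]

    def test_day0_threshold_marks_almost_nothing_on_day0(self):
        """The 2-SD rule leaves the day-0 sample itself near N=0."""
        df = self._series_df()
        curve = growth_curve(df)
        n0 = curve.loc[curve.timepoint == 0.0, "N"].iloc[0]
        n_pos = (df.loc[df.timepoint == 0.0, "growth_value"] > 0).sum()
        assert n0 <= 0.05 * max(n_pos, 1)

    def test_scopes_agree_at_global_max_timepoint(self):
        df = self._series_df()
        glob = growth_curve(df, scope="series-global")
        per = growth_curve(df, scope="per-timepoint")
        idx = df.groupby("timepoint")["growth_value"].max().idxmax()
        g = glob.loc[glob.timepoint == idx, "score"].iloc[0]
        p = per.loc[per.timepoint == idx, "score"].iloc[0]
        assert g == pytest.approx(p, rel=1e-12)

    def test_missing_day0_rejected(self):
        df = self._series_df(timepoints=(24.0, 48.0))
        with pytest.raises(ConfigurationError):
            growth_curve(df)

    def test_single_timepoint_rejected(self):
        df = self._series_df(timepoints=(0.0,))
        with pytest.raises(ConfigurationError):
            growth_curve(df)


def test_threshold_false_positive_rate_on_measured_day0_populations():
    """Re-applying a day-0 threshold to its own values marks ≤5% as grown.

    Populations are measured (rendered + segmented) day-0 droplet scenes, so
    the positive values carry realistic segmentation noise; the rate is
    aggregated over 50 seeded populations.
    """
    flagged = positives = 0
    for s in range(50):
        scene = generate_series(
            n_droplets=10, seed=9000 + s, timepoints=[0.0], lambda_=2.0,
            pixel_size=1.0, shape=(448, 448),
        )[0]
        df = measure_population([(scene.image, gt_rois(scene, "img"), "img", 0.0)])
        vals = df.growth_value.to_numpy()
        if (vals > 0).sum() == 0:
            continue
        thr = compute_threshold(vals)
        pos = vals[vals > 0]
        positives += pos.size
        flagged += (pos > thr.value).sum()
    assert positives > 100
    assert flagged / positives <= 0.05


def test_two_timepoint_significance_matches_reported_contrast():
    """Day 0 vs post-saturation non-empty droplets separate at p < 1e-4.

    Mirrors the incubation contrast on ground-truth trajectories: in ≥95% of
    20 seeded replicates the two-sided Mann-Whitney p-value for non-empty
    growth values is below 1e-4.
    """
    hits = 0
    for rep in range(20):
        counts = sample_occupancy(600, 0.11, seed=4000 + rep)
        traj, _ = simulate_trajectories(
            counts, GrowthModelParams(), [0.0, 48.0], seed=4000 + rep
        )
        day0 = traj[:, 0]
        day2 = traj[:, 1]
        thr = compute_threshold(day0)
        nonempty0 = day0[day0 > 0]
        nonempty2 = day2[classify_droplets(day2, thr)["above_mask"]]
        _, p = compare_growth_distributions(nonempty0, nonempty2)
        if p < 1e-4:
            hits += 1
    assert hits >= 19  # ≥95% of replicates
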