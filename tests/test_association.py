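"""Binary association, profiling, smoothing, correlation, sign calls."""

import numpy as np
import pytest

from solscore.association import (
    CATEGORIES,
    ProfileBin,
    CategoryProfile,
    binary_association,
    correlate_profile,
    profile_feature,
    sign_from_binary,
    sign_from_profile,
    smooth_profile,
)


def make_profile(xs, pct_a, counts=None, kind="continuous"):
    """Profile with A percentages as given; C takes the complement, N = 0."""
    bins = []
    counts = counts or [30] * len(xs)
    for x, pa, cnt in zip(xs, pct_a, counts):
        bins.append(
            ProfileBin(
                label=str(x),
                representative=float(x),
                count=cnt,
                percentages={"A": float(pa), "C": 100.0 - float(pa), "N": 0.0},
            )
        )
    return CategoryProfile(
        feature="f", kind=kind, bins=tuple(bins), usable=len(bins) >= 3
    )


class TestBinaryAssociation:
    def test_feature_identical_to_category_indicator(self):
        cats = np.array(["A"] * 10 + ["C"] * 10 + ["N"] * 10)
        present = cats == "A"
        results = binary_association(cats, present)
        a_table = results["A"].table
        assert a_table == (10, 0, 0, 20)  # diagonal concentration
        # minimal attainable p over these margins: all other tables with
        # the same margins are strictly more probable
        assert results["A"].p < 1e-4
        assert results["A"].direction == 1

    def test_constant_feature_is_nd(self):
        cats = np.array(["A", "C", "N", "A"])
        results = binary_association(cats, np.ones(4, dtype=bool))
        assert all(results[c].nd for c in CATEGORIES)
        assert sign_from_binary(results) == {c: "ND" for c in CATEGORIES}

    def test_tables_share_grand_total(self):
        rng = np.random.default_rng(5)
        cats = rng.choice(list("ACN"), size=200)
        present = rng.random(200) < 0.4
        results = binary_association(cats, present)
        totals = {sum(results[c].table) for c in CATEGORIES}
        assert totals == {200}

    def test_null_false_positive_rate_near_alpha(self):
        # independent feature: significance should fire at roughly alpha
        rng = np.random.default_rng(99)
        n_reps, hits, tests = 120, 0, 0
        for _ in range(n_reps):
            cats = rng.choice(list("ACN"), size=400, p=[0.26, 0.37, 0.37])
            present = rng.random(400) < 0.3
            results = binary_association(cats, present, alpha=0.05)
            for c in CATEGORIES:
                tests += 1
                hits += results[c].significant
        rate = hits / tests
        assert rate < 0.11  # loose 3-sigma-ish sanity bound around 0.05


class TestProfileFeature:
    def test_constant_feature_single_bin_nd(self):
        cats = np.array(["A"] * 30 + ["C"] * 30)
        profile = profile_feature(cats, np.ones(60), "continuous")
        assert len(profile.bins) == 1
        assert not profile.usable

    def test_discrete_merge_rule(self):
        # values {0: 50, 1: 50, 2: 5} with min_bin 20 -> bins {0}, {1,2}
        values = np.array([0] * 50 + [1] * 50 + [2] * 5, dtype=float)
        cats = np.array(["A", "C", "N"] * 35)
        profile = profile_feature(cats, values, "discrete", min_bin=20)
        assert [b.label for b in profile.bins] == ["0", "1-2"]
        assert [b.count for b in profile.bins] == [50, 55]

    def test_percentages_partition(self):
        rng = np.random.default_rng(3)
        cats = rng.choice(list("ACN"), size=500)
        values = rng.normal(size=500)
        profile = profile_feature(cats, values, "continuous")
        for b in profile.bins:
            assert sum(b.percentages.values()) == pytest.approx(100.0, abs=1e-6)
        assert profile.counts.sum() == 500

    def test_nan_values_excluded_and_counted(self):
        rng = np.random.default_rng(4)
        cats = rng.choice(list("ACN"), size=200)
        values = rng.normal(size=200)
        values[:25] = np.nan
        profile = profile_feature(cats, values, "continuous")
        assert profile.n_excluded == 25
        assert profile.counts.sum() == 175


class TestSmoothProfile:
    def test_window_one_is_identity(self):
        profile = make_profile([1, 2, 3], [10, 50, 90])
        assert smooth_profile(profile, 1) is profile

    def test_constant_curve_is_fixed_point(self):
        profile = make_profile([1, 2, 3, 4], [40, 40, 40, 40])
        smoothed = smooth_profile(profile, 3)
        assert np.allclose(smoothed.percentages("A"), 40.0)

    def test_edge_shrinking_hand_example(self):
        profile = make_profile([1, 2, 3], [0, 100, 0])
        smoothed = smooth_profile(profile, 3)
        assert np.allclose(
            smoothed.percentages("A"), [50.0, 100 / 3, 50.0]
        )

    def test_partition_preserved(self):
        rng = np.random.default_rng(8)
        pct = rng.uniform(0, 100, size=7)
        profile = make_profile(range(7), pct)
        smoothed = smooth_profile(profile, 5)
        for b in smoothed.bins:
            assert sum(b.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(make_profile([1, 2, 3], [1, 2, 3]), 4)


class TestCorrelateProfile:
    def test_perfect_linear_increase(self):
        profile = make_profile(range(5), [10, 20, 30, 40, 50])
        results = correlate_profile(profile)
        assert results["A"].r == pytest.approx(1.0)
        assert results["A"].p_one_tailed == pytest.approx(0.0, abs=1e-9)

    def test_mirror_categories_have_opposite_r(self):
        pct_a = [12, 25, 33, 47, 58, 71]
        profile = make_profile(range(6), pct_a)
        results = correlate_profile(profile)
        assert results["A"].r == pytest.approx(-results["C"].r)

    def test_null_r_gives_half(self):
        # zig-zag with zero net correlation
        profile = make_profile([0, 1, 2, 3], [40, 60, 40, 60])
        # x symmetric, y anti-symmetric halves -> r = 0.447...; build a true
        # zero-r case instead
        profile = make_profile([-1, 0, 1], [50, 70, 50])
        results = correlate_profile(profile)
        assert results["A"].r == pytest.approx(0.0, abs=1e-12)
        assert results["A"].p_one_tailed == pytest.approx(0.5)

    def test_unusable_profile_is_nd(self):
        profile = make_profile([1, 2], [10, 20])
        results = correlate_profile(profile)
        assert all(results[c].nd for c in CATEGORIES)

    def test_affine_rescaling_leaves_r_unchanged(self):
        pct = [15, 22, 41, 48, 63]
        p1 = make_profile([0, 1, 2, 3, 4], pct)
        p2 = make_profile([10, 30, 50, 70, 90], pct)  # x -> 20x + 10
        r1 = correlate_profile(p1)["A"].r
        r2 = correlate_profile(p2)["A"].r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestSignCall:
    def test_significant_positive(self):
        profile = make_profile(range(8), np.linspace(5, 75, 8))
        assert sign_from_profile(profile)["A"] == "+"
        assert sign_from_profile(profile)["C"] == "-"

    def test_insignificant_is_nd(self):
        rng = np.random.default_rng(12)
        profile = make_profile(range(8), 40 + rng.normal(0, 2, 8))
        signs = sign_from_profile(profile)
        assert signs["A"] in ("ND", "+", "-")  # weak noise: usually ND
        flat = make_profile(range(8), [40, 41, 40, 41, 40, 41, 40, 41])
        assert sign_from_profile(flat)["A"] == "ND"

    def test_v_shape_triggers_plus_minus(self):
        xs = range(9)
        pct_a = [80, 60, 40, 20, 5, 20, 40, 60, 80]
        profile = make_profile(xs, pct_a)
        assert sign_from_profile(profile)["A"] == "+/-"

    def test_n_constant_is_nd(self):
        profile = make_profile(range(6), [10, 20, 30, 40, 50, 60])
        assert sign_from_profile(profile)["N"] == "ND"  # zero variance
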