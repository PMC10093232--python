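import itertools
import math

import numpy as np
import pytest
from scipy import stats

from eccdiff import filtermerge, lengthstats
from eccdiff.model import CircleCall, CircleCatalog, EccdiffError


def enumeration_oracle(x, y, alternative):
    """Independent exact rank-sum p by direct enumeration."""
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)]
    ge = sum(1 for w in ws if w >= w_obs - 1e-9) / len(ws)
    le = sum(1 for w in ws if w <= w_obs + 1e-9) / len(ws)
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2 * min(ge, le))


class TestCountUnique:
    def test_distinct(self):
        cat = CircleCatalog("s", "HC", [CircleCall("chr1", i, i + 100, 2) for i in (0, 200, 400)])
        assert lengthstats.count_unique(cat) == 3

    def test_empty(self):
        assert lengthstats.count_unique(CircleCatalog("s", "HC", [])) == 0

    def test_toy_catalog_full_chain(self, toy_catalog, params):
        filtered, _ = filtermerge.run_filter_chain(toy_catalog, params)
        assert lengthstats.count_unique(filtered) == 4


class TestExactRankSum:
    def test_complete_separation_6v4_one_sided(self):
        control = [109, 300, 500, 700, 900, 1095]
        case = [1401, 5000, 20_000, 47_738]
        p = lengthstats.exact_rank_sum_test(case, control, alternative="greater")
        assert p == pytest.approx(1 / math.comb(10, 4))
        assert round(p, 5) == 0.00476

    def test_identical_singletons_two_sided_p1(self):
        assert lengthstats.exact_rank_sum_test([5], [5]) == 1.0

    @pytest.mark.parametrize("seed", range(100))
    def test_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        # integer values induce ties
        x = rng.integers(0, 6, n1).tolist()
        y = rng.integers(0, 6, n2).tolist()
        for alt in ("greater", "less", "two-sided"):
            assert lengthstats.exact_rank_sum_test(x, y, alt) == pytest.approx(
                enumeration_oracle(x, y, alt)
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy_exact_when_tie_free(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5).tolist()
        y = rng.normal(size=5).tolist()
        for alt in ("greater", "less", "two-sided"):
            expected = stats.mannwhitneyu(x, y, alternative=alt, method="exact").pvalue
            assert lengthstats.exact_rank_sum_test(x, y, alt) == pytest.approx(float(expected))

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1, 1, 20).tolist()
        y = rng.normal(0, 1, 20).tolist()
        p = lengthstats.exact_rank_sum_test(x, y, "greater")
        expected = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
        assert p == pytest.approx(float(expected))


class TestCompareGroupCounts:
    def _counts(self):
        control = {"h1": 109, "h2": 1095, "h3": 527, "h4": 527, "h5": 527, "h6": 527}
        case = {"c1": 1401, "c2": 47_738, "c3": 9854, "c4": 9855}
        groups = {**{k: "HC" for k in control}, **{k: "SLE" for k in case}}
        return {**control, **case}, groups

    def test_printed_p_and_fold(self):
        counts, groups = self._counts()
        comp = lengthstats.compare_group_counts(counts, groups, "SLE", "HC")
        assert comp.p_one_sided == pytest.approx(1 / 210)
        assert comp.mu["HC"] == pytest.approx(552)
        assert comp.mu["SLE"] == pytest.approx(17_212)
        assert round(comp.fold_ratio, 4) == 0.0321

    def test_label_symmetry(self):
        counts, groups = self._counts()
        a = lengthstats.compare_group_counts(counts, groups, "SLE", "HC")
        b = lengthstats.compare_group_counts(counts, groups, "HC", "SLE")
        assert a.p_two_sided == pytest.approx(b.p_two_sided)
        assert a.fold_ratio == pytest.approx(1 / b.fold_ratio)

    def test_sem(self):
        counts, groups = self._counts()
        comp = lengthstats.compare_group_counts(counts, groups, "SLE", "HC")
        control = [109, 1095, 527, 527, 527, 527]
        assert comp.sem["HC"] == pytest.approx(np.std(control, ddof=1) / np.sqrt(6))

    def test_needs_two_per_group(self):
        with pytest.raises(EccdiffError):
            lengthstats.compare_group_counts(
                {"a": 1, "b": 2, "c": 3}, {"a": "X", "b": "Y", "c": "Y"}, "X", "Y"
            )


def _catalog_from_lengths(sample_id, group, lengths):
    calls = [
        CircleCall("chr1", 10_000 * i, 10_000 * i + int(l), 2)
        for i, l in enumerate(lengths)
    ]
    return CircleCatalog(sample_id, group, calls)


class TestLengthDensity:
    def test_single_length_single_maximum(self):
        cats = {"s1": _catalog_from_lengths("s1", "HC", [300] * 20)}
        summary = lengthstats.length_density(cats, {"s1": "HC"}, bandwidth=10,
                                             length_range=(0, 600))
        assert list(summary.peaks["HC"]) == [300]

    def test_two_component_mixture_two_maxima(self):
        rng = np.random.default_rng(0)
        lengths = np.concatenate(
            [rng.normal(200, 15, 400), rng.normal(350, 15, 400)]
        ).round().astype(int)
        cats = {"s1": _catalog_from_lengths("s1", "HC", lengths)}
        summary = lengthstats.length_density(cats, {"s1": "HC"}, bandwidth=10,
                                             length_range=(100, 500))
        peaks = summary.peaks["HC"]
        assert len(peaks) == 2
        assert abs(peaks[0] - 200) <= 5 and abs(peaks[1] - 350) <= 5

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        cats = {
            "s1": _catalog_from_lengths("s1", "HC", rng.integers(100, 900, 100)),
            "s2": _catalog_from_lengths("s2", "SLE", rng.integers(100, 900, 100)),
        }
        summary = lengthstats.length_density(cats, {"s1": "HC", "s2": "SLE"})
        for g in ("HC", "SLE"):
            area = np.trapezoid(summary.density[g], summary.grid)
            assert area == pytest.approx(1.0, abs=1e-6)
            assert (summary.density[g] >= 0).all()

    def test_empty_group_flagged(self):
        cats = {
            "s1": _catalog_from_lengths("s1", "HC", [300]),
            "s2": _catalog_from_lengths("s2", "SLE", [5000]),
        }
        with pytest.warns(UserWarning, match="no circles"):
            summary = lengthstats.length_density(
                cats, {"s1": "HC", "s2": "SLE"}, length_range=(0, 1000)
            )
        assert summary.empty_groups == ["SLE"]
        assert summary.density["SLE"].size == 0

    def test_bad_bandwidth(self):
        with pytest.raises(EccdiffError):
            lengthstats.length_density({}, {}, bandwidth=0)


class TestCumulativeCurve:
    def test_thirds(self):
        cat = _catalog_from_lengths("s", "HC", [100, 200, 300])
        curve = lengthstats.cumulative_curve(cat, (0, 1000))
        v = dict(zip(curve.grid, curve.values))
        assert v[99] == 0
        assert v[100] == pytest.approx(1 / 3)
        assert v[250] == pytest.approx(2 / 3)
        assert v[300] == pytest.approx(1.0)
        assert curve.values[-1] == 1.0
        assert (np.diff(curve.values) >= 0).all()

    def test_all_above_range_flagged(self):
        cat = _catalog_from_lengths("s", "HC", [5000, 6000])
        with pytest.warns(UserWarning, match="above"):
            curve = lengthstats.cumulative_curve(cat, (0, 1000))
        assert curve.all_above_range
        assert (curve.values == 0).all()

    def test_single_length_step(self):
        cat = _catalog_from_lengths("s", "HC", [500])
        curve = lengthstats.cumulative_curve(cat, (0, 1000))
        assert set(np.unique(curve.values)) == {0.0, 1.0}

    def test_empty_catalog_errors(self):
        with pytest.raises(EccdiffError):
            lengthstats.cumulative_curve(CircleCatalog("s", "HC", []), (0, 100))


class TestRhomboidSummary:
    def test_degenerate_counts(self):
        cats = {
            f"s{i}": _catalog_from_lengths(f"s{i}", "HC", [100])
            for i in range(3)
        }
        out = lengthstats.rhomboid_summary(cats, {f"s{i}": "HC" for i in range(3)})
        assert out["HC"].count_mu == 1
        assert out["HC"].count_sigma == 0

    def test_pooled_length_sample_sd(self):
        cats = {"s1": _catalog_from_lengths("s1", "HC", [100, 300])}
        with pytest.warns(UserWarning, match="count SD"):
            out = lengthstats.rhomboid_summary(cats, {"s1": "HC"})
        assert out["HC"].length_mu == pytest.approx(200)
        assert out["HC"].length_sigma == pytest.approx(math.sqrt(2 * 100**2 / 1))
        assert out["HC"].length_vertices == pytest.approx((200 - 141.4213562, 200, 341.4213562))

    def test_single_sample_group_count_sd_zero_with_warning(self):
        cats = {
            "s1": _catalog_from_lengths("s1", "HC", [100, 200]),
            "s2": _catalog_from_lengths("s2", "HC", [150]),
            "s3": _catalog_from_lengths("s3", "SLE", [500]),
        }
        groups = {"s1": "HC", "s2": "HC", "s3": "SLE"}
        with pytest.warns(UserWarning):
            out = lengthstats.rhomboid_summary(cats, groups)
        assert out["SLE"].count_sigma == 0.0
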