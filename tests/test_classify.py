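import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from potlip import (
    AnalysisConfig,
    SherdSample,
    Site,
    SourceClass,
    ThresholdClass,
    classify_ellipses,
    classify_samples,
    classify_threshold,
    delta13c,
    latitudinal_gradient,
    summarize_regions,
)
from potlip.reference import mahalanobis_sq
from scipy import stats
from tests.conftest import make_group


class TestDelta13C:
    def test_subtraction(self):
        s = SherdSample("A", "S1", d13c_16=-27.0, d13c_18=-31.2)
        d, sd = delta13c(s)
        assert d == pytest.approx(-4.2)
        assert sd == pytest.approx(np.hypot(0.1, 0.1))

    def test_identity_zero(self):
        s = SherdSample("A", "S1", d13c_16=-27.0, d13c_18=-27.0)
        assert delta13c(s)[0] == 0.0

    def test_translation_invariance(self):
        a = SherdSample("A", "S1", d13c_16=-27.0, d13c_18=-31.2)
        b = SherdSample("B", "S1", d13c_16=-26.5, d13c_18=-30.7)
        assert delta13c(a)[0] == pytest.approx(delta13c(b)[0])

    def test_missing_value_raises(self):
        with pytest.raises(ValueError, match="lacks"):
            delta13c(SherdSample("A", "S1", d13c_16=-27.0))


class TestThresholds:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (-4.2, ThresholdClass.DAIRY),
            (-3.3, ThresholdClass.DAIRY),              # boundary inclusive
            (-3.2999, ThresholdClass.RUMINANT_ADIPOSE),
            (-2.0, ThresholdClass.RUMINANT_ADIPOSE),
            (-1.0001, ThresholdClass.RUMINANT_ADIPOSE),
            (-1.0, ThresholdClass.NON_RUMINANT),       # boundary inclusive
            (0.5, ThresholdClass.NON_RUMINANT),
        ],
    )
    def test_boundaries(self, delta, expected):
        assert classify_threshold(delta) == expected

    def test_nan_errors(self):
        with pytest.raises(ValueError):
            classify_threshold(float("nan"))

    @given(st.floats(-20, 20, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_total_partition(self, delta):
        # exactly one class for every finite delta
        assert classify_threshold(delta) in ThresholdClass.ALL


class TestEllipseClassification:
    def test_group_mean_is_member(self):
        g = make_group(SourceClass.RUMINANT_DAIRY, (-29.0, -34.0), np.eye(2) * 0.5)
        s = SherdSample("A", "S1", d13c_16=-29.0, d13c_18=-34.0)
        classes, marine = classify_ellipses(s, {SourceClass.RUMINANT_DAIRY: g})
        assert SourceClass.RUMINANT_DAIRY in classes and not marine

    def test_far_point_outside_all(self):
        groups = {
            SourceClass.RUMINANT_DAIRY: make_group(
                SourceClass.RUMINANT_DAIRY, (-29.0, -34.0), np.eye(2) * 0.5
            ),
            SourceClass.MARINE_OIL: make_group(
                SourceClass.MARINE_OIL, (-22.0, -20.5), np.eye(2) * 0.5
            ),
        }
        s = SherdSample("A", "S1", d13c_16=-5.0, d13c_18=-5.0)
        classes, marine = classify_ellipses(s, groups)
        assert classes == set() and not marine

    def test_overlapping_groups_match_bruteforce(self):
        rng = np.random.default_rng(9)
        groups = {
            SourceClass.RUMINANT_DAIRY: make_group(
                SourceClass.RUMINANT_DAIRY, (-29.0, -34.0),
                [[1.0, 0.3], [0.3, 1.2]],
            ),
            SourceClass.RUMINANT_ADIPOSE: make_group(
                SourceClass.RUMINANT_ADIPOSE, (-29.5, -32.0),
                [[0.8, 0.2], [0.2, 0.9]],
            ),
        }
        q = stats.chi2.ppf(0.68, df=2)
        for _ in range(200):
            pt = rng.uniform([-33, -37], [-26, -29])
            s = SherdSample("A", "S1", d13c_16=float(pt[0]), d13c_18=float(pt[1]))
            classes, _ = classify_ellipses(s, groups)
            oracle = {
                cls for cls, g in groups.items()
                if mahalanobis_sq(pt, g.mean, g.cov) <= q
            }
            assert classes == oracle


class TestGradient:
    def _dataset(self, lats, deltas):
        sites = [Site(f"S{i}", latitude=float(lat)) for i, lat in enumerate(lats)]
        samples = [
            SherdSample(f"A{i}", f"S{i}", region="r",
                        d13c_16=-28.0, d13c_18=-28.0 + float(d))
            for i, d in enumerate(deltas)
        ]
        classified = classify_samples(samples)
        return classified, sites

    def test_perfect_monotone_decrease(self):
        lats = np.linspace(37, 58, 10)
        classified, sites = self._dataset(lats, -0.2 * lats)
        rho, p, n = latitudinal_gradient(classified, sites)
        assert rho == pytest.approx(-1.0)
        assert n == 10

    def test_null_shuffle_small_rho(self):
        rng = np.random.default_rng(21)
        lats = rng.uniform(37, 58, 1000)
        deltas = np.clip(rng.normal(-2.5, 1.0, 1000), -15, 10)
        classified, sites = self._dataset(lats, deltas)
        rho, p, n = latitudinal_gradient(classified, sites)
        assert abs(rho) < 0.1

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        lats = rng.uniform(37, 58, 50)
        deltas = np.clip(-0.1 * lats + rng.normal(0, 1, 50), -15, 5)
        classified, sites = self._dataset(lats, deltas)
        rho1, _, _ = latitudinal_gradient(classified, sites)
        # strictly increasing bounded transform of latitude
        from scipy.special import expit

        sites2 = [
            Site(s.site_id, latitude=float(-90 + 180 * expit((s.latitude - 47) / 5)))
            for s in sites
        ]
        rho2, _, _ = latitudinal_gradient(classified, sites2)
        assert rho1 == pytest.approx(rho2)

    def test_identical_latitudes_error(self):
        classified, sites = self._dataset([45.0] * 5, [-1, -2, -3, -4, -5])
        with pytest.raises(ValueError, match="identical"):
            latitudinal_gradient(classified, sites)

    def test_permutation_pvalue_close_to_t(self):
        rng = np.random.default_rng(8)
        lats = rng.uniform(37, 58, 60)
        deltas = np.clip(-0.15 * lats + rng.normal(0, 2, 60), -15, 5)
        classified, sites = self._dataset(lats, deltas)
        _, p_t, _ = latitudinal_gradient(classified, sites, method="t")
        _, p_perm, _ = latitudinal_gradient(
            classified, sites, method="perm", n_perm=4999, seed=1
        )
        assert p_perm == pytest.approx(p_t, abs=0.02) or (p_t < 1e-4 and p_perm < 1e-2)


class TestRegionalSummary:
    def test_mean_and_sd(self):
        samples = [
            SherdSample("A", "S1", region="Northern Spain",
                        d13c_16=-28.0, d13c_18=-32.0),
            SherdSample("B", "S1", region="Northern Spain",
                        d13c_16=-28.0, d13c_18=-30.0),
        ]
        (summary,) = summarize_regions(classify_samples(samples))
        assert summary.delta_mean == pytest.approx(-3.0)
        assert summary.delta_sd == pytest.approx(np.sqrt(2.0))
        assert summary.n == 2

    def test_fractions_sum_to_one(self, classified):
        for s in summarize_regions(classified):
            assert sum(s.class_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_dairy_dominated_region_fraction(self):
        # forward-simulate a nearly pure dairy region and count classes
        from potlip import default_scenario, gen_sherds, gen_sites
        from potlip.simulate import RegionSpec

        region = RegionSpec("pure dairy", (50.0, 52.0), (-5.0, 0.0),
                            6, 40, (0.0, 0.02, 0.96, 0.02), 4000.0)
        scenario = default_scenario(seed=13, regions=(region,),
                                    dirichlet_conc=200.0, obs_sigma=0.2)
        sites = gen_sites(scenario)
        sherds, _ = gen_sherds(scenario, sites)
        classified = classify_samples(sherds)
        (summary,) = summarize_regions(classified)
        assert summary.class_fractions["dairy"] > 0.8
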