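import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from potlip import (
    AnalysisConfig,
    MixingModel,
    MixingProblem,
    SourceClass,
    classify_samples,
    forward_mix,
    regional_medians,
    run_mixing,
)
from potlip.reference import FattyAcidConcentration
from tests.conftest import make_group

EQ_CONC = FattyAcidConcentration(25.0, 25.0, 0.0, 0.0)


class TestForwardMix:
    def test_shared_signature_conserved(self):
        # if every source has the same d13C16:0, the mixture must too
        g1 = make_group(SourceClass.RUMINANT_DAIRY, (-29.0, -34.0), np.eye(2))
        g2 = make_group(SourceClass.NON_RUMINANT, (-29.0, -25.0), np.eye(2))
        mu = forward_mix(np.array([0.3, 0.7]), [g1, g2])
        assert mu[0] == pytest.approx(-29.0)

    def test_equal_concentration_midpoint(self):
        g1 = make_group(SourceClass.RUMINANT_DAIRY, (-32.0, -32.0), np.eye(2))
        g2 = make_group(SourceClass.NON_RUMINANT, (-28.0, -28.0), np.eye(2))
        mu = forward_mix(np.array([0.5, 0.5]), [g1, g2])
        assert np.allclose(mu, -30.0)

    def test_concentration_weighting_hand_arithmetic(self):
        # c = (10, 30)%, f = (0.5, 0.5), delta = (-32, -28):
        # mu = (0.5*10*-32 + 0.5*30*-28) / (0.5*10 + 0.5*30) = -29
        g1 = make_group(SourceClass.RUMINANT_DAIRY, (-32.0, -32.0), np.eye(2),
                        conc=FattyAcidConcentration(10.0, 10.0))
        g2 = make_group(SourceClass.NON_RUMINANT, (-28.0, -28.0), np.eye(2),
                        conc=FattyAcidConcentration(30.0, 30.0))
        mu = forward_mix(np.array([0.5, 0.5]), [g1, g2])
        assert np.allclose(mu, -29.0)

    def test_off_simplex_rejected(self):
        g1 = make_group(SourceClass.RUMINANT_DAIRY, (-32.0, -32.0), np.eye(2))
        g2 = make_group(SourceClass.NON_RUMINANT, (-28.0, -28.0), np.eye(2))
        with pytest.raises(ValueError, match="simplex"):
            forward_mix(np.array([0.5, 0.6]), [g1, g2])

    @given(
        f1=st.floats(0.0, 1.0),
        d16=st.floats(-35, -20),
        d18=st.floats(-38, -20),
        c16=st.floats(1.0, 60.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_convex_hull_property(self, f1, d16, d18, c16):
        # mixture always lies within [min, max] of source signatures per proxy
        g1 = make_group(SourceClass.RUMINANT_DAIRY, (d16, d18), np.eye(2),
                        conc=FattyAcidConcentration(c16, 20.0))
        g2 = make_group(SourceClass.NON_RUMINANT, (-28.0, -28.0), np.eye(2))
        mu = forward_mix(np.array([f1, 1.0 - f1]), [g1, g2])
        for k, vals in enumerate(zip((d16, d18), (-28.0, -28.0))):
            assert min(vals) - 1e-9 <= mu[k] <= max(vals) + 1e-9


class TestRunMixing:
    def test_two_source_symmetric_oracle(self, two_source_pair):
        # y exactly midway between well-separated sources with tiny
        # signature uncertainty: posterior mean of each f is 0.5
        problem = MixingProblem(y=(-28.0, -30.0), sources=two_source_pair)
        res = MixingModel(problem).fit(burn_in=2000, iters=5000, seed=5)
        assert np.all(np.abs(res.mean() - 0.5) < 0.05)

    def test_interpolation_fraction_oracle(self, two_source_pair):
        # analytic oracle: with equal concentrations the posterior
        # concentrates near the interpolation fraction of y between the
        # source signatures (f* = 0.75 toward the dairy end here)
        y16 = 0.75 * -32.0 + 0.25 * -24.0
        y18 = 0.75 * -36.0 + 0.25 * -24.0
        problem = MixingProblem(y=(y16, y18), sources=two_source_pair)
        res = MixingModel(problem).fit(burn_in=2000, iters=5000, seed=6)
        assert res.mean()[0] == pytest.approx(0.75, abs=0.05)

    def test_observation_at_source_mean_favors_that_source(self, groups):
        from potlip.mixing import DEFAULT_SOURCE_ORDER

        sources = [groups[c] for c in DEFAULT_SOURCE_ORDER]
        dairy = groups[SourceClass.RUMINANT_DAIRY]
        problem = MixingProblem(y=tuple(dairy.mean), sources=sources,
                                obs_sigma=0.5)
        res = MixingModel(problem).fit(burn_in=2000, iters=5000, seed=7)
        medians = res.median()
        dairy_idx = res.source_names.index("ruminant_dairy")
        assert medians[dairy_idx] == max(medians)

    def test_single_source_degenerate(self, two_source_pair):
        problem = MixingProblem(y=(-30.0, -30.0), sources=two_source_pair[:1])
        res = MixingModel(problem).fit(burn_in=10, iters=100, seed=1)
        assert np.all(res.pooled == 1.0)

    def test_determinism(self, two_source_pair):
        problem = MixingProblem(y=(-28.0, -30.0), sources=two_source_pair)
        r1 = MixingModel(problem).fit(burn_in=200, iters=500, seed=11)
        r2 = MixingModel(problem).fit(burn_in=200, iters=500, seed=11)
        assert np.array_equal(r1.draws, r2.draws)
        assert not np.array_equal(
            r1.draws, MixingModel(problem).fit(burn_in=200, iters=500, seed=12).draws
        )

    def test_simplex_closure_every_draw(self, groups):
        from potlip.mixing import DEFAULT_SOURCE_ORDER

        sources = [groups[c] for c in DEFAULT_SOURCE_ORDER]
        problem = MixingProblem(y=(-28.5, -31.0), sources=sources)
        res = MixingModel(problem).fit(burn_in=500, iters=1000, seed=3)
        pooled = res.pooled
        assert np.all(pooled >= 0)
        assert np.allclose(pooled.sum(axis=1), 1.0, atol=1e-9)
        ci68, ci95 = res.ci(0.68), res.ci(0.95)
        assert np.all(ci95[:, 0] <= ci68[:, 0])
        assert np.all(ci68[:, 1] <= ci95[:, 1])

    def test_colinear_sources_stay_dispersed(self):
        # equifinality honesty: colinear sources cannot be resolved, so no
        # credible interval may collapse
        g1 = make_group(SourceClass.RUMINANT_DAIRY, (-32.0, -34.0),
                        np.eye(2) * 0.01, conc=EQ_CONC)
        g2 = make_group(SourceClass.RUMINANT_ADIPOSE, (-29.0, -30.0),
                        np.eye(2) * 0.01, conc=EQ_CONC)
        g3 = make_group(SourceClass.NON_RUMINANT, (-26.0, -26.0),
                        np.eye(2) * 0.01, conc=EQ_CONC)   # all on one line
        problem = MixingProblem(y=(-29.0, -30.0), sources=[g1, g2, g3])
        res = MixingModel(problem).fit(burn_in=2000, iters=5000, seed=9)
        widths = res.ci(0.95)[:, 1] - res.ci(0.95)[:, 0]
        assert np.all(widths > 0.02)

    def test_diagnostics_frame(self, two_source_pair):
        problem = MixingProblem(y=(-28.0, -30.0), sources=two_source_pair)
        res = MixingModel(problem).fit(burn_in=1000, iters=2000, seed=2)
        diag = res.diagnostics()
        assert set(diag.columns) == {"rhat", "ess_bulk"}
        assert res.converged
        summary = res.summary()
        assert list(summary.index) == res.source_names


class TestRegionalMedians:
    def _classified(self, values16, values18, region="Northern Spain"):
        from potlip import SherdSample

        samples = [
            SherdSample(f"A{i}", "S1", region=region,
                        d13c_16=float(a), d13c_18=float(b))
            for i, (a, b) in enumerate(zip(values16, values18))
        ]
        return classify_samples(samples)

    def test_odd_median(self):
        cls = self._classified([-27, -26, -25], [-30, -29, -31])
        m16, m18, n = regional_medians(cls, "Northern Spain")
        assert (m16, m18, n) == (-26.0, -30.0, 3)

    def test_even_median_midpoint(self):
        cls = self._classified([-27, -26, -25, -24], [-30, -29, -31, -28])
        m16, _, _ = regional_medians(cls, "Northern Spain")
        assert m16 == pytest.approx(-25.5)

    def test_western_baltic_refused_by_default(self):
        cls = self._classified([-27, -26], [-30, -29], region="Western Baltic")
        with pytest.raises(ValueError, match="bimodal"):
            regional_medians(cls, "Western Baltic")

    def test_exclusion_configurable(self):
        cls = self._classified([-27, -26], [-30, -29], region="Western Baltic")
        cfg = AnalysisConfig(excluded_regions=[])
        m16, _, n = regional_medians(cls, "Western Baltic", cfg)
        assert n == 2
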