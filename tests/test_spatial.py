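import subprocess
import shutil

import numpy as np
import pytest

from potlip.spatial import (
    QuantileSurfaceGAMM,
    SurfaceGAMM,
    fit_averager,
    fit_spreadr,
)


def site_layout(ns=20, per_site=10, seed=0):
    rng = np.random.default_rng(seed)
    site_lon = rng.uniform(-9, 1, ns)
    site_lat = rng.uniform(37, 58, ns)
    lon = np.repeat(site_lon, per_site)
    lat = np.repeat(site_lat, per_site)
    ids = np.repeat(np.arange(ns), per_site)
    return lon, lat, ids, rng


class TestSurfaceGAMM:
    def test_constant_recovery(self):
        lon, lat, ids, _ = site_layout(10, 5)
        fit = SurfaceGAMM(lon, lat, np.full(len(lon), -2.0), ids).fit()
        pred = fit.predict(np.array([-8.0, -3.0, 0.5]), np.array([38.0, 47.0, 56.0]))
        assert np.allclose(pred, -2.0, atol=1e-6)
        assert fit.sigma_u2 < 1e-6

    def test_plane_recovery_rmse_below_noise(self):
        lon, lat, ids, rng = site_layout(20, 10, seed=3)
        truth = -1.0 - 0.12 * (lat - 47)
        noise_sd = 0.3
        y = truth + rng.normal(0, noise_sd, len(lon)) \
            + np.repeat(rng.normal(0, 0.2, 20), 10)
        fit = SurfaceGAMM(lon, lat, y, ids).fit()
        rmse = float(np.sqrt(np.mean((fit.predict(lon, lat) - truth) ** 2)))
        assert rmse < noise_sd

    def test_duplication_weighting_sanity(self):
        # duplicating every observation doubles the data-fit term, which is
        # equivalent to halving the penalty: refitting the doubled data
        # with doubled lambdas must reproduce the surface exactly
        lon, lat, ids, rng = site_layout(12, 6, seed=4)
        y = -2.0 - 0.1 * (lat - 47) + rng.normal(0, 0.3, len(lon))
        fit1 = SurfaceGAMM(lon, lat, y, ids).fit(lam=10.0, lam_u=5.0)
        fit2 = SurfaceGAMM(
            np.concatenate([lon, lon]), np.concatenate([lat, lat]),
            np.concatenate([y, y]), np.concatenate([ids, ids]),
        ).fit(lam=20.0, lam_u=10.0)
        gx = np.array([-8.0, -4.0, 0.0])
        gy = np.array([39.0, 47.0, 55.0])
        assert np.allclose(fit1.predict(gx, gy), fit2.predict(gx, gy), atol=1e-8)

    def test_single_site_errors(self):
        with pytest.raises(ValueError, match="single site"):
            SurfaceGAMM([0.0, 0.1], [45.0, 45.1], [1.0, 2.0], ["s1", "s1"])

    def test_excessive_k_errors(self):
        lon, lat, ids, _ = site_layout(6, 2)
        with pytest.raises(ValueError, match="k"):
            SurfaceGAMM(lon, lat, np.zeros(len(lon)), ids, k=50)

    def test_large_lambda_degenerates_to_plane(self):
        # as lambda -> inf only the unpenalised null space (a plane)
        # survives; a pure plane signal is then fit exactly
        lon, lat, ids, rng = site_layout(15, 6, seed=6)
        y = 1.0 + 0.2 * lon - 0.1 * lat + rng.normal(0, 0.05, len(lon))
        fit = SurfaceGAMM(lon, lat, y, ids).fit(lam=1e9, lam_u=1e9)
        # fitted surface should be essentially affine in (lon, lat)
        gx = np.linspace(-8, 0, 10)
        gy = np.linspace(38, 57, 10)
        pred_a = fit.predict(gx, gy)
        # affine check: second differences along the transect vanish
        second_diff = np.diff(pred_a, n=2)
        assert np.max(np.abs(second_diff)) < 1e-3

    def test_se_mask_extremes_and_monotonicity(self):
        lon, lat, ids, rng = site_layout(15, 8, seed=7)
        y = -2.0 + rng.normal(0, 0.5, len(lon))
        fit = SurfaceGAMM(lon, lat, y, ids).fit()
        surf_inf = fit.predict_surface(resolution=2.0, se_mask=np.inf)
        assert not surf_inf.mask.any()
        surf_zero = fit.predict_surface(resolution=2.0, se_mask=0.0)
        assert surf_zero.mask.all()
        fracs = [
            fit.predict_surface(resolution=2.0, se_mask=m).mask.mean()
            for m in (0.5, 0.2, 0.05)
        ]
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_extrapolation_flagged_outside_hull(self):
        lon, lat, ids, rng = site_layout(15, 4, seed=8)
        y = rng.normal(0, 1, len(lon))
        fit = SurfaceGAMM(lon, lat, y, ids).fit()
        surf = fit.predict_surface(resolution=1.0)
        # padded grid corners lie outside the data hull
        assert surf.extrapolated[0, 0] and surf.extrapolated[-1, -1]
        assert not surf.extrapolated.all()

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_against_mgcv_oracle(self, tmp_path):
        # independent cross-check: mgcv's gam(y ~ s(lon,lat,bs='tp') +
        # s(site, bs='re'), method='REML') on the same data
        import pandas as pd

        lon, lat, ids, rng = site_layout(15, 8, seed=5)
        truth = -2.0 - 0.1 * (lat - 47) + 0.02 * (lon + 4) ** 2
        y = truth + rng.normal(0, 0.3, len(lon)) \
            + np.repeat(rng.normal(0, 0.2, 15), 8)
        fit = SurfaceGAMM(lon, lat, y, ids).fit()
        gx = np.linspace(-8, 0, 5)
        gy = np.linspace(38, 57, 5)
        mine = fit.predict(gx, gy)

        pd.DataFrame({"lon": lon, "lat": lat, "y": y,
                      "site": [f"s{i}" for i in ids]}).to_csv(
            tmp_path / "fix.csv", index=False)
        pd.DataFrame({"lon": gx, "lat": gy}).to_csv(
            tmp_path / "grid.csv", index=False)
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(mgcv))\n'
            f'd <- read.csv("{tmp_path}/fix.csv"); d$site <- factor(d$site)\n'
            f'g <- read.csv("{tmp_path}/grid.csv")\n'
            'm <- gam(y ~ s(lon, lat, bs="tp", k=15) + s(site, bs="re"),'
            ' data=d, method="REML")\n'
            'g$site <- d$site[1]\n'
            'p <- predict(m, newdata=g, exclude="s(site)",'
            ' newdata.guaranteed=TRUE)\n'
            f'write.csv(data.frame(pred=p), "{tmp_path}/pred.csv",'
            ' row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        theirs = pd.read_csv(tmp_path / "pred.csv")["pred"].to_numpy()
        assert np.max(np.abs(mine - theirs)) < 1e-3


class TestQuantileSurface:
    def test_iid_dates_match_order_statistic_oracle(self):
        rng = np.random.default_rng(2)
        n = 120
        lon = rng.uniform(-9, 1, n)
        lat = rng.uniform(37, 58, n)
        dates = rng.normal(4500, 200, n)
        fit = fit_spreadr(lon, lat, dates, tau=0.005, seed=0)
        surf = fit.arrival_map(resolution=2.0, bootstrap_reps=60, seed=1)
        inside = ~surf.extrapolated
        oracle = float(np.quantile(dates, 0.005))
        boot_se = float(surf.se[inside].mean())
        assert abs(float(surf.value[inside].mean()) - oracle) < max(3 * boot_se, 50.0)

    def test_tau_half_close_to_mean_surface(self):
        # symmetric noise: the tau = 0.5 surface approximates the mean fit
        rng = np.random.default_rng(4)
        n = 100
        lon = rng.uniform(-9, 1, n)
        lat = rng.uniform(37, 58, n)
        truth = 5400 - 90 * (lat - 37)
        dates = truth + rng.normal(0, 100, n)
        qfit = fit_spreadr(lon, lat, dates, tau=0.499, lam=10.0)
        mfit = fit_averager(lon, lat, dates, [f"s{i}" for i in range(n)])
        gx = np.full(5, -4.0)
        gy = np.linspace(38, 57, 5)
        assert np.max(np.abs(qfit.predict(gx, gy) - mfit.predict(gx, gy))) < 100.0

    def test_gradient_scenario_monotone_northward(self):
        rng = np.random.default_rng(6)
        n = 100
        lon = rng.uniform(-9, 1, n)
        lat = rng.uniform(37, 58, n)
        dates = 5400 - 90 * (lat - 37) + rng.normal(0, 50, n)
        fit = fit_spreadr(lon, lat, dates, tau=0.005, seed=0)
        gy = np.linspace(38, 57, 8)
        preds = fit.predict(np.full(8, -4.0), gy)
        assert np.all(np.diff(preds) < 0)

    def test_exceedance_fraction_bounded(self):
        rng = np.random.default_rng(8)
        n = 150
        lon = rng.uniform(-9, 1, n)
        lat = rng.uniform(37, 58, n)
        dates = 5000 - 50 * (lat - 37) + rng.normal(0, 150, n)
        fit = fit_spreadr(lon, lat, dates, tau=0.005, seed=0)
        assert 0.0 <= fit.exceedance_fraction() <= 0.005 + 2.0 / n

    def test_tau_out_of_range(self):
        with pytest.raises(ValueError, match="tau"):
            QuantileSurfaceGAMM([0, 1, 2, 3], [45, 46, 47, 48],
                                [1, 2, 3, 4], tau=0.7)

    def test_arrival_map_determinism_and_se(self):
        rng = np.random.default_rng(9)
        n = 60
        lon = rng.uniform(-9, 1, n)
        lat = rng.uniform(37, 58, n)
        dates = 5000 - 60 * (lat - 37) + rng.normal(0, 100, n)
        fit = fit_spreadr(lon, lat, dates, tau=0.005, lam=100.0)
        s1 = fit.arrival_map(resolution=3.0, bootstrap_reps=30, seed=7)
        s2 = fit.arrival_map(resolution=3.0, bootstrap_reps=30, seed=7)
        assert np.array_equal(s1.value, s2.value)
        assert np.array_equal(s1.se, s2.se)
        assert np.all(s1.se >= 0)
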