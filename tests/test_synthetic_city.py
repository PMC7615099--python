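"""Generator contracts: planted effects, rendering encodings, corruption."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import urbansense as us
from urbansense import synthetic_city as sc

from conftest import make_site, quiet_config


def _day_effects(cfg, value=0.0):
    start = min(s.start for s in cfg.sites)
    end = max(s.end for s in cfg.sites)
    dates = pd.date_range(start.normalize(), end.normalize(), freq="D").date
    return pd.Series(value, index=dates)


class TestSimulatePollution:
    def test_zero_activity_zero_error_gives_constant_noise(self):
        site = make_site(activity_amplitude=0.0, baseline_noise=47.0)
        cfg = quiet_config(sites=[site])
        poll = sc.simulate_pollution(site, cfg, _day_effects(cfg), np.random.default_rng(0))
        assert np.allclose(poll["noise_dba"], 47.0)
        assert len(poll) == 1440

    def test_harmattan_multiplier_sets_mean_pm_ratio(self):
        # one Harmattan day, one outside; all other PM effects off
        site = make_site(days=("2019-12-10", "2019-06-10"), activity_amplitude=0.0)
        cfg = quiet_config(sites=[site], harmattan_pm_multiplier=2.0)
        poll = sc.simulate_pollution(site, cfg, _day_effects(cfg), np.random.default_rng(0))
        harm = sc.is_harmattan(poll["timestamp"])
        ratio = poll.loc[harm, "pm25_ugm3"].mean() / poll.loc[~harm, "pm25_ugm3"].mean()
        assert ratio == pytest.approx(2.0, rel=1e-9)

    def test_shared_day_effects_correlate_sites(self):
        days = [str(d.date()) for d in pd.date_range("2019-05-01", periods=40)]
        s1 = make_site("a", days=days, activity_amplitude=0.0)
        s2 = make_site("b", days=days, activity_amplitude=0.0, baseline_pm_log=np.log(30))
        cfg = quiet_config(sites=[s1, s2], regional_pm_sd=0.4)
        rng = np.random.default_rng(1)
        eff = sc.make_day_effects(s1.start, s1.end, cfg, rng)
        p1 = sc.simulate_pollution(s1, cfg, eff, np.random.default_rng(2))
        p2 = sc.simulate_pollution(s2, cfg, eff, np.random.default_rng(3))
        d1 = np.log(p1.groupby(p1["timestamp"].dt.date)["pm25_ugm3"].mean())
        d2 = np.log(p2.groupby(p2["timestamp"].dt.date)["pm25_ugm3"].mean())
        assert np.corrcoef(d1, d2)[0, 1] > 0.999  # only the shared effect varies

    def test_noise_coefficient_recovered_by_regression(self):
        days = [str(d.date()) for d in pd.date_range("2019-05-01", periods=8)]
        site = make_site(days=days, activity_amplitude=1.3)
        cfg = quiet_config(sites=[site], noise_error_sd=1.5, noise_coeff=12.0)
        poll = sc.simulate_pollution(site, cfg, _day_effects(cfg), np.random.default_rng(4))
        assert len(poll) >= 10_000
        slope = stats.linregress(poll["activity"], poll["noise_dba"]).slope
        assert slope == pytest.approx(12.0, rel=0.05)

    def test_missing_day_effects_is_configuration_error(self):
        site = make_site()
        cfg = quiet_config(sites=[site])
        empty = pd.Series(dtype=float)
        with pytest.raises(sc.ConfigurationError):
            sc.simulate_pollution(site, cfg, empty, np.random.default_rng(0))


class TestClockRules:
    @pytest.mark.parametrize(
        "stamp,expected",
        [
            ("2019-11-01", True),
            ("2020-02-28", True),
            ("2019-12-15", True),
            ("2020-01-10", True),
            ("2019-10-31", False),
            ("2020-03-01", False),
            ("2019-06-15", False),
        ],
    )
    def test_harmattan_window_boundaries_inclusive(self, stamp, expected):
        assert sc.is_harmattan(pd.DatetimeIndex([stamp]))[0] == expected

    def test_day_night_fixed_clock_rule(self):
        times = pd.DatetimeIndex(
            ["2019-06-01 05:59", "2019-06-01 06:00", "2019-06-01 17:59", "2019-06-01 18:00"]
        )
        assert sc.is_day(times).tolist() == [False, True, True, False]


class TestSimulateCounts:
    def test_poisson_mean_recovered(self):
        cfg = quiet_config(object_rate_params={"car": (np.log(3.0), 0.0)})
        act = np.zeros(20_000)
        day = np.ones(20_000, bool)
        counts = sc.simulate_counts(act, cfg, day, np.random.default_rng(5))
        se = np.sqrt(3.0 / 20_000)
        assert counts["car"].mean() == pytest.approx(3.0, abs=4 * se)

    def test_no_activity_coupling_means_no_association(self):
        rates = {c: (0.0, 0.0) for c in sc.OBJECT_CATEGORIES}
        cfg = quiet_config(object_rate_params=rates)
        rng = np.random.default_rng(6)
        act = rng.uniform(0, 2, 5000)
        counts = sc.simulate_counts(act, cfg, np.ones(5000, bool), rng)
        rho = stats.spearmanr(counts["car"], act).statistic
        assert abs(rho) < 0.05

    def test_planted_effect_ordering_reflected_in_rank_correlations(self):
        rates = {c: (0.0, 0.0) for c in sc.OBJECT_CATEGORIES}
        rates["person"] = (0.5, 1.2)
        rates["animal"] = (0.5, 0.3)
        cfg = quiet_config(object_rate_params=rates)
        rng = np.random.default_rng(7)
        act = rng.uniform(0, 2, 8000)
        noise = 45 + 12 * act  # the latent that drives noise
        counts = sc.simulate_counts(act, cfg, np.ones(8000, bool), rng)
        rho_person = stats.spearmanr(counts["person"], noise).statistic
        rho_animal = stats.spearmanr(counts["animal"], noise).statistic
        assert rho_person > rho_animal > 0

    def test_sparse_categories_near_absent(self, small_world):
        _, data, _ = small_world
        assert data.frames[list(sc.SPARSE_CATEGORIES)].to_numpy().sum() == 0

    def test_unknown_category_rejected(self):
        with pytest.raises(sc.ConfigurationError):
            quiet_config(object_rate_params={"spaceship": (0.0, 0.0)})


class TestRenderFrame:
    def _render(self, pm, cfg, daylight=True, seed=8, counts=None):
        return sc.render_frame(
            counts or {"car": 2, "person": 1}, pm, daylight, cfg, np.random.default_rng(seed)
        )

    def test_red_tint_monotone_in_pm(self):
        cfg = quiet_config(haze_blur_coeff=0.0, contrast_coeff=0.0)
        lo = self._render(10.0, cfg)
        hi = self._render(100.0, cfg)
        assert hi[..., 0].mean() > lo[..., 0].mean()
        assert hi[..., 2].mean() < lo[..., 2].mean()

    def test_disabled_encoding_makes_frames_pm_independent(self):
        cfg = quiet_config(red_tint_coeff=0.0, haze_blur_coeff=0.0, contrast_coeff=0.0)
        assert np.array_equal(self._render(10.0, cfg), self._render(100.0, cfg))

    def test_night_grayscale_sd_decreases_with_pm(self):
        cfg = quiet_config()
        sds = []
        for pm in (10.0, 50.0, 200.0):
            img = self._render(pm, cfg, daylight=False, seed=9, counts={})
            sds.append(img.mean(axis=2).std())
        assert sds[0] > sds[1] > sds[2]

    def test_deterministic_given_rng_state(self):
        cfg = quiet_config()
        assert np.array_equal(self._render(25.0, cfg, seed=10), self._render(25.0, cfg, seed=10))

    def test_nonpositive_pm_rejected(self):
        with pytest.raises(ValueError):
            self._render(0.0, quiet_config())


class TestCorruption:
    def test_clock_failed_site_gets_2017_five_minute_grid(self, small_world):
        cfg, data, _ = small_world
        failed = [s.site_id for s in cfg.sites if s.clock_failed]
        assert failed
        grp = (
            data.frames[data.frames["site_id"] == failed[0]]
            .groupby("camera_id")
            .first()
        )
        for cam, row in grp.iterrows():
            sub = data.frames[
                (data.frames["site_id"] == failed[0]) & (data.frames["camera_id"] == cam)
            ].sort_values("true_time")
            stamps = pd.to_datetime(sub["stamped_time"]).reset_index(drop=True)
            assert stamps[0] == pd.Timestamp("2017-01-01T00:00:00")
            assert stamps[2] == pd.Timestamp("2017-01-01T00:10:00")  # 3rd frame
            assert (stamps.diff().dropna() == pd.Timedelta(minutes=5)).all()

    def test_no_corruption_is_identity(self):
        days = [str(d.date()) for d in pd.date_range("2019-05-01", periods=2)]
        site = make_site(days=days)
        cfg = quiet_config(sites=[site])
        data = sc.generate_campaign(cfg)
        assert not data.frames["corrupted"].any()
        assert not data.pollution[site.site_id]["corrupted"].any()
        assert (data.frames["stamped_time"] == data.frames["true_time"]).all()
        assert len(data.pollution[site.site_id]) == 2 * 1440

    def test_dropout_removes_binomial_fraction(self):
        days = [str(d.date()) for d in pd.date_range("2019-05-01", periods=7)]
        site = make_site(days=days)
        cfg = quiet_config(sites=[site], measurement_dropout=0.2)
        data = sc.generate_campaign(cfg)
        n_total = 7 * 1440
        n_kept = len(data.pollution[site.site_id])
        sd = np.sqrt(n_total * 0.2 * 0.8)
        assert abs((n_total - n_kept) - 0.2 * n_total) < 4 * sd


class TestCampaignStructure:
    def test_generation_reproducible_bit_for_bit(self, small_world_cfg):
        d1 = sc.generate_campaign(small_world_cfg)
        d2 = sc.generate_campaign(small_world_cfg)
        pd.testing.assert_frame_equal(d1.frames, d2.frames)
        for site in d1.pollution:
            pd.testing.assert_frame_equal(d1.pollution[site], d2.pollution[site])
        i1 = sc.render_frames(d1.frames.head(3), small_world_cfg)
        i2 = sc.render_frames(d2.frames.head(3), small_world_cfg)
        assert np.array_equal(i1, i2)

    def test_fixed_sites_have_sevenfold_per_site_volume(self):
        cfg = us.default_campaign(seed=0)
        per_site = {}
        for site in cfg.sites:
            per_site.setdefault(site.deployment, []).append(
                len(sc._frame_times(site, cfg)) * site.camera_count
            )
        ratio = np.mean(per_site["fixed"]) / np.mean(per_site["rotating"])
        assert 7.0 * 0.8 <= ratio <= 7.0 * 1.2

    def test_default_world_site_census(self):
        cfg = us.default_campaign(seed=0)
        dep = pd.Series([s.deployment for s in cfg.sites]).value_counts()
        assert dep["fixed"] == 10 and dep["rotating"] == 135
        assert {s.land_use for s in cfg.sites} == set(sc.LAND_USES)
        for s in cfg.sites:
            if s.deployment == "fixed":
                assert (s.end - s.start).days >= 365
            else:
                assert (s.end - s.start).days == 7

    def test_image_interval_must_be_multiple_of_pollution_interval(self):
        with pytest.raises(sc.ConfigurationError):
            quiet_config(image_interval=90, pollution_interval=60)
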