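import numpy as np
import pandas as pd
import pytest

import urbansense as us


@pytest.fixture(scope="session")
def small_world_cfg():
    """Two fixed + three rotating sites, one clock failure, tiny volumes."""
    return us.make_world(
        n_fixed=2, n_rotating=3, seed=7,
        fixed_recording_days=2, rotating_recording_days=1, n_clock_failures=1,
    )


@pytest.fixture(scope="session")
def small_world(small_world_cfg):
    data, records = us.prepare_records(small_world_cfg)
    return small_world_cfg, data, records


@pytest.fixture(scope="session")
def single_site():
    """One fixed site, ~1,500 records: the same-site (1a) workhorse."""
    cfg = us.make_world(
        n_fixed=1, n_rotating=0, seed=11, fixed_recording_days=3, n_clock_failures=0
    )
    data, records = us.prepare_records(cfg)
    return cfg, data, records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def quiet_config(**overrides):
    """A campaign config with every stochastic effect switched off."""
    defaults = dict(
        sites=[],
        seed=0,
        noise_error_sd=0.0,
        regional_pm_sd=0.0,
        pm_ar1_sd=0.0,
        local_traffic_coeff=0.0,
        harmattan_pm_multiplier=1.0,
        measurement_dropout=0.0,
        corruption_rate=0.0,
    )
    defaults.update(overrides)
    return us.CampaignConfig(**defaults)


def make_site(site_id="s1", days=("2019-06-01",), clock_failed=False, **kw):
    import datetime as dt

    kw.setdefault("deployment", "fixed")
    kw.setdefault("land_use", "CBI")
    kw.setdefault("start", pd.Timestamp("2019-04-01"))
    kw.setdefault("end", pd.Timestamp("2020-06-30"))
    return us.SiteSpec(
        site_id=site_id,
        clock_failed=clock_failed,
        recording_days=tuple(dt.date.fromisoformat(d) for d in days),
        **kw,
    )
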