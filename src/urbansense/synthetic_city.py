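"""Synthetic street-level monitoring campaign generator.

Emulates a multi-site urban pollution monitoring campaign in a West African
city: fixed sites instrumented for 15 months and one-week rotating sites,
each producing time-lapsed street images (5-min cadence), co-located 1-min
noise (dBA) and PM2.5 (µg/m³) series, and per-image object counts.

The generative model plants the statistical structure the downstream
analysis assumes:

* a nonnegative diurnal *activity* latent (human/traffic intensity, peak in
  the afternoon, trough at night) that drives both noise and object counts;
* log-normal PM2.5 composed of a site baseline, a shared day-level regional
  effect, a Harmattan-season (Nov-Feb) multiplier, a local-traffic term
  proportional to activity, and AR(1) log-noise;
* rendered frames in which objects appear as coloured rectangles and PM2.5
  is visually encoded as a red tint (with matched blue decrease), blur and
  contrast compression — the haze/reddening signature of Harmattan dust;
* realistic data pathologies: camera clocks resetting to a January-2017
  factory default, sensor dropout, and a small fraction of corrupted files.

All randomness flows from ``CampaignConfig.seed``; generation is
reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "OBJECT_CATEGORIES",
    "SPARSE_CATEGORIES",
    "RETAINED_CATEGORIES",
    "SiteSpec",
    "CampaignConfig",
    "CampaignData",
    "ConfigurationError",
    "is_day",
    "is_harmattan",
    "activity_profile",
    "make_day_effects",
    "simulate_pollution",
    "simulate_counts",
    "render_frame",
    "render_frames",
    "corrupt_campaign",
    "generate_campaign",
    "write_campaign",
    "default_campaign",
    "make_world",
]

# ---------------------------------------------------------------------------
# Object vocabulary
# ---------------------------------------------------------------------------

#: The 20 time-varying object categories detected in street scenes.
OBJECT_CATEGORIES: tuple[str, ...] = (
    "person",
    "market_vendor",
    "car",
    "taxi",
    "pickup_truck",
    "bus",
    "lorry",
    "van",
    "tro_tro",
    "motorcycle",
    "bicycle",
    "market_stall",
    "loudspeaker",
    "umbrella",
    "cookstove",
    "cooking_pot",
    "food",
    "trash",
    "debris",
    "animal",
)

#: Categories too sparse to be usable as model features (near-absent in the
#: emulated detector output); excluded from analysis feature vectors.
SPARSE_CATEGORIES: tuple[str, ...] = ("cookstove", "loudspeaker", "market_vendor", "bus")

#: The 16 categories retained as model features.
RETAINED_CATEGORIES: tuple[str, ...] = tuple(
    c for c in OBJECT_CATEGORIES if c not in SPARSE_CATEGORIES
)

LAND_USES: tuple[str, ...] = ("CBI", "informal", "formal", "other")

#: Factory-default epoch that failed camera clocks reset to.
CLOCK_RESET_EPOCH = pd.Timestamp("2017-01-01T00:00:00")


class ConfigurationError(ValueError):
    """Raised when a campaign configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteSpec:
    """One monitoring site and its deployment window.

    ``baseline_noise`` (dBA) and ``baseline_pm_log`` (log µg/m³) set the
    site's quiet-hour levels; ``activity_amplitude`` scales the diurnal
    latent.  ``recording_days`` optionally restricts frame/pollution
    generation to a subset of days inside the deployment window (the scaled
    default world records a few days per site so the full campaign generates
    quickly); ``None`` records every day.
    """

    site_id: str
    deployment: str  # "fixed" | "rotating"
    land_use: str
    start: pd.Timestamp
    end: pd.Timestamp
    baseline_noise: float = 45.0
    baseline_pm_log: float = np.log(15.0)
    activity_amplitude: float = 1.0
    camera_count: int = 1
    clock_failed: bool = False
    recording_days: tuple[dt.date, ...] | None = None

    def __post_init__(self) -> None:
        if self.deployment not in ("fixed", "rotating"):
            raise ConfigurationError(f"unknown deployment {self.deployment!r}")
        if self.land_use not in LAND_USES:
            raise ConfigurationError(f"unknown land use {self.land_use!r}")
        if not self.end > self.start:
            raise ConfigurationError(f"site {self.site_id}: end must be after start")
        if self.camera_count not in (1, 2):
            raise ConfigurationError("camera_count must be 1 or 2")
        if self.activity_amplitude < 0:
            raise ConfigurationError("activity_amplitude must be >= 0")

    @property
    def cameras(self) -> tuple[str, ...]:
        return tuple(f"cam{i}" for i in range(1, self.camera_count + 1))

    def record_dates(self) -> list[dt.date]:
        """Dates on which this site records, in order."""
        if self.recording_days is not None:
            return sorted(self.recording_days)
        days = pd.date_range(self.start.normalize(), self.end.normalize(), freq="D")
        return [d.date() for d in days]


@dataclass
class CampaignConfig:
    """Full parameterisation of the synthetic world.

    Effect-size parameters
    ----------------------
    noise_coeff : dBA added per unit activity.
    local_traffic_coeff : log-PM2.5 added per unit activity.
    harmattan_pm_multiplier : multiplicative PM2.5 increase inside the
        Harmattan window (>1).
    regional_pm_sd : SD (log scale) of the day-level regional PM effect
        shared by all sites.
    red_tint_coeff : red-channel intensity added (blue subtracted) per unit
        log(PM2.5 / 10 µg/m³).
    haze_blur_coeff : Gaussian blur radius (pixels) per unit log PM2.5.
    contrast_coeff : contrast-compression strength per unit log PM2.5.
    object_rate_params : per category ``(a, b)`` of the log-linear Poisson
        rate ``exp(a + b * activity)``.
    """

    sites: list[SiteSpec] = field(default_factory=list)
    seed: int = 0
    image_size: int = 64
    image_interval: int = 300  # seconds between frames
    pollution_interval: int = 60  # seconds between pollution records
    harmattan_window: tuple[tuple[int, int], tuple[int, int]] = ((11, 1), (2, 28))
    harmattan_pm_multiplier: float = 2.5
    red_tint_coeff: float = 0.06
    haze_blur_coeff: float = 0.35
    contrast_coeff: float = 0.10
    object_rate_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_coeff: float = 12.0
    noise_error_sd: float = 1.5
    local_traffic_coeff: float = 0.45
    regional_pm_sd: float = 0.35
    pm_ar1_phi: float = 0.9
    pm_ar1_sd: float = 0.12
    night_visibility: float = 0.4
    detector_recall: float = 1.0
    measurement_dropout: float = 0.02
    corruption_rate: float = 0.005
    n_lamps: int = 3

    def __post_init__(self) -> None:
        for name in ("measurement_dropout", "corruption_rate", "detector_recall", "night_visibility"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.image_interval % self.pollution_interval != 0:
            raise ConfigurationError(
                "image_interval must be an integer multiple of pollution_interval"
            )
        if self.image_size <= 0:
            raise ConfigurationError("image_size must be positive")
        if self.harmattan_pm_multiplier <= 0:
            raise ConfigurationError("harmattan_pm_multiplier must be > 0")
        if not self.object_rate_params:
            self.object_rate_params = default_object_rates()
        unknown = set(self.object_rate_params) - set(OBJECT_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown object categories: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sites"] = [
            {
                **dataclasses.asdict(s),
                "start": str(s.start),
                "end": str(s.end),
                "recording_days": None
                if s.recording_days is None
                else [str(x) for x in s.recording_days],
            }
            for s in self.sites
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CampaignConfig":
        d = dict(d)
        sites = []
        for s in d.pop("sites", []):
            s = dict(s)
            s["start"] = pd.Timestamp(s["start"])
            s["end"] = pd.Timestamp(s["end"])
            if s.get("recording_days") is not None:
                s["recording_days"] = tuple(
                    dt.date.fromisoformat(x) for x in s["recording_days"]
                )
            sites.append(SiteSpec(**s))
        if "harmattan_window" in d:
            (m1, d1), (m2, d2) = d["harmattan_window"]
            d["harmattan_window"] = ((int(m1), int(d1)), (int(m2), int(d2)))
        if "object_rate_params" in d and d["object_rate_params"]:
            d["object_rate_params"] = {
                k: (float(a), float(b)) for k, (a, b) in d["object_rate_params"].items()
            }
        return cls(sites=sites, **d)


def default_object_rates() -> dict[str, tuple[float, float]]:
    """Log-linear Poisson rate parameters ``(a, b)`` per object category.

    Common street objects (cars, people, taxis, umbrellas, tro-tros) have
    the strongest activity coupling ``b``; the four sparse categories get a
    near-zero base rate so they are essentially absent, as in real detector
    output.
    """
    rates: dict[str, tuple[float, float]] = {
        "person": (0.6, 1.1),
        "car": (0.9, 0.9),
        "taxi": (0.0, 0.8),
        "umbrella": (-0.3, 0.7),
        "tro_tro": (-0.4, 0.6),
        "motorcycle": (-0.5, 0.5),
        "pickup_truck": (-0.8, 0.45),
        "van": (-0.9, 0.4),
        "lorry": (-1.1, 0.35),
        "bicycle": (-0.7, 0.3),
        "market_stall": (-0.4, 0.25),
        "cooking_pot": (-1.3, 0.2),
        "food": (-1.1, 0.15),
        "trash": (-0.9, 0.1),
        "debris": (-0.6, 0.1),
        "animal": (-1.6, 0.05),
    }
    for cat in SPARSE_CATEGORIES:
        rates[cat] = (-12.0, 0.0)
    return rates


@dataclass
class CampaignData:
    """In-memory result of a full campaign generation.

    ``frames`` has one row per (site, camera, frame time) with true and
    stamped timestamps, the relative PNG path, per-category true counts,
    the co-temporal true pollution values and a ``corrupted`` flag.
    ``pollution`` maps site_id to its (possibly corrupted) 1-min series.
    """

    config: CampaignConfig
    frames: pd.DataFrame
    pollution: dict[str, pd.DataFrame]
    logsheet: pd.DataFrame
    day_effects: pd.Series


# ---------------------------------------------------------------------------
# Deterministic clock rules
# ---------------------------------------------------------------------------


def is_day(times: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Day/night by fixed clock rule: 06:00 <= t < 18:00 is day."""
    hours = pd.DatetimeIndex(times).hour
    return np.asarray((hours >= 6) & (hours < 18))


def is_harmattan(
    times: pd.Series | pd.DatetimeIndex,
    window: tuple[tuple[int, int], tuple[int, int]] = ((11, 1), (2, 28)),
) -> np.ndarray:
    """True where the date falls inside the (year-wrapping) Harmattan window.

    Boundary dates are inclusive.
    """
    idx = pd.DatetimeIndex(times)
    md = idx.month * 100 + idx.day
    lo = window[0][0] * 100 + window[0][1]
    hi = window[1][0] * 100 + window[1][1]
    if lo <= hi:
        return np.asarray((md >= lo) & (md <= hi))
    return np.asarray((md >= lo) | (md <= hi))


def activity_profile(times: pd.DatetimeIndex, amplitude: float) -> np.ndarray:
    """Nonnegative diurnal activity latent.

    A raised-cosine with afternoon peak (15:00) and night trough (03:00),
    scaled by the site's amplitude; values in ``[0, amplitude]``.
    """
    h = times.hour + times.minute / 60.0 + times.second / 3600.0
    return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * (h - 3.0) / 24.0))


# ---------------------------------------------------------------------------
# Pollution simulation
# ---------------------------------------------------------------------------


def make_day_effects(
    start: pd.Timestamp, end: pd.Timestamp, cfg: CampaignConfig, rng: np.random.Generator
) -> pd.Series:
    """Shared day-level regional log-PM effects, N(0, regional_pm_sd) per date."""
    dates = pd.date_range(start.normalize(), end.normalize(), freq="D").date
    return pd.Series(rng.normal(0.0, cfg.regional_pm_sd, len(dates)), index=dates)


def simulate_pollution(
    site: SiteSpec,
    cfg: CampaignConfig,
    shared_day_effects: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate a site's co-located 1-min noise and PM2.5 series.

    Timestamps mark the end of each 1-min averaging window (the 00:00:00
    stamp closes the window ending at midnight).  Noise is the site
    baseline plus ``noise_coeff * activity(t)`` plus Gaussian error; PM2.5
    is log-normal with site baseline, shared day effect, Harmattan
    log-multiplier, local-traffic activity term and AR(1) log-noise.
    """
    times: list[pd.Timestamp] = []
    record_dates: list[dt.date] = []
    for date in site.record_dates():
        day0 = pd.Timestamp(date)
        n = 86400 // cfg.pollution_interval
        times.extend(day0 + pd.to_timedelta(np.arange(n) * cfg.pollution_interval, "s"))
        record_dates.extend([date] * n)
    idx = pd.DatetimeIndex(times)

    missing = set(record_dates) - set(shared_day_effects.index)
    if missing:
        raise ConfigurationError(
            f"site {site.site_id}: shared_day_effects missing dates {sorted(missing)[:3]}..."
        )

    act = activity_profile(idx, site.activity_amplitude)
    noise = site.baseline_noise + cfg.noise_coeff * act
    if cfg.noise_error_sd > 0:
        noise = noise + rng.normal(0.0, cfg.noise_error_sd, len(idx))

    day_eff = shared_day_effects.reindex(record_dates).to_numpy()
    harm = is_harmattan(idx, cfg.harmattan_window) * np.log(cfg.harmattan_pm_multiplier)
    ar = np.zeros(len(idx))
    if cfg.pm_ar1_sd > 0:
        innov = rng.normal(0.0, cfg.pm_ar1_sd * np.sqrt(1 - cfg.pm_ar1_phi**2), len(idx))
        innov[0] = rng.normal(0.0, cfg.pm_ar1_sd)
        for k in range(1, len(idx)):
            ar[k] = cfg.pm_ar1_phi * ar[k - 1] + innov[k]
        ar[0] = innov[0]
    pm25 = np.exp(site.baseline_pm_log + day_eff + harm + cfg.local_traffic_coeff * act + ar)

    return pd.DataFrame(
        {"timestamp": idx, "noise_dba": noise, "pm25_ugm3": pm25, "activity": act}
    )


# ---------------------------------------------------------------------------
# Object counts
# ---------------------------------------------------------------------------


def simulate_counts(
    activity: np.ndarray,
    cfg: CampaignConfig,
    daylight: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw per-frame object counts from log-linear Poisson rates.

    ``rate_o(t) = exp(a_o + b_o * activity(t)) * visibility(t) * recall``
    with ``visibility < 1`` at night (objects less detectable in the dark).
    """
    activity = np.asarray(activity, float)
    daylight = np.asarray(daylight, bool)
    vis = np.where(daylight, 1.0, cfg.night_visibility) * cfg.detector_recall
    out = {}
    for cat in OBJECT_CATEGORIES:
        a, b = cfg.object_rate_params.get(cat, (-np.inf, 0.0))  # unlisted => absent
        lam = np.exp(a + b * activity) * vis
        out[cat] = rng.poisson(lam)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

_OBJECT_COLORS: dict[str, tuple[float, float, float]] = {
    "person": (0.85, 0.55, 0.35),
    "market_vendor": (0.9, 0.6, 0.3),
    "car": (0.2, 0.3, 0.75),
    "taxi": (0.95, 0.8, 0.1),
    "pickup_truck": (0.5, 0.5, 0.55),
    "bus": (0.7, 0.2, 0.2),
    "lorry": (0.35, 0.45, 0.35),
    "van": (0.6, 0.6, 0.65),
    "tro_tro": (0.8, 0.75, 0.6),
    "motorcycle": (0.3, 0.2, 0.2),
    "bicycle": (0.25, 0.55, 0.45),
    "market_stall": (0.55, 0.3, 0.55),
    "loudspeaker": (0.1, 0.1, 0.1),
    "umbrella": (0.85, 0.25, 0.55),
    "cookstove": (0.4, 0.25, 0.15),
    "cooking_pot": (0.7, 0.7, 0.75),
    "food": (0.9, 0.7, 0.45),
    "trash": (0.35, 0.35, 0.25),
    "debris": (0.5, 0.42, 0.3),
    "animal": (0.65, 0.5, 0.3),
}

_OBJECT_SIZES: dict[str, int] = {  # half-width in 1/64 units of image size
    "person": 2, "market_vendor": 2, "car": 4, "taxi": 4, "pickup_truck": 4,
    "bus": 6, "lorry": 6, "van": 5, "tro_tro": 5, "motorcycle": 2,
    "bicycle": 2, "market_stall": 4, "loudspeaker": 1, "umbrella": 3,
    "cookstove": 1, "cooking_pot": 1, "food": 1, "trash": 2, "debris": 2,
    "animal": 2,
}

PM_REFERENCE = 10.0  # µg/m³; zero point of the visual tint encoding


def render_frame(
    counts: dict[str, int] | pd.Series,
    pm25: float,
    daylight: bool,
    cfg: CampaignConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one synthetic street frame, intensities in [0, 1].

    Background is a sky/ground gradient (dark with sparse bright lamps at
    night); each counted object adds one category-coloured rectangle at a
    random position.  PM2.5 is encoded as an additive red tint with matched
    blue decrease (per unit log(pm25/10)), plus Gaussian blur and contrast
    compression growing with log PM2.5 — the haze signature.
    """
    if pm25 <= 0:
        raise ValueError("pm25 must be positive")
    n = cfg.image_size
    if n <= 0:
        raise ConfigurationError("image_size must be positive")
    img = np.empty((n, n, 3), dtype=float)
    horizon = int(0.4 * n)
    rows = np.arange(n)[:, None]
    if daylight:
        sky = np.array([0.55, 0.70, 0.90])
        ground = np.array([0.45, 0.40, 0.33])
    else:
        sky = np.array([0.03, 0.03, 0.06])
        ground = np.array([0.06, 0.06, 0.07])
    for c in range(3):
        grad = np.where(
            rows < horizon,
            sky[c] * (1.0 - 0.3 * rows / max(horizon, 1)),
            ground[c] * (0.8 + 0.2 * (rows - horizon) / max(n - horizon, 1)),
        )
        img[:, :, c] = grad

    if not daylight:
        for _ in range(cfg.n_lamps):
            r = int(rng.integers(horizon, n - 2))
            cpos = int(rng.integers(1, n - 2))
            img[max(r - 1, 0) : r + 2, max(cpos - 1, 0) : cpos + 2] = (0.95, 0.88, 0.6)

    for cat in OBJECT_CATEGORIES:
        k = int(counts.get(cat, 0) if isinstance(counts, dict) else counts.get(cat, 0))
        color = np.array(_OBJECT_COLORS[cat])
        half = max(1, _OBJECT_SIZES[cat] * n // 64)
        shade = color if daylight else color * (0.35 + 0.4 * cfg.night_visibility)
        for _ in range(k):
            r = int(rng.integers(horizon, n - 1))
            cpos = int(rng.integers(0, n - 1))
            img[max(r - half, 0) : r + half, max(cpos - half, 0) : cpos + half] = shade

    d = np.log(pm25 / PM_REFERENCE)
    img[:, :, 0] += cfg.red_tint_coeff * d
    img[:, :, 2] -= cfg.red_tint_coeff * d

    haze = max(np.log(pm25), 0.0)
    if cfg.haze_blur_coeff > 0 and haze > 0:
        sigma = cfg.haze_blur_coeff * haze
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0), mode="nearest")
    if cfg.contrast_coeff > 0 and haze > 0:
        mean = img.mean()
        img = mean + (img - mean) / (1.0 + cfg.contrast_coeff * haze)

    return np.clip(img, 0.0, 1.0)


def render_frames(
    frames: pd.DataFrame, cfg: CampaignConfig, out_size: int | None = None
) -> np.ndarray:
    """Render an (N, H, W, 3) array for the given frame rows.

    Each frame gets an independent RNG stream derived from the campaign
    seed and the frame's global index, so rendering any subset reproduces
    the exact frames a full render would produce.
    """
    imgs = []
    for _, row in frames.iterrows():
        rng = _frame_rng(cfg.seed, int(row["frame_index"]))
        img = render_frame(
            {c: row[c] for c in OBJECT_CATEGORIES},
            float(row["pm25_true"]),
            bool(row["is_day"]),
            cfg,
            rng,
        )
        imgs.append(img)
    arr = np.stack(imgs) if imgs else np.zeros((0, cfg.image_size, cfg.image_size, 3))
    if out_size is not None and out_size != cfg.image_size:
        zoom = out_size / cfg.image_size
        arr = ndimage.zoom(arr, (1, zoom, zoom, 1), order=1)
    return arr


def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 7919, frame_index]))


# ---------------------------------------------------------------------------
# Campaign assembly and corruption
# ---------------------------------------------------------------------------


def _frame_times(site: SiteSpec, cfg: CampaignConfig) -> pd.DatetimeIndex:
    times: list[pd.Timestamp] = []
    for date in site.record_dates():
        day0 = pd.Timestamp(date)
        n = 86400 // cfg.image_interval
        times.extend(day0 + pd.to_timedelta(np.arange(n) * cfg.image_interval, "s"))
    return pd.DatetimeIndex(times)


def generate_campaign(cfg: CampaignConfig) -> CampaignData:
    """Generate the full campaign: pollution series, frames and counts.

    Frames are described (not yet rasterised) in ``CampaignData.frames``;
    use :func:`render_frames` or :func:`write_campaign` to rasterise.
    Corruption (clock resets, dropout, unreadable records) is applied by
    :func:`corrupt_campaign`.
    """
    if not cfg.sites:
        raise ConfigurationError("campaign has no sites")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    start = min(s.start for s in cfg.sites)
    end = max(s.end for s in cfg.sites)
    day_effects = make_day_effects(start, end, cfg, rng)

    pollution: dict[str, pd.DataFrame] = {}
    frame_parts: list[pd.DataFrame] = []
    log_rows = []
    frame_counter = 0
    for site in cfg.sites:
        site_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, _site_key(site)]))
        poll = simulate_pollution(site, cfg, day_effects, site_rng)
        pollution[site.site_id] = poll

        ftimes = _frame_times(site, cfg)
        act = activity_profile(ftimes, site.activity_amplitude)
        day = is_day(ftimes)
        # true pollution at frame instants, read off the 1-min series
        poll_at = poll.set_index("timestamp")
        aligned = poll_at.reindex(ftimes, method="nearest")
        for camera in site.cameras:
            cam_rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 3, _site_key(site), site.cameras.index(camera)])
            )
            counts = simulate_counts(act, cfg, day, cam_rng)
            part = pd.DataFrame(
                {
                    "site_id": site.site_id,
                    "camera_id": camera,
                    "true_time": ftimes,
                    "stamped_time": ftimes,
                    "is_day": day,
                    "is_harmattan": is_harmattan(ftimes, cfg.harmattan_window),
                    "land_use": site.land_use,
                    "pm25_true": aligned["pm25_ugm3"].to_numpy(),
                    "noise_true": aligned["noise_dba"].to_numpy(),
                    "activity": act,
                }
            )
            part = pd.concat([part.reset_index(drop=True), counts], axis=1)
            part["frame_index"] = np.arange(frame_counter, frame_counter + len(part))
            frame_counter += len(part)
            frame_parts.append(part)
            log_rows.append(
                {"site_id": site.site_id, "camera_id": camera, "start_time": ftimes[0]}
            )

    frames = pd.concat(frame_parts, ignore_index=True)
    frames["corrupted"] = False
    logsheet = pd.DataFrame(log_rows)
    data = CampaignData(
        config=cfg, frames=frames, pollution=pollution, logsheet=logsheet, day_effects=day_effects
    )
    return corrupt_campaign(data, cfg, np.random.default_rng(np.random.SeedSequence([cfg.seed, 4])))


def corrupt_campaign(
    data: CampaignData, cfg: CampaignConfig, rng: np.random.Generator
) -> CampaignData:
    """Apply the campaign's data pathologies in place and return it.

    Clock-failed sites have stamped times rewritten to the January-2017
    factory default plus a 5-minute grid; a ``measurement_dropout`` fraction
    of pollution rows is deleted; a ``corruption_rate`` fraction of frames
    and pollution rows is flagged corrupted (written as unreadable bytes /
    garbage fields by :func:`write_campaign`).  The logsheet retains every
    deployment's true start time.
    """
    frames = data.frames
    failed_sites = {s.site_id for s in cfg.sites if s.clock_failed}
    for (site_id, cam), grp in frames.groupby(["site_id", "camera_id"], sort=False):
        if site_id not in failed_sites:
            continue
        order = grp.sort_values("true_time").index
        k = np.arange(len(order))
        frames.loc[order, "stamped_time"] = CLOCK_RESET_EPOCH + pd.to_timedelta(
            k * (cfg.image_interval // 60), "m"
        )

    if cfg.corruption_rate > 0:
        mask = rng.random(len(frames)) < cfg.corruption_rate
        frames.loc[mask, "corrupted"] = True

    for site_id, poll in data.pollution.items():
        n = len(poll)
        keep = np.ones(n, bool)
        if cfg.measurement_dropout > 0:
            keep &= rng.random(n) >= cfg.measurement_dropout
        poll = poll.loc[keep].reset_index(drop=True)
        poll["corrupted"] = (
            rng.random(len(poll)) < cfg.corruption_rate if cfg.corruption_rate > 0 else False
        )
        data.pollution[site_id] = poll
    return data


def _site_key(site: SiteSpec) -> int:
    # stable across processes (unlike builtin str hash)
    return zlib.crc32(site.site_id.encode()) % (2**31)


# ---------------------------------------------------------------------------
# Disk layout
# ---------------------------------------------------------------------------


def frame_path(row: pd.Series) -> str:
    """Relative PNG path: <site>/<camera>/<stamped YYYYMMDDTHHMMSS>.png."""
    stamp = pd.Timestamp(row["stamped_time"]).strftime("%Y%m%dT%H%M%S")
    return f"{row['site_id']}/{row['camera_id']}/{stamp}.png"


def write_campaign(
    data: CampaignData, out_dir: str | Path, write_frames: bool = True
) -> dict[str, Path]:
    """Write the campaign to disk in the analysis' external layout.

    ``frames/<site>/<camera>/<stamp>.png`` (stamped, i.e. possibly wrong,
    clock), ``pollution/<site>.csv``, ``counts.csv`` (the emulated
    object-detector output, keyed by frame path), ``logsheet.csv`` and a
    ground-truth ``truth.csv`` for validation.  Corrupted frames are
    written as unreadable bytes; corrupted pollution rows as garbage fields.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    cfg = data.config
    (out / "pollution").mkdir(parents=True, exist_ok=True)
    frames = data.frames.copy()
    frames["path"] = [frame_path(r) for _, r in frames.iterrows()]

    if write_frames:
        imgs = render_frames(frames, cfg)
        for img, (_, row) in zip(imgs, frames.iterrows()):
            p = out / "frames" / row["path"]
            p.parent.mkdir(parents=True, exist_ok=True)
            if row["corrupted"]:
                p.write_bytes(b"\x00CORRUPTED" * 4)
            else:
                iio.imwrite(p, (img * 255).astype(np.uint8))

    for site_id, poll in data.pollution.items():
        dfp = poll.copy()
        dfp["timestamp"] = dfp["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        cols = ["timestamp", "noise_dba", "pm25_ugm3"]
        body = dfp[cols].astype(object)
        if "corrupted" in dfp:
            bad = dfp["corrupted"].to_numpy(bool)
            body.loc[bad, ["noise_dba", "pm25_ugm3"]] = "###"
        body.to_csv(out / "pollution" / f"{site_id}.csv", index=False)

    count_cols = ["path", "site_id", "camera_id", "stamped_time", *OBJECT_CATEGORIES]
    counts = frames[count_cols].copy()
    counts["stamped_time"] = pd.to_datetime(counts["stamped_time"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    counts.to_csv(out / "counts.csv", index=False)

    logsheet = data.logsheet.copy()
    logsheet["start_time"] = pd.to_datetime(logsheet["start_time"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    logsheet.to_csv(out / "logsheet.csv", index=False)

    truth_cols = [
        "path", "site_id", "camera_id", "true_time", "stamped_time",
        "pm25_true", "noise_true", "activity", "corrupted",
    ]
    frames[truth_cols].to_csv(out / "truth.csv", index=False)

    (out / "world.json").write_text(json.dumps(cfg.to_dict(), indent=1, default=str))
    return {
        "frames": out / "frames",
        "pollution": out / "pollution",
        "counts": out / "counts.csv",
        "logsheet": out / "logsheet.csv",
        "truth": out / "truth.csv",
    }


# ---------------------------------------------------------------------------
# World factories
# ---------------------------------------------------------------------------

_CAMPAIGN_START = pd.Timestamp("2019-04-01")
_CAMPAIGN_END = pd.Timestamp("2020-06-30")

_LAND_USE_BASELINES = {
    # (baseline noise dBA, baseline log-PM, activity amplitude)
    "CBI": (52.0, np.log(22.0), 1.4),
    "informal": (48.0, np.log(18.0), 1.1),
    "formal": (44.0, np.log(13.0), 0.8),
    "other": (40.0, np.log(10.0), 0.5),
}


def make_world(
    n_fixed: int = 10,
    n_rotating: int = 135,
    seed: int = 0,
    fixed_recording_days: int = 7,
    rotating_recording_days: int = 1,
    site_noise_sd: float = 3.0,
    site_pm_log_sd: float = 0.3,
    n_clock_failures: int = 2,
    **config_overrides,
) -> CampaignConfig:
    """Build a campaign configuration with heterogeneous sites.

    Fixed sites span the full 15-month campaign window (recording on
    ``fixed_recording_days`` evenly spaced days); rotating sites get 7-day
    windows tiled across the campaign (recording ``rotating_recording_days``
    of them).  The 7:1 default recording-day ratio reproduces the fixed
    sites' roughly seven-fold per-site data volume.  Site baselines are
    land-use level + seeded jitter (site heterogeneity drives the spatial
    generalisability results).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    sites: list[SiteSpec] = []
    land_cycle = list(LAND_USES)

    failure_ids = set(rng.choice(n_fixed, size=min(n_clock_failures, n_fixed), replace=False))
    for i in range(n_fixed):
        lu = land_cycle[i % len(land_cycle)]
        bn, bp, amp = _LAND_USE_BASELINES[lu]
        all_days = pd.date_range(_CAMPAIGN_START, _CAMPAIGN_END, freq="D")
        if i in failure_ids:
            # timestamp repair reconstructs a contiguous 5-min grid from the
            # deployment start, so failed cameras must record contiguously
            pick = np.arange(fixed_recording_days)
        else:
            pick = np.linspace(0, len(all_days) - 1, fixed_recording_days).round().astype(int)
        sites.append(
            SiteSpec(
                site_id=f"fixed_{i:02d}",
                deployment="fixed",
                land_use=lu,
                start=_CAMPAIGN_START,
                end=_CAMPAIGN_END,
                baseline_noise=bn + rng.normal(0, site_noise_sd),
                baseline_pm_log=bp + rng.normal(0, site_pm_log_sd),
                activity_amplitude=max(0.1, amp + rng.normal(0, 0.2)),
                camera_count=2 if i % 5 == 0 else 1,
                clock_failed=i in failure_ids,
                recording_days=tuple(all_days[pick].date),
            )
        )

    n_days_total = (_CAMPAIGN_END - _CAMPAIGN_START).days - 7
    for j in range(n_rotating):
        lu = land_cycle[j % len(land_cycle)]
        bn, bp, amp = _LAND_USE_BASELINES[lu]
        offset = int(round(j * n_days_total / max(n_rotating - 1, 1)))
        start = _CAMPAIGN_START + pd.Timedelta(days=offset)
        end = start + pd.Timedelta(days=7)
        days = pd.date_range(start, end - pd.Timedelta(days=1), freq="D")
        pick = np.linspace(0, len(days) - 1, rotating_recording_days).round().astype(int)
        sites.append(
            SiteSpec(
                site_id=f"rot_{j:03d}",
                deployment="rotating",
                land_use=lu,
                start=start,
                end=end,
                baseline_noise=bn + rng.normal(0, site_noise_sd),
                baseline_pm_log=bp + rng.normal(0, site_pm_log_sd),
                activity_amplitude=max(0.1, amp + rng.normal(0, 0.2)),
                camera_count=1,
                clock_failed=False,
                recording_days=tuple(days[pick].date),
            )
        )

    return CampaignConfig(sites=sites, seed=seed, **config_overrides)


def default_campaign(seed: int = 0) -> CampaignConfig:
    """The scaled default world: 10 fixed + 135 rotating sites."""
    return make_world(seed=seed)
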