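"""Timestamp repair, exclusion windows, and image-pollution pairing.

Turns raw campaign artifacts (frame listings with possibly-corrupted
stamped times, per-site 1-min pollution series, deployment log-sheets)
into the analysis Record table: one row per frame with its nearest-in-time
noise and PM2.5 values (within +/- 30 s), day/night and Harmattan flags,
land use, and the retained object-count features.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_city import (
    OBJECT_CATEGORIES,
    RETAINED_CATEGORIES,
    is_day,
    is_harmattan,
)

__all__ = [
    "IngestError",
    "repair_timestamps",
    "apply_exclusions",
    "pair_nearest",
    "merge_report",
    "build_records",
    "load_frames_dir",
    "load_pollution_dir",
    "load_counts_csv",
    "load_logsheet_csv",
    "DEFAULT_EXCLUSION_WINDOW",
    "PAIRING_TOLERANCE_S",
]

logger = logging.getLogger(__name__)

#: Pandemic-lockdown maintenance gap: data inside this closed window are excluded.
DEFAULT_EXCLUSION_WINDOW = (pd.Timestamp("2020-03-23"), pd.Timestamp("2020-05-11"))

#: Maximum |image time - pollution time| for a pairing, seconds (inclusive).
PAIRING_TOLERANCE_S = 30.0

#: Stamps earlier than this are taken as evidence of a factory clock reset
#: (cameras reset to January 2017, predating any deployment).
CLOCK_FAILURE_EPOCH = pd.Timestamp("2018-01-01")


class IngestError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Timestamp repair
# ---------------------------------------------------------------------------


def repair_timestamps(
    frames: pd.DataFrame,
    logsheet: pd.DataFrame,
    image_interval: int = 300,
) -> pd.DataFrame:
    """Correct stamped times of cameras whose clocks reset to the 2017 default.

    A camera is treated as clock-failed when its earliest stamped time
    predates :data:`CLOCK_FAILURE_EPOCH`.  Its k-th frame (0-based, sorted
    by stamped time) is re-stamped ``logsheet start + k * image_interval``;
    healthy cameras pass through unchanged.  Raises :class:`IngestError`
    naming the camera if a failed camera is absent from the log-sheet.
    """
    frames = frames.copy()
    frames["time"] = pd.to_datetime(frames["stamped_time"])
    starts = {
        (r["site_id"], r["camera_id"]): pd.Timestamp(r["start_time"])
        for _, r in logsheet.iterrows()
    }
    for (site_id, cam), grp in frames.groupby(["site_id", "camera_id"], sort=False):
        if grp["time"].min() >= CLOCK_FAILURE_EPOCH:
            continue
        if (site_id, cam) not in starts:
            raise IngestError(
                f"clock-failed camera ({site_id}, {cam}) missing from log-sheet"
            )
        order = grp.sort_values("time").index
        k = np.arange(len(order))
        frames.loc[order, "time"] = starts[(site_id, cam)] + pd.to_timedelta(
            k * image_interval, "s"
        )
    return frames


# ---------------------------------------------------------------------------
# Exclusion window
# ---------------------------------------------------------------------------


def apply_exclusions(
    records: pd.DataFrame,
    window: tuple[pd.Timestamp, pd.Timestamp] = DEFAULT_EXCLUSION_WINDOW,
    time_column: str = "time",
) -> pd.DataFrame:
    """Drop records whose *date* falls inside the closed exclusion window."""
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if hi < lo:
        raise ValueError(f"reversed exclusion window {window}")
    if len(records) == 0:
        return records.copy()
    dates = pd.to_datetime(records[time_column]).dt.normalize()
    inside = (dates >= lo.normalize()) & (dates <= hi.normalize())
    n_removed = int(inside.sum())
    if n_removed:
        logger.info("exclusion window removed %d records", n_removed)
    return records.loc[~inside].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Nearest-in-time pairing
# ---------------------------------------------------------------------------


def _match_nearest(
    frame_times: np.ndarray, poll_times: np.ndarray, tolerance_s: float
) -> np.ndarray:
    """Index of the nearest pollution row per frame (-1 = no match).

    Ties (equidistant rows, or exactly at tolerance) resolve to the earlier
    row, making the rule deterministic.
    """
    if len(poll_times) == 0:
        return np.full(len(frame_times), -1, dtype=np.int64)
    order = np.argsort(poll_times, kind="stable")
    pt = poll_times[order]
    pos = np.searchsorted(pt, frame_times)
    out = np.full(len(frame_times), -1, dtype=np.int64)
    tol = np.timedelta64(int(tolerance_s * 1e9), "ns")
    for i, (t, p) in enumerate(zip(frame_times, pos)):
        best = -1
        best_dt = None
        # candidate before (earlier first so it wins ties via strict '<')
        for j in (p - 1, p):
            if 0 <= j < len(pt):
                d = abs(t - pt[j])
                if d <= tol and (best_dt is None or d < best_dt):
                    best, best_dt = j, d
        out[i] = order[best] if best >= 0 else -1
    return out


def pair_nearest(
    frames: pd.DataFrame,
    pollution: dict[str, pd.DataFrame] | pd.DataFrame,
    tolerance: float = PAIRING_TOLERANCE_S,
) -> pd.DataFrame:
    """Assign each frame the nearest-in-time pollution values within tolerance.

    Noise and PM2.5 are matched independently (their valid rows can
    differ), so a frame may carry one, both, or neither value; unmatched
    targets are left missing.  Corrupted/unparseable pollution rows are
    skipped with a logged count.  Frames from two cameras at one site
    match against the same site series and hence receive the same values.
    """
    frames = frames.copy()
    frames["time"] = pd.to_datetime(frames["time"])
    frames["noise_dba"] = np.nan
    frames["pm25_ugm3"] = np.nan

    for site_id, grp in frames.groupby("site_id", sort=False):
        poll = pollution.get(site_id) if isinstance(pollution, dict) else pollution
        if poll is None or len(poll) == 0:
            continue
        poll = poll.copy()
        poll["timestamp"] = pd.to_datetime(poll["timestamp"], errors="coerce")
        n_bad = int(poll["timestamp"].isna().sum())
        for target in ("noise_dba", "pm25_ugm3"):
            vals = pd.to_numeric(poll[target], errors="coerce")
            valid = poll["timestamp"].notna() & vals.notna()
            skipped = int((~valid).sum()) - n_bad
            if skipped > 0 or n_bad > 0:
                logger.info(
                    "site %s %s: skipped %d unusable pollution rows",
                    site_id, target, skipped + n_bad,
                )
            pt = poll.loc[valid, "timestamp"].to_numpy()
            pv = vals.loc[valid].to_numpy()
            idx = _match_nearest(grp["time"].to_numpy(), pt, tolerance)
            matched = idx >= 0
            frames.loc[grp.index[matched], target] = pv[idx[matched]]
    return frames


def merge_report(records: pd.DataFrame) -> pd.DataFrame:
    """Per-site (and overall) fraction of frames with a matched value."""
    rows = []
    groups = list(records.groupby("site_id", sort=True))
    groups.append(("ALL", records))
    for site_id, grp in groups:
        rows.append(
            {
                "site_id": site_id,
                "n_frames": len(grp),
                "noise_match_rate": float(grp["noise_dba"].notna().mean()) if len(grp) else np.nan,
                "pm25_match_rate": float(grp["pm25_ugm3"].notna().mean()) if len(grp) else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Record assembly
# ---------------------------------------------------------------------------


def build_records(
    frames: pd.DataFrame,
    pollution: dict[str, pd.DataFrame],
    logsheet: pd.DataFrame,
    image_interval: int = 300,
    exclusion_window: tuple[pd.Timestamp, pd.Timestamp] | None = DEFAULT_EXCLUSION_WINDOW,
    tolerance: float = PAIRING_TOLERANCE_S,
    harmattan_window: tuple[tuple[int, int], tuple[int, int]] = ((11, 1), (2, 28)),
) -> pd.DataFrame:
    """Full ingest: repair -> exclude -> pair -> flag -> feature columns.

    Returns the analysis Record table with a unique ``record_id``,
    corrected ``time``, matched ``noise_dba``/``pm25_ugm3`` (missing where
    unmatched), ``is_day``/``is_harmattan`` flags and the 16 retained
    object-count columns (sparse categories dropped).
    """
    frames = frames.copy()
    if "corrupted" in frames.columns:
        n_corrupt = int(frames["corrupted"].sum())
        if n_corrupt:
            logger.info("skipping %d corrupted frames", n_corrupt)
        frames = frames.loc[~frames["corrupted"].astype(bool)].reset_index(drop=True)
    frames = repair_timestamps(frames, logsheet, image_interval)
    if exclusion_window is not None:
        frames = apply_exclusions(frames, exclusion_window)
        pollution = {
            s: apply_exclusions(p, exclusion_window, time_column="timestamp")
            for s, p in pollution.items()
        }
    records = pair_nearest(frames, pollution, tolerance)
    records["is_day"] = is_day(records["time"])
    records["is_harmattan"] = is_harmattan(records["time"], harmattan_window)
    records["record_id"] = [
        f"{r.site_id}|{r.camera_id}|{pd.Timestamp(r.time).isoformat()}"
        for r in records.itertuples()
    ]
    keep = [
        "record_id", "site_id", "camera_id", "time", "is_day", "is_harmattan",
        "noise_dba", "pm25_ugm3",
    ]
    for opt in ("land_use", "path", "frame_index", "pm25_true", "noise_true", "activity"):
        if opt in records.columns:
            keep.append(opt)
    keep += [c for c in RETAINED_CATEGORIES if c in records.columns]
    return records[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Disk loaders (external layout)
# ---------------------------------------------------------------------------

_STAMP_RE = re.compile(r"(\d{8}T\d{6})\.png$")


def load_frames_dir(frames_dir: str | Path, check_readable: bool = True) -> pd.DataFrame:
    """Scan ``<root>/<site>/<camera>/<YYYYMMDDTHHMMSS>.png`` into a frame table.

    Unreadable files (failed PNG decode) are flagged corrupted, never fatal.
    """
    import imageio.v3 as iio

    root = Path(frames_dir)
    rows = []
    for p in sorted(root.glob("*/*/*.png")):
        m = _STAMP_RE.search(p.name)
        if not m:
            continue
        corrupted = False
        if check_readable:
            try:
                iio.imread(p)
            except Exception:
                corrupted = True
        rows.append(
            {
                "site_id": p.parent.parent.name,
                "camera_id": p.parent.name,
                "stamped_time": pd.to_datetime(m.group(1), format="%Y%m%dT%H%M%S"),
                "path": str(p.relative_to(root)),
                "corrupted": corrupted,
            }
        )
    df = pd.DataFrame(rows)
    n_bad = int(df["corrupted"].sum()) if len(df) else 0
    if n_bad:
        logger.info("found %d unreadable frames", n_bad)
    return df


def load_pollution_dir(pollution_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read per-site ``<site>.csv`` pollution series (garbage rows retained
    as NaN; the pairing step skips them)."""
    out = {}
    for p in sorted(Path(pollution_dir).glob("*.csv")):
        df = pd.read_csv(p)
        df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
        for c in ("noise_dba", "pm25_ugm3"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
        out[p.stem] = df
    return out


def load_counts_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in OBJECT_CATEGORIES:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce").fillna(0).astype(int)
    df["stamped_time"] = pd.to_datetime(df["stamped_time"])
    return df


def load_logsheet_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["start_time"] = pd.to_datetime(df["start_time"])
    return df


@dataclass
class IngestResult:
    records: pd.DataFrame
    report: pd.DataFrame


def ingest_directory(
    root: str | Path,
    image_interval: int = 300,
    tolerance: float = PAIRING_TOLERANCE_S,
) -> IngestResult:
    """Ingest a generated campaign directory into a Record table."""
    root = Path(root)
    frames = load_frames_dir(root / "frames")
    counts = load_counts_csv(root / "counts.csv")
    frames = frames.merge(
        counts.drop(columns=["site_id", "camera_id", "stamped_time"]),
        on="path", how="left",
    )
    pollution = load_pollution_dir(root / "pollution")
    logsheet = load_logsheet_csv(root / "logsheet.csv")
    records = build_records(frames, pollution, logsheet, image_interval=image_interval,
                            tolerance=tolerance)
    return IngestResult(records=records, report=merge_report(records))
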