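"""Attribution analyses: permutation importance, object-pollution
correlations, their explained-variance linkage, and Harmattan pixel
features.

These reproduce the interpretability layer of the campaign analysis: which
objects drive the count-based model (permutation importance on the test
set), whether an object's importance tracks its raw rank correlation with
pollution (explained variance = squared Pearson correlation between the
two per-category vectors), and whether the image model can exploit the
Harmattan haze signature (red/blue channel means by day, grayscale
mean/SD by night, and their Spearman correlations with PM2.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import accuracy
from .synthetic_city import RETAINED_CATEGORIES

__all__ = [
    "ImportanceReport",
    "permutation_importance",
    "object_pollution_correlations",
    "explained_variance_link",
    "pixel_features",
    "harmattan_pixel_analysis",
    "plot_importances",
]

logger = logging.getLogger(__name__)

#: Pairwise count correlation above which the collinearity caveat is raised
#: (correlated objects share importance, deflating per-object scores).
COLLINEARITY_WARN = 0.8


@dataclass
class ImportanceReport:
    """Per-category permutation importance: accuracy drop after shuffling."""

    importances: dict[str, float]
    sds: dict[str, float]
    baseline_accuracy: float
    repetitions: int
    seed: int
    collinearity_warning: list = field(default_factory=list)

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.importances.items(), key=lambda kv: -kv[1])


def permutation_importance(
    model,
    features: pd.DataFrame,
    truths: np.ndarray,
    repetitions: int = 10,
    seed: int = 0,
) -> ImportanceReport:
    """Drop in test exact accuracy after shuffling each feature column.

    Each category's importance is the baseline accuracy minus the mean
    accuracy over ``repetitions`` seeded shuffles of that column (labels
    and all other columns fixed).  Negative values are reported as-is.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if len(features) == 0:
        raise ValueError("empty test set")
    truths = np.asarray(truths, int)
    cols = [c for c in features.columns if c in RETAINED_CATEGORIES] or list(features.columns)
    base, _ = accuracy(model.predict(features), truths)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    importances, sds = {}, {}
    for col in cols:
        drops = np.empty(repetitions)
        for r in range(repetitions):
            shuffled = features.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            acc, _ = accuracy(model.predict(shuffled), truths)
            drops[r] = base - acc
        importances[col] = float(drops.mean())
        sds[col] = float(drops.std(ddof=1)) if repetitions > 1 else 0.0

    warn = []
    corr = features[cols].corr().to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if np.isfinite(corr[i, j]) and abs(corr[i, j]) > COLLINEARITY_WARN:
                warn.append((cols[i], cols[j], float(corr[i, j])))
    if warn:
        logger.warning(
            "highly correlated feature pairs %s: importances may be shared/deflated", warn
        )
    return ImportanceReport(
        importances=importances, sds=sds, baseline_accuracy=base,
        repetitions=repetitions, seed=seed, collinearity_warning=warn,
    )


def object_pollution_correlations(
    records: pd.DataFrame,
    target: str = "noise_dba",
    min_records: int = 30,
) -> pd.DataFrame:
    """Per-site Spearman correlation between each object's counts and the
    continuous pollution value (average ranks for ties).

    Sites below ``min_records`` usable rows are skipped; zero-variance
    columns yield missing correlations.
    """
    rows = []
    for site_id, grp in records.groupby("site_id"):
        grp = grp.loc[grp[target].notna()]
        if len(grp) < min_records:
            continue
        y = grp[target].to_numpy(float)
        for cat in RETAINED_CATEGORIES:
            if cat not in grp.columns:
                continue
            x = grp[cat].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho = np.nan
            else:
                rho = stats.spearmanr(x, y).statistic
            rows.append({"site_id": site_id, "category": cat, "spearman": rho})
    return pd.DataFrame(rows)


def explained_variance_link(
    correlations: dict[str, float] | pd.Series,
    importances: dict[str, float] | pd.Series,
) -> float:
    """Squared Pearson correlation between per-category object-pollution
    correlations and permutation importances (NaN if undefined)."""
    corr = pd.Series(correlations, dtype=float)
    imp = pd.Series(importances, dtype=float)
    common = corr.index.intersection(imp.index)
    x = corr.loc[common].to_numpy()
    y = imp.loc[common].to_numpy()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 categories with both quantities")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector; explained variance undefined")
        return float("nan")
    r = stats.pearsonr(x, y).statistic
    return float(r**2)


# ---------------------------------------------------------------------------
# Pixel features (Harmattan haze signature)
# ---------------------------------------------------------------------------


def pixel_features(images: np.ndarray, records: pd.DataFrame) -> pd.DataFrame:
    """Per-record pixel features: RGB channel means for day frames,
    grayscale mean/SD for night frames (grayscale = channel mean).

    ``images`` aligns row-wise with ``records``; intensities in [0, 1].
    Day rows have missing grayscale features and vice versa.
    """
    if len(images) != len(records):
        raise ValueError("images and records must align")
    day = records["is_day"].to_numpy(bool)
    imgs = np.asarray(images, float)
    channel_means = imgs.mean(axis=(1, 2))  # (N, 3)
    gray = imgs.mean(axis=3)
    out = pd.DataFrame(
        {
            "record_id": records["record_id"].to_numpy()
            if "record_id" in records.columns
            else np.arange(len(records)),
            "site_id": records["site_id"].to_numpy(),
            "is_day": day,
            "is_harmattan": records["is_harmattan"].to_numpy(bool),
            "mean_red": np.where(day, channel_means[:, 0], np.nan),
            "mean_green": np.where(day, channel_means[:, 1], np.nan),
            "mean_blue": np.where(day, channel_means[:, 2], np.nan),
            "gray_mean": np.where(~day, gray.mean(axis=(1, 2)), np.nan),
            "gray_sd": np.where(~day, gray.std(axis=(1, 2)), np.nan),
        }
    )
    if "pm25_ugm3" in records.columns:
        out["pm25_ugm3"] = records["pm25_ugm3"].to_numpy(float)
    return out


def plot_importances(report: ImportanceReport, path=None, ax=None):
    """Horizontal bar chart of permutation importances with SD whiskers."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * len(report.importances) + 1))
    ranked = report.ranked()[::-1]
    names = [k for k, _ in ranked]
    vals = [v for _, v in ranked]
    errs = [report.sds[k] for k in names]
    ax.barh(names, vals, xerr=errs, color="#4878a8")
    ax.set_xlabel("permutation importance (drop in exact accuracy)")
    ax.axvline(0, color="k", lw=0.8)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=120)
        plt.close(ax.figure)
    return ax


_FEATURES_DAY = ("mean_red", "mean_blue")
_FEATURES_NIGHT = ("gray_mean", "gray_sd")


def harmattan_pixel_analysis(features: pd.DataFrame) -> dict:
    """Summarise the haze signature per site and on average.

    For each site: Harmattan minus non-Harmattan deltas of each pixel
    feature, and Spearman correlations of red/blue day means and night
    grayscale mean/SD with PM2.5.  The cross-site average is the
    unweighted mean over sites (a reporting convention; sites contribute
    equally regardless of record counts).
    """
    per_site = []
    for site_id, grp in features.groupby("site_id"):
        row: dict = {"site_id": site_id}
        for feat in (*_FEATURES_DAY, *_FEATURES_NIGHT):
            harm = grp.loc[grp["is_harmattan"], feat].dropna()
            non = grp.loc[~grp["is_harmattan"].astype(bool), feat].dropna()
            row[f"delta_{feat}"] = (
                float(harm.mean() - non.mean()) if len(harm) and len(non) else np.nan
            )
            if "pm25_ugm3" in grp.columns:
                sub = grp[[feat, "pm25_ugm3"]].dropna()
                row[f"rho_{feat}"] = (
                    float(stats.spearmanr(sub[feat], sub["pm25_ugm3"]).statistic)
                    if len(sub) >= 3 and np.ptp(sub[feat].to_numpy()) > 0
                    else np.nan
                )
        per_site.append(row)
    table = pd.DataFrame(per_site)
    summary = {"per_site": table}
    for col in table.columns:
        if col == "site_id":
            continue
        summary[f"mean_{col}"] = float(np.nanmean(table[col].to_numpy(float))) if len(table) else np.nan
    return summary
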