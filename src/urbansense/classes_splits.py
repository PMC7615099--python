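"""Ordinal pollution class schemes and experiment split plans.

The analysis frames pollution estimation as ordinal classification: noise
(dBA) into 10 classes and PM2.5 (µg/m³) into 11, with right-open interior
bins and open-ended extreme classes.  Five experimental designs probe
generalisability:

* 1a — same-site, different times (random 10% test within one fixed site);
* 1b — train at one fixed site, test at another's 1a test set;
* 2a — train on nine fixed sites, test on the held-out tenth;
* 2b — leave-sites-out 10-fold cross-validation over the rotating sites;
* 2c — few-sites/many-records vs many-sites/few-records on a shared test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClassScheme",
    "NOISE_SCHEME",
    "PM25_SCHEME",
    "scheme_for",
    "SplitPlan",
    "split_1a",
    "split_1b",
    "split_2a",
    "split_2b",
    "split_2c",
]


# ---------------------------------------------------------------------------
# Class schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassScheme:
    """Ordered bin edges mapping a continuous target to ordinal classes.

    ``edges`` are the interior boundaries; a value equal to an interior
    boundary joins the upper class (right-open bins).  The noise scheme's
    lowest class is "<= lower_closed" (values in the printed gap between
    39 and 40 dBA are closed upward into class 1).
    """

    target: str  # "noise" | "pm25"
    edges: tuple[float, ...]
    labels: tuple[str, ...]
    lower_closed: float | None = None  # bottom class is (-inf, lower_closed]

    def __post_init__(self) -> None:
        if list(self.edges) != sorted(self.edges) or len(set(self.edges)) != len(self.edges):
            raise ValueError("edges must be strictly increasing")
        if len(self.labels) != len(self.edges) + 1:
            raise ValueError("need len(edges) + 1 labels")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def bin(self, values) -> np.ndarray:
        """Map continuous values to 0-based class indices (vectorised)."""
        v = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if self.target == "pm25" and np.any(v < 0):
            raise ValueError("negative PM2.5 value")
        if self.lower_closed is not None:
            inner = np.asarray(self.edges[1:], dtype=float)
            idx = np.where(
                v <= self.lower_closed,
                0,
                1 + np.searchsorted(inner, v, side="right"),
            )
        else:
            idx = np.searchsorted(np.asarray(self.edges), v, side="right")
        return idx if idx.shape else int(idx)

    def class_distribution(self, labels: np.ndarray) -> np.ndarray:
        """Empirical distribution over the scheme's classes."""
        counts = np.bincount(np.asarray(labels, int), minlength=self.n_classes)
        return counts / counts.sum()


#: Noise (dBA), 10 classes: <=39, 40-<45, ..., 75-<80, >=80.
NOISE_SCHEME = ClassScheme(
    target="noise",
    edges=(39.0, 45.0, 50.0, 55.0, 60.0, 65.0, 70.0, 75.0, 80.0),
    labels=(
        "<=39", "40-<45", "45-<50", "50-<55", "55-<60",
        "60-<65", "65-<70", "70-<75", "75-<80", ">=80",
    ),
    lower_closed=39.0,
)

#: PM2.5 (µg/m³), 11 classes: 0-<5, ..., 100-<150, >=150.
PM25_SCHEME = ClassScheme(
    target="pm25",
    edges=(5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 100.0, 150.0),
    labels=(
        "0-<5", "5-<10", "10-<15", "15-<20", "20-<25", "25-<30",
        "30-<40", "40-<50", "50-<100", "100-<150", ">=150",
    ),
)


def scheme_for(target: str) -> ClassScheme:
    if target in ("noise", "noise_dba"):
        return NOISE_SCHEME
    if target in ("pm25", "pm25_ugm3"):
        return PM25_SCHEME
    raise ValueError(f"unknown target {target!r}")


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Assignment of record ids to train/val/test for one design question."""

    question: str
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    train_sites: list[str] = field(default_factory=list)
    test_sites: list[str] = field(default_factory=list)
    fold_index: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        a, b, c = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        if a & b or a & c or b & c:
            raise ValueError("train/val/test sets must be pairwise disjoint")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "question": self.question,
            "fold": self.fold_index,
            "train_ids": list(self.train_ids),
            "val_ids": list(self.val_ids),
            "test_ids": list(self.test_ids),
            "train_sites": list(self.train_sites),
            "test_sites": list(self.test_sites),
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SplitPlan":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            question=d["question"],
            train_ids=d["train_ids"],
            val_ids=d["val_ids"],
            test_ids=d["test_ids"],
            train_sites=d.get("train_sites", []),
            test_sites=d.get("test_sites", []),
            fold_index=d.get("fold"),
            seed=d.get("seed"),
        )


def _train_val(ids: np.ndarray, rng: np.random.Generator, val_frac: float = 0.25):
    """75/25 train/validation split of a training pool."""
    ids = np.asarray(ids)
    perm = rng.permutation(len(ids))
    n_val = int(round(val_frac * len(ids)))
    return ids[perm[n_val:]].tolist(), ids[perm[:n_val]].tolist()


def _usable(records: pd.DataFrame, target: str) -> pd.DataFrame:
    col = "noise_dba" if target.startswith("noise") else "pm25_ugm3"
    return records.loc[records[col].notna()]


def split_1a(
    records: pd.DataFrame, seed: int, target: str = "noise", test_frac: float = 0.10
) -> SplitPlan:
    """Same-site design: random 10% test, remainder split 75/25 train/val.

    The test draw is seeded per site (derived from ``seed`` and the site
    id) so that every design evaluating at this site — including the
    cross-site 1b runs — shares the identical test set.
    """
    records = _usable(records, target)
    sites = records["site_id"].unique()
    if len(sites) != 1:
        raise ValueError("split_1a needs records from exactly one site")
    if len(records) < 100:
        raise ValueError(f"too few records ({len(records)}) for a 1a split")
    site = str(sites[0])
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, hash_site(site)])
    )
    ids = records["record_id"].to_numpy()
    perm = rng.permutation(len(ids))
    n_test = int(round(test_frac * len(ids)))
    test = ids[perm[:n_test]]
    train, val = _train_val(ids[perm[n_test:]], rng)
    return SplitPlan(
        question="1a", train_ids=list(train), val_ids=list(val), test_ids=list(test),
        train_sites=[site], test_sites=[site], seed=seed,
    )


def hash_site(site_id: str) -> int:
    import zlib

    return zlib.crc32(site_id.encode()) % (2**31)


def split_1b(
    train_records: pd.DataFrame,
    test_records: pd.DataFrame,
    seed: int,
    target: str = "noise",
) -> SplitPlan:
    """Cross-site design: train at one fixed site, test on another site's
    1a test set (so same-site and cross-site accuracies are comparable)."""
    train_site = train_records["site_id"].unique()
    test_site = test_records["site_id"].unique()
    if len(train_site) != 1 or len(test_site) != 1:
        raise ValueError("split_1b needs single-site record sets")
    if train_site[0] == test_site[0]:
        raise ValueError("train and test sites identical; use split_1a")
    test_plan = split_1a(test_records, seed, target=target)
    pool = _usable(train_records, target)["record_id"].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, hash_site(str(train_site[0])), 1]))
    train, val = _train_val(pool, rng)
    return SplitPlan(
        question="1b", train_ids=train, val_ids=val, test_ids=list(test_plan.test_ids),
        train_sites=[str(train_site[0])], test_sites=[str(test_site[0])], seed=seed,
    )


def split_2a(
    records: pd.DataFrame, holdout_site: str, seed: int, target: str = "noise"
) -> SplitPlan:
    """Leave-one-fixed-site-out: train on the other nine (75/25), test on
    every record of the held-out site."""
    records = _usable(records, target)
    sites = set(records["site_id"].unique())
    if holdout_site not in sites:
        raise ValueError(f"holdout site {holdout_site!r} not among fixed sites")
    test = records.loc[records["site_id"] == holdout_site, "record_id"].to_numpy()
    pool = records.loc[records["site_id"] != holdout_site, "record_id"].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5, hash_site(holdout_site)]))
    train, val = _train_val(pool, rng)
    return SplitPlan(
        question="2a", train_ids=train, val_ids=val, test_ids=list(test),
        train_sites=sorted(sites - {holdout_site}), test_sites=[holdout_site], seed=seed,
    )


def split_2b(
    records: pd.DataFrame, n_folds: int = 10, seed: int = 0, target: str = "noise"
) -> list[SplitPlan]:
    """Leave-sites-out cross-validation over rotating sites.

    Sites (not records) are randomly partitioned into ``n_folds`` groups of
    near-equal size (13-14 for 135 sites); per fold the group's records are
    the test set and all other sites form the training pool (75/25
    train/val; model tuning may additionally cross-validate internally).
    """
    records = _usable(records, target)
    sites = np.array(sorted(records["site_id"].unique()))
    if len(sites) < n_folds:
        raise ValueError("fewer sites than folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    perm = rng.permutation(len(sites))
    groups = [sorted(sites[perm[i::n_folds]].tolist()) for i in range(n_folds)]
    plans = []
    for fold, test_sites in enumerate(groups):
        mask = records["site_id"].isin(test_sites)
        test = records.loc[mask, "record_id"].to_numpy()
        pool = records.loc[~mask, "record_id"].to_numpy()
        fold_rng = np.random.default_rng(np.random.SeedSequence([seed, 6, fold]))
        train, val = _train_val(pool, fold_rng)
        plans.append(
            SplitPlan(
                question="2b", train_ids=train, val_ids=val, test_ids=list(test),
                train_sites=sorted(set(sites) - set(test_sites)), test_sites=test_sites,
                fold_index=fold, seed=seed,
            )
        )
    return plans


def split_2c(
    fixed_records: pd.DataFrame,
    rotating_plan: SplitPlan,
    seed: int,
    target: str = "noise",
) -> tuple[SplitPlan, SplitPlan]:
    """Sampling-allocation comparison: two arms, one shared test set.

    Arm A trains on the fixed sites' abundant records (2a-style sampling);
    arm B is the given rotating-site fold plan (2b-style sampling).  Both
    are evaluated on the identical test set — the rotating fold's test
    records — so the comparison isolates the allocation of a fixed
    measurement budget.
    """
    fixed_records = _usable(fixed_records, target)
    test_sites = set(rotating_plan.test_sites)
    if test_sites & set(fixed_records["site_id"].unique()):
        raise ValueError("test sites overlap arm A training sites")
    pool = fixed_records["record_id"].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    train, val = _train_val(pool, rng)
    arm_a = SplitPlan(
        question="2c", train_ids=train, val_ids=val, test_ids=list(rotating_plan.test_ids),
        train_sites=sorted(fixed_records["site_id"].unique()),
        test_sites=sorted(test_sites), seed=seed,
    )
    arm_b = SplitPlan(
        question="2c", train_ids=list(rotating_plan.train_ids),
        val_ids=list(rotating_plan.val_ids), test_ids=list(rotating_plan.test_ids),
        train_sites=list(rotating_plan.train_sites), test_sites=sorted(test_sites),
        fold_index=rotating_plan.fold_index, seed=seed,
    )
    return arm_a, arm_b
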