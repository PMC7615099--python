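"""Classifier scoring: exact and ±1 accuracy, null benchmarks,
distribution-similarity and environmental stratifications.

The central comparison throughout is against a *null model* that knows
only the training-set class distribution: its expected exact accuracy
under marginal sampling is ``Σ_c p_train(c) p_test(c)`` (closed form), and
the modal variant always predicts the training modal class.  Train/test
distribution similarity is summarised by the Bhattacharyya coefficient
``Σ_c sqrt(p_c q_c)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classes_splits import ClassScheme, SplitPlan

__all__ = [
    "accuracy",
    "null_accuracy",
    "bhattacharyya",
    "EvalReport",
    "stratified_eval",
    "compare_2c",
]


def accuracy(predictions, truths) -> tuple[float, float]:
    """(exact, ±1) classification accuracy."""
    pred = np.asarray(predictions, int)
    true = np.asarray(truths, int)
    if len(pred) != len(true):
        raise ValueError("length mismatch")
    if len(pred) == 0:
        raise ValueError("empty input")
    exact = float((pred == true).mean())
    pm1 = float((np.abs(pred - true) <= 1).mean())
    return exact, pm1


def _distribution(labels: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(np.asarray(labels, int), minlength=n_classes)
    return counts / counts.sum()


def null_accuracy(
    train_labels,
    test_labels,
    n_classes: int,
    mode: str = "marginal_draw",
) -> tuple[float, float]:
    """Null-model (exact, ±1) accuracy from the training class distribution.

    ``marginal_draw``: expected accuracy when each prediction is an
    independent draw from the training distribution — exact part
    ``Σ_c p_train(c) p_test(c)`` and ±1 part with the ``|i-j| <= 1``
    kernel, both in closed form.  ``modal``: always predict the training
    modal class.
    """
    train_labels = np.asarray(train_labels, int)
    test_labels = np.asarray(test_labels, int)
    if len(train_labels) == 0 or len(test_labels) == 0:
        raise ValueError("empty label set")
    p = _distribution(train_labels, n_classes)
    q = _distribution(test_labels, n_classes)
    if mode == "marginal_draw":
        exact = float(p @ q)
        kernel = np.abs(np.subtract.outer(np.arange(n_classes), np.arange(n_classes))) <= 1
        pm1 = float(p @ kernel @ q)
    elif mode == "modal":
        modal = int(p.argmax())
        exact = float(q[modal])
        pm1 = float(q[max(modal - 1, 0) : modal + 2].sum())
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    return exact, pm1


def bhattacharyya(p, q) -> float:
    """Bhattacharyya coefficient Σ_c sqrt(p_c q_c) of two class distributions.

    1 iff identical, 0 iff disjoint support.  Non-normalised inputs are
    normalised with a warning.
    """
    import logging

    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("distributions must share a class scheme")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-8:
            logging.getLogger(__name__).warning("normalising non-normalised %s", name)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sqrt(p * q).sum())


# ---------------------------------------------------------------------------
# Stratified evaluation
# ---------------------------------------------------------------------------

_STRATA = (
    ("day", lambda df: df["is_day"]),
    ("night", lambda df: ~df["is_day"].astype(bool)),
    ("harmattan", lambda df: df["is_harmattan"]),
    ("non_harmattan", lambda df: ~df["is_harmattan"].astype(bool)),
)


@dataclass
class EvalReport:
    """Scored evaluation of one model on one split plan."""

    question: str
    family: str
    target: str
    n_test: int
    exact_accuracy: float
    pm1_accuracy: float
    null_accuracy: float
    null_pm1_accuracy: float
    improvement: float  # exact - null
    bhattacharyya: float | None = None
    strata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def stratified_eval(
    predictions: np.ndarray,
    records: pd.DataFrame,
    plan: SplitPlan,
    scheme: ClassScheme,
    truths: np.ndarray,
    train_labels: np.ndarray,
    family: str = "gbm",
    null_mode: str = "marginal_draw",
) -> EvalReport:
    """Score predictions on a plan's test records with stratifications.

    ``records`` must be the test-record table aligned row-wise with
    ``predictions``/``truths`` and carry ``is_day``/``is_harmattan`` (and
    optionally ``land_use``) flags.  Per-stratum null baselines reuse the
    full training class distribution (the null model knows only training
    labels, never the stratum); empty strata report ``n=0`` with null
    accuracies, never an error.
    """
    predictions = np.asarray(predictions, int)
    truths = np.asarray(truths, int)
    if not (len(predictions) == len(truths) == len(records)):
        raise ValueError("predictions, truths and records must align")
    exact, pm1 = accuracy(predictions, truths)
    nexact, npm1 = null_accuracy(train_labels, truths, scheme.n_classes, null_mode)
    bc = bhattacharyya(
        _distribution(train_labels, scheme.n_classes),
        _distribution(truths, scheme.n_classes),
    )
    strata: dict[str, dict] = {}

    def add_stratum(name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask, bool)
        if mask.sum() == 0:
            strata[name] = {"n": 0, "exact": None, "pm1": None, "null": None}
            return
        e, p1 = accuracy(predictions[mask], truths[mask])
        ne, _ = null_accuracy(train_labels, truths[mask], scheme.n_classes, null_mode)
        strata[name] = {"n": int(mask.sum()), "exact": e, "pm1": p1, "null": ne}

    for name, fn in _STRATA:
        add_stratum(name, fn(records).to_numpy())
    if "land_use" in records.columns:
        for lu, grp in records.reset_index(drop=True).groupby("land_use"):
            add_stratum(f"land_use:{lu}", records.reset_index(drop=True).index.isin(grp.index))

    return EvalReport(
        question=plan.question,
        family=family,
        target=scheme.target,
        n_test=len(truths),
        exact_accuracy=exact,
        pm1_accuracy=pm1,
        null_accuracy=nexact,
        null_pm1_accuracy=npm1,
        improvement=exact - nexact,
        bhattacharyya=bc,
        strata=strata,
    )


# ---------------------------------------------------------------------------
# Question 2c: sampling-allocation comparison
# ---------------------------------------------------------------------------


def compare_2c(
    preds_few_sites: np.ndarray,
    preds_many_sites: np.ndarray,
    truths: np.ndarray,
    test_ids_a: list[str],
    test_ids_b: list[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Paired comparison of the two sampling arms on one shared test set.

    Returns the exact-accuracy difference (many-sites arm minus few-sites
    arm) with a seeded paired-bootstrap percentile interval over test
    records.
    """
    if list(test_ids_a) != list(test_ids_b):
        raise ValueError("the two arms must be evaluated on identical test sets")
    a = np.asarray(preds_few_sites, int)
    b = np.asarray(preds_many_sites, int)
    t = np.asarray(truths, int)
    if not (len(a) == len(b) == len(t)):
        raise ValueError("length mismatch")
    hit_a = (a == t).astype(float)
    hit_b = (b == t).astype(float)
    diff = float(hit_b.mean() - hit_a.mean())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    n = len(t)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        take = rng.integers(0, n, n)
        boots[i] = hit_b[take].mean() - hit_a[take].mean()
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return {
        "accuracy_few_sites_many_records": float(hit_a.mean()),
        "accuracy_many_sites_few_records": float(hit_b.mean()),
        "difference": diff,
        "bootstrap_interval": [float(lo), float(hi)],
        "n_test": n,
        "n_boot": n_boot,
    }
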