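"""End-to-end pipeline: generate -> ingest -> split -> train -> evaluate
-> interpret, for any of the five design questions, in one seeded run.

Every run is reproducible from (world config, train config, seed): the
manifest records config hashes, per-stage record counts and wall-clock, so
an experiment can be replayed exactly.  The GBM path is bit-deterministic;
the CNN path is deterministic in single-threaded execution.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classes_splits as cs
from . import evaluation as ev
from . import interpretation as interp
from . import models as md
from . import synthetic_city as sc
from .ingest_pairing import build_records

__all__ = ["RunManifest", "RunResult", "prepare_records", "run_question"]


@dataclass
class RunManifest:
    question: str
    seed: int
    config_hash: str
    stage_counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=1, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class RunResult:
    manifest: RunManifest
    reports: dict
    extras: dict = field(default_factory=dict)


def _hash_config(cfg: sc.CampaignConfig, train_cfg: md.TrainConfig) -> str:
    blob = json.dumps([cfg.to_dict(), train_cfg.__dict__], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def prepare_records(cfg: sc.CampaignConfig) -> tuple[sc.CampaignData, pd.DataFrame]:
    """Generate a campaign and ingest it into the Record table (in memory)."""
    data = sc.generate_campaign(cfg)
    records = build_records(
        data.frames,
        {k: v.copy() for k, v in data.pollution.items()},
        data.logsheet,
        image_interval=cfg.image_interval,
        harmattan_window=cfg.harmattan_window,
    )
    return data, records


def _target_column(target: str) -> str:
    return "noise_dba" if target.startswith("noise") else "pm25_ugm3"


def _labels(records: pd.DataFrame, target: str) -> pd.Series:
    scheme = cs.scheme_for(target)
    col = _target_column(target)
    usable = records.loc[records[col].notna()]
    return pd.Series(
        scheme.bin(usable[col].to_numpy()), index=usable["record_id"], name="label"
    )


def _features(records: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in sc.RETAINED_CATEGORIES if c in records.columns]
    return records.set_index("record_id")[cols]


def _images_for(
    ids: list[str], records: pd.DataFrame, data: sc.CampaignData, out_size: int | None = None
) -> dict[str, np.ndarray]:
    by_id = records.set_index("record_id")
    fidx = by_id.loc[ids, "frame_index"].to_numpy(int)
    frame_rows = data.frames.set_index("frame_index").loc[fidx].reset_index()
    imgs = sc.render_frames(frame_rows, data.config, out_size=out_size)
    return {rid: imgs[i].astype(np.float32) for i, rid in enumerate(ids)}


def _train_and_eval(
    family: str,
    plan: cs.SplitPlan,
    records: pd.DataFrame,
    data: sc.CampaignData,
    target: str,
    train_cfg: md.TrainConfig,
    null_mode: str = "marginal_draw",
):
    """Train one family on a plan and produce its stratified EvalReport."""
    scheme = cs.scheme_for(target)
    labels = _labels(records, target)
    by_id = records.set_index("record_id")
    test_records = by_id.loc[plan.test_ids].reset_index()
    truths = labels.loc[plan.test_ids].to_numpy(int)
    train_labels = labels.loc[plan.train_ids].to_numpy(int)

    import dataclasses as _dc

    cfg = _dc.replace(train_cfg, family=family)
    if family == "gbm":
        features = _features(records)
        model = md.train_gbm(features, labels, plan, cfg, n_classes=scheme.n_classes)
        preds = model.predict(features.loc[plan.test_ids])
    else:
        ids = list(plan.train_ids) + list(plan.val_ids) + list(plan.test_ids)
        images = _images_for(ids, records, data)
        model = md.train_cnn(images, labels.loc[ids], plan, cfg)
        test_imgs = np.stack([images[r] for r in plan.test_ids])
        preds = model.predict(test_imgs)
    report = ev.stratified_eval(
        preds, test_records, plan, scheme, truths, train_labels,
        family=family, null_mode=null_mode,
    )
    return model, preds, report


def run_question(
    question: str,
    world_cfg: sc.CampaignConfig,
    train_cfg: md.TrainConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    families: tuple[str, ...] = ("gbm", "cnn"),
    target: str = "noise",
    max_folds: int = 3,
    n_folds: int = 10,
    holdout_site: str | None = None,
) -> RunResult:
    """Execute one design question end to end for the requested families.

    Question semantics: 1a — same-site split at the best-covered fixed
    site; 1b — 1a models from every fixed site evaluated on every other
    fixed site's 1a test set (with Bhattacharyya similarity per pair);
    2a — leave-one-fixed-site-out; 2b — leave-sites-out folds over
    rotating sites (first ``max_folds`` folds); 2c — few-sites/many-records
    vs many-sites/few-records arms on a shared rotating test set.
    """
    train_cfg = train_cfg or md.TrainConfig(seed=seed)
    manifest = RunManifest(
        question=question, seed=seed, config_hash=_hash_config(world_cfg, train_cfg)
    )
    reports: dict = {}
    extras: dict = {}
    t0 = time.perf_counter()
    try:
        data, records = prepare_records(world_cfg)
    except Exception:
        manifest.failed_stage = "generate/ingest"
        raise
    manifest.stage_seconds["generate_ingest"] = round(time.perf_counter() - t0, 3)
    manifest.stage_counts["records"] = len(records)
    col = _target_column(target)
    usable = records.loc[records[col].notna()]
    manifest.stage_counts["records_with_target"] = len(usable)
    fixed_sites = sorted(
        {s.site_id for s in world_cfg.sites if s.deployment == "fixed"}
        & set(records["site_id"].unique())
    )
    rotating = records.loc[records["site_id"].str.startswith("rot")]

    t1 = time.perf_counter()
    try:
        if question == "1a":
            site = _busiest_site(usable, fixed_sites)
            site_records = records.loc[records["site_id"] == site]
            plan = cs.split_1a(site_records, seed, target=target)
            for fam in families:
                model, preds, rep = _train_and_eval(fam, plan, records, data, target, train_cfg)
                reports[fam] = rep
                if fam == "gbm":
                    extras.update(
                        _interpret_gbm(model, plan, records, target, seed)
                    )
                extras.setdefault("plans", {})[fam] = plan
            extras["pixel_summary"] = _pixel_summary(plan, records, data)
        elif question == "1b":
            reports["pairs"] = _run_1b(records, data, fixed_sites, target, train_cfg, seed, families)
        elif question == "2a":
            site = holdout_site or fixed_sites[0]
            plan = cs.split_2a(
                records.loc[records["site_id"].isin(fixed_sites)], site, seed, target=target
            )
            for fam in families:
                _, _, rep = _train_and_eval(fam, plan, records, data, target, train_cfg)
                reports[fam] = rep
        elif question == "2b":
            plans = cs.split_2b(rotating, n_folds=n_folds, seed=seed, target=target)[:max_folds]
            for fam in families:
                fold_reports = []
                for plan in plans:
                    _, _, rep = _train_and_eval(fam, plan, records, data, target, train_cfg)
                    fold_reports.append(rep)
                reports[fam] = fold_reports
        elif question == "2c":
            reports.update(
                _run_2c(records, data, fixed_sites, rotating, target, train_cfg, seed,
                        families, n_folds=n_folds)
            )
        else:
            raise ValueError(f"unknown question {question!r}")
    except Exception:
        manifest.failed_stage = manifest.failed_stage or f"question_{question}"
        manifest.stage_seconds["modelling"] = round(time.perf_counter() - t1, 3)
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            manifest.to_json(Path(out_dir) / "manifest.json")
        raise
    manifest.stage_seconds["modelling"] = round(time.perf_counter() - t1, 3)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, rep in reports.items():
            if isinstance(rep, ev.EvalReport):
                rep.to_json(out / f"report_{key}.json")
                manifest.outputs[key] = str(out / f"report_{key}.json")
            elif isinstance(rep, list):
                for r in rep:
                    r.to_json(out / f"report_{key}_fold{r.question}_{rep.index(r)}.json")
            elif isinstance(rep, pd.DataFrame):
                rep.to_csv(out / f"report_{key}.csv", index=False)
            elif isinstance(rep, dict):
                (out / f"report_{key}.json").write_text(json.dumps(rep, indent=1, default=str))
        manifest.to_json(out / "manifest.json")
    return RunResult(manifest=manifest, reports=reports, extras=extras)


def _busiest_site(usable: pd.DataFrame, fixed_sites: list[str]) -> str:
    counts = usable.loc[usable["site_id"].isin(fixed_sites), "site_id"].value_counts()
    if counts.empty:
        raise ValueError("no fixed-site records with the target present")
    return str(counts.index[0])


def _interpret_gbm(model, plan, records, target, seed) -> dict:
    features = _features(records)
    labels = _labels(records, target)
    imp = interp.permutation_importance(
        model, features.loc[plan.test_ids], labels.loc[plan.test_ids].to_numpy(int), seed=seed
    )
    site_records = records.loc[records["record_id"].isin(plan.train_ids + plan.test_ids)]
    corrs = interp.object_pollution_correlations(site_records, target=_target_column(target))
    link = np.nan
    if len(corrs):
        mean_corr = corrs.groupby("category")["spearman"].mean()
        try:
            link = interp.explained_variance_link(mean_corr.abs(), pd.Series(imp.importances))
        except ValueError:
            pass
    return {"importance": imp, "correlations": corrs, "explained_variance": link}


def _pixel_summary(plan, records, data) -> dict:
    by_id = records.set_index("record_id")
    ids = list(plan.test_ids)
    test_records = by_id.loc[ids].reset_index()
    images = _images_for(ids, records, data)
    arr = np.stack([images[r] for r in ids])
    feats = interp.pixel_features(arr, test_records)
    return interp.harmattan_pixel_analysis(feats)


def _run_1b(records, data, fixed_sites, target, train_cfg, seed, families) -> pd.DataFrame:
    """Train a 1a model per fixed site; evaluate on every site's 1a test set."""
    scheme = cs.scheme_for(target)
    labels = _labels(records, target)
    by_id = records.set_index("record_id")
    plans = {
        s: cs.split_1a(records.loc[records["site_id"] == s], seed, target=target)
        for s in fixed_sites
    }
    rows = []
    for fam in families:
        models = {}
        for s in fixed_sites:
            models[s], _, _ = _train_and_eval(fam, plans[s], records, data, target, train_cfg)
        for a in fixed_sites:
            train_dist = scheme.class_distribution(labels.loc[plans[a].train_ids].to_numpy(int))
            for b in fixed_sites:
                test_ids = plans[b].test_ids
                truths = labels.loc[test_ids].to_numpy(int)
                if fam == "gbm":
                    feats = _features(records).loc[test_ids]
                    preds = models[a].predict(feats)
                else:
                    images = _images_for(list(test_ids), records, data)
                    preds = models[a].predict(np.stack([images[r] for r in test_ids]))
                exact, pm1 = ev.accuracy(preds, truths)
                nexact, _ = ev.null_accuracy(
                    labels.loc[plans[a].train_ids].to_numpy(int), truths, scheme.n_classes
                )
                rows.append(
                    {
                        "family": fam, "train_site": a, "test_site": b,
                        "same_site": a == b, "exact": exact, "pm1": pm1,
                        "null": nexact, "improvement": exact - nexact,
                        "bhattacharyya": ev.bhattacharyya(
                            train_dist, scheme.class_distribution(truths)
                        ),
                        "n_test": len(truths),
                    }
                )
    return pd.DataFrame(rows)


def _run_2c(records, data, fixed_sites, rotating, target, train_cfg, seed, families,
            n_folds: int = 10) -> dict:
    fold_plan = cs.split_2b(rotating, n_folds=n_folds, seed=seed, target=target)[0]
    arm_a, arm_b = cs.split_2c(
        records.loc[records["site_id"].isin(fixed_sites)], fold_plan, seed, target=target
    )
    labels = _labels(records, target)
    out: dict = {}
    for fam in families:
        _, preds_a, rep_a = _train_and_eval(fam, arm_a, records, data, target, train_cfg)
        _, preds_b, rep_b = _train_and_eval(fam, arm_b, records, data, target, train_cfg)
        comparison = ev.compare_2c(
            preds_a, preds_b, labels.loc[arm_a.test_ids].to_numpy(int),
            arm_a.test_ids, arm_b.test_ids, seed=seed,
        )
        comparison["train_records_few_sites"] = len(arm_a.train_ids) + len(arm_a.val_ids)
        comparison["train_records_many_sites"] = len(arm_b.train_ids) + len(arm_b.val_ids)
        out[fam] = {
            "few_sites_report": rep_a, "many_sites_report": rep_b, "comparison": comparison,
        }
    return out
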