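"""End-to-end experiment orchestration.

``run_experiment`` wires the stages together: simulate (or ingest) a
dataset, preprocess it, train one model per requested metadata condition,
evaluate and statistically compare the conditions, and run the Monte
Carlo-dropout reliability analysis on the last condition.  Every artifact
and every seed is recorded in a JSON manifest, so a run is reproducible
from its config alone.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .evaluate import compare_models, evaluate_reconstructions
from .io import RunConfig, read_dataset, write_dataset
from .model import ModelConfig, build_model, predict, train
from .preprocess import FEATURE_ORDER, make_pairs, stack_pairs
from .synth import ParameterError
from .uncertainty import (mc_predict, normalize_std, predictive_std,
                          quantile_error_table, relative_error,
                          uncertainty_error_correlation)

#: named metadata conditions mirroring the single / pairwise / full setups
CONDITIONS: dict[str, tuple[str, ...]] = {
    "none": (),
    "raxis": ("RAxis",),
    "taxis": ("TAxis",),
    "qrsduration": ("QRSDuration",),
    "ventricularrate": ("VentricularRate",),
    "qrscount": ("QRSCount",),
    "raxis+qrsduration": ("RAxis", "QRSDuration"),
    "all": FEATURE_ORDER,
}


def _pairs_by_split(pairs):
    return {s: [p for p in pairs if p.split == s] for s in ("train", "val", "test")}


def run_experiment(config: RunConfig, data_dir: str | Path | None = None) -> Path:
    """Run the full pipeline; returns the artifact directory.

    ``data_dir`` ingests an existing dataset directory instead of
    simulating one.  Raises with the failing stage's name on error; the
    manifest written so far is preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(config.__dict__, default=list)),
                      "stages": {}, "reports": {}}
    manifest_path = out / "manifest.json"

    def stage(name):
        t0 = time.time()

        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 2), **info}
            manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

        return done

    try:
        finish = stage("data")
        if data_dir is None:
            records, split = synth.generate_dataset(
                config.n_records, seed=config.data_seed,
                stratified=config.stratified)
            write_dataset(records, split, out / "data")
        else:
            records, split = read_dataset(data_dir)
        counts = {s: sum(1 for v in split.values() if v == s)
                  for s in ("train", "val", "test")}
        finish(n_records=len(records), split_counts=counts)

        reports = {}
        trained = {}
        for cond in config.conditions:
            if cond not in CONDITIONS:
                raise ParameterError(
                    f"unknown condition {cond!r}; pick from {sorted(CONDITIONS)}")
            finish = stage(f"train[{cond}]")
            feats = CONDITIONS[cond]
            pairs = _pairs_by_split(make_pairs(records, split, feats))
            d = pairs["train"][0].onehot.size
            cfg = ModelConfig(bilstm_units=config.bilstm_units,
                              epochs=config.epochs,
                              batch_size=config.batch_size,
                              learning_rate=config.learning_rate,
                              seed=config.model_seed)
            model = build_model(config.arch, cfg, d)
            train(model, stack_pairs(pairs["train"]), stack_pairs(pairs["val"]), cfg)
            model.save(out / f"model_{cond}")
            xt, mt, yt = stack_pairs(pairs["test"])
            preds = predict(model, xt, mt if d else None)
            rep = evaluate_reconstructions(preds, yt, label=cond)
            reports[cond] = rep
            trained[cond] = (model, pairs)
            summ = rep.summary()
            finish(metadata_dim=d, best_epoch=model.best_epoch,
                   best_val_loss=model.best_val_loss,
                   test_R=summ["R"][0], test_RMSE=summ["RMSE"][0],
                   test_SSIM=summ["SSIM"][0])
            manifest["reports"][cond] = {
                "R": summ["R"], "RMSE": summ["RMSE"], "SSIM": summ["SSIM"],
                "segments": rep.segments,
            }
        rows = [{"condition": c,
                 "R_mean": r.summary()["R"][0], "R_sd": r.summary()["R"][1],
                 "RMSE_mean": r.summary()["RMSE"][0], "RMSE_sd": r.summary()["RMSE"][1],
                 "SSIM_mean": r.summary()["SSIM"][0], "SSIM_sd": r.summary()["SSIM"][1],
                 **{f"seg_{k}": v for k, v in r.segments.items()}}
                for c, r in reports.items()]
        pd.DataFrame(rows).to_csv(out / "report.csv", index=False)

        if len(config.conditions) >= 2:
            finish = stage("compare")
            a, b = (reports[c] for c in config.conditions[:2])
            tests = compare_models(
                {"R": a.per_record_r, "RMSE": a.per_record_rmse,
                 "SSIM": a.per_record_ssim},
                {"R": b.per_record_r, "RMSE": b.per_record_rmse,
                 "SSIM": b.per_record_ssim},
                alpha=config.alpha)
            pd.DataFrame([t.__dict__ for t in tests]).to_csv(
                out / "comparison.csv", index=False)
            finish(tests={t.metric: t.p_adjusted for t in tests})

        finish = stage("uncertainty")
        cond = config.conditions[-1]
        model, pairs = trained[cond]
        profiles, errors = [], []
        for p in pairs["test"]:
            stack = mc_predict(model, p.lead1, p.onehot,
                               n_passes=config.mc_passes, seed=config.mc_seed)
            profiles.append(normalize_std(predictive_std(stack)))
            errors.append(relative_error(stack.mean, p.target,
                                         epsilon=config.epsilon))
        corr = uncertainty_error_correlation(profiles, errors)
        pd.DataFrame([corr]).to_csv(out / "uncertainty_correlation.csv", index=False)
        table = quantile_error_table(profiles, errors)
        pd.DataFrame(table).to_csv(out / "uncertainty_quartiles.csv", index=False)
        finish(condition=cond, min_lead_corr=min(corr.values()),
               q1=table[0]["mean_error"], q4=table[-1]["mean_error"])
    except Exception as err:  # annotate the failing stage, keep the manifest
        pending = [s for s in ("data", "train", "compare", "uncertainty")
                   if not any(k.startswith(s) for k in manifest["stages"])]
        manifest["failed"] = {"error": str(err),
                              "pending_stages": pending}
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return out
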