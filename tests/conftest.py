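"""Shared fixtures.

The expensive artifacts — the 500-record study dataset, the six trained
models of the metadata-benefit experiment, the Monte Carlo reliability
profiles and the copy-task model — are session-scoped so the model,
uncertainty and acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import leadrecon as lr
from leadrecon.model import ModelConfig, build_dual_branch, train, predict
from leadrecon.preprocess import make_pairs, stack_pairs
from leadrecon.uncertainty import (mc_predict, normalize_std, predictive_std,
                                   relative_error)

STUDY_N = 500
STUDY_DATA_SEED = 101
STUDY_MODEL_SEEDS = (0, 1, 2)


def pairs_by_split(pairs):
    return {s: [p for p in pairs if p.split == s] for s in ("train", "val", "test")}


@pytest.fixture(scope="session")
def study_dataset():
    """500 synthetic records with the default population sampler, split 70/15/15."""
    records, split = lr.generate_dataset(STUDY_N, seed=STUDY_DATA_SEED)
    return records, split


@pytest.fixture(scope="session")
def study_pairs(study_dataset):
    records, split = study_dataset
    return {
        "all": pairs_by_split(make_pairs(records, split)),
        "none": pairs_by_split(make_pairs(records, split, selected_features=())),
    }


def _train_condition(pairs, metadata_dim, seed):
    cfg = ModelConfig(bilstm_units=64, epochs=10, seed=seed,
                      validation_interval_epochs=20)
    model = build_dual_branch(cfg, metadata_dim)
    train(model, stack_pairs(pairs["train"]), stack_pairs(pairs["val"]), cfg)
    return model


def _mean_test_r(model, pairs, metadata_dim):
    from leadrecon.evaluate import pearson_r

    x, m, y = stack_pairs(pairs["test"])
    preds = predict(model, x, m if metadata_dim else None)
    per_record = [
        float(np.nanmean([pearson_r(preds[i, j], y[i, j]) for j in range(11)]))
        for i in range(preds.shape[0])
    ]
    return float(np.mean(per_record))


@pytest.fixture(scope="session")
def study_models(study_pairs):
    """Dual-branch models with/without metadata over three seeds, plus test R."""
    out = {"r_all": [], "r_none": [], "models_all": []}
    for seed in STUDY_MODEL_SEEDS:
        m_all = _train_condition(study_pairs["all"], 16, seed)
        m_none = _train_condition(study_pairs["none"], 0, seed)
        out["models_all"].append(m_all)
        out["r_all"].append(_mean_test_r(m_all, study_pairs["all"], 16))
        out["r_none"].append(_mean_test_r(m_none, study_pairs["none"], 0))
    return out


@pytest.fixture(scope="session")
def study_uncertainty(study_models, study_pairs):
    """MC-dropout reliability profiles (N=100) on the seed-0 metadata model."""
    model = study_models["models_all"][0]
    profiles, errors = [], []
    for p in study_pairs["all"]["test"]:
        stack = mc_predict(model, p.lead1, p.onehot, n_passes=100, seed=7)
        profiles.append(normalize_std(predictive_std(stack)))
        errors.append(relative_error(stack.mean, p.target))
    return profiles, errors


@pytest.fixture(scope="session")
def copy_task_model():
    """Copy-task sanity model: 200 records, targets = Lead I repeated 11x."""
    records, split = lr.generate_dataset(200, seed=55)
    pairs = make_pairs(records, split, selected_features=())
    x, m, _ = stack_pairs(pairs)
    y = np.repeat(x, 11, axis=1)
    tr = (x[:140], m[:140], y[:140])
    va = (x[140:170], m[140:170], y[140:170])
    te = (x[170:], m[170:], y[170:])
    cfg = ModelConfig(bilstm_units=32, epochs=10, seed=0, learning_rate=0.003,
                      batch_size=16, validation_interval_epochs=20)
    model = build_dual_branch(cfg, 0)
    train(model, tr, va, cfg)
    return model, tr, va, te
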