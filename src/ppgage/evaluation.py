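"""Fivefold cross-validation harness and the Table-1-style model comparison.

All models are compared on one shared fold assignment (a seeded shuffle with
round-robin assignment), so differences between rows reflect the models, not
the splits.  Metrics follow the standard definitions: MSE (years²), MAE
(years) and Spearman's rank correlation between predicted and true age; a
constant prediction vector has no rank ordering, so its rho is undefined and
reported as N/A.  Per-model, per-fold seeds are derived from the global seed
and a stable hash of the model specification, so two registered copies of the
same specification produce identical rows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .asi import extract_asi_table
from .models import (
    MeanAgeModel, LinearAsiModel, SplineGamModel,
    SmolkAgeModel, ResnetAgeModel, SmolkConfig, ResNetConfig, TrainConfig,
)
from .models.base import FitError

__all__ = ["FoldAssignment", "ModelSpec", "MetricsTable",
           "make_folds", "evaluate_predictions", "run_comparison"]


@dataclass(frozen=True)
class FoldAssignment:
    """Mapping subject_id -> fold index; folds partition the subjects."""

    assignment: dict
    k: int

    def fold_ids(self, fold: int):
        return [sid for sid, f in self.assignment.items() if f == fold]

    def sizes(self):
        counts = np.zeros(self.k, dtype=int)
        for f in self.assignment.values():
            counts[f] += 1
        return counts


def make_folds(subject_ids, k: int, seed: int) -> FoldAssignment:
    """Seeded uniform shuffle, then round-robin assignment to k folds."""
    subject_ids = list(subject_ids)
    n = len(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xF01D]))
    order = rng.permutation(n)
    assignment = {subject_ids[order[i]]: i % k for i in range(n)}
    return FoldAssignment(assignment=assignment, k=k)


def evaluate_predictions(y_true, y_pred) -> dict:
    """MSE, MAE and Spearman rho; rho is NaN for constant predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty validation set")
    err = y_pred - y_true
    out = {"mse": float(np.mean(err ** 2)), "mae": float(np.mean(np.abs(err)))}
    if np.ptp(y_pred) == 0.0:
        out["spearman_rho"] = np.nan  # undefined for a constant predictor
    else:
        rho = spearmanr(y_true, y_pred).statistic
        out["spearman_rho"] = float(rho)
    return out


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one comparison entry."""

    name: str
    kind: str                      # mean | linear | gam | smolk | resnet
    params: dict = field(default_factory=dict)

    def stable_hash(self) -> int:
        blob = json.dumps({"kind": self.kind, "params": self.params},
                          sort_keys=True).encode()
        return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") & 0x7FFFFFFF


DEFAULT_SPECS = (
    ModelSpec("mean_baseline", "mean"),
    ModelSpec("asi_linear", "linear"),
    ModelSpec("asi_gam", "gam"),
    ModelSpec("smolk", "smolk"),
    ModelSpec("resnet", "resnet"),
)


class MetricsTable:
    """Per-fold metrics plus the mean ± SD aggregate across folds."""

    def __init__(self, per_fold: pd.DataFrame, k: int, attrition: dict | None = None):
        self.per_fold = per_fold.reset_index(drop=True)
        self.k = k
        self.attrition = attrition or {}
        self.aggregate = self._aggregate()

    def _aggregate(self) -> pd.DataFrame:
        rows = []
        for name, grp in self.per_fold.groupby("model", sort=False):
            row = {"model": name, "n_folds": len(grp)}
            for metric in ("mse", "mae", "spearman_rho"):
                vals = grp[metric].to_numpy(dtype=float)
                if np.all(np.isnan(vals)):
                    row[f"{metric}_mean"] = np.nan
                    row[f"{metric}_sd"] = np.nan
                else:
                    row[f"{metric}_mean"] = float(np.nanmean(vals))
                    row[f"{metric}_sd"] = float(np.nanstd(vals, ddof=1)) if len(grp) > 1 else 0.0
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        def fmt(m, s):
            return "N/A" if np.isnan(m) else f"{m:.2f} ± {s:.2f}"

        lines = [f"{'Model':<16}{'MSE (years²)':>18}{'MAE (years)':>16}"
                 f"{'Spearman ρ':>14}", "-" * 64]
        for _, r in self.aggregate.iterrows():
            lines.append(f"{r['model']:<16}"
                         f"{fmt(r['mse_mean'], r['mse_sd']):>18}"
                         f"{fmt(r['mae_mean'], r['mae_sd']):>16}"
                         f"{fmt(r['spearman_rho_mean'], r['spearman_rho_sd']):>14}")
        if self.attrition:
            lines.append(f"(ASI extraction attrition: "
                         f"{self.attrition.get('rejected', 0)} of "
                         f"{self.attrition.get('total', 0)} waveforms rejected)")
        return "\n".join(lines)

    def mae(self, model: str) -> float:
        row = self.aggregate.loc[self.aggregate["model"] == model]
        return float(row["mae_mean"].iloc[0])

    def rho(self, model: str) -> float:
        row = self.aggregate.loc[self.aggregate["model"] == model]
        return float(row["spearman_rho_mean"].iloc[0])


def _fit_and_predict(spec: ModelSpec, ages_tr, asi_tr, wav_tr,
                     asi_val, wav_val, seed: int):
    params = dict(spec.params)
    train_params = params.pop("train", {})
    if spec.kind == "mean":
        res = MeanAgeModel(ages_tr).fit()
        return res.predict(asi_val if asi_val is not None else np.empty(0))
    if spec.kind == "linear":
        return LinearAsiModel(ages_tr, asi_tr).fit().predict(asi_val)
    if spec.kind == "gam":
        return SplineGamModel(ages_tr, asi_tr, **params).fit().predict(asi_val)
    if spec.kind in ("smolk", "resnet"):
        tc = TrainConfig(**{**train_params, "seed": seed})
        if spec.kind == "smolk":
            model = SmolkAgeModel(ages_tr, wav_tr,
                                  SmolkConfig(**params) if params else None)
        else:
            model = ResnetAgeModel(ages_tr, wav_tr,
                                   ResNetConfig(**params) if params else None)
        return model.fit(tc).predict(wav_val)
    raise ValueError(f"unknown model kind {spec.kind!r}")


def run_comparison(subjects, waveforms, specs=DEFAULT_SPECS, k: int = 5,
                   seed: int = 0) -> MetricsTable:
    """Fit every model spec under shared k-fold CV and tabulate the metrics.

    Waveforms whose ASI extraction is rejected are excluded from the
    comparison (all models see the same subjects); the attrition count is
    recorded on the returned table.  A fold where a model fails to fit is
    recorded with NaN metrics and the failure message.
    """
    asi_table = extract_asi_table(waveforms, subjects)
    accepted = asi_table.loc[asi_table["quality_flag"] != "rejected", "id"]
    accepted = set(accepted)
    attrition = {"total": len(waveforms), "rejected": len(waveforms) - len(accepted)}

    subj = [s for s in subjects if s.id in accepted]
    wave_by_id = {w.subject_id: w for w in waveforms}
    asi_by_id = dict(zip(asi_table["id"], asi_table["asi"]))
    ids = [s.id for s in subj]
    ages = np.array([s.age for s in subj])
    asi = np.array([asi_by_id[i] for i in ids])
    wav = np.stack([wave_by_id[i].samples for i in ids])

    folds = make_folds(ids, k=k, seed=seed)
    fold_of = np.array([folds.assignment[i] for i in ids])

    rows = []
    for spec in specs:
        for fold in range(k):
            val_mask = fold_of == fold
            tr_mask = ~val_mask
            assert not np.any(val_mask & tr_mask), "train/validation overlap"
            model_seed = int(np.random.SeedSequence(
                [seed & 0x7FFFFFFF, spec.stable_hash(), fold]
            ).generate_state(1)[0] & 0x7FFFFFFF)
            try:
                pred = _fit_and_predict(
                    spec, ages[tr_mask], asi[tr_mask], wav[tr_mask],
                    asi[val_mask], wav[val_mask], model_seed)
                metrics = evaluate_predictions(ages[val_mask], pred)
                note = ""
            except FitError as exc:
                metrics = {"mse": np.nan, "mae": np.nan, "spearman_rho": np.nan}
                note = f"fit failed: {exc}"
            rows.append({"model": spec.name, "fold": fold,
                         "n_val": int(val_mask.sum()), **metrics, "note": note})
    return MetricsTable(pd.DataFrame(rows), k=k, attrition=attrition)
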