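"""End-to-end pipeline: generate -> extract -> fit/evaluate -> analyze.

One configuration object drives the whole synthetic Table-1 analogue.  Every
artefact is written atomically, and a manifest records the seed, a hash of
the full configuration, package versions, per-stage timing and the ASI
extraction attrition, so a run can be audited and reproduced bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .asi import extract_asi_table
from .buckets import make_age_buckets
from .cohort import CohortConfig, generate_cohort
from .evaluation import ModelSpec, run_comparison
from .io import (atomic_write, write_cohort_csv, write_json_atomic,
                 write_waveforms_h5)
from .models import SmolkAgeModel, ResnetAgeModel, TrainConfig
from .morphology import cross_bucket_groups
from .projection import age_gradient_score, project

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_MODEL_SPECS = (
    {"name": "mean_baseline", "kind": "mean"},
    {"name": "asi_linear", "kind": "linear"},
    {"name": "asi_gam", "kind": "gam"},
    {"name": "smolk", "kind": "smolk"},
)


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    k_folds: int = 5
    seed: int = 0
    models: tuple = DEFAULT_MODEL_SPECS
    group_size: int = 6
    n_groups: int = 2
    projection_neighbors: int = 15
    projection_subsample: int = 2000

    def validate(self) -> "PipelineConfig":
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        self.cohort.validate()
        for spec in self.model_specs():
            if spec.kind not in ("mean", "linear", "gam", "smolk", "resnet"):
                raise ValueError(f"unknown model kind {spec.kind!r}")
        return self

    def model_specs(self):
        return [ModelSpec(name=m["name"], kind=m["kind"],
                          params=m.get("params", {})) for m in self.models]

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "k_folds": self.k_folds,
            "seed": self.seed,
            "models": [dict(m) for m in self.models],
            "group_size": self.group_size,
            "n_groups": self.n_groups,
            "projection_neighbors": self.projection_neighbors,
            "projection_subsample": self.projection_subsample,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort_dict = d.pop("cohort", {})
        if "seed" not in cohort_dict:
            cohort_dict["seed"] = d.get("seed", 0)
        models = tuple(d.pop("models", DEFAULT_MODEL_SPECS))
        return cls(cohort=CohortConfig.from_dict(cohort_dict),
                   models=models, **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _first_deep_spec(specs):
    for spec in specs:
        if spec.kind in ("smolk", "resnet"):
            return spec
    return None


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages, write artefacts under ``out_dir``, return the manifest.

    Stages: cohort generation, ASI extraction (with Fig.-3-style quantile
    summary), cross-validated model comparison, cross-bucket morphology
    groups, and the embedding projection with its age-gradient score.  A
    stage failure is recorded in the manifest (partial completion) and
    re-raised.
    """
    import os

    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": {"ppgage": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": [],
    }

    def stage(name):
        record = {"name": name, "status": "running", "seconds": None}
        manifest["stages"].append(record)
        return record, time.perf_counter()

    state = {}
    try:
        rec, t0 = stage("generate")
        subjects, waveforms = generate_cohort(config.cohort)
        write_cohort_csv(subjects, os.path.join(out_dir, "cohort.csv"))
        write_waveforms_h5(waveforms, os.path.join(out_dir, "waveforms.h5"))
        state.update(subjects=subjects, waveforms=waveforms)
        rec.update(status="complete", seconds=round(time.perf_counter() - t0, 3),
                   n_subjects=len(subjects))

        rec, t0 = stage("extract_asi")
        asi_table = extract_asi_table(waveforms, subjects)
        with atomic_write(os.path.join(out_dir, "asi.csv")) as fh:
            asi_table.to_csv(fh, index=False)
        from .asi import quantile_summary
        ages = np.array([s.age for s in subjects])
        qs = quantile_summary(asi_table["asi"].to_numpy(), ages,
                              age_range=config.cohort.age_range)
        with atomic_write(os.path.join(out_dir, "asi_quantiles.csv")) as fh:
            qs.to_csv(fh, index=False)
        n_rej = int((asi_table["quality_flag"] == "rejected").sum())
        rec.update(status="complete", seconds=round(time.perf_counter() - t0, 3),
                   attrition={"rejected": n_rej, "total": len(waveforms)})

        rec, t0 = stage("evaluate")
        table = run_comparison(subjects, waveforms, config.model_specs(),
                               k=config.k_folds, seed=config.seed)
        with atomic_write(os.path.join(out_dir, "metrics.csv")) as fh:
            table.aggregate.to_csv(fh, index=False)
        with atomic_write(os.path.join(out_dir, "metrics_per_fold.csv")) as fh:
            table.per_fold.to_csv(fh, index=False)
        state["metrics"] = table
        rec.update(status="complete", seconds=round(time.perf_counter() - t0, 3))

        rec, t0 = stage("morphology_groups")
        ids = [s.id for s in subjects]
        buckets = make_age_buckets(ages, ids, age_range=config.cohort.age_range)
        groups = cross_bucket_groups(waveforms, buckets,
                                     group_size=config.group_size,
                                     n_groups=config.n_groups)
        age_of = {s.id: s.age for s in subjects}
        payload = [{"member_ids": list(g.member_ids),
                    "ages": [age_of[m] for m in g.member_ids],
                    "source_buckets": list(g.source_buckets),
                    "intra_distance": g.intra_distance} for g in groups]
        write_json_atomic(payload, os.path.join(out_dir, "groups.json"))
        rec.update(status="complete", seconds=round(time.perf_counter() - t0, 3),
                   n_groups=len(groups))

        rec, t0 = stage("projection")
        deep_spec = _first_deep_spec(config.model_specs())
        if deep_spec is None:
            rec.update(status="skipped", seconds=0.0,
                       reason="no deep model in spec list")
        else:
            wav = np.stack([w.samples for w in waveforms])
            params = dict(deep_spec.params)
            train_params = params.pop("train", {})
            tc = TrainConfig(**{**train_params, "seed": config.seed})
            if deep_spec.kind == "smolk":
                from .models import SmolkConfig
                model = SmolkAgeModel(ages, wav,
                                      SmolkConfig(**params) if params else None)
            else:
                from .models import ResNetConfig
                model = ResnetAgeModel(ages, wav,
                                       ResNetConfig(**params) if params else None)
            fitted = model.fit(tc)
            emb = fitted.embed()
            sub = min(config.projection_subsample, emb.shape[0])
            rng = np.random.default_rng(np.random.SeedSequence(
                [config.seed & 0x7FFFFFFF, 0xBEEF]))
            keep = rng.choice(emb.shape[0], size=sub, replace=False)
            proj = project(emb[keep], seed=config.seed, ages=ages[keep],
                           n_neighbors=config.projection_neighbors)
            frame = pd.DataFrame({"id": np.asarray(ids)[keep],
                                  "x": proj.coords[:, 0],
                                  "y": proj.coords[:, 1],
                                  "age": ages[keep]})
            with atomic_write(os.path.join(out_dir, "projection.csv")) as fh:
                frame.to_csv(fh, index=False)
            rec.update(status="complete",
                       seconds=round(time.perf_counter() - t0, 3),
                       age_gradient_score=age_gradient_score(proj))
    except Exception as exc:
        for record in manifest["stages"]:
            if record["status"] == "running":
                record.update(status="failed", error=str(exc))
        write_json_atomic(manifest, os.path.join(out_dir, "manifest.json"))
        raise

    write_json_atomic(manifest, os.path.join(out_dir, "manifest.json"))
    return manifest
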