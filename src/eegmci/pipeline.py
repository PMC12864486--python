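"""End-to-end orchestration: simulate → preprocess → features → longitudinal
table → classification and group comparisons, with all artifacts written to a
run directory.

Every run writes its resolved configuration (plus a config hash) next to its
outputs; stage outputs are plain CSV/JSON so runs diff cleanly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .channels import CHANNELS
from .core import CohortDataset
from .errors import InvalidConfigError
from .features import FeatureConfig, extract_cohort_features
from .longitudinal import LongitudinalConfig, build_feature_table
from .modeling import (
    CLASSIFIER_NAMES,
    evaluate_classifiers,
    mann_whitney_map,
    summary_grid,
)
from .preprocess import PreprocessConfig, preprocess_epoch
from .synthetic import EffectSchedule, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one full run (YAML-serializable)."""

    seed: int = 0
    n_smci: int = 38
    n_pmci: int = 27
    timepoints: tuple[int, ...] = (1, 2, 3, 4)
    feature_timepoints: tuple[int, ...] = (1, 2, 3)
    fs: float = 250.0
    duration: float = 30.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    longitudinal: LongitudinalConfig = field(default_factory=LongitudinalConfig)
    k: int = 100
    folds: int = 5
    repeats: int = 10
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    compare_timepoints: tuple[int, ...] = (1, 3)

    def validate(self) -> None:
        self.preprocess.validate()
        if self.k < 1 or self.folds < 2 or self.repeats < 1:
            raise InvalidConfigError("k >= 1, folds >= 2 and repeats >= 1 required")
        if not set(self.feature_timepoints) <= set(self.timepoints):
            raise InvalidConfigError("feature_timepoints must be generated timepoints")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess"] = dataclasses.asdict(self.preprocess)
        d["features"] = dataclasses.asdict(self.features)
        d["longitudinal"] = dataclasses.asdict(self.longitudinal)
        return json.loads(json.dumps(d, default=list))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "preprocess" in kwargs:
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        if "features" in kwargs:
            fc = dict(kwargs["features"])
            fc.pop("welch", None)  # welch params keep their defaults in file round-trips
            kwargs["features"] = FeatureConfig(**fc)
        if "longitudinal" in kwargs:
            lc = dict(kwargs["longitudinal"])
            if "times_months" in lc and lc["times_months"] is not None:
                lc["times_months"] = tuple(lc["times_months"])
            kwargs["longitudinal"] = LongitudinalConfig(**lc)
        for key in ("timepoints", "feature_timepoints", "classifiers", "compare_timepoints"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def preprocess_cohort(cohort: CohortDataset, config: PreprocessConfig | None = None
                      ) -> CohortDataset:
    cfg = config or PreprocessConfig()
    return cohort.map_epochs(lambda ep: preprocess_epoch(ep, cfg))


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    schedule: EffectSchedule | None = None,
    cohort: CohortDataset | None = None,
) -> dict:
    """Execute the full analysis and write all artifacts under ``outdir``.

    Returns a summary dict (feature counts, per-classifier metric grid, paths).
    Deterministic given the config seed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    config.to_yaml(outdir / "resolved_config.yaml")
    stage_times: dict[str, float] = {}

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self

            def __exit__(self, *exc):
                stage_times[name] = round(time.perf_counter() - self.t0, 2)
                logger.info("stage %s finished in %.1f s", name, stage_times[name])

        return _Timer()

    with _stage("simulate"):
        if cohort is None:
            cohort = generate_cohort(
                schedule,
                n_smci=config.n_smci, n_pmci=config.n_pmci,
                timepoints=config.timepoints, fs=config.fs,
                duration=config.duration, seed=config.seed,
            )

    with _stage("preprocess"):
        clean = preprocess_cohort(cohort, config.preprocess)

    with _stage("features"):
        cross = extract_cohort_features(
            clean, timepoints=tuple(sorted(set(config.feature_timepoints)
                                           | set(config.compare_timepoints))),
            config=config.features,
        )
        feat_dir = outdir / "features"
        feat_dir.mkdir(exist_ok=True)
        for (sid, tp), row in cross.iterrows():
            row.drop("group").to_csv(feat_dir / f"{sid}_t{tp}.csv",
                                     header=["value"], index_label="feature")
        cross.to_csv(outdir / "cross_sectional_features.csv")

    with _stage("longitudinal"):
        table = build_feature_table(cross, timepoints=config.feature_timepoints,
                                    config=config.longitudinal)
        table.to_csv(outdir / "longitudinal_table.csv")

    with _stage("compare"):
        comparisons = {}
        for tp in config.compare_timepoints:
            sub = cross.xs(tp, level="timepoint")
            labels = (sub["group"] == "PMCI").astype(int).to_numpy()
            pmap = mann_whitney_map(sub.drop(columns=["group"]), labels)
            pmap.to_csv(outdir / f"mann_whitney_t{tp}.csv")
            comparisons[tp] = pmap

    with _stage("classify"):
        reports = evaluate_classifiers(
            table, classifiers=config.classifiers,
            folds=config.folds, repeats=config.repeats, k=config.k,
            seed=config.seed,
        )
        grid = summary_grid(reports)
        grid.to_csv(outdir / "classification_summary.csv")
        detail = {
            name: {
                "summary": rep.summary(),
                "scheme": rep.scheme,
            }
            for name, rep in reports.items()
        }

    n_features = cross.shape[1] - 1
    summary = {
        "config_hash": cfg_hash,
        "n_subjects": len(cohort),
        "n_cross_sectional_features": int(n_features),
        "n_longitudinal_features": int(table.shape[1] - 1),
        "n_complete_subjects": int(table.shape[0]),
        "stage_seconds": stage_times,
        "significant_fraction": {
            int(tp): float((pmap["p"] < 0.05).mean())
            for tp, pmap in comparisons.items()
        },
        "classification": detail,
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2, default=float))
    logger.info("pipeline finished: %d cross-sectional, %d longitudinal features",
                n_features, table.shape[1] - 1)
    summary["_tables"] = {"cross_sectional": cross, "longitudinal": table,
                          "grid": grid, "comparisons": comparisons}
    return summary
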