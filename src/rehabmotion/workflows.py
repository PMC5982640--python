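"""File-based pipeline functions tying the modules together.

These are the batch analogues of an interactive trainer/assessment loop:
``run_simulate`` writes a labelled synthetic cohort, ``run_train`` performs
leave-one-subject-out training and serializes one registry per subject,
``run_bic`` scans candidate state counts, and ``run_assess`` writes a JSON
assessment report for one trial. Every function is driven by a
:class:`RunConfig`, is reproducible (identical config + seed give identical
payloads) and echoes its numeric settings into the report for audit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .assessment import (
    AssessConfig, ModelRegistry, canonical_registry, classify_movement,
    loso_train,
)
from .features import FeatureSeries, assessment_preset, extract_features
from .hmm import bic_scan
from .skeleton import read_labels_csv, read_motion_csv
from .synth import generate_cohort

__all__ = ["RunConfig", "run_simulate", "run_features", "run_train",
           "run_bic", "run_assess", "OUTCOME_CODES"]

log = logging.getLogger("rehabmotion")

#: Outcome -> status code (scriptability contract: 0 good, 1 fair, 2 bad).
OUTCOME_CODES = {"good": 0, "fair": 1, "bad": 2}


@dataclass(frozen=True)
class RunConfig:
    """Settings shared by the pipeline stages."""

    data_dir: str = "cohort"
    models_dir: str = "models"
    reports_dir: str = "reports"
    seed: int = 0
    n_subjects: int = 9
    trials_per_subject: int = 8
    fault_rate: float = 0.25
    frame_rate: float = 60.0
    state_range: tuple[int, int] = (2, 6)
    n_folds: int = 3
    bic_entry: str = "V"
    assess: AssessConfig = field(default_factory=AssessConfig)

    def to_dict(self) -> dict:
        return asdict(self)


def run_simulate(config: RunConfig) -> Path:
    """Write a synthetic labelled cohort to ``config.data_dir``."""
    cohort = generate_cohort(config.n_subjects, config.trials_per_subject,
                             fault_rate=config.fault_rate, seed=config.seed,
                             frame_rate=config.frame_rate)
    out = cohort.write(config.data_dir)
    n_fault = sum(1 for t in cohort.trials if t.truth.faults)
    log.info("simulated %d trials (%d faulted) -> %s", len(cohort), n_fault, out)
    return out


def _load_cohort_features(config: RunConfig
                          ) -> dict[tuple[str, str], FeatureSeries]:
    data_dir = Path(config.data_dir)
    features = {}
    for path in sorted(data_dir.glob("*.csv")):
        if path.name == "labels.csv":
            continue
        seq = read_motion_csv(path, frame_rate=config.frame_rate)
        subject, _, trial = path.stem.split("_", 2)
        trial = trial.split("_")[-1]
        features[(subject, trial)] = extract_features(seq, assessment_preset())
    if not features:
        raise FileNotFoundError(f"no trial CSVs under {data_dir}")
    return features


def run_features(config: RunConfig, trial_path: str | Path) -> Path:
    """Extract the assessment feature set of one trial to a wide CSV."""
    trial_path = Path(trial_path)
    seq = read_motion_csv(trial_path, frame_rate=config.frame_rate)
    features = extract_features(seq, assessment_preset())
    reports_dir = Path(config.reports_dir)
    reports_dir.mkdir(parents=True, exist_ok=True)
    out = features.to_csv(reports_dir / f"features_{trial_path.stem}.csv")
    log.info("%s -> %d frames x %d channels", trial_path.stem,
             len(features), len(features.feature_names))
    return out


def run_train(config: RunConfig) -> dict[str, Path]:
    """Leave-one-subject-out training; one registry JSON per held-out subject."""
    labels_path = Path(config.data_dir) / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"missing labels file {labels_path}")
    labels = read_labels_csv(labels_path)
    features = _load_cohort_features(config)
    registries = loso_train(features, labels, canonical_registry(),
                            seed=config.seed, config=config.assess)
    models_dir = Path(config.models_dir)
    models_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for subject, reg in registries.items():
        paths[subject] = reg.save(models_dir / f"registry_{subject}.json")
    log.info("trained %d LOSO registries -> %s", len(paths), models_dir)
    return paths


def run_bic(config: RunConfig) -> Path:
    """Cross-validated BIC scan for one registry entry's feature set."""
    features = _load_cohort_features(config)
    entry = canonical_registry()[config.bic_entry]
    obs = [f.matrix(entry.feature_names) for f in features.values()]
    lo, hi = config.state_range
    table, best = bic_scan(obs, state_range=range(lo, hi + 1),
                           n_folds=config.n_folds, seed=config.seed)
    reports_dir = Path(config.reports_dir)
    reports_dir.mkdir(parents=True, exist_ok=True)
    out = reports_dir / f"bic_{config.bic_entry}.json"
    with open(out, "w") as fh:
        json.dump({"config": config.to_dict(),
                   "entry": config.bic_entry,
                   "table": table.to_dict(orient="records"),
                   "recommended_states": best}, fh, indent=1)
    log.info("BIC scan over states %d-%d: recommended %d", lo, hi, best)
    return out


def run_assess(config: RunConfig, trial_path: str | Path,
               registry: ModelRegistry | str | Path | None = None
               ) -> tuple[Path, int]:
    """Assess one trial CSV; returns (report path, status code 0/1/2)."""
    trial_path = Path(trial_path)
    seq = read_motion_csv(trial_path, frame_rate=config.frame_rate)
    features = extract_features(seq, assessment_preset())
    if registry is None:
        subject = trial_path.stem.split("_", 1)[0]
        registry = Path(config.models_dir) / f"registry_{subject}.json"
    if not isinstance(registry, ModelRegistry):
        registry = ModelRegistry.load(registry)
    assessment = classify_movement(registry, features, config.assess)
    reports_dir = Path(config.reports_dir)
    reports_dir.mkdir(parents=True, exist_ok=True)
    out = reports_dir / f"assessment_{trial_path.stem}.json"
    payload = {"config": config.to_dict(), "trial": trial_path.stem}
    payload.update(assessment.to_dict())
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=1)
    code = OUTCOME_CODES[assessment.outcome]
    log.info("%s -> %s (status %d)", trial_path.stem, assessment.outcome, code)
    return out, code
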