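"""Pipeline orchestration: simulate -> extract -> fit -> evaluate.

Every run writes its resolved configuration beside its artifacts and logs
per-stage timing and seeds; reruns with an identical config reproduce
identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from immunorad import evaluation, signature, synthetic
from immunorad.features import extract_all, feature_names
from immunorad.volumes import read_clinical_table, read_mask, read_volume

logger = logging.getLogger("immunorad.pipeline")


@dataclass
class PipelineConfig:
    cohort_dir: str = "cohort"
    output_dir: str = "run"
    simulate: bool = True
    n_patients: int = 30
    seed: int = 7
    hot_fraction: float = 0.5
    texture_effect: float = 2.0
    response_slope: float = 4.0
    n_bins: int = 64
    alpha: float = 0.2
    n_folds: int = 10
    label_definition: str = "immune_group:high"
    continuity_correction: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cohort_config(config: PipelineConfig) -> synthetic.CohortConfig:
    return synthetic.CohortConfig(
        n_patients=config.n_patients,
        seed=config.seed,
        hot_fraction=config.hot_fraction,
        texture_effect=config.texture_effect,
        response_slope=config.response_slope,
    )


def extract_features_for_cohort(
    cohort_dir: str | Path, n_bins: int = 64
) -> pd.DataFrame:
    """One 97-column row per patient listed in the cohort manifest."""
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    rows, ids = [], []
    for entry in manifest["patients"]:
        pid = entry["patient_id"]
        vol_path = cohort_dir / entry["volume"]
        mask_path = cohort_dir / entry["mask"]
        if not vol_path.exists() or not mask_path.exists():
            raise FileNotFoundError(f"missing image file for patient {pid}")
        vol = read_volume(vol_path)
        mask = read_mask(mask_path, vol)
        rows.append(extract_all(vol, mask, n_bins=n_bins).values)
        ids.append(pid)
    return pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"),
                        columns=feature_names())


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory containing the artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    log: list[dict] = []

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        return lambda: log.append(
            {"stage": name, "seconds": round(time.perf_counter() - t0, 3)}
        )

    cohort_dir = Path(config.cohort_dir)
    if config.simulate:
        done = stage("simulate")
        patients = synthetic.generate_cohort(_cohort_config(config))
        synthetic.write_cohort(patients, cohort_dir)
        done()
    if not (cohort_dir / "manifest.json").exists():
        raise FileNotFoundError(f"no cohort manifest in {cohort_dir}")

    done = stage("extract")
    features = extract_features_for_cohort(cohort_dir, n_bins=config.n_bins)
    features.to_csv(out / "features.csv")
    done()

    done = stage("fit_immune")
    records = read_clinical_table(cohort_dir / "cohort.csv")
    immune_model = signature.build_immunomarker_classifier(
        records, seed=config.seed, n_folds=config.n_folds
    )
    immune_model.to_json(out / "immune_model.json")
    scores = np.array(
        [signature.immune_score(r.delta_cd8, r.delta_cd68) for r in records]
    )
    immune_high = scores >= signature.REFERENCE_IMMUNE_MODEL.cutoff
    done()

    done = stage("fit_radiomics")
    if config.label_definition == "immune_group:high":
        target = immune_high.astype(float)
    elif config.label_definition == "response:CR":
        target = np.array([1.0 if r.response == "CR" else 0.0 for r in records])
    elif config.label_definition == "latent_class:hot":
        target = np.array(
            [1.0 if r.extra.get("latent_class") == "hot" else 0.0 for r in records]
        )
    else:
        raise ValueError(f"unknown label_definition {config.label_definition!r}")
    model, screening = signature.build_radiomics_signature(
        features, target, seed=config.seed, alpha=config.alpha,
        n_folds=config.n_folds, label_definition=config.label_definition,
    )
    model.to_json(out / "model.json")
    (out / "screening.json").write_text(json.dumps({
        "alpha": screening.alpha,
        "n_retained": len(screening.retained),
        "retained": screening.retained,
        "p_values": screening.p_values,
        "flagged_separation": screening.flagged_separation,
    }, indent=1, sort_keys=True))
    done()

    done = stage("evaluate")
    cr = np.array([1.0 if r.response == "CR" else 0.0 for r in records])
    report = {}
    if len(np.unique(cr)) == 2:
        roc = evaluation.roc_curve(scores, cr)
        cutoff = evaluation.youden_cutoff(roc)
        strat = evaluation.stratify_and_test(
            scores, cr, signature.REFERENCE_IMMUNE_MODEL.cutoff,
            continuity_correction=config.continuity_correction,
        )
        rad_scores = model.score(features)
        rad_roc = evaluation.roc_curve(rad_scores, target)
        report = {
            "immune": {
                "auc": roc.auc, "auc_ci95": list(roc.auc_ci95),
                "youden_cutoff": cutoff,
                "reference_cutoff": signature.REFERENCE_IMMUNE_MODEL.cutoff,
                "table": strat.table.counts.tolist(),
                "chi2": strat.chi2, "p": strat.p,
                "sensitivity": strat.sensitivity, "specificity": strat.specificity,
                "cr_rate_low": strat.cr_rate_low, "cr_rate_high": strat.cr_rate_high,
            },
            "radiomics": {
                "auc": rad_roc.auc, "auc_ci95": list(rad_roc.auc_ci95),
                "youden_cutoff": evaluation.youden_cutoff(rad_roc),
                "n_screened": model.n_screened,
                "support": model.support,
                "lambda": model.lambda_,
            },
        }
        pd.DataFrame({
            "patient_id": [r.patient_id for r in records],
            "immune_score": scores,
            "immune_group": np.where(immune_high, "high", "low"),
            "radiomics_score": rad_scores,
            "response": [r.response for r in records],
        }).to_csv(out / "scores.csv", index=False)
    (out / "evaluation.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    done()

    (out / "run_log.json").write_text(json.dumps({
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": log,
    }, indent=1))
    return out


def make_paper_fixtures(directory: str | Path | None = None) -> dict:
    """The two printed 2x2 stratification tables plus the reference constants.

    Counts: immune classifier low {2 CR, 10 PR} / high {15 CR, 3 PR};
    radiomics low {7 CR, 12 PR} / high {10 CR, 1 PR} (reconstructed from the
    printed group sizes and CR percentages).
    """
    fixtures = {
        "immune_table": {"low_pr": 10, "low_cr": 2, "high_pr": 3, "high_cr": 15},
        "radiomics_table": {"low_pr": 12, "low_cr": 7, "high_pr": 1, "high_cr": 10},
        "immune_model": {
            "intercept": signature.REFERENCE_IMMUNE_MODEL.intercept,
            "coef_delta_cd8": signature.REFERENCE_IMMUNE_MODEL.coef_delta_cd8,
            "coef_delta_cd68": signature.REFERENCE_IMMUNE_MODEL.coef_delta_cd68,
            "cutoff": signature.REFERENCE_IMMUNE_MODEL.cutoff,
        },
        "radiomics_cutoff": 1.036,
    }
    if directory is not None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "fixtures.json").write_text(json.dumps(fixtures, indent=1))
    return fixtures
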