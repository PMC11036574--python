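"""Synthetic cohorts with the latent structure the analysis pipeline assumes.

Each patient carries a latent immune state ("hot" / "cold") that drives

1. class-conditional changes in CD8+/CD68+ counts,
2. the CR probability through the fixed reference immune-score model
   (``P(CR) = sigmoid(slope * (score - center))``), and
3. class-dependent tumor texture: the foreground HU field is baseline +
   Gaussian-filtered noise whose smoothing scale grows with
   ``texture_effect`` for hot patients (correlation-length separation), so
   texture features — not raw intensity statistics — carry the class signal.

Randomness: one ``SeedSequence`` per patient, spawned from the cohort seed
and split into purpose-specific child streams (class, markers, blood,
covariates, volume, response) so adding a field never perturbs earlier
draws.  Identical (config, seed) reproduces bit-identical arrays and CSVs.

Default class-conditional marker parameters are invented so that default
cohorts straddle the reference cutoff; they are configuration values, not
estimates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from immunorad.signature import immune_score
from immunorad.volumes import CTVolume, PatientRecord, ROIMask, records_to_frame

Class = Literal["hot", "cold"]

_MAX_ELLIPSOID_RETRIES = 100


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 30
    seed: int = 0
    hot_fraction: float = 0.5
    delta_cd8_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"hot": (150.0, 60.0), "cold": (-30.0, 40.0)}
    )
    delta_cd68_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"hot": (-50.0, 60.0), "cold": (80.0, 70.0)}
    )
    response_slope: float = 4.0
    response_center: float = 0.307
    texture_effect: float = 2.0
    grid_shape: tuple[int, int, int] = (48, 48, 20)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 5.0)
    half_axis_bounds_vox: tuple[tuple[float, float], ...] = (
        (8.0, 14.0), (8.0, 14.0), (3.0, 6.0)
    )

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.hot_fraction <= 1.0:
            raise ValueError("hot_fraction must be in [0, 1]")
        if self.response_slope < 0:
            raise ValueError("response_slope must be >= 0")
        if self.texture_effect < 0:
            raise ValueError("texture_effect must be >= 0")
        for params in (self.delta_cd8_params, self.delta_cd68_params):
            for cls in ("hot", "cold"):
                if params[cls][1] <= 0:
                    raise ValueError(f"degenerate sd for class {cls!r}: {params[cls]}")
        if any(s <= 0 for s in self.voxel_spacing_mm) or any(
            g <= 0 for g in self.grid_shape
        ):
            raise ValueError("grid_shape and voxel_spacing_mm must be positive")
        for axis, (lo, hi) in enumerate(self.half_axis_bounds_vox):
            if not 0 < lo <= hi:
                raise ValueError("half-axis bounds must satisfy 0 < lo <= hi")
            if 2 * hi + 2 > self.grid_shape[axis]:
                raise ValueError(
                    f"grid axis {axis} too small for ellipsoid half-axis {hi}"
                )


@dataclass
class SyntheticPatient:
    patient_id: str
    latent_class: Class
    record: PatientRecord
    volume: CTVolume | None
    mask: ROIMask | None


def _correlated_field(shape, rng, sigma_vox: float) -> np.ndarray:
    """Unit-variance Gaussian field with correlation length sigma_vox voxels."""
    noise = rng.standard_normal(shape)
    if sigma_vox <= 0:
        return noise
    smoothed = gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    sd = smoothed.std()
    return smoothed / sd if sd > 0 else smoothed


def generate_tumor_volume(
    latent_class: Class, config: CohortConfig, rng: np.random.Generator
) -> tuple[CTVolume, ROIMask]:
    """Sample an ellipsoidal VOI and a class-textured HU field around it."""
    shape = np.asarray(config.grid_shape)
    for _ in range(_MAX_ELLIPSOID_RETRIES):
        half = np.array([rng.uniform(lo, hi) for lo, hi in config.half_axis_bounds_vox])
        center = np.array(
            [rng.uniform(h + 1, dim - h - 1) for h, dim in zip(half, shape)]
        )
        if np.all(center - half >= 0) and np.all(center + half <= shape - 1):
            break
    else:  # pragma: no cover - bounds are validated at config time
        raise RuntimeError("could not place ellipsoid inside grid")
    grids = np.meshgrid(*(np.arange(d) for d in shape), indexing="ij")
    dist2 = sum(((g - c) / h) ** 2 for g, c, h in zip(grids, center, half))
    fg = dist2 <= 1.0

    # hot tumors get a longer correlation length, scaled by texture_effect
    sigma = 0.6 * (1.0 + config.texture_effect) if latent_class == "hot" else 0.6
    field_fg = _correlated_field(tuple(shape), rng, sigma)
    background = -80.0 + 10.0 * rng.standard_normal(tuple(shape))
    intensities = np.where(fg, 45.0 + 25.0 * field_fg, background)

    vol = CTVolume(intensities.astype(np.float64), config.voxel_spacing_mm)
    mask = ROIMask(fg.astype(np.uint8), config.voxel_spacing_mm)
    return vol, mask


def _blood_counts(rng: np.random.Generator) -> dict[str, float]:
    """Log-normal draws around adult reference means (units 1e9/L)."""
    means = {
        "plt_baseline": 250.0, "anc_baseline": 4.2, "amc_baseline": 0.50,
        "alc_baseline": 1.8, "plt_10f": 210.0, "anc_10f": 3.4,
        "amc_10f": 0.45, "alc_10f": 0.9,
    }
    return {
        k: float(rng.lognormal(mean=np.log(m), sigma=0.25)) for k, m in means.items()
    }


def _sigmoid(x: float) -> float:
    return float(0.5 * (1.0 + np.tanh(0.5 * x)))


def generate_patient(
    index: int,
    config: CohortConfig,
    seed_seq: np.random.SeedSequence,
    with_images: bool = True,
) -> SyntheticPatient:
    streams = [np.random.default_rng(s) for s in seed_seq.spawn(6)]
    rng_class, rng_markers, rng_blood, rng_covar, rng_volume, rng_response = streams

    latent: Class = "hot" if rng_class.random() < config.hot_fraction else "cold"

    mu8, sd8 = config.delta_cd8_params[latent]
    mu68, sd68 = config.delta_cd68_params[latent]
    delta_cd8 = rng_markers.normal(mu8, sd8)
    delta_cd68 = rng_markers.normal(mu68, sd68)
    cd8_baseline = max(0.0, rng_markers.normal(250.0, 50.0))
    cd68_baseline = max(0.0, rng_markers.normal(200.0, 40.0))
    cd8_10f = max(0.0, cd8_baseline + delta_cd8)
    cd68_10f = max(0.0, cd68_baseline + delta_cd68)
    # 11 further marker deltas: pure noise candidates for LASSO screening
    extra_deltas = {
        col: float(rng_markers.normal(0.0, 30.0))
        for col in (
            "delta_pdl1", "delta_serpinb9", "delta_cd47", "delta_irf1",
            "delta_stat1", "delta_hla_a", "delta_hla_bc", "delta_b2m",
            "delta_tap1", "delta_lmp2", "delta_lmp7",
        )
    }

    blood = _blood_counts(rng_blood)
    age = float(np.clip(rng_covar.normal(52.0, 10.0), 25.0, 85.0))
    figo_stage = int(rng_covar.choice([1, 2, 3, 4], p=[0.15, 0.35, 0.4, 0.1]))
    tumor_size = float(rng_covar.lognormal(np.log(4.0), 0.3))
    ln_positive = bool(rng_covar.random() < 0.4)

    # volume uses its own child stream, so skipping it leaves all other
    # draws untouched (records are identical with and without images)
    volume, mask = (
        generate_tumor_volume(latent, config, rng_volume)
        if with_images
        else (None, None)
    )

    score = immune_score(cd8_10f - cd8_baseline, cd68_10f - cd68_baseline)
    p_cr = _sigmoid(config.response_slope * (score - config.response_center))
    response = "CR" if rng_response.random() < p_cr else "PR"

    record = PatientRecord(
        patient_id=f"P{index:04d}",
        cd8_baseline=cd8_baseline, cd8_10f=cd8_10f,
        cd68_baseline=cd68_baseline, cd68_10f=cd68_10f,
        age_years=age, figo_stage=figo_stage, tumor_size_cm=tumor_size,
        ln_positive=ln_positive, response=response,
        extra={"latent_class": latent, **extra_deltas},
        **blood,
    )
    return SyntheticPatient(record.patient_id, latent, record, volume, mask)


def generate_cohort(
    config: CohortConfig, with_images: bool = True
) -> list[SyntheticPatient]:
    """Generate ``config.n_patients`` patients deterministically from the seed.

    ``with_images=False`` skips volume synthesis (records are unchanged),
    which is much faster when only the clinical table is needed.
    """
    root = np.random.SeedSequence(config.seed)
    return [
        generate_patient(i, config, child, with_images=with_images)
        for i, child in enumerate(root.spawn(config.n_patients))
    ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(patients: list[SyntheticPatient], directory: str | Path) -> dict:
    """Write NIfTI volumes/masks plus the cohort CSV; return a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in patients:
        if p.volume is None or p.mask is None:
            raise ValueError(f"{p.patient_id}: cohort was generated without images")
        affine = np.diag(list(p.volume.spacing_mm) + [1.0])
        vol_path = directory / f"{p.patient_id}_volume.nii.gz"
        mask_path = directory / f"{p.patient_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(p.volume.intensities, affine), vol_path)
        nib.save(nib.Nifti1Image(p.mask.labels.astype(np.uint8), affine), mask_path)
        entries.append(
            {
                "patient_id": p.patient_id,
                "volume": vol_path.name,
                "mask": mask_path.name,
                "volume_sha256": _sha256(vol_path),
                "mask_sha256": _sha256(mask_path),
            }
        )
    csv_path = directory / "cohort.csv"
    records_to_frame([p.record for p in patients]).to_csv(csv_path, index=False)
    manifest = {
        "n_patients": len(patients),
        "clinical_table": csv_path.name,
        "clinical_table_sha256": _sha256(csv_path),
        "patients": entries,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)
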