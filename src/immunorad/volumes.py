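"""Volume, mask and clinical-table I/O.

All geometry is computed in physical millimetres using the voxel spacing;
voxel indices are 0-based and arrays are indexed ``[x, y, z]`` in the NIfTI
affine's native axis order.  Volumes are never resampled by default: feature
extraction operates on the native (typically anisotropic) grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: spacing equality tolerance (mm) when pairing a mask with its volume
SPACING_TOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Mask and volume do not share shape/spacing within tolerance."""


@dataclass(frozen=True)
class CTVolume:
    """3D scalar grid in Hounsfield units with anisotropic spacing."""

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D volume, got {arr.ndim}D")
        if not np.all(np.isfinite(arr)):
            idx = tuple(int(i) for i in np.argwhere(~np.isfinite(arr))[0])
            raise ValueError(f"non-finite intensity at voxel index {idx}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class ROIMask:
    """Binary foreground mask congruent with its paired :class:`CTVolume`."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got {arr.ndim}D")
        binary = arr > 0  # any strictly positive label is foreground
        if not binary.any():
            raise ValueError("empty VOI: mask has no foreground voxels")
        object.__setattr__(self, "labels", binary.astype(np.uint8))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def foreground(self) -> np.ndarray:
        return self.labels.astype(bool)

    @property
    def n_foreground(self) -> int:
        return int(self.labels.sum())


@dataclass
class PatientRecord:
    """One clinical/immunological row: marker counts, blood counts, covariates."""

    patient_id: str
    cd8_baseline: float
    cd8_10f: float
    cd68_baseline: float
    cd68_10f: float
    plt_baseline: float
    anc_baseline: float
    amc_baseline: float
    alc_baseline: float
    plt_10f: float
    anc_10f: float
    amc_10f: float
    alc_10f: float
    age_years: float
    figo_stage: int
    tumor_size_cm: float
    ln_positive: bool
    response: str | None = None  # "CR" | "PR" | None when unavailable
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{self.patient_id}: {name}={v!r} must be finite and >= 0")
        if self.response is not None and self.response not in ("CR", "PR"):
            raise ValueError(f"{self.patient_id}: response must be CR/PR, got {self.response!r}")

    @property
    def delta_cd8(self) -> float:
        return self.cd8_10f - self.cd8_baseline

    @property
    def delta_cd68(self) -> float:
        return self.cd68_10f - self.cd68_baseline


_COUNT_FIELDS = (
    "cd8_baseline", "cd8_10f", "cd68_baseline", "cd68_10f",
    "plt_baseline", "anc_baseline", "amc_baseline", "alc_baseline",
    "plt_10f", "anc_10f", "amc_10f", "alc_10f",
)

#: mandatory clinical CSV columns, in canonical order
CLINICAL_COLUMNS = (
    "patient_id",
    *_COUNT_FIELDS,
    "age_years", "figo_stage", "tumor_size_cm", "ln_positive", "response",
)


def read_volume(path: str | Path) -> CTVolume:
    """Load a 3D NIfTI volume; fails loudly on non-3D or non-finite data."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin)


def read_mask(path: str | Path, reference: CTVolume) -> ROIMask:
    """Load a mask on the reference grid; any positive label is foreground."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D mask, got {data.ndim}D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if data.shape != reference.shape:
        raise GridMismatchError(
            f"{path}: mask shape {data.shape} != volume shape {reference.shape}"
        )
    if any(abs(a - b) > SPACING_TOL_MM for a, b in zip(zooms, reference.spacing_mm)):
        raise GridMismatchError(
            f"{path}: mask spacing {zooms} != volume spacing {reference.spacing_mm}"
        )
    return ROIMask(data, reference.spacing_mm, reference.origin_mm)


def extract_voi(
    volume: CTVolume, mask: ROIMask, margin_voxels: int = 0
) -> tuple[CTVolume, ROIMask]:
    """Crop both grids to the foreground bounding box dilated by ``margin_voxels``.

    The crop is clipped to the grid, so the foreground voxel count is preserved.
    """
    if volume.shape != mask.shape:
        raise GridMismatchError(f"volume {volume.shape} vs mask {mask.shape}")
    if margin_voxels < 0:
        raise ValueError("margin_voxels must be >= 0")
    fg = mask.foreground
    slices = []
    for axis in range(3):
        proj = np.any(fg, axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        lo = max(0, int(idx[0]) - margin_voxels)
        hi = min(fg.shape[axis], int(idx[-1]) + 1 + margin_voxels)
        slices.append(slice(lo, hi))
    sl = tuple(slices)
    origin = tuple(
        o + s.start * sp
        for o, s, sp in zip(volume.origin_mm, sl, volume.spacing_mm)
    )
    return (
        CTVolume(volume.intensities[sl], volume.spacing_mm, origin),
        ROIMask(mask.labels[sl], mask.spacing_mm, origin),
    )


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    """Read the cohort CSV into typed records.

    Unknown columns are preserved in ``record.extra``; a missing ``response``
    column loads records with response unavailable.  Duplicate patient ids and
    rows missing mandatory fields are rejected with the offending id/row.
    """
    df = pd.read_csv(path)
    mandatory = [c for c in CLINICAL_COLUMNS if c != "response"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    ids = df["patient_id"].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate patient_id {dup[0]!r}")
    has_response = "response" in df.columns
    extras = [c for c in df.columns if c not in CLINICAL_COLUMNS]
    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        if row[mandatory].isna().any():
            bad = [c for c in mandatory if pd.isna(row[c])]
            raise ValueError(f"{path}: row {i} missing mandatory fields {bad}")
        response = None
        if has_response and not pd.isna(row["response"]):
            response = str(row["response"]).strip()
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                **{name: float(row[name]) for name in _COUNT_FIELDS},
                age_years=float(row["age_years"]),
                figo_stage=int(row["figo_stage"]),
                tumor_size_cm=float(row["tumor_size_cm"]),
                ln_positive=_parse_bool(row["ln_positive"]),
                response=response,
                extra={c: row[c] for c in extras},
            )
        )
    return records


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Canonical CSV-schema DataFrame for a collection of records."""
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in CLINICAL_COLUMNS if c != "response"}
        row["ln_positive"] = bool(r.ln_positive)
        row["response"] = r.response if r.response is not None else ""
        row.update(r.extra)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS) + sorted(
        {k for r in records for k in r.extra}
    ))
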