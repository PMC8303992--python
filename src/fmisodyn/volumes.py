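"""Data model and NIfTI I/O for SUV volumes, masks and longitudinal patient studies.

The pipeline works on co-registered 3D PET volumes in standardized-uptake-value
units (SUV, g/mL) acquired before chemo-radiotherapy (W0) and in treatment weeks
2 and 5 (W2/W5).  SUV normalisation and rigid registration happen upstream; this
module only verifies that volumes and masks share one voxel grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

TIME_POINTS = ("W0", "W2", "W5")

#: tolerance (mm) for deciding two grids are "the same"; registration is upstream
GRID_TOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Two voxel grids differ in shape, spacing or origin beyond tolerance."""


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-patient treatment outcome.

    Survival times are months from the start of chemo-radiotherapy; event flags
    are 1 when the event was observed and 0 when censored.
    """

    pfs_months: float
    pfs_event: int
    os_months: float
    os_event: int
    local_recurrence: int
    distant_metastasis: int

    def __post_init__(self) -> None:
        if self.pfs_months < 0 or self.os_months < 0:
            raise ValueError("survival times must be >= 0")


@dataclass(frozen=True)
class PETVolume:
    """A 3D SUV-valued grid with voxel geometry.

    values : float array, SUV in g/mL
    spacing : voxel edge lengths (mm) per axis
    origin : world coordinate (mm) of voxel (0, 0, 0)
    time_point : one of ``W0``, ``W2``, ``W5``
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    time_point: str = "W0"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {values.shape}")
        bad = np.argwhere(~np.isfinite(values))
        if bad.size:
            raise ValueError(f"non-finite voxel at index {tuple(int(i) for i in bad[0])}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def with_values(self, values: np.ndarray, time_point: str | None = None) -> "PETVolume":
        return PETVolume(values, self.spacing, self.origin,
                         self.time_point if time_point is None else time_point)


@dataclass(frozen=True)
class BinaryMask:
    """A voxel-aligned region on the same grid as a :class:`PETVolume`.

    ``role`` labels what the region is: the hypoxic sub-volume (``HSV``), the
    clinician-drawn ``boost`` target, or the ``background`` reference ROI.
    Masks are inclusive voxel sets; there is no fractional membership.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "HSV"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {values.shape}")
        object.__setattr__(self, "values", values.astype(bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_ml

    def with_values(self, values: np.ndarray, role: str | None = None) -> "BinaryMask":
        return BinaryMask(values, self.spacing, self.origin,
                          self.role if role is None else role)


@dataclass
class PatientStudy:
    """One patient's longitudinal study: volumes per time-point, masks, outcome.

    The baseline (W0) volume is mandatory; W2/W5 may be missing and are then
    simply absent from ``volumes``.
    """

    patient_id: str
    volumes: dict[str, PETVolume]
    boost_mask: BinaryMask
    background_mask: BinaryMask
    outcome: OutcomeRecord | None = None
    #: free-form provenance (synthetic ground truth, processing notes)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "W0" not in self.volumes:
            raise ValueError(f"patient {self.patient_id}: baseline W0 volume is required")
        ref = self.volumes["W0"]
        for tp, vol in self.volumes.items():
            check_same_grid(ref, vol, what=f"{self.patient_id}/{tp}")
        for mask in (self.boost_mask, self.background_mask):
            check_same_grid(ref, mask, what=f"{self.patient_id}/{mask.role}")

    @property
    def available_time_points(self) -> tuple[str, ...]:
        return tuple(tp for tp in TIME_POINTS if tp in self.volumes)


def grids_match(a, b, tol_mm: float = GRID_TOL_MM) -> bool:
    """True when two volumes/masks share shape, spacing and origin within tolerance."""
    return (
        a.shape == b.shape
        and all(abs(x - y) <= tol_mm for x, y in zip(a.spacing, b.spacing))
        and all(abs(x - y) <= tol_mm for x, y in zip(a.origin, b.origin))
    )


def check_same_grid(a, b, tol_mm: float = GRID_TOL_MM, what: str = "input") -> None:
    if not grids_match(a, b, tol_mm):
        raise GridMismatchError(
            f"{what}: grid mismatch "
            f"(shape {a.shape} vs {b.shape}, spacing {a.spacing} vs {b.spacing}, "
            f"origin {a.origin} vs {b.origin})"
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _geometry_from(img: nib.Nifti1Image) -> tuple[tuple, tuple]:
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in np.asarray(img.affine)[:3, 3])
    return spacing, origin


def read_volume(path: str | Path, time_point: str = "W0") -> PETVolume:
    """Read one SUV volume from a NIfTI file.

    Rejects 4D/non-scalar images and volumes with non-finite or negative
    voxels (SUV is non-negative by construction).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar image, got shape {data.shape}")
    data = np.asarray(data, dtype=np.float64)
    bad = np.argwhere(~np.isfinite(data))
    if bad.size:
        raise ValueError(f"{path}: non-finite voxel at index {tuple(int(i) for i in bad[0])}")
    neg = np.argwhere(data < 0)
    if neg.size:
        raise ValueError(f"{path}: negative SUV at index {tuple(int(i) for i in neg[0])}")
    spacing, origin = _geometry_from(img)
    return PETVolume(data, spacing, origin, time_point)


def write_volume(vol: PETVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.values.astype(np.float64), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, path)
    return path


def read_mask(path: str | Path, reference: PETVolume, role: str = "HSV") -> BinaryMask:
    """Read a mask and verify it sits on the reference volume's grid.

    Voxels are thresholded at 0.5; values other than {0, 1} trigger a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    data = np.asarray(data, dtype=np.float64)
    spacing, origin = _geometry_from(img)
    candidate = BinaryMask(data > 0.5, spacing, origin, role)
    if candidate.shape != reference.shape:
        raise GridMismatchError(
            f"{path}: mask shape {candidate.shape} != volume shape {reference.shape}")
    check_same_grid(reference, candidate, what=str(path))
    nonbinary = ~np.isin(data, (0.0, 1.0))
    if nonbinary.any():
        warnings.warn(f"{path}: {int(nonbinary.sum())} voxels outside {{0,1}} "
                      "were thresholded at 0.5", stacklevel=2)
    # grid metadata copied from the reference once verified
    return BinaryMask(data > 0.5, reference.spacing, reference.origin, role)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, path)
    return path


# ---------------------------------------------------------------------------
# Patient manifest (delimited text)
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "patient_id", "w0_path", "w2_path", "w5_path", "boost_path", "background_path",
    "pfs_months", "pfs_event", "os_months", "os_event",
    "local_recurrence", "distant_metastasis",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest (CSV, one row per patient)."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient_id entries")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_patient(row: Mapping, base_dir: str | Path | None = None) -> PatientStudy:
    """Materialise one manifest row into a :class:`PatientStudy`."""
    base = Path(base_dir) if base_dir is not None else Path(".")

    def _resolve(p):
        p = Path(str(p))
        return p if p.is_absolute() else base / p

    volumes: dict[str, PETVolume] = {}
    for tp, col in (("W0", "w0_path"), ("W2", "w2_path"), ("W5", "w5_path")):
        val = row.get(col)
        if val is None or (isinstance(val, float) and np.isnan(val)) or str(val) == "":
            continue
        volumes[tp] = read_volume(_resolve(val), tp)
    ref = volumes["W0"]
    boost = read_mask(_resolve(row["boost_path"]), ref, role="boost")
    background = read_mask(_resolve(row["background_path"]), ref, role="background")
    outcome = OutcomeRecord(
        pfs_months=float(row["pfs_months"]), pfs_event=int(row["pfs_event"]),
        os_months=float(row["os_months"]), os_event=int(row["os_event"]),
        local_recurrence=int(row["local_recurrence"]),
        distant_metastasis=int(row["distant_metastasis"]),
    )
    return PatientStudy(str(row["patient_id"]), volumes, boost, background, outcome)


def load_cohort(manifest_path: str | Path) -> list[PatientStudy]:
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    return [load_patient(row, base_dir=manifest_path.parent) for _, row in df.iterrows()]
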