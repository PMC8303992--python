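"""Synthetic longitudinal FMISO-PET cohorts with known ground truth.

Each patient receives three co-registered SUV volumes (W0/W2/W5): a Gaussian
background near 1 g/mL, a sub-threshold lesion shell, and a hypoxic core whose
voxels exceed 1.4 × background.  Between time-points the core is resized
within the ΔV band of the patient's planted size class (IH/SH/DH), translated
by a drift vector for geographically-dynamic patients, or removed entirely
(resolved hypoxia).  Core heterogeneity is controlled by a zone-mixture
parameter: small low-intensity pockets widen the in-mask intensity spread and
thereby lower the low gray-level zone emphasis (LGZE) under min-anchored
fixed-bin discretization — homogeneous regions score near 1, heterogeneous
ones orders of magnitude lower.

Outcomes carry the statistical structure the analysis pipeline assumes:
progression-free survival is exponential with a configurable hazard ratio for
dynamic versus static patients (uniform censoring), and local recurrence is
Bernoulli with a logit linear in the patient's realized ΔLGZE — either with a
fixed coefficient or with the coefficient calibrated so the model-implied AUC
matches a target.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import classify_size
from .radiomics import build_matrices, discretize_fixed, lgze
from .segmentation import estimate_background, segment_hsv
from .volumes import (BinaryMask, OutcomeRecord, PatientStudy, PETVolume,
                      write_manifest, write_mask, write_volume)

PATIENT_CLASSES = ("static-IH", "static-SH", "static-DH", "dynamic", "resolved")

#: ΔV sampling bands (percent) per size class at W2
DELTA_V_BANDS = {
    "IH": (20.0, 50.0),
    "SH": (-8.0, 8.0),
    "DH": (-60.0, -25.0),
}
#: deeper shrinkage band used for DH at W5
DELTA_V_BAND_DH_W5 = (-70.0, -35.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    The default dynamics mix plants decreasing hypoxia in 64% of patients at
    W2 (40% static-DH + 24% dynamic, which also shrink) and roughly 80% at
    W5 after the W5 class shift; drift applies to dynamic patients only.
    """

    n_patients: int = 25
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_mean: float = 1.0
    noise_sd: float = 0.05
    lesion_radius_mm: tuple[float, float] = (8.0, 14.0)
    hsv_tbr_contrast: float = 2.0
    shell_contrast: float = 1.15
    dynamics_mix: dict[str, float] = field(default_factory=lambda: {
        "static-IH": 0.08, "static-SH": 0.16, "static-DH": 0.40,
        "dynamic": 0.24, "resolved": 0.12,
    })
    #: allocate class counts exactly proportional to the mix (largest
    #: remainder, seeded shuffle) instead of i.i.d. draws — the balanced
    #: design used by the power simulations
    deterministic_mix: bool = False
    #: probabilities that a stable / increasing patient turns decreasing at W5
    w5_sh_to_dh: float = 0.75
    w5_ih_to_dh: float = 0.5
    drift_mm: float = 10.0
    #: half-width of the stable-class ΔV sampling band (0 → no size change)
    sh_band_halfwidth: float = 8.0
    #: skip the generator-side ΔLGZE measurement (and its LR link) when False
    link_lr_to_lgze: bool = True
    heterogeneity: float = 3.0           # expected low-intensity zone count
    zone_radius_mm: tuple[float, float] = (2.0, 4.0)
    zone_contrast: tuple[float, float] = (1.5, 1.75)
    hazard_ratio_dynamic: float = 3.0
    baseline_hazard_per_month: float = math.log(2) / 24.0
    censoring_rate: float = 0.2
    lr_base_rate: float = 0.4
    lr_beta: float = 5.0                 # logit slope on ΔLGZE (fixed-β mode)
    lr_auc_target: float | None = None   # calibrate β to this implied AUC
    dm_rate: float = 0.24
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.dynamics_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dynamics_mix must sum to 1, got {total}")
        if set(self.dynamics_mix) - set(PATIENT_CLASSES):
            raise ValueError(f"unknown classes in dynamics_mix: {self.dynamics_mix}")
        if self.hazard_ratio_dynamic <= 0:
            raise ValueError("hazard ratio must be > 0")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _distance_grid(shape, spacing, center_mm) -> np.ndarray:
    ax = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, center_mm)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij", sparse=True)
    return np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)


def _sphere(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    return _distance_grid(shape, spacing, center_mm) <= radius_mm


def _background_roi_mask(shape, spacing) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[1:6, 1:6, 1:6] = True
    return m


# ---------------------------------------------------------------------------
# Patient generation
# ---------------------------------------------------------------------------

def _draw_class(rng: np.random.Generator, mix: dict[str, float]) -> str:
    classes = [c for c in PATIENT_CLASSES if c in mix]
    probs = np.array([mix[c] for c in classes])
    return classes[rng.choice(len(classes), p=probs / probs.sum())]


def _allocated_class(spec: CohortSpec, index: int) -> str:
    """Exact-proportion class allocation (largest remainder), seeded shuffle."""
    classes = [c for c in PATIENT_CLASSES if c in spec.dynamics_mix]
    probs = np.array([spec.dynamics_mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    ideal = probs * spec.n_patients
    counts = np.floor(ideal).astype(int)
    remainder = spec.n_patients - counts.sum()
    for k in np.argsort(-(ideal - counts))[:remainder]:
        counts[k] += 1
    allocation = [c for c, n in zip(classes, counts) for _ in range(n)]
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 424_242)))
    shuffle_rng.shuffle(allocation)
    return allocation[index]


def _censor_time(rng: np.random.Generator, hazard: float, rate: float) -> float:
    """Uniform(0, c_max) censoring time with P(C < T) = rate for T ~ Exp(hazard).

    Solves (1 − e^(−x))/x = rate for x = hazard·c_max by bisection.
    """
    if rate <= 0:
        return math.inf
    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if (1.0 - math.exp(-mid)) / mid > rate:
            lo = mid
        else:
            hi = mid
    return rng.uniform(0.0, math.sqrt(lo * hi) / hazard)


def _w5_class(rng: np.random.Generator, cls_w2: str, spec: CohortSpec) -> str:
    if cls_w2 == "static-SH" and rng.random() < spec.w5_sh_to_dh:
        return "static-DH"
    if cls_w2 == "static-IH" and rng.random() < spec.w5_ih_to_dh:
        return "static-DH"
    return cls_w2


def _size_class_of(cls: str) -> str:
    return cls.split("-")[1] if cls.startswith("static-") else ("DH" if cls == "dynamic" else cls)


def _core_suv_map(rng, spec, shape, center_mm, radius_mm):
    """Core indicator and SUV values: high base with low-intensity zones."""
    core = _sphere(shape, spec.spacing, center_mm, radius_mm)
    suv = np.full(shape, spec.hsv_tbr_contrast * spec.background_mean)
    n_zones = rng.poisson(spec.heterogeneity)
    for _ in range(n_zones):
        # zone center uniform inside the core sphere
        while True:
            off = rng.uniform(-radius_mm, radius_mm, size=3)
            if np.linalg.norm(off) <= radius_mm:
                break
        zr = rng.uniform(*spec.zone_radius_mm)
        zc = rng.uniform(*spec.zone_contrast) * spec.background_mean
        zone = _sphere(shape, spec.spacing, tuple(np.array(center_mm) + off), zr)
        suv[zone] = zc
    return core, suv


def generate_patient(spec: CohortSpec, index: int) -> PatientStudy:
    """One synthetic patient study with planted ground truth in ``meta``.

    ``meta`` records the planted class per time-point, realized ΔV of the
    planted cores, drift, and the generator's own ΔLGZE measured on the
    planted baseline core (the value the local-recurrence link uses).
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, index)))
    shape, spacing = spec.grid_shape, spec.spacing
    extent = np.array(shape) * np.array(spacing)
    center = extent / 2.0 + rng.uniform(-2.0, 2.0, size=3)

    r0 = rng.uniform(*spec.lesion_radius_mm)
    if spec.deterministic_mix:
        cls_w2 = _allocated_class(spec, index)
    else:
        cls_w2 = _draw_class(rng, spec.dynamics_mix)
    cls_w5 = _w5_class(rng, cls_w2, spec)
    is_dynamic = cls_w2 == "dynamic"
    drift_dir = rng.normal(size=3)
    drift_dir /= np.linalg.norm(drift_dir)
    drift = drift_dir * spec.drift_mm if is_dynamic else np.zeros(3)

    radii: dict[str, float | None] = {"W0": r0}
    centers = {"W0": center}
    planted_dv: dict[str, float | None] = {"W0": 0.0}
    for tp, cls in (("W2", cls_w2), ("W5", cls_w5)):
        if cls == "resolved":
            radii[tp], planted_dv[tp] = None, None
            centers[tp] = center
            continue
        size_cls = _size_class_of(cls)
        if tp == "W5" and size_cls == "DH":
            band = DELTA_V_BAND_DH_W5
        elif size_cls == "SH":
            band = (-spec.sh_band_halfwidth, spec.sh_band_halfwidth)
        else:
            band = DELTA_V_BANDS[size_cls]
        dv = rng.uniform(*band) if band[0] < band[1] else band[0]
        radii[tp] = r0 * (1.0 + dv / 100.0) ** (1.0 / 3.0)
        planted_dv[tp] = dv
        centers[tp] = center + drift

    r_max = max(r for r in radii.values() if r is not None)
    boost_radius = r_max * 1.3 + (spec.drift_mm if is_dynamic else 0.0) + 6.0
    if np.any(center - boost_radius < 0) or np.any(center + boost_radius > extent):
        raise ValueError(
            f"patient {index}: lesion/boost (radius {boost_radius:.1f} mm) exceeds the grid")
    boost = _sphere(shape, spacing, center, boost_radius)
    bg_roi = _background_roi_mask(shape, spacing)
    if (boost & bg_roi).any():
        raise ValueError(f"patient {index}: boost volume reaches the background ROI corner")

    volumes: dict[str, PETVolume] = {}
    core_masks: dict[str, np.ndarray] = {}
    for tp in ("W0", "W2", "W5"):
        vals = spec.background_mean + rng.normal(0.0, spec.noise_sd, size=shape)
        if radii[tp] is not None:
            shell = _sphere(shape, spacing, centers[tp], radii[tp] * 1.25)
            vals[shell] = spec.shell_contrast * spec.background_mean \
                + rng.normal(0.0, spec.noise_sd, size=int(shell.sum()))
            core, core_suv = _core_suv_map(rng, spec, shape, centers[tp], radii[tp])
            vals[core] = core_suv[core] + rng.normal(0.0, spec.noise_sd, size=int(core.sum()))
            core_masks[tp] = core
        else:
            core_masks[tp] = np.zeros(shape, dtype=bool)
        volumes[tp] = PETVolume(np.clip(vals, 0.0, None), spacing, time_point=tp)

    # generator-side ΔLGZE on the planted baseline core (drives the LR link)
    mask_w0 = BinaryMask(core_masks["W0"], spacing, role="HSV")
    delta_lgze = math.nan
    if spec.link_lr_to_lgze and mask_w0.voxel_count:
        l0 = lgze(build_matrices(discretize_fixed(volumes["W0"], mask_w0)).glszm)
        l2 = lgze(build_matrices(discretize_fixed(volumes["W2"], mask_w0)).glszm)
        if l0 != 0:
            delta_lgze = (l2 - l0) / abs(l0)

    # outcomes: PFS exponential with class-dependent hazard; independent
    # Uniform(0, c_max) censoring times calibrated to the target censoring rate
    hazard = spec.baseline_hazard_per_month * (
        spec.hazard_ratio_dynamic if is_dynamic else 1.0)
    t_event = rng.exponential(1.0 / hazard)
    c_pfs = _censor_time(rng, hazard, spec.censoring_rate)
    t_pfs = min(t_event, c_pfs)
    pfs_event = int(t_event <= c_pfs)
    t_os_event = t_event + rng.exponential(2.0 / hazard)
    c_os = _censor_time(rng, hazard / 3.0, spec.censoring_rate)
    t_os = min(t_os_event, c_os)
    os_event = int(t_os_event <= c_os)
    if t_os < t_pfs:          # censoring for OS cannot precede observed PFS
        t_os, os_event = t_pfs, 0

    # provisional LR from the fixed-β logit; cohort-level calibration may redraw
    alpha = math.log(spec.lr_base_rate / (1 - spec.lr_base_rate))
    x = 0.0 if not np.isfinite(delta_lgze) else delta_lgze
    p_lr = 1.0 / (1.0 + math.exp(-(alpha + spec.lr_beta * x)))
    lr = int(rng.random() < p_lr)
    dm = int(rng.random() < spec.dm_rate)

    outcome = OutcomeRecord(
        pfs_months=float(t_pfs), pfs_event=pfs_event,
        os_months=float(t_os), os_event=os_event,
        local_recurrence=lr, distant_metastasis=dm,
    )
    study = PatientStudy(
        patient_id=f"P{index:03d}",
        volumes=volumes,
        boost_mask=BinaryMask(boost, spacing, role="boost"),
        background_mask=BinaryMask(bg_roi, spacing, role="background"),
        outcome=outcome,
    )
    study.meta = {
        "class_w2": cls_w2, "class_w5": cls_w5,
        "size_class_w2": _size_class_of(cls_w2) if cls_w2 != "resolved" else "resolved",
        "size_class_w5": _size_class_of(cls_w5) if cls_w5 != "resolved" else "resolved",
        "is_dynamic": is_dynamic,
        "planted_dv_w2": planted_dv["W2"], "planted_dv_w5": planted_dv["W5"],
        "core_radius_mm": r0,
        "delta_lgze": delta_lgze,
        "core_masks": core_masks,
    }
    return study


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _implied_auc(x: np.ndarray, beta: float, alpha: float) -> float:
    """Model-implied AUC of the score β·x given the realized covariates."""
    p = 1.0 / (1.0 + np.exp(-np.clip(alpha + beta * x, -60, 60)))
    s = beta * x
    gt = (s[:, None] > s[None, :]).astype(float) + 0.5 * (s[:, None] == s[None, :])
    np.fill_diagonal(gt, 0.0)
    w = p[:, None] * (1 - p)[None, :]
    np.fill_diagonal(w, 0.0)
    total = w.sum()
    return float((w * gt).sum() / total) if total > 0 else 0.5


def _solve_alpha(x: np.ndarray, beta: float, rate: float) -> float:
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        mean_p = float(np.mean(1.0 / (1.0 + np.exp(-np.clip(mid + beta * x, -60, 60)))))
        lo, hi = (mid, hi) if mean_p < rate else (lo, mid)
    return 0.5 * (lo + hi)


def calibrate_lr_beta(delta_lgze: np.ndarray, auc_target: float, base_rate: float,
                      sign: float = 1.0) -> tuple[float, float]:
    """Find (β, α) so the logistic LR link implies a given AUC and base rate.

    The default positive sign encodes the observed direction: a rise in
    heterogeneity lowers LGZE, so patients with strongly negative ΔLGZE
    (re-oxygenating, increasingly heterogeneous tracer uptake) recur less
    often — recurrence probability increases with ΔLGZE.
    """
    x = delta_lgze[np.isfinite(delta_lgze)]
    if x.size < 3 or np.ptp(x) == 0:
        raise ValueError("not enough ΔLGZE variation to calibrate the LR link")
    lo, hi = 0.0, 500.0 / (np.std(x) + 1e-12)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        beta = sign * mid
        alpha = _solve_alpha(x, beta, base_rate)
        if _implied_auc(x, beta, alpha) < auc_target:
            lo = mid
        else:
            hi = mid
    beta = sign * 0.5 * (lo + hi)
    return beta, _solve_alpha(x, beta, base_rate)


def generate_cohort_studies(spec: CohortSpec) -> list[PatientStudy]:
    """All patient studies in memory, with the LR link optionally calibrated.

    When ``spec.lr_auc_target`` is set, the local-recurrence labels are drawn
    from a logit whose slope on the cohort's realized ΔLGZE values implies
    that AUC (replacing the per-patient fixed-β draw).
    """
    studies = [generate_patient(spec, i) for i in range(spec.n_patients)]
    if spec.lr_auc_target is not None:
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 771_003_917)))
        x = np.array([s.meta["delta_lgze"] for s in studies])
        beta, alpha = calibrate_lr_beta(x, spec.lr_auc_target, spec.lr_base_rate)
        for s in studies:
            xi = s.meta["delta_lgze"]
            xi = 0.0 if not np.isfinite(xi) else xi
            p = 1.0 / (1.0 + math.exp(-(alpha + beta * xi)))
            lr = int(rng.random() < p)
            s.outcome = replace(s.outcome, local_recurrence=lr)
            s.meta["p_lr"] = p
    return studies


def cohort_truth_table(studies: Sequence[PatientStudy]) -> pd.DataFrame:
    rows = []
    for s in studies:
        m = s.meta
        rows.append({
            "patient_id": s.patient_id,
            "class_w2": m["class_w2"], "class_w5": m["class_w5"],
            "is_dynamic": m["is_dynamic"],
            "planted_dv_w2": m["planted_dv_w2"], "planted_dv_w5": m["planted_dv_w5"],
            "delta_lgze": m["delta_lgze"],
        })
    return pd.DataFrame(rows).set_index("patient_id")


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write NIfTI volumes/masks, the outcome columns and a manifest to disk.

    Returns the manifest path; re-running with the same seed reproduces the
    manifest byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    studies = generate_cohort_studies(spec)
    rows = []
    for s in studies:
        pdir = out_dir / s.patient_id
        paths = {}
        for tp, vol in s.volumes.items():
            paths[tp] = write_volume(vol, pdir / f"{tp.lower()}.nii.gz")
        boost_p = write_mask(s.boost_mask, pdir / "boost.nii.gz")
        bg_p = write_mask(s.background_mask, pdir / "background.nii.gz")
        o = s.outcome
        rows.append({
            "patient_id": s.patient_id,
            "w0_path": paths["W0"].relative_to(out_dir).as_posix(),
            "w2_path": paths["W2"].relative_to(out_dir).as_posix(),
            "w5_path": paths["W5"].relative_to(out_dir).as_posix(),
            "boost_path": boost_p.relative_to(out_dir).as_posix(),
            "background_path": bg_p.relative_to(out_dir).as_posix(),
            "pfs_months": round(o.pfs_months, 6), "pfs_event": o.pfs_event,
            "os_months": round(o.os_months, 6), "os_event": o.os_event,
            "local_recurrence": o.local_recurrence,
            "distant_metastasis": o.distant_metastasis,
        })
    manifest = pd.DataFrame(rows)
    cohort_truth_table(studies).to_csv(out_dir / "truth.csv")
    return write_manifest(manifest, out_dir / "manifest.csv")
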