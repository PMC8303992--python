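"""Radiomic feature extraction inside the baseline hypoxic sub-volume.

The feature set holds 130 named features: 10 first-order/histogram/shape
features plus 40 texture features (9 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM)
computed under three pre-processing variants:

* plain — SUV discretized with a fixed bin width (default W = 0.01 g/mL,
  bins anchored at the in-mask minimum),
* ``wf_`` — after a one-level 3D wavelet band-pass filter that weights the
  mixed low/high sub-bands twice as strongly as the pure low-pass and pure
  high-pass sub-bands (1:2 ratio), then fixed-bin discretization,
* ``q_`` — after equal-probability quantization (histogram equalisation)
  to a fixed number of gray levels (default 64).

Texture matrices are built in 3D: GLCM and GLRLM aggregate (sum) counts over
the 13 unique distance-1 directions into one merged matrix; GLSZM zones and
NGTDM neighbourhoods use 26-connectivity.  Features undefined on degenerate
regions (e.g. co-occurrence correlation with a single occupied gray level)
are reported as missing (NaN), never fabricated.

Longitudinal change is quantified by the relative deviation
``Δ_RF = (RF_Wk − RF_W0) / |RF_W0|`` for each feature, computed inside the
baseline contour transferred to the later scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pywt
from scipy import ndimage, stats
from skimage import measure

from .volumes import BinaryMask, PETVolume, check_same_grid

# ---------------------------------------------------------------------------
# Feature catalogue (frozen, version 1)
# ---------------------------------------------------------------------------

FIRST_ORDER_FEATURES = (
    "suv_max", "suv_mean", "suv_variance", "suv_skewness", "suv_kurtosis",
    "hist_entropy", "hist_uniformity",
    "volume_ml", "sphericity", "major_axis_mm",
)

GLCM_FEATURES = (
    "energy", "contrast", "entropy", "homogeneity", "correlation",
    "sum_average", "variance", "dissimilarity", "autocorrelation",
)
GLRLM_FEATURES = (
    "sre", "lre", "gln", "rln", "rp",
    "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge", "glv", "rlv",
)
GLSZM_FEATURES = (
    "sze", "lze", "gln", "zsn", "zp",
    "lgze", "hgze", "szlge", "szhge", "lzlge", "lzhge", "glv", "zsv",
)
NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

TEXTURE_FAMILIES = {
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}
VARIANTS = ("", "wf_", "q_")


def _build_feature_names() -> tuple[str, ...]:
    names = list(FIRST_ORDER_FEATURES)
    for variant in VARIANTS:
        for family, feats in TEXTURE_FAMILIES.items():
            names.extend(f"{variant}{family}_{f}" for f in feats)
    return tuple(names)


#: the frozen 130-feature list, in stable order
FEATURE_NAMES: tuple[str, ...] = _build_feature_names()
assert len(FEATURE_NAMES) == 130

#: field names used in the clinic mapped onto catalogue names
FEATURE_ALIASES = {
    "LGZE": "glszm_lgze",
    "C_CM": "glcm_correlation",
}


def resolve_feature_name(name: str) -> str:
    name = FEATURE_ALIASES.get(name, name)
    if name not in FEATURE_NAMES:
        raise KeyError(f"unknown radiomic feature {name!r}")
    return name


@dataclass(frozen=True)
class RadiomicsConfig:
    """Extraction parameters.

    bin_width : fixed-bin discretization width in SUV (g/mL)
    q_levels : gray-level count for equal-probability quantization
    wavelet : PyWavelets basis name for the band-pass variant
    aggregation : texture direction handling; only ``merged`` is implemented
    features : subset of feature names to compute (None = all 130)
    """

    bin_width: float = 0.01
    q_levels: int = 64
    wavelet: str = "coif1"
    aggregation: str = "merged"
    features: tuple[str, ...] | None = None

    def feature_list(self) -> tuple[str, ...]:
        if self.features is None:
            return FEATURE_NAMES
        return tuple(resolve_feature_name(f) for f in self.features)


DEFAULT_CONFIG = RadiomicsConfig()


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizedVolume:
    """Integer gray levels (1-based) inside a mask; 0 marks outside voxels."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    scheme: str
    bin_width: float | None = None

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("discretized volume has an empty mask")
        if inside.min() < 1:
            raise ValueError("every in-mask voxel must have level >= 1")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize_fixed(
    volume: PETVolume | np.ndarray,
    mask: BinaryMask,
    bin_width: float = 0.01,
) -> DiscretizedVolume:
    """Fixed-bin-width discretization anchored at the in-mask minimum.

    Level of a voxel with value ``s``: ``g = floor((s − min) / W) + 1``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = volume.values if isinstance(volume, PETVolume) else np.asarray(volume)
    m = mask.values
    if not m.any():
        raise ValueError("mask is empty")
    inside = values[m]
    levels = np.zeros(values.shape, dtype=np.int32)
    levels[m] = np.floor((inside - inside.min()) / bin_width).astype(np.int32) + 1
    return DiscretizedVolume(levels, m, int(levels.max()), "fixed_bin_width", bin_width)


def discretize_equal_probability(
    volume: PETVolume | np.ndarray,
    mask: BinaryMask,
    n_levels: int = 64,
) -> DiscretizedVolume:
    """Equal-probability quantization: level boundaries at empirical quantiles.

    Each level receives as near-equal a voxel count as ties in the data
    permit (histogram equalisation).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    values = volume.values if isinstance(volume, PETVolume) else np.asarray(volume)
    m = mask.values
    if not m.any():
        raise ValueError("mask is empty")
    inside = values[m]
    edges = np.quantile(inside, np.arange(1, n_levels) / n_levels)
    levels = np.zeros(values.shape, dtype=np.int32)
    levels[m] = np.searchsorted(edges, inside, side="right").astype(np.int32) + 1
    return DiscretizedVolume(levels, m, n_levels, "equal_probability", None)


# ---------------------------------------------------------------------------
# Wavelet band-pass filter
# ---------------------------------------------------------------------------

def wavelet_bandpass(
    volume: PETVolume,
    mask: BinaryMask,
    wavelet: str = "coif1",
) -> PETVolume:
    """One-level 3D wavelet decomposition with band-pass emphasis.

    The six mixed (band-pass) sub-bands — those containing both low- and
    high-pass axes — are weighted 2; the pure low-pass (aaa) and pure
    high-pass (ddd) sub-bands are weighted 1, so a constant input is returned
    unchanged.  Filtering acts on the mask's bounding box; voxels outside the
    box keep their original values (features are read inside the mask only).
    """
    check_same_grid(volume, mask, what="wavelet filter")
    if not mask.values.any():
        raise ValueError("mask is empty")
    wav = pywt.Wavelet(wavelet)
    bbox = ndimage.find_objects(mask.values.astype(np.int8))[0]
    sub = volume.values[bbox]
    if min(sub.shape) < wav.dec_len:
        raise ValueError(
            f"mask bounding box {sub.shape} is smaller than the filter support "
            f"({wav.dec_len} taps) of wavelet {wavelet!r}")
    coeffs = pywt.dwtn(sub, wav, mode="symmetric")
    for key in coeffs:
        if "a" in key and "d" in key:          # band-pass sub-band
            coeffs[key] = coeffs[key] * 2.0
    rec = pywt.idwtn(coeffs, wav, mode="symmetric")
    rec = rec[: sub.shape[0], : sub.shape[1], : sub.shape[2]]
    out = volume.values.copy()
    out[bbox] = rec
    return PETVolume(out, volume.spacing, volume.origin, volume.time_point)


# ---------------------------------------------------------------------------
# Texture matrices
# ---------------------------------------------------------------------------

#: the 13 unique distance-1 directions of the 26-neighbourhood
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class TextureMatrices:
    """Texture count matrices; row/column index 0 is unused padding.

    glcm : (Ng+1, Ng+1) symmetric co-occurrence counts, merged over directions
    glrlm : (Ng+1, Lmax+1) run-length counts, merged over directions
    glszm : (Ng+1, Smax+1) zone-size counts (26-connected zones)
    ngtdm_s : (Ng+1,) per-level sums of |level − mean 26-neighbour level|
    ngtdm_n : (Ng+1,) per-level counts of voxels with >= 1 in-mask neighbour
    n_voxels : in-mask voxel count
    """

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    ngtdm_s: np.ndarray
    ngtdm_n: np.ndarray
    n_voxels: int


def _crop(disc: DiscretizedVolume) -> np.ndarray:
    bbox = ndimage.find_objects(disc.mask.astype(np.int8))[0]
    return np.where(disc.mask[bbox], disc.levels[bbox], 0)


def _glcm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    counts = np.zeros((n_levels + 1) * (n_levels + 1), dtype=np.float64)
    for d in DIRECTIONS_13:
        src = [slice(max(0, -o), levels.shape[k] - max(0, o)) for k, o in enumerate(d)]
        dst = [slice(max(0, o), levels.shape[k] - max(0, -o)) for k, o in enumerate(d)]
        a = levels[tuple(src)].ravel()
        b = levels[tuple(dst)].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        pair = a[ok].astype(np.int64) * (n_levels + 1) + b[ok]
        counts += np.bincount(pair, minlength=counts.size)
    glcm = counts.reshape(n_levels + 1, n_levels + 1)
    return glcm + glcm.T          # symmetric counting


def _glrlm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    max_len = int(np.ceil(np.linalg.norm(levels.shape))) + 1
    rlm = np.zeros((n_levels + 1, max_len + 1), dtype=np.float64)
    shape = levels.shape

    def inb(c, d):
        return ((0 <= c[0] + d[0]) & (c[0] + d[0] < shape[0])
                & (0 <= c[1] + d[1]) & (c[1] + d[1] < shape[1])
                & (0 <= c[2] + d[2]) & (c[2] + d[2] < shape[2]))

    coords_all = np.argwhere(levels > 0)
    for d in DIRECTIONS_13:
        c = coords_all.T
        # run starts: no in-bounds predecessor with the same level
        has_prev = inb(c, (-d[0], -d[1], -d[2]))
        prev_same = np.zeros(c.shape[1], dtype=bool)
        if has_prev.any():
            pc = c[:, has_prev] - np.array(d)[:, None]
            prev_same[has_prev] = levels[pc[0], pc[1], pc[2]] == levels[c[0], c[1], c[2]][has_prev]
        starts = c[:, ~prev_same]
        lev = levels[starts[0], starts[1], starts[2]]
        length = np.ones(starts.shape[1], dtype=np.int64)
        cur = starts.copy()
        active = np.ones(starts.shape[1], dtype=bool)
        while active.any():
            ca = cur[:, active]
            nxt_ok = inb(ca, d)
            same = np.zeros(ca.shape[1], dtype=bool)
            if nxt_ok.any():
                nc = ca[:, nxt_ok] + np.array(d)[:, None]
                same[nxt_ok] = levels[nc[0], nc[1], nc[2]] == levels[ca[0], ca[1], ca[2]][nxt_ok]
            idx = np.flatnonzero(active)
            grow = idx[same]
            cur[:, grow] += np.array(d)[:, None]
            length[grow] += 1
            active[idx[~same]] = False
        np.add.at(rlm, (lev, np.minimum(length, max_len)), 1.0)
    return rlm


def _glszm(levels: np.ndarray, n_levels: int, n_voxels: int) -> np.ndarray:
    szm = np.zeros((n_levels + 1, n_voxels + 1), dtype=np.float64)
    for g in np.unique(levels[levels > 0]):
        lab, n = ndimage.label(levels == g, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s, cnt in zip(*np.unique(sizes, return_counts=True)):
            szm[g, s] += cnt
    return szm


def _ngtdm(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    inmask = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(levels.astype(np.float64), kernel, mode="constant")
    nb_cnt = ndimage.correlate(inmask.astype(np.float64), kernel, mode="constant")
    valid = inmask & (nb_cnt > 0.5)
    s = np.zeros(n_levels + 1)
    n = np.zeros(n_levels + 1)
    g = levels[valid]
    diff = np.abs(g - nb_sum[valid] / nb_cnt[valid])
    np.add.at(s, g, diff)
    np.add.at(n, g, 1.0)
    return s, n


def build_matrices(disc: DiscretizedVolume) -> TextureMatrices:
    """All four texture matrices from one discretized volume."""
    levels = _crop(disc)
    ng = disc.n_levels
    nvox = disc.n_voxels
    s, n = _ngtdm(levels, ng)
    return TextureMatrices(
        glcm=_glcm(levels, ng),
        glrlm=_glrlm(levels, ng),
        glszm=_glszm(levels, ng, nvox),
        ngtdm_s=s,
        ngtdm_n=n,
        n_voxels=nvox,
    )


# ---------------------------------------------------------------------------
# Texture features
# ---------------------------------------------------------------------------

def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    total = glcm.sum()
    if total == 0:
        return {f: math.nan for f in GLCM_FEATURES}
    p = glcm / total
    ng = p.shape[0] - 1
    i = np.arange(ng + 1)[:, None].astype(float)
    j = np.arange(ng + 1)[None, :].astype(float)
    px = p.sum(axis=1)
    mu = float((np.arange(ng + 1) * px).sum())
    sigma2 = float(((np.arange(ng + 1) - mu) ** 2 * px).sum())
    out = {
        "energy": float((p ** 2).sum()),
        "contrast": float(((i - j) ** 2 * p).sum()),
        "entropy": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        "homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "sum_average": float(((i + j) * p).sum()),
        "variance": float(((i - mu) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(i - j) * p).sum()),
        "autocorrelation": float((i * j * p).sum()),
    }
    if sigma2 <= 0:
        out["correlation"] = math.nan
    else:
        out["correlation"] = float((((i - mu) * (j - mu) * p).sum()) / sigma2)
    return out


def glcm_correlation(glcm: np.ndarray) -> float:
    """Co-occurrence correlation (C_CM); NaN when a single gray level occupies
    the matrix (marginal variance zero)."""
    if glcm.sum() == 0:
        raise ValueError("empty co-occurrence matrix")
    return glcm_features(glcm)["correlation"]


def _run_zone_features(mat: np.ndarray, n_voxels: int, prefix: str) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas.

    ``mat[g, l]`` counts runs (zones) of gray level g and length (size) l.
    """
    total = mat.sum()
    if total == 0:
        return {}
    p = mat / total
    g = np.arange(mat.shape[0])[:, None].astype(float)
    l = np.arange(mat.shape[1])[None, :].astype(float)
    g2 = np.where(g > 0, g ** 2, 1.0)        # index 0 never occupied
    l2 = np.where(l > 0, l ** 2, 1.0)
    mu_g = float((g * p).sum())
    mu_l = float((l * p).sum())
    feats = {
        "sre" if prefix == "r" else "sze": float((p / l2).sum()),
        "lre" if prefix == "r" else "lze": float((p * l2).sum()),
        "gln": float((mat.sum(axis=1) ** 2).sum() / total),
        "rln" if prefix == "r" else "zsn": float((mat.sum(axis=0) ** 2).sum() / total),
        "rp" if prefix == "r" else "zp": float(total / n_voxels),
        "lgre" if prefix == "r" else "lgze": float((p / g2).sum()),
        "hgre" if prefix == "r" else "hgze": float((p * g ** 2).sum()),
        "srlge" if prefix == "r" else "szlge": float((p / (g2 * l2)).sum()),
        "srhge" if prefix == "r" else "szhge": float((p * g ** 2 / l2).sum()),
        "lrlge" if prefix == "r" else "lzlge": float((p * l2 / g2).sum()),
        "lrhge" if prefix == "r" else "lzhge": float((p * g ** 2 * l2).sum()),
        "glv": float((p * (g - mu_g) ** 2).sum()),
        "rlv" if prefix == "r" else "zsv": float((p * (l - mu_l) ** 2).sum()),
    }
    return feats


def glrlm_features(glrlm: np.ndarray, n_voxels: int) -> dict[str, float]:
    feats = _run_zone_features(glrlm, n_voxels, "r")
    return feats or {f: math.nan for f in GLRLM_FEATURES}


def glszm_features(glszm: np.ndarray, n_voxels: int) -> dict[str, float]:
    feats = _run_zone_features(glszm, n_voxels, "z")
    return feats or {f: math.nan for f in GLSZM_FEATURES}


def lgze(glszm: np.ndarray) -> float:
    """Low gray-level zone emphasis: (1/N_z) Σ_g Σ_s n(g, s) / g².

    High when the region holds many low-intensity zones — i.e. a
    heterogeneous tracer distribution with low-concentration pockets.
    """
    total = glszm.sum()
    if total == 0:
        raise ValueError("empty size-zone matrix")
    g = np.arange(glszm.shape[0]).astype(float)
    g2 = np.where(g > 0, g ** 2, 1.0)
    return float((glszm.sum(axis=1) / g2).sum() / total)


def ngtdm_features(s: np.ndarray, n: np.ndarray, n_voxels: int) -> dict[str, float]:
    total = n.sum()
    if total == 0:
        return {f: math.nan for f in NGTDM_FEATURES}
    p = n / total
    idx = np.flatnonzero(p > 0)
    pi = p[idx]
    si = s[idx]
    gi = idx.astype(float)
    ngp = idx.size
    out: dict[str, float] = {}
    denom = float((pi * si).sum())
    out["coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        dg2 = (gi[:, None] - gi[None, :]) ** 2
        out["contrast"] = float(
            (pi[:, None] * pi[None, :] * dg2).sum() / (ngp * (ngp - 1)) * (si.sum() / total))
        bus_den = float(np.abs(gi[:, None] * pi[:, None] - gi[None, :] * pi[None, :]).sum())
        out["busyness"] = denom / bus_den if bus_den > 0 else math.nan
        dg = np.abs(gi[:, None] - gi[None, :])
        psum = pi[:, None] + pi[None, :]
        out["complexity"] = float(
            (dg * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :]) / psum).sum() / total)
        s_tot = float(si.sum())
        out["strength"] = float((psum * dg2).sum() / s_tot) if s_tot > 0 else 0.0
    else:
        out["contrast"] = math.nan
        out["busyness"] = math.nan
        out["complexity"] = math.nan
        out["strength"] = math.nan
    return out


# ---------------------------------------------------------------------------
# First-order / histogram / shape features
# ---------------------------------------------------------------------------

def first_order_features(
    volume: PETVolume, mask: BinaryMask, bin_width: float = 0.01
) -> dict[str, float]:
    vals = volume.values[mask.values]
    if vals.size == 0:
        raise ValueError("mask is empty")
    var = float(vals.var())
    distinct = var > 1e-12 * (1.0 + float(vals.mean()) ** 2)
    out = {
        "suv_max": float(vals.max()),
        "suv_mean": float(vals.mean()),
        "suv_variance": var,
        "suv_skewness": float(stats.skew(vals)) if distinct else math.nan,
        "suv_kurtosis": float(stats.kurtosis(vals, fisher=False)) if distinct else math.nan,
    }
    # fixed-bin histogram features
    g = np.floor((vals - vals.min()) / bin_width).astype(np.int64)
    p = np.bincount(g) / vals.size
    p = p[p > 0]
    out["hist_entropy"] = float(-(p * np.log2(p)).sum())
    out["hist_uniformity"] = float((p ** 2).sum())
    out.update(shape_features(mask))
    return out


def shape_features(mask: BinaryMask) -> dict[str, float]:
    """Mesh-based sphericity and inertia-based major axis length (mm)."""
    m = mask.values
    if not m.any():
        raise ValueError("mask is empty")
    volume_mm3 = mask.voxel_count * float(np.prod(mask.spacing))
    out = {"volume_ml": volume_mm3 / 1000.0}
    bbox = ndimage.find_objects(m.astype(np.int8))[0]
    sub = np.pad(m[bbox], 1).astype(float)
    try:
        verts, faces, _, _ = measure.marching_cubes(sub, level=0.5, spacing=mask.spacing)
        area = measure.mesh_surface_area(verts, faces)
        out["sphericity"] = float(np.pi ** (1 / 3) * (6 * volume_mm3) ** (2 / 3) / area)
    except (ValueError, RuntimeError):
        out["sphericity"] = math.nan
    try:
        props = measure.regionprops(m.astype(np.uint8), spacing=mask.spacing)[0]
        out["major_axis_mm"] = float(props.axis_major_length)
    except (ValueError, IndexError):
        out["major_axis_mm"] = math.nan
    return out


# ---------------------------------------------------------------------------
# Feature vectors and delta-radiomics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """Named radiomic feature values at one time-point (NaN = missing)."""

    values: dict[str, float]
    time_point: str = "W0"

    def __getitem__(self, name: str) -> float:
        return self.values[resolve_feature_name(name)]

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DeltaFeatures:
    """Relative deviations Δ_RF = (RF_Wk − RF_W0)/|RF_W0| for one pair."""

    values: dict[str, float]
    pair: tuple[str, str] = ("W0", "W2")

    def __getitem__(self, name: str) -> float:
        return self.values[resolve_feature_name(name)]


def _texture_block(matrices: TextureMatrices, family: str) -> dict[str, float]:
    if family == "glcm":
        return glcm_features(matrices.glcm)
    if family == "glrlm":
        return glrlm_features(matrices.glrlm, matrices.n_voxels)
    if family == "glszm":
        return glszm_features(matrices.glszm, matrices.n_voxels)
    if family == "ngtdm":
        return ngtdm_features(matrices.ngtdm_s, matrices.ngtdm_n, matrices.n_voxels)
    raise ValueError(family)


def feature_vector(
    volume: PETVolume,
    mask: BinaryMask,
    config: RadiomicsConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """Compute the configured radiomic features inside ``mask``.

    Only the matrices required by the requested feature subset are built, so a
    single-feature extraction (e.g. LGZE for a screening pass) stays cheap.
    """
    check_same_grid(volume, mask, what="feature extraction")
    if not mask.values.any():
        raise ValueError("mask is empty")
    wanted = config.feature_list()
    if config.aggregation != "merged":
        raise NotImplementedError("only merged direction aggregation is implemented")

    out: dict[str, float] = {}
    if any(n in FIRST_ORDER_FEATURES for n in wanted):
        out.update(first_order_features(volume, mask, config.bin_width))

    needed: dict[str, set[str]] = {v: set() for v in VARIANTS}
    for name in wanted:
        for variant in ("wf_", "q_", ""):
            if variant and name.startswith(variant):
                fam = name[len(variant):].split("_", 1)[0]
                needed[variant].add(fam)
                break
        else:
            fam = name.split("_", 1)[0]
            if fam in TEXTURE_FAMILIES:
                needed[""].add(fam)

    for variant, families in needed.items():
        if not families:
            continue
        if variant == "":
            disc = discretize_fixed(volume, mask, config.bin_width)
        elif variant == "wf_":
            filtered = wavelet_bandpass(volume, mask, config.wavelet)
            disc = discretize_fixed(filtered, mask, config.bin_width)
        else:
            disc = discretize_equal_probability(volume, mask, config.q_levels)
        matrices = build_matrices(disc)
        for family in families:
            block = _texture_block(matrices, family)
            out.update({f"{variant}{family}_{k}": v for k, v in block.items()})

    values = {name: out[name] for name in wanted}
    return FeatureVector(values, volume.time_point)


def delta_features(fv0: FeatureVector, fvk: FeatureVector) -> DeltaFeatures:
    """Relative deviation of every feature between baseline and follow-up.

    A delta is missing (NaN) when the baseline value is zero or either value
    is itself missing.
    """
    if set(fv0.values) != set(fvk.values):
        raise ValueError("feature lists differ between time-points")
    deltas: dict[str, float] = {}
    for name, v0 in fv0.values.items():
        vk = fvk.values[name]
        if not (np.isfinite(v0) and np.isfinite(vk)) or v0 == 0:
            deltas[name] = math.nan
        else:
            deltas[name] = (vk - v0) / abs(v0)
    return DeltaFeatures(deltas, (fv0.time_point, fvk.time_point))
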