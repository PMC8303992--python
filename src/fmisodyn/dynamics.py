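"""Hypoxia dynamics: size change, spatial overlap, and the classification parameter.

Between baseline (W0) and a later scan, the hypoxic sub-volume can grow,
shrink, or move.  Size change is the relative volume difference

    ΔV = 100 · (V_new − V_ref) / V_ref   [%]

with the baseline mask always the reference.  Patients are classed as
increasing (IH, ΔV ≥ 15%), stable (SH, −15% < ΔV < 15%) or decreasing
hypoxia (DH, ΔV ≤ −15%).  Location change is quantified by a single
classification parameter CP picked from three overlap measures according to
the size class:

    SH → CP = DICE,   IH → CP = Sens.,   DH → CP = PPV

so that a follow-up contour that fully covers (IH), is fully contained in
(DH), or equals (SH) the baseline contour scores CP = 1 regardless of the
size change: geographically static hypoxia has CP near 1, dynamic hypoxia
CP near 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .volumes import BinaryMask, check_same_grid

#: half-width (%) of the stable band for the size classification
STABLE_BAND_PERCENT = 15.0

SIZE_CLASSES = ("IH", "SH", "DH", "resolved", "absent")


@dataclass(frozen=True)
class OverlapMetrics:
    """Volume change and spatial-overlap measures for one mask pair.

    DICE = 2·|ref ∩ new| / (|ref| + |new|);  Sens. = |ref ∩ new| / |ref|;
    PPV = |ref ∩ new| / |new|.  The baseline (W0) mask is the reference.
    """

    delta_v: float          # percent
    dice: float
    sens: float
    ppv: float
    v_ref_ml: float
    v_new_ml: float
    intersection_ml: float


@dataclass(frozen=True)
class HypoxiaStatus:
    """Size class and classification parameter for one (W0 → Wk) pair.

    ``cp`` is None exactly when the pair cannot be classified: the follow-up
    HSV vanished (``resolved``) or the baseline HSV was already empty
    (``absent``).
    """

    size_class: str
    cp: float | None
    pair: tuple[str, str] = ("W0", "W2")

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}")
        has_cp = self.cp is not None
        if has_cp != (self.size_class in ("IH", "SH", "DH")):
            raise ValueError("cp must be present exactly for IH/SH/DH")
        if has_cp and not (0.0 <= self.cp <= 1.0):
            raise ValueError(f"cp must lie in [0, 1], got {self.cp}")


def overlap_metrics(ref: BinaryMask, new: BinaryMask) -> OverlapMetrics:
    """Compute ΔV, DICE, Sens. and PPV with ``ref`` (the W0 HSV) as reference."""
    check_same_grid(ref, new, what="overlap masks")
    n_ref = ref.voxel_count
    if n_ref == 0:
        raise ValueError("reference mask is empty; ΔV is undefined")
    n_new = new.voxel_count
    n_int = int((ref.values & new.values).sum())
    vv = ref.voxel_volume_ml
    delta_v = 100.0 * (n_new - n_ref) / n_ref
    dice = 2.0 * n_int / (n_ref + n_new)
    sens = n_int / n_ref
    ppv = n_int / n_new if n_new > 0 else 0.0
    return OverlapMetrics(delta_v, dice, sens, ppv, n_ref * vv, n_new * vv, n_int * vv)


def classify_size(delta_v: float) -> str:
    """IH / SH / DH from the relative volume difference (percent).

    The stable band is open: −15 < ΔV < 15.  ΔV = +15 is IH; ΔV = −15 is
    assigned to DH, closing the partition symmetrically to the IH boundary.
    """
    if not np.isfinite(delta_v):
        raise ValueError(f"delta_v must be finite, got {delta_v}")
    if delta_v >= STABLE_BAND_PERCENT:
        return "IH"
    if delta_v <= -STABLE_BAND_PERCENT:
        return "DH"
    return "SH"


def classification_parameter(
    metrics: OverlapMetrics, pair: tuple[str, str] = ("W0", "W2")
) -> HypoxiaStatus:
    """The classification parameter CP for one overlap-metrics record.

    CP = DICE for stable, Sens. for increasing, PPV for decreasing hypoxia.
    A vanished follow-up volume yields ``resolved`` with no CP.
    """
    if metrics.v_new_ml == 0:
        return HypoxiaStatus("resolved", None, pair)
    size_class = classify_size(metrics.delta_v)
    cp = {"SH": metrics.dice, "IH": metrics.sens, "DH": metrics.ppv}[size_class]
    return HypoxiaStatus(size_class, float(cp), pair)


def classify_pair(
    ref: BinaryMask, new: BinaryMask, pair: tuple[str, str] = ("W0", "W2")
) -> HypoxiaStatus:
    """End-to-end status for a mask pair, handling empty masks.

    Empty baseline → ``absent`` (nothing to track); empty follow-up →
    ``resolved`` (hypoxia vanished).  Otherwise delegates to
    :func:`overlap_metrics` + :func:`classification_parameter`.
    """
    check_same_grid(ref, new, what="overlap masks")
    if ref.voxel_count == 0:
        return HypoxiaStatus("absent", None, pair)
    if new.voxel_count == 0:
        return HypoxiaStatus("resolved", None, pair)
    return classification_parameter(overlap_metrics(ref, new), pair)


def dichotomize_cp(
    statuses: Sequence[HypoxiaStatus],
    rule: str = "median",
    threshold: float | None = None,
    resolved_to_high: bool = False,
) -> list[str]:
    """Split patients into CP_high / CP_low groups for survival analysis.

    rule="median": cut at the cohort median of the non-missing CP values,
    ties going to CP_high (cp >= median).  rule="fixed" cuts at ``threshold``.
    Patients without CP are ``excluded`` unless ``resolved_to_high`` maps
    resolved hypoxia (the volume vanished, i.e. hypoxia is gone) to CP_high.
    """
    cps = [s.cp for s in statuses if s.cp is not None]
    if len(cps) < 2:
        raise ValueError("need at least 2 patients with a defined CP")
    if rule == "median":
        cut = float(np.median(cps))
    elif rule == "fixed":
        if threshold is None:
            raise ValueError("rule='fixed' requires a threshold")
        cut = float(threshold)
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")

    labels = []
    for s in statuses:
        if s.cp is not None:
            labels.append("CP_high" if s.cp >= cut else "CP_low")
        elif s.size_class == "resolved" and resolved_to_high:
            labels.append("CP_high")
        else:
            labels.append("excluded")
    return labels
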