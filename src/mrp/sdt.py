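"""Criterion-sweep signal detection scoring of 8-level decision x confidence
responses.

A response is encoded as dxc = (+confidence) for a "yes" decision and
(-confidence) for "no", giving the ordered scale
(-4, -3, -2, -1, 1, 2, 3, 4).  Type 1 ROC curves sweep the 7 cut points of
that scale from strictest to most lenient; Type 2 ROC curves sweep the 3 cut
points of the 4-level confidence scale over correct vs incorrect trials.
Areas are non-parametric (trapezoidal over the criterion points), which for
these exhaustive criterion sets coincides with the rank (Mann-Whitney)
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import eccentricity_class
from .exceptions import InsufficientDataError

DXC_LEVELS = (-4, -3, -2, -1, 1, 2, 3, 4)
TDXC_LEVELS = (-3.5, -2.5, -1.5, -0.5, 0.5, 1.5, 2.5, 3.5)
TYPE1_CRITERIA = (4, 3, 2, 1, -1, -2, -3)   # strictest -> most lenient
TYPE2_CRITERIA = (4, 3, 2)

DECISIONS = ("yes", "no")
CONFIDENCES = (1, 2, 3, 4)


def encode_dxc(decision: str, confidence: int) -> int:
    """Signed decision x confidence code: +confidence for yes, -confidence for no."""
    if confidence not in CONFIDENCES:
        raise ValueError(f"confidence must be 1-4, got {confidence!r}")
    if decision == "yes":
        return confidence
    if decision == "no":
        return -confidence
    raise ValueError(f"decision must be 'yes' or 'no', got {decision!r}")


def decode_dxc(dxc: int) -> tuple[str, int]:
    """Inverse of :func:`encode_dxc`."""
    if dxc not in DXC_LEVELS:
        raise ValueError(f"dxc must be in {DXC_LEVELS}, got {dxc!r}")
    return ("yes", dxc) if dxc > 0 else ("no", -dxc)


def transform_tdxc(dxc):
    """Shift dxc half a step toward zero: the 8 levels become -3.5 .. +3.5
    with uniform spacing 1.  Accepts a scalar or an array."""
    arr = np.asarray(dxc)
    if not np.isin(arr, DXC_LEVELS).all():
        bad = arr[~np.isin(arr, DXC_LEVELS)]
        raise ValueError(f"dxc values must be in {DXC_LEVELS}, got {bad[:5]!r}")
    out = np.where(arr > 0, arr - 0.5, arr + 0.5)
    return float(out) if np.isscalar(dxc) else out


@dataclass(frozen=True)
class ProbeResponse:
    """One probe judgement."""
    participant_id: str
    image_id: str
    congruence: str          # congruent | incongruent
    patch_type: str          # present | original | modified | null
    location: int            # 1-9
    decision: str            # yes | no
    confidence: int          # 1-4
    eccentricity_class: str = ""
    dxc: int = field(default=0)

    def __post_init__(self):
        object.__setattr__(self, "dxc", encode_dxc(self.decision, self.confidence))
        ecc = eccentricity_class(self.location)
        if self.eccentricity_class and self.eccentricity_class != ecc:
            raise ValueError(
                f"location {self.location} is {ecc}, not {self.eccentricity_class}")
        object.__setattr__(self, "eccentricity_class", ecc)

    @property
    def tdxc(self) -> float:
        return transform_tdxc(self.dxc)


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (false-alarm, hit) points from a strict-to-lenient criterion sweep."""
    points: tuple[tuple[float, float], ...]
    criteria: tuple[float, ...]
    curve_kind: str          # type1 | type2
    auc: float

    def full_path(self) -> np.ndarray:
        """Points with the implicit (0,0) and (1,1) endpoints, sorted."""
        pts = sorted(set(self.points) | {(0.0, 0.0), (1.0, 1.0)})
        return np.asarray(pts)


def auc_trapezoid(points) -> float:
    """Area under the piecewise-linear curve through (0,0), ``points``, (1,1).

    Duplicate points are collapsed and points are sorted lexicographically by
    (fa, hit) before integration.
    """
    pts = {(float(fa), float(hit)) for fa, hit in points}
    for fa, hit in pts:
        if not (0.0 <= fa <= 1.0 and 0.0 <= hit <= 1.0):
            raise ValueError(f"ROC point outside the unit square: {(fa, hit)}")
    pts |= {(0.0, 0.0), (1.0, 1.0)}
    arr = np.asarray(sorted(pts))
    return float(np.trapezoid(arr[:, 1], arr[:, 0]))


def auc_rank_oracle(signal, noise) -> float:
    """Mann-Whitney AUC: P(signal > noise) + 0.5 P(tie), by full enumeration."""
    s = np.asarray(signal, dtype=float)
    n = np.asarray(noise, dtype=float)
    if s.size == 0 or n.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    diff = s[:, None] - n[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def _sweep(signal, noise, criteria, kind) -> ROCCurve:
    s = np.asarray(signal, dtype=float)
    n = np.asarray(noise, dtype=float)
    if s.size == 0 or n.size == 0:
        raise InsufficientDataError(
            f"{kind} ROC needs non-empty signal and noise samples")
    points = tuple((float((n >= c).mean()), float((s >= c).mean())) for c in criteria)
    return ROCCurve(points, tuple(criteria), kind, auc_trapezoid(points))


def type1_roc(signal_dxc, noise_dxc) -> ROCCurve:
    """7-criterion ROC over dxc values (signal vs noise probes)."""
    for name, vals in (("signal", signal_dxc), ("noise", noise_dxc)):
        if not np.isin(np.asarray(vals), DXC_LEVELS).all():
            raise ValueError(f"{name} contains values outside the dxc scale")
    return _sweep(signal_dxc, noise_dxc, TYPE1_CRITERIA, "type1")


def type2_roc(correct_confidences, incorrect_confidences) -> ROCCurve:
    """3-criterion metacognitive ROC over confidences of correct vs incorrect trials."""
    for name, vals in (("correct", correct_confidences),
                       ("incorrect", incorrect_confidences)):
        if not np.isin(np.asarray(vals), CONFIDENCES).all():
            raise ValueError(f"{name} contains values outside the confidence scale")
    return _sweep(correct_confidences, incorrect_confidences, TYPE2_CRITERIA, "type2")


#: task -> (signal patch types, noise patch types)
TASKS = {
    "present_vs_null": (frozenset({"present", "original"}), frozenset({"null"})),
    "original_vs_modified": (frozenset({"original"}), frozenset({"modified"})),
}


def classify_correct(decision: str, patch_type: str, task: str) -> bool | None:
    """Whether a judgement counts as correct under ``task``.

    Signal patches are correct when endorsed ("yes"), noise patches when
    rejected ("no").  Returns None for patch types outside the task's domain
    (the caller filters those probes out).
    """
    if decision not in DECISIONS:
        raise ValueError(f"decision must be 'yes' or 'no', got {decision!r}")
    signal, noise = TASKS[task]
    if patch_type in signal:
        return decision == "yes"
    if patch_type in noise:
        return decision == "no"
    return None
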