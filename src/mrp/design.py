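"""Trial-design planning: 3x3 grid geometry, probe schedules, null-patch
allocation, catch-trial arithmetic.

Two experiment layouts are supported.  ``exp1`` is the in-laboratory layout:
80 trials per participant (40 congruent, 40 incongruent initial images), each
trial probed with 21 patches when the critical object sits on an odd grid
location (1 original + 1 modified + 4 present + 15 null) or 20 when it sits on
an even location (3 present).  ``exp2`` is the online layout: 34 experimental
trials per participant (17/17 congruence), each probed with 6 patches
(2 present + 3 null + 1 original-XOR-modified), plus 12 experimental catch
trials and 1 practice catch trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CapacityError

LOCATIONS = tuple(range(1, 10))
ODD_LOCATIONS = (1, 3, 5, 7, 9)
EVEN_LOCATIONS = (2, 4, 6, 8)

#: grid location -> eccentricity stratum (row-major numbering, 5 = centre)
LOCATION_CLASSES: Mapping[int, str] = {
    5: "fovea",
    2: "parafovea", 4: "parafovea", 6: "parafovea", 8: "parafovea",
    1: "periphery", 3: "periphery", 7: "periphery", 9: "periphery",
}

ECCENTRICITY_ORDER = ("fovea", "parafovea", "periphery")

PATCH_TYPES = ("present", "original", "modified", "null")


def eccentricity_class(location: int) -> str:
    """Map a grid location (1-9) onto its eccentricity stratum."""
    try:
        return LOCATION_CLASSES[location]
    except KeyError:
        raise ValueError(f"location must be 1-9, got {location!r}") from None


# distance from the central patch centre, in units of one patch width
_STEPS = {"fovea": 0.0, "parafovea": 1.0, "periphery": math.sqrt(2)}


def eccentricity_dva(location: int, image_width_dva: float, *,
                     method: str = "planar", ndigits: int | None = None) -> float:
    """Centre-to-centre eccentricity of a grid patch, in degrees of visual angle.

    ``method="planar"`` treats the image as rendered on a flat display:
    patch offsets add linearly on the screen plane and are converted back to
    angle with atan.  For a 19.4-dva image this yields 6.5 dva for edge
    patches and 9.2 dva for corner patches.  ``method="small_angle"`` uses
    the linear approximation ``(image_width/3) * step`` instead (step 0, 1 or
    sqrt(2)); the two agree to <0.1 dva below ~15 dva.
    """
    if image_width_dva <= 0:
        raise ValueError("image_width_dva must be positive")
    step = _STEPS[eccentricity_class(location)]
    if method == "small_angle":
        ecc = image_width_dva / 3.0 * step
    elif method == "planar":
        patch_w = 2.0 * math.tan(math.radians(image_width_dva) / 2.0) / 3.0
        ecc = math.degrees(math.atan(patch_w * step))
    else:
        raise ValueError(f"unknown method {method!r}")
    return round(ecc, ndigits) if ndigits is not None else ecc


def visual_angle(extent_cm: float, distance_cm: float) -> float:
    """Visual angle (degrees) subtended by ``extent_cm`` at ``distance_cm``."""
    if distance_cm <= 0:
        raise ValueError("distance_cm must be positive")
    if extent_cm < 0:
        raise ValueError("extent_cm must be non-negative")
    return math.degrees(2.0 * math.atan(extent_cm / (2.0 * distance_cm)))


def split_grid(image: np.ndarray) -> dict[int, np.ndarray]:
    """Split a raster into 9 equal patches tagged 1-9 (row-major, 5 = centre).

    Non-square images are cropped to the top-left square; dimensions not
    divisible by 3 are truncated (trailing rows/columns dropped) so all
    patches are exactly equal-sized.
    """
    image = np.asarray(image)
    if image.ndim < 2:
        raise ValueError("image must be at least 2-D")
    side = min(image.shape[0], image.shape[1])
    side -= side % 3
    if side < 3:
        raise ValueError("image too small to split into a 3x3 grid")
    cropped = image[:side, :side]
    step = side // 3
    patches = {}
    for r in range(3):
        for c in range(3):
            loc = 3 * r + c + 1
            patches[loc] = cropped[r * step:(r + 1) * step, c * step:(c + 1) * step]
    return patches


# ---------------------------------------------------------------------------
# catch-trial exclusion threshold

def catch_cutoff(n_catch: int = 13, n_options: int = 8, quantile: float = 0.99,
                 *, rounded: bool = True) -> float:
    """Accuracy threshold for random responding on catch trials.

    Returns ``k*/n_catch`` where ``k*`` is the smallest count with
    ``Binomial(n_catch, 1/n_options)`` CDF at or above ``quantile``.
    """
    if n_catch < 1 or n_options < 1:
        raise ValueError("n_catch and n_options must be >= 1")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    k = int(stats.binom.ppf(quantile, n_catch, 1.0 / n_options))
    acc = k / n_catch
    return round(acc, 2) if rounded else acc


def catch_cutoff_mc(n_catch: int = 13, n_options: int = 8, quantile: float = 0.99,
                    n_rep: int = 100_000, seed: int | None = 0) -> float:
    """Monte-Carlo cross-check of :func:`catch_cutoff` (un-rounded)."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    rng = np.random.default_rng(seed)
    accs = rng.binomial(n_catch, 1.0 / n_options, size=n_rep) / n_catch
    return float(np.quantile(accs, quantile, method="inverted_cdf"))


# ---------------------------------------------------------------------------
# probe schedules

@dataclass(frozen=True)
class ProbePlan:
    patch_type: str           # present | original | modified | null
    location: int             # 1-9
    patch_id: str


@dataclass
class TrialPlan:
    participant_id: str
    trial_index: int
    image_pair_id: str
    initial_congruence: str   # congruent | incongruent
    location_set: str | None  # odd | even (exp1), None (exp2)
    probes: list[ProbePlan]
    is_catch: bool = False
    catch_required: str | None = None  # e.g. "yes:4"
    is_practice: bool = False


@dataclass
class DesignPlan:
    experiment: str
    participants: list[str]
    trials: list[TrialPlan]

    @property
    def n_experimental_trials(self) -> int:
        return sum(1 for t in self.trials if not t.is_catch and not t.is_practice)

    def to_frame(self) -> pd.DataFrame:
        """One row per scheduled probe (catch trials contribute one row each)."""
        rows = []
        for t in self.trials:
            if t.is_catch:
                rows.append({
                    "participant_id": t.participant_id, "experiment": self.experiment,
                    "trial_index": t.trial_index, "image_pair_id": "",
                    "initial_congruence": "", "probe_index": 0, "patch_type": "",
                    "location": -1, "eccentricity_class": "", "patch_id": "",
                    "is_catch": True, "catch_required": t.catch_required,
                    "is_practice": t.is_practice,
                })
                continue
            for i, p in enumerate(t.probes):
                rows.append({
                    "participant_id": t.participant_id, "experiment": self.experiment,
                    "trial_index": t.trial_index, "image_pair_id": t.image_pair_id,
                    "initial_congruence": t.initial_congruence, "probe_index": i,
                    "patch_type": p.patch_type, "location": p.location,
                    "eccentricity_class": eccentricity_class(p.location),
                    "patch_id": p.patch_id, "is_catch": False,
                    "catch_required": None, "is_practice": t.is_practice,
                })
        return pd.DataFrame(rows)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def plan_trial(experiment: str, image_pair_id: str, congruence: str,
               critical_location: int, rng, *, participant_id: str = "p0",
               trial_index: int = 0, object_patch: str | None = None,
               null_ids: Sequence[str] | None = None) -> TrialPlan:
    """Plan the probe sequence for one trial.

    ``exp1`` probes both the original and the modified patch plus all other
    patches from the location set (odd/even) containing the critical
    location, and 15 null patches.  ``exp2`` probes 2 present + 3 null + one
    of original/modified (``object_patch``, randomized when None).  Probe
    order is fully randomized; deterministic given the generator state.
    """
    rng = _as_rng(rng)
    if critical_location not in LOCATIONS:
        raise ValueError(f"critical_location must be 1-9, got {critical_location!r}")
    if congruence not in ("congruent", "incongruent"):
        raise ValueError(f"bad congruence {congruence!r}")
    pid = image_pair_id
    if experiment == "exp1":
        if critical_location % 2 == 1:
            loc_set, set_name = ODD_LOCATIONS, "odd"
        else:
            loc_set, set_name = EVEN_LOCATIONS, "even"
        probes = [ProbePlan("original", critical_location, f"{pid}:orig"),
                  ProbePlan("modified", critical_location, f"{pid}:mod")]
        for loc in loc_set:
            if loc != critical_location:
                probes.append(ProbePlan("present", loc, f"{pid}:present:{loc}"))
        n_null = 15
    elif experiment == "exp2":
        if object_patch is None:
            object_patch = "original" if rng.random() < 0.5 else "modified"
        if object_patch not in ("original", "modified"):
            raise ValueError(f"bad object_patch {object_patch!r}")
        suffix = "orig" if object_patch == "original" else "mod"
        probes = [ProbePlan(object_patch, critical_location, f"{pid}:{suffix}")]
        present_locs = rng.choice([l for l in LOCATIONS if l != critical_location],
                                  size=2, replace=False)
        probes += [ProbePlan("present", int(l), f"{pid}:present:{int(l)}")
                   for l in present_locs]
        loc_set = set_name = None
        n_null = 3
    else:
        raise ValueError(f"unknown experiment {experiment!r}")

    if null_ids is None:
        null_ids = [f"null:{pid}:{participant_id}:{j}" for j in range(n_null)]
    if len(null_ids) != n_null:
        raise ValueError(f"expected {n_null} null ids, got {len(null_ids)}")
    null_locs = rng.integers(1, 10, size=n_null)
    probes += [ProbePlan("null", int(loc), nid)
               for loc, nid in zip(null_locs, null_ids)]
    order = rng.permutation(len(probes))
    probes = [probes[i] for i in order]
    return TrialPlan(participant_id, trial_index, pid, congruence,
                     set_name, probes)


def allocate_nulls(n_participants: int, nulls_per_trial: int,
                   pool: Sequence[str], image_id: str | None = None,
                   rng=None) -> dict[int, list[str]]:
    """Assign each participant a disjoint set of null patches for one image.

    Raises :class:`CapacityError` when the pool cannot supply
    ``n_participants * nulls_per_trial`` distinct patches.
    """
    need = n_participants * nulls_per_trial
    if len(pool) < need:
        raise CapacityError(
            f"null pool for image {image_id!r} has {len(pool)} patches; "
            f"{need} required ({need - len(pool)} short)")
    rng = _as_rng(rng)
    order = rng.permutation(len(pool))
    picked = [pool[i] for i in order[:need]]
    return {p: picked[p * nulls_per_trial:(p + 1) * nulls_per_trial]
            for p in range(n_participants)}


@dataclass(frozen=True)
class Experiment2Layout:
    n_pairs: int
    pairs_per_participant: int
    participants_per_pair: int
    batches: tuple[tuple[int, ...], ...]   # 1-based pair indices per batch

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    @property
    def total_participants(self) -> int:
        return self.participants_per_pair * self.n_pairs // self.pairs_per_participant

    @property
    def total_trials(self) -> int:
        return self.total_participants * self.pairs_per_participant


def plan_experiment2(n_pairs: int = 136, pairs_per_participant: int = 34,
                     participants_per_pair: int = 60) -> Experiment2Layout:
    """Batch arithmetic for the online layout (equal-size batches of pairs)."""
    if n_pairs % pairs_per_participant != 0:
        raise ValueError(
            f"{n_pairs} pairs cannot be grouped into equal batches of "
            f"{pairs_per_participant}")
    n_batches = n_pairs // pairs_per_participant
    batches = tuple(
        tuple(range(b * pairs_per_participant + 1, (b + 1) * pairs_per_participant + 1))
        for b in range(n_batches))
    return Experiment2Layout(n_pairs, pairs_per_participant,
                             participants_per_pair, batches)


# ---------------------------------------------------------------------------
# full cohort designs

_RESPONSE_OPTIONS = [("yes", c) for c in (1, 2, 3, 4)] + [("no", c) for c in (1, 2, 3, 4)]


def _random_catch_requirement(rng) -> str:
    d, c = _RESPONSE_OPTIONS[int(rng.integers(len(_RESPONSE_OPTIONS)))]
    return f"{d}:{c}"


def build_design(experiment: str, n_participants: int | None = None,
                 seed: int = 0, pairs: Sequence[tuple[str, int]] | None = None,
                 n_pairs: int | None = None) -> DesignPlan:
    """Generate a complete, seeded cohort design.

    ``pairs`` is a list of (image_pair_id, critical_location); when omitted a
    synthetic set is generated (80 pairs for exp1, 136 for exp2) with random
    critical locations.  Each participant gets an independent substream of the
    master seed, so plans are reproducible probe-for-probe.
    """
    master = np.random.default_rng(seed)
    if experiment == "exp1":
        return _build_exp1(n_participants or 15, master, pairs, n_pairs or 80)
    if experiment == "exp2":
        return _build_exp2(n_participants, master, pairs, n_pairs or 136)
    raise ValueError(f"unknown experiment {experiment!r}")


def _make_pairs(n_pairs: int, rng) -> list[tuple[str, int]]:
    locs = rng.integers(1, 10, size=n_pairs)
    return [(f"pair{i + 1:03d}", int(locs[i])) for i in range(n_pairs)]


def _build_exp1(n_participants, master, pairs, n_pairs) -> DesignPlan:
    if pairs is None:
        pairs = _make_pairs(n_pairs, master)
    if len(pairs) % 2 != 0:
        raise ValueError("exp1 needs an even number of image pairs")
    participants = [f"P{p + 1:03d}" for p in range(n_participants)]
    # one disjoint null assignment per image, shared pool namespaced per image
    null_by_image = {}
    for pid, _loc in pairs:
        pool = [f"null:{pid}:{j}" for j in range(n_participants * 15)]
        null_by_image[pid] = allocate_nulls(n_participants, 15, pool, pid, master)
    substreams = master.spawn(n_participants)
    trials: list[TrialPlan] = []
    half = len(pairs) // 2
    for p, (part, rng) in enumerate(zip(participants, substreams)):
        # image order fixed across participants; congruence randomized per
        # participant, balanced half/half
        cong = np.array(["congruent"] * half + ["incongruent"] * half)
        rng.shuffle(cong)
        for t, ((pid, loc), cg) in enumerate(zip(pairs, cong)):
            trials.append(plan_trial(
                "exp1", pid, str(cg), loc, rng, participant_id=part,
                trial_index=t, null_ids=null_by_image[pid][p]))
    return DesignPlan("exp1", participants, trials)


def _build_exp2(n_participants, master, pairs, n_pairs,
                pairs_per_participant: int = 34,
                participants_per_pair: int = 60,
                n_catch: int = 12, n_practice_catch: int = 1) -> DesignPlan:
    if pairs is None:
        pairs = _make_pairs(n_pairs, master)
    layout = plan_experiment2(len(pairs), pairs_per_participant, participants_per_pair)
    if n_participants is None:
        n_participants = layout.total_participants
    participants = [f"P{p + 1:03d}" for p in range(n_participants)]
    substreams = master.spawn(n_participants)
    trials: list[TrialPlan] = []
    half = pairs_per_participant // 2
    for p, (part, rng) in enumerate(zip(participants, substreams)):
        batch = layout.batches[p % layout.n_batches]
        my_pairs = [pairs[i - 1] for i in batch]
        order = rng.permutation(len(my_pairs))
        cong = np.array(["congruent"] * half
                        + ["incongruent"] * (pairs_per_participant - half))
        rng.shuffle(cong)
        # interleave catch trials uniformly among the experimental positions
        n_slots = pairs_per_participant + n_catch
        catch_slots = set(rng.choice(n_slots, size=n_catch, replace=False).tolist())
        trials.append(TrialPlan(part, -1, "", "", None, [], is_catch=True,
                                catch_required=_random_catch_requirement(rng),
                                is_practice=True))
        exp_i = 0
        for slot in range(n_slots):
            if slot in catch_slots:
                trials.append(TrialPlan(part, slot, "", "", None, [],
                                        is_catch=True,
                                        catch_required=_random_catch_requirement(rng)))
                continue
            pid, loc = my_pairs[order[exp_i]]
            trials.append(plan_trial(
                "exp2", pid, str(cong[exp_i]), loc, rng,
                participant_id=part, trial_index=slot))
            exp_i += 1
    return DesignPlan("exp2", participants, trials)
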