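"""Empirical significance of structural distances.

Normalized warping distances have no closed-form null distribution, so
p-values are empirical: a library of molecules is stratified into length
classes (defaults 200, 500, 1000 and 5000 nt, 100 molecules per class), all
pairwise open-begin/end distances are computed within and between classes,
and an observed distance is ranked against the stored null of the nearest
class pair.  Smaller distances are more significant; the add-one
pseudocount keeps p strictly positive:

    p = (1 + #{null <= observed}) / (1 + n_null)

The module also provides a shuffling control: the distance of a putatively
homologous pair is compared against the distances obtained after shuffling
one of the two profiles, verifying that the observed similarity exceeds a
composition-matched null.

A normalized distance of 0.10 or higher is conventionally annotated as
"different" -- an annotation, never a hard filter.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dtw_core import dtw_obe
from .profile_io import StructureProfile, shuffle_profile, SHUFFLE_BLOCK_LEN_DEFAULT

__all__ = [
    "NullDistribution",
    "ControlReport",
    "build_null",
    "empirical_pvalue",
    "shuffled_control",
    "assign_length_class",
    "classify_distance",
    "DEFAULT_LENGTH_CLASSES",
    "DEFAULT_PER_CLASS",
    "DIFFERENT_THRESHOLD",
    "MIN_CLASS_SIZE",
]

#: Length classes (nt) used for null stratification.
DEFAULT_LENGTH_CLASSES = (200, 500, 1000, 5000)
#: Molecules sampled per length class when calibrating.
DEFAULT_PER_CLASS = 100
#: Minimum molecules per class accepted at calibration time.
MIN_CLASS_SIZE = 30
#: Normalized distances at/above this value are annotated as "different".
DIFFERENT_THRESHOLD = 0.10


def assign_length_class(length: int, classes: tuple[int, ...]) -> int:
    """Nearest length class in log-length space."""
    if length < 1:
        raise ValueError("length must be >= 1")
    logs = np.log(np.asarray(classes, dtype=float))
    return int(classes[int(np.argmin(np.abs(logs - np.log(length))))])


def classify_distance(d: float) -> str:
    """Annotate a normalized distance as 'similar' or 'different' (cut 0.10)."""
    return "different" if d >= DIFFERENT_THRESHOLD else "similar"


@dataclass
class NullDistribution:
    """Length-class-stratified empirical null of normalized distances.

    ``pairs`` maps an unordered class pair ``(c_small, c_large)`` to the
    sorted array of null distances observed for that pair.
    """

    classes: tuple[int, ...]
    pairs: dict[tuple[int, int], np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, arr in list(self.pairs.items()):
            arr = np.sort(np.asarray(arr, dtype=float))
            if arr.size == 0:
                raise ValueError(f"empty null for class pair {key}")
            if np.any(arr < 0):
                raise ValueError(f"negative null distance in class pair {key}")
            self.pairs[key] = arr

    def n(self, class_pair: tuple[int, int]) -> int:
        return int(self.pairs[class_pair].size)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "pairs": {f"{a}-{b}": arr.tolist() for (a, b), arr in self.pairs.items()},
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "NullDistribution":
        payload = json.loads(Path(path).read_text())
        pairs = {}
        for key, values in payload["pairs"].items():
            a, b = key.split("-")
            pairs[(int(a), int(b))] = np.asarray(values, dtype=float)
        return cls(
            classes=tuple(payload["classes"]),
            pairs=pairs,
            provenance=payload.get("provenance", {}),
        )


def build_null(
    profiles: list[StructureProfile],
    classes: tuple[int, ...] = DEFAULT_LENGTH_CLASSES,
    per_class: int = DEFAULT_PER_CLASS,
    seed: int = 0,
    normalization: str = "sum_lengths",
) -> NullDistribution:
    """Calibrate a length-stratified null from a profile collection.

    Profiles are assigned to the nearest class on log-length; ``per_class``
    molecules are sampled from each class (deterministically under
    ``seed``) and all pairwise open-begin/end distances are computed within
    and between classes.  Classes with fewer than 30 assignable profiles
    (or ``per_class`` below 30) are rejected -- small nulls give dishonest
    p-values.
    """
    if per_class < MIN_CLASS_SIZE:
        raise ValueError(
            f"per_class={per_class} is below the calibration floor of {MIN_CLASS_SIZE}"
        )
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[StructureProfile]] = {c: [] for c in classes}
    for p in profiles:
        by_class[assign_length_class(len(p), classes)].append(p)

    sampled: dict[int, list[StructureProfile]] = {}
    for c in classes:
        members = by_class[c]
        if len(members) < MIN_CLASS_SIZE:
            raise ValueError(
                f"length class {c} nt has only {len(members)} assignable "
                f"profiles (need >= {MIN_CLASS_SIZE})"
            )
        take = min(per_class, len(members))
        idx = rng.choice(len(members), size=take, replace=False)
        sampled[c] = [members[i] for i in np.sort(idx)]

    pairs: dict[tuple[int, int], np.ndarray] = {}
    for a, b in itertools.combinations_with_replacement(sorted(classes), 2):
        if a == b:
            combos = itertools.combinations(sampled[a], 2)
        else:
            combos = itertools.product(sampled[a], sampled[b])
        dists = [
            dtw_obe(x, y, norm=normalization).normalized_distance
            for x, y in combos
        ]
        pairs[(a, b)] = np.sort(np.asarray(dists))

    return NullDistribution(
        classes=tuple(classes),
        pairs=pairs,
        provenance={
            "seed": seed,
            "per_class": per_class,
            "mode": "obe",
            "normalization": normalization,
            "n_profiles": len(profiles),
        },
    )


def empirical_pvalue(
    obs: float,
    qlen: int,
    rlen: int,
    nulls: NullDistribution,
) -> float:
    """Empirical p-value of an observed normalized distance.

    The null of the class pair nearest to (qlen, rlen) is used; smaller
    distances are more significant.  Always in (0, 1].
    """
    ca = assign_length_class(qlen, nulls.classes)
    cb = assign_length_class(rlen, nulls.classes)
    key = (min(ca, cb), max(ca, cb))
    if key not in nulls.pairs:
        raise KeyError(
            f"no null distribution for length-class pair {key}; "
            "recalibrate with build_null covering these classes"
        )
    null = nulls.pairs[key]
    count = int(np.searchsorted(null, obs, side="right"))
    return (1 + count) / (1 + null.size)


@dataclass(frozen=True)
class ControlReport:
    """Shuffling control around one putatively homologous pair."""

    query_id: str
    reference_id: str
    true_distance: float
    true_pvalue: float | None
    shuffle_distances: tuple[float, ...]
    frac_shuffles_leq_true: float

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "reference_id": self.reference_id,
            "true_distance": self.true_distance,
            "true_pvalue": self.true_pvalue,
            "n_shuffles": len(self.shuffle_distances),
            "frac_shuffles_leq_true": self.frac_shuffles_leq_true,
            "shuffle_distances": list(self.shuffle_distances),
        }


def shuffled_control(
    query: StructureProfile,
    reference: StructureProfile,
    n_shuffles: int = 100,
    seed: int = 0,
    nulls: NullDistribution | None = None,
    shuffle_mode: str = "block",
    block_len: int = SHUFFLE_BLOCK_LEN_DEFAULT,
    normalization: str = "sum_lengths",
) -> ControlReport:
    """Compare the true pair distance against shuffled-reference distances.

    The reference is shuffled ``n_shuffles`` times (block mode by default)
    and re-aligned to the query; a genuinely structured match should score
    below (nearly) all shuffles.  The fraction of shuffles scoring at or
    below the true distance is reported alongside the true distance and,
    when a null is supplied, its empirical p-value.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    true = dtw_obe(query, reference, norm=normalization)
    pval = (
        empirical_pvalue(true.normalized_distance, len(query), len(reference), nulls)
        if nulls is not None
        else None
    )
    rng = np.random.default_rng(seed)
    dists = []
    for _ in range(n_shuffles):
        shuf = shuffle_profile(reference, mode=shuffle_mode, block_len=block_len,
                               seed=int(rng.integers(2**31)))
        dists.append(dtw_obe(query, shuf, norm=normalization).normalized_distance)
    dists_arr = np.asarray(dists)
    frac = float(np.mean(dists_arr <= true.normalized_distance))
    return ControlReport(
        query_id=query.id,
        reference_id=reference.id,
        true_distance=float(true.normalized_distance),
        true_pvalue=pval,
        shuffle_distances=tuple(float(d) for d in dists),
        frac_shuffles_leq_true=frac,
    )
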