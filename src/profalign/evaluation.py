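"""Validation instruments: sequence identity, min-distance AUC, warped correlation.

These quantify how well structural distance separates true homologs from
composition-matched decoys, and how much of that signal is (not) explained
by plain sequence similarity:

* ``global_identity`` -- percent identity from a Needleman-Wunsch global
  alignment with EDNAFULL-style scoring (match +5 / mismatch -4, gap open
  10, gap extend 0.5, terminal gaps free), identity counted over the full
  alignment length including gap columns.
* ``min_distance_auc`` -- each benchmark item is assigned its closest
  reference by minimal normalized distance; the AUC of that score
  (lower = more positive) is computed with the Mann-Whitney midrank
  formulation.
* ``warped_correlation`` -- Pearson correlation of the two score tracks
  sampled along a warping path, quantifying profile agreement after
  alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from Bio.Align import PairwiseAligner, substitution_matrices

from .dtw_core import AlignmentResult, dtw_standard, dtw_obe
from .profile_io import StructureProfile

__all__ = [
    "BenchmarkLabeling",
    "global_identity",
    "min_distance_auc",
    "min_distance_labeling",
    "warped_correlation",
]

_ALPHABET = "ACGTRYSWKMBDHVN"
_MATCH = 5.0
_MISMATCH = -4.0
_GAP_OPEN = 10.0
_GAP_EXTEND = 0.5


def _make_aligner() -> PairwiseAligner:
    mat = substitution_matrices.Array(_ALPHABET, dims=2)
    for x in _ALPHABET:
        for y in _ALPHABET:
            mat[x, y] = _MISMATCH
    for x in "ACGT":
        mat[x, x] = _MATCH
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_internal_gap_score = -_GAP_OPEN
    aligner.extend_internal_gap_score = -_GAP_EXTEND
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def global_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from an optimal global nucleotide alignment.

    Scoring: match +5, mismatch -4 (ambiguity codes always score as
    mismatch), affine gaps (open 10, extend 0.5), terminal gaps free.
    Identity = identical aligned positions / alignment length (gap columns
    included), as a percentage.  U and T are treated as equivalent.
    """
    a = _prepare(seq_a, "seq_a")
    b = _prepare(seq_b, "seq_b")
    alignment = _ALIGNER.align(a, b)[0]
    s1, s2 = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return 100.0 * matches / len(s1)


def _prepare(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} is empty")
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set(_ALPHABET)
    if bad:
        raise ValueError(f"{name} contains non-IUPAC characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class BenchmarkLabeling:
    """Min-distance assignments of positive/negative items to references.

    ``assignments`` maps each scored item id to its closest reference and
    the minimal normalized distance.  Positive and negative id sets must be
    disjoint.
    """

    reference_ids: tuple[str, ...]
    positive_ids: tuple[str, ...]
    negative_ids: tuple[str, ...]
    assignments: dict[str, tuple[str, float]]

    def __post_init__(self) -> None:
        overlap = set(self.positive_ids) & set(self.negative_ids)
        if overlap:
            raise ValueError(f"positive/negative sets overlap: {sorted(overlap)}")
        missing = (set(self.positive_ids) | set(self.negative_ids)) - set(
            self.assignments
        )
        if missing:
            raise ValueError(f"items without a min-distance assignment: {sorted(missing)}")

    def scores(self, ids: tuple[str, ...]) -> np.ndarray:
        return np.asarray([self.assignments[i][1] for i in ids])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("item_id\tclosest_ref\tmin_distance\tlabel\n")
            for label, ids in (("positive", self.positive_ids),
                               ("negative", self.negative_ids)):
                for i in ids:
                    ref, d = self.assignments[i]
                    fh.write(f"{i}\t{ref}\t{d!r}\t{label}\n")


def min_distance_labeling(
    references: list[StructureProfile],
    positives: list[StructureProfile],
    negatives: list[StructureProfile],
    mode: str = "standard",
    normalization: str = "sum_lengths",
) -> BenchmarkLabeling:
    """Score every item by its minimal distance to any reference.

    Ties between references go to the lexicographically smallest reference
    id (deterministic).  ``mode`` selects end-to-end ("standard") or
    open-begin/end ("obe") alignment.
    """
    if not references:
        raise ValueError("empty reference set")
    align = dtw_standard if mode == "standard" else dtw_obe
    refs = sorted(references, key=lambda p: p.id)

    def _assign(item: StructureProfile) -> tuple[str, float]:
        best_ref, best_d = None, np.inf
        for ref in refs:
            d = align(item, ref, norm=normalization).normalized_distance
            if d < best_d:  # strict: first (smallest id) wins ties
                best_ref, best_d = ref.id, d
        return best_ref, float(best_d)

    assignments = {p.id: _assign(p) for p in positives}
    assignments.update({n.id: _assign(n) for n in negatives})
    return BenchmarkLabeling(
        reference_ids=tuple(r.id for r in refs),
        positive_ids=tuple(p.id for p in positives),
        negative_ids=tuple(n.id for n in negatives),
        assignments=assignments,
    )


def min_distance_auc(labeling: BenchmarkLabeling) -> float:
    """AUC of the min-distance score, lower distance = more positive.

    Mann-Whitney midrank formulation: with pooled ascending ranks, the AUC
    is the fraction of (positive, negative) pairs in which the positive has
    the smaller distance, ties counting one half.
    """
    pos = labeling.scores(labeling.positive_ids)
    neg = labeling.scores(labeling.negative_ids)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum_neg = ranks[pos.size:].sum()
    u_neg = rank_sum_neg - neg.size * (neg.size + 1) / 2.0
    return float(u_neg / (pos.size * neg.size))


def warped_correlation(
    result: AlignmentResult,
    query: StructureProfile,
    reference: StructureProfile,
) -> float:
    """Pearson correlation of the two profiles sampled along a warping path.

    ``query``/``reference`` must be the profiles in the roles recorded in
    ``result`` (mind ``result.swapped`` for OBE alignments).  Raises if
    either track is constant along the path (correlation undefined).
    """
    if not result.path:
        raise ValueError("empty warping path")
    qi = np.asarray([i - 1 for i, _ in result.path])
    rj = np.asarray([j - 1 for _, j in result.path])
    x = query.scores[qi]
    y = reference.scores[rj]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a profile is constant along the path")
    return float(np.corrcoef(x, y)[0, 1])
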