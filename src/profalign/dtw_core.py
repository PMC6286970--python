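"""Dynamic time warping of structure profiles.

The distance between two profiles is the accumulated Manhattan (absolute
difference) cost along an optimal warping path, normalized by length.  The
recursion uses the *asymmetric* step pattern

    D(i, j) = |q_i - r_j| + min{ D(i-1, j), D(i-1, j-1), D(i-1, j-2) }

in which the query index advances by exactly one per step while the
reference index advances by 0, 1 or 2.  This is the only classical step
family compatible with open-begin/end (OBE) alignment, because the path
length -- and hence the normalizer -- does not depend on where the path
enters or leaves the reference.

Two modes are provided:

* ``standard``: both profiles are aligned end to end (paths run from (1,1)
  to (N,M)); recommended when one profile is less than ~3x the other.
* ``obe``: open begin and end on the reference axis -- the query may enter
  the reference at any position and leave at any position, which locates
  the best-matching sub-interval of a longer profile.

A brute-force path enumerator (`brute_force_dtw`) is included as an
independent testing oracle for tiny instances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profile_io import StructureProfile

__all__ = [
    "StepPattern",
    "ASYMMETRIC",
    "AlignmentResult",
    "NoAdmissiblePathError",
    "local_cost",
    "normalize_distance",
    "dtw_standard",
    "dtw_obe",
    "brute_force_dtw",
    "NORMALIZATIONS",
    "LENGTH_RATIO_WARN",
]

NORMALIZATIONS = ("sum_lengths", "query_length", "reference_length")

#: Length ratio at/above which standard mode warns that OBE is more suitable.
LENGTH_RATIO_WARN = 3.0


class NoAdmissiblePathError(ValueError):
    """No warping path exists under the asymmetric step pattern."""


@dataclass(frozen=True)
class StepPattern:
    """A set of predecessor offsets on (query, reference), unit-weighted."""

    name: str
    steps: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if any(dq != 1 for dq, _ in self.steps):
            raise ValueError(
                "every step must advance the query index by exactly 1 "
                "(required for open-end normalizability)"
            )


#: The asymmetric pattern: query advances 1 per step, reference 0/1/2.
ASYMMETRIC = StepPattern(name="asymmetric", steps=((1, 0), (1, 1), (1, 2)))


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a profile-vs-profile warping alignment.

    ``path`` is 1-based (query_index, reference_index) pairs;
    ``ref_interval`` is the 1-based inclusive span of reference positions
    visited by the optimal path.  ``normalized_distance`` is the
    length-normalized accumulated cost (the headline structural distance:
    ~0 means structurally identical, >= 0.10 conventionally "different").
    ``swapped`` records whether query and reference were exchanged so that
    the shorter profile is searched within the longer one (OBE mode).
    """

    raw_distance: float
    normalized_distance: float
    path: tuple[tuple[int, int], ...]
    ref_interval: tuple[int, int]
    mode: str
    normalization: str
    query_id: str = ""
    reference_id: str = ""
    query_length: int = 0
    reference_length: int = 0
    swapped: bool = False

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "reference_id": self.reference_id,
            "mode": self.mode,
            "normalization": self.normalization,
            "raw_distance": self.raw_distance,
            "normalized_distance": self.normalized_distance,
            "ref_interval": list(self.ref_interval),
            "query_length": self.query_length,
            "reference_length": self.reference_length,
            "swapped": self.swapped,
            "path": [list(step) for step in self.path],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    def path_to_tsv(self, path: str | Path) -> None:
        """Dump the warping path as two 1-based columns (query, reference)."""
        with open(path, "w") as fh:
            fh.write("query_index\treference_index\n")
            for qi, rj in self.path:
                fh.write(f"{qi}\t{rj}\n")


def local_cost(x: float, y: float) -> float:
    """Manhattan (absolute-difference) local cost between two scores."""
    return abs(x - y)


def normalize_distance(raw: float, N: int, M: int, norm: str = "sum_lengths") -> float:
    """Normalize an accumulated cost by profile lengths.

    ``sum_lengths`` divides by N+M (default -- accounts for both profiles);
    ``query_length`` divides by N (the classical asymmetric-pattern
    normalizer); ``reference_length`` divides by M.
    """
    if N < 1 or M < 1:
        raise ValueError("profile lengths must be >= 1")
    if norm == "sum_lengths":
        return raw / (N + M)
    if norm == "query_length":
        return raw / N
    if norm == "reference_length":
        return raw / M
    raise ValueError(f"unknown normalization {norm!r}; expected one of {NORMALIZATIONS}")


def _dp(q: np.ndarray, r: np.ndarray, open_begin: bool) -> tuple[np.ndarray, np.ndarray]:
    """Row-recursive DP. Returns (final cost row, predecessor-offset matrix)."""
    N, M = q.size, r.size
    ptr = np.zeros((N, M), dtype=np.uint8)
    prev = np.abs(q[0] - r)
    if not open_begin:
        closed = np.full(M, np.inf)
        closed[0] = prev[0]
        prev = closed
    cand = np.empty((3, M))
    cols = np.arange(M)
    for i in range(1, N):
        cand[0] = prev
        cand[1, 0] = np.inf
        cand[1, 1:] = prev[:-1]
        cand[2, :2] = np.inf
        cand[2, 2:] = prev[: M - 2] if M > 2 else prev[:0]
        # ties prefer the smallest reference advance -> shortest matched interval
        choice = np.argmin(cand, axis=0)
        prev = np.abs(q[i] - r) + cand[choice, cols]
        ptr[i] = choice
    return prev, ptr


def _backtrack(ptr: np.ndarray, j_end: int) -> list[tuple[int, int]]:
    N = ptr.shape[0]
    path = [(N - 1, j_end)]
    j = j_end
    for i in range(N - 1, 0, -1):
        j -= int(ptr[i, j])
        path.append((i - 1, j))
    path.reverse()
    return path


def _result(q: StructureProfile, r: StructureProfile, raw: float,
            path0: list[tuple[int, int]], mode: str, norm: str,
            swapped: bool) -> AlignmentResult:
    N, M = len(q), len(r)
    path = tuple((i + 1, j + 1) for i, j in path0)
    ref_positions = [j for _, j in path]
    return AlignmentResult(
        raw_distance=float(raw),
        normalized_distance=float(normalize_distance(raw, N, M, norm)),
        path=path,
        ref_interval=(min(ref_positions), max(ref_positions)),
        mode=mode,
        normalization=norm,
        query_id=q.id,
        reference_id=r.id,
        query_length=N,
        reference_length=M,
        swapped=swapped,
    )


def dtw_standard(query: StructureProfile, reference: StructureProfile,
                 norm: str = "sum_lengths") -> AlignmentResult:
    """End-to-end DTW alignment of two profiles.

    The path is anchored at (1,1) and (N,M).  Because each step consumes at
    most two reference positions, the end cell is reachable only when
    M <= 2N-1; otherwise a :class:`NoAdmissiblePathError` is raised.  A
    warning (not an error) is emitted when one profile is >= 3x the other,
    where OBE mode is the better instrument.
    """
    q, r = query.scores, reference.scores
    N, M = q.size, r.size
    if M > 2 * N - 1:
        raise NoAdmissiblePathError(
            f"no admissible warping path: reference length {M} exceeds the "
            f"maximal reach 2N-1 = {2 * N - 1} of a length-{N} query under "
            "the asymmetric step pattern (use OBE mode instead)"
        )
    ratio = max(N, M) / min(N, M)
    if ratio >= LENGTH_RATIO_WARN:
        warnings.warn(
            f"profiles differ {ratio:.1f}x in length; standard mode is "
            "recommended only below 3x -- consider OBE mode",
            UserWarning,
            stacklevel=2,
        )
    final, ptr = _dp(q, r, open_begin=False)
    raw = final[M - 1]
    if not np.isfinite(raw):
        raise NoAdmissiblePathError("no admissible warping path reaches (N, M)")
    path0 = _backtrack(ptr, M - 1)
    return _result(query, reference, raw, path0, "standard", norm, swapped=False)


def dtw_obe(query: StructureProfile, reference: StructureProfile,
            norm: str = "sum_lengths", auto_swap: bool = True) -> AlignmentResult:
    """Open-begin/end DTW: locate the query within a (longer) reference.

    The path may enter the reference at any position (open begin) and the
    reported distance is the minimum over all ending positions (open end);
    ties on the ending index are broken toward the smallest index, then the
    shortest matched interval.  If the query is longer than the reference
    the two are swapped (recorded in ``swapped``) so that the shorter
    profile is always the one searched for.
    """
    swapped = False
    if len(query) > len(reference):
        if not auto_swap:
            raise ValueError(
                "query is longer than reference; pass auto_swap=True to search "
                "the shorter profile within the longer one"
            )
        query, reference = reference, query
        swapped = True
    q, r = query.scores, reference.scores
    final, ptr = _dp(q, r, open_begin=True)
    j_end = int(np.argmin(final))  # first minimum -> smallest ending index
    raw = final[j_end]
    path0 = _backtrack(ptr, j_end)
    return _result(query, reference, raw, path0, "obe", norm, swapped=swapped)


def brute_force_dtw(query: StructureProfile, reference: StructureProfile,
                    mode: str = "standard",
                    step_pattern: StepPattern = ASYMMETRIC) -> float:
    """Exhaustive-path oracle: minimal accumulated cost over all step sequences.

    Enumerates every admissible warping path (and, for OBE, every begin and
    end on the reference) and returns the minimal accumulated Manhattan
    cost.  Only feasible for tiny instances; intended for testing.
    """
    q, r = query.scores, reference.scores
    N, M = q.size, r.size
    if N > 7 or N * M > 100:
        raise ValueError(f"instance too large for brute force (N={N}, M={M})")
    if mode not in ("standard", "obe"):
        raise ValueError(f"unknown mode {mode!r}")

    offsets = [dj for _, dj in step_pattern.steps]
    best = np.inf

    def walk(i: int, j: int, acc: float) -> None:
        nonlocal best
        acc += abs(q[i] - r[j])
        if acc >= best:
            return
        if i == N - 1:
            if mode == "obe" or j == M - 1:
                best = acc
            return
        for dj in offsets:
            nj = j + dj
            if nj < M:
                walk(i + 1, nj, acc)

    starts = range(M) if mode == "obe" else [0]
    for j0 in starts:
        walk(0, j0, 0.0)
    if not np.isfinite(best):
        raise NoAdmissiblePathError("no admissible warping path for this instance")
    return float(best)
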