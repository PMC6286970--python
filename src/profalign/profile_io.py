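"""Reading, writing and transforming per-nucleotide structure profiles.

A *structure profile* is a real-valued track with one score per nucleotide.
The sign carries the structural state: positive scores mean the position is
predicted (or observed) to be double-stranded / paired, negative scores mean
single-stranded / unpaired.  Profiles arrive from several encodings:

* precomputed predictor score tables (two-column TSV: position, score),
* Vienna dot-bracket strings (brackets -> paired, dots -> unpaired),
* SHAPE reactivity files (high reactivity -> flexible -> unpaired).

All external formats use 1-based contiguous positions; in memory everything
is a 0-based :class:`numpy.ndarray`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "StructureProfile",
    "read_fasta",
    "dotbracket_to_profile",
    "shape_to_profile",
    "read_shape",
    "read_score_table",
    "write_score_table",
    "ds_only_transform",
    "shuffle_profile",
    "smooth_profile",
    "SHAPE_THRESHOLD_DEFAULT",
    "SHAPE_MISSING",
    "SMOOTH_WINDOW_DEFAULT",
    "SHUFFLE_BLOCK_LEN_DEFAULT",
]

PROFILE_SOURCES = ("cross_scores", "dotbracket_binary", "shape_derived", "synthetic")

#: Default SHAPE reactivity cut separating paired (below) from unpaired (above).
#: 0.5 reactivity units is a conventional paired/unpaired boundary.
SHAPE_THRESHOLD_DEFAULT = 0.5

#: Sentinel used in SHAPE files for positions with no measurement.
SHAPE_MISSING = -999.0

#: Default window (nt) for the report-only moving-average smoother.
SMOOTH_WINDOW_DEFAULT = 51

#: Default block length (nt) for block-mode profile shuffling.  Block shuffling
#: preserves the local autocorrelation that a re-predicted shuffled sequence
#: would retain; pointwise shuffling destroys it.
SHUFFLE_BLOCK_LEN_DEFAULT = 10

_IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")

_OPEN = {"(": ")", "[": "]", "<": ">"}
_CLOSE = {v: k for k, v in _OPEN.items()}


@dataclass(frozen=True)
class StructureProfile:
    """A named per-nucleotide structural propensity track.

    Parameters
    ----------
    id : str
        Transcript identifier.
    scores : array-like of float
        One finite score per nucleotide.  Positive = double-stranded,
        negative = single-stranded.
    source : {"cross_scores", "dotbracket_binary", "shape_derived", "synthetic"}
        Provenance of the track.  ``dotbracket_binary`` promises scores
        restricted to {+1, -1}.
    sequence : str, optional
        Nucleotide string of the same length as ``scores``.
    """

    id: str
    scores: np.ndarray
    source: str = "cross_scores"
    sequence: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError(f"profile {self.id!r}: scores must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"profile {self.id!r}: scores contain non-finite values")
        if self.source not in PROFILE_SOURCES:
            raise ValueError(
                f"profile {self.id!r}: unknown source {self.source!r}; "
                f"expected one of {PROFILE_SOURCES}"
            )
        if self.source == "dotbracket_binary" and not np.all(np.isin(arr, (-1.0, 1.0))):
            raise ValueError(
                f"profile {self.id!r}: dotbracket_binary profiles must contain only +1/-1"
            )
        if self.sequence is not None and len(self.sequence) != arr.size:
            raise ValueError(
                f"profile {self.id!r}: sequence length {len(self.sequence)} "
                f"!= number of scores {arr.size}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "scores", arr)

    def __len__(self) -> int:
        return int(self.scores.size)

    def with_scores(self, scores: np.ndarray, *, id: str | None = None,
                    source: str | None = None) -> "StructureProfile":
        """Return a copy with replaced scores (and optionally id/source)."""
        return StructureProfile(
            id=self.id if id is None else id,
            scores=scores,
            source=self.source if source is None else source,
            sequence=self.sequence if len(scores) == len(self) else None,
        )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record, possibly line-folded) FASTA file.

    Returns ordered ``(id, sequence)`` pairs.  Both U and T are accepted and
    sequences are case-folded to uppercase.  A file with zero records or a
    record containing a non-IUPAC character is an error.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in _IUPAC_NT:
                raise ValueError(
                    f"{path}: record {rec.id!r} has non-IUPAC character "
                    f"{ch!r} at position {pos}"
                )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def dotbracket_to_profile(structure: str, id: str = "structure") -> StructureProfile:
    """Convert a dot-bracket string to a binary +1/-1 profile.

    Every bracketed position (any of ``()[]<>``) is paired (+1); dots are
    unpaired (-1).  Brackets of each kind must balance.
    """
    if not structure:
        raise ValueError("empty dot-bracket string")
    scores = np.empty(len(structure), dtype=float)
    stacks: dict[str, int] = {k: 0 for k in _OPEN}
    for pos, ch in enumerate(structure):
        if ch == ".":
            scores[pos] = -1.0
        elif ch in _OPEN:
            stacks[ch] += 1
            scores[pos] = 1.0
        elif ch in _CLOSE:
            opener = _CLOSE[ch]
            stacks[opener] -= 1
            if stacks[opener] < 0:
                raise ValueError(
                    f"unbalanced {ch!r} at position {pos + 1} in dot-bracket string"
                )
            scores[pos] = 1.0
        else:
            raise ValueError(
                f"illegal character {ch!r} at position {pos + 1} in dot-bracket string"
            )
    unclosed = {k: v for k, v in stacks.items() if v != 0}
    if unclosed:
        raise ValueError(f"unbalanced brackets in dot-bracket string: {unclosed}")
    return StructureProfile(id=id, scores=scores, source="dotbracket_binary")


def shape_to_profile(
    reactivities: Iterable[tuple[int, float]],
    threshold: float = SHAPE_THRESHOLD_DEFAULT,
    id: str = "shape",
) -> StructureProfile:
    """Threshold SHAPE reactivities into a +1/0/-1 profile.

    Reactivity below ``threshold`` -> +1 (protected, double-stranded);
    at/above -> -1 (flexible, single-stranded); the -999 missing sentinel
    maps to 0 (neutral) so profile length always equals transcript length.
    Positions must run 1..N without gaps.
    """
    pairs = list(reactivities)
    if not pairs:
        raise ValueError("empty reactivity list")
    scores = np.empty(len(pairs), dtype=float)
    for i, (pos, val) in enumerate(pairs):
        if pos != i + 1:
            raise ValueError(
                f"SHAPE positions must be contiguous 1..N: expected {i + 1}, got {pos}"
            )
        if val == SHAPE_MISSING:
            scores[i] = 0.0
        elif val < threshold:
            scores[i] = 1.0
        else:
            scores[i] = -1.0
    return StructureProfile(id=id, scores=scores, source="shape_derived")


def read_shape(path: str | Path) -> list[tuple[int, float]]:
    """Read a two-column (position, reactivity) SHAPE file."""
    path = Path(path)
    pairs: list[tuple[int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'position reactivity'")
            try:
                pairs.append((int(fields[0]), float(fields[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
    if not pairs:
        raise ValueError(f"{path}: no reactivity rows found")
    return pairs


def read_score_table(path: str | Path, id: str | None = None) -> StructureProfile:
    """Read a per-nucleotide score table (TSV ``position<TAB>score``).

    An optional single header line is tolerated.  Positions must be 1-based
    and contiguous; duplicates, gaps and non-numeric scores are errors.
    """
    path = Path(path)
    rows: list[tuple[int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'position<TAB>score'")
            try:
                pos = int(fields[0])
            except ValueError:
                if not rows:
                    continue  # header line
                raise ValueError(f"{path}:{lineno}: non-numeric position in {line!r}") from None
            try:
                score = float(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric score in {line!r}") from None
            rows.append((pos, score))
    if not rows:
        raise ValueError(f"{path}: no score rows found")
    scores = np.empty(len(rows), dtype=float)
    for i, (pos, score) in enumerate(rows):
        if pos == i:  # duplicate of the previous position
            raise ValueError(f"{path}: duplicate position {pos}")
        if pos != i + 1:
            raise ValueError(
                f"{path}: positions must be contiguous from 1; expected {i + 1}, got {pos}"
            )
        scores[i] = score
    return StructureProfile(id=id or path.stem, scores=scores, source="cross_scores")


def write_score_table(profile: StructureProfile, path: str | Path,
                      header: bool = True) -> None:
    """Write ``position<TAB>score`` (full float precision, round-trip safe)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("position\tscore\n")
        for i, s in enumerate(profile.scores, start=1):
            fh.write(f"{i}\t{float(s)!r}\n")


def ds_only_transform(p: StructureProfile) -> StructureProfile:
    """Keep only double-stranded signal: scores below 0 are set to 0.

    Single-stranded regions are noisier and less conserved than stems, so
    zeroing the negative half of the track focuses the comparison on
    structured (paired) regions.  Length is preserved.
    """
    scores = np.maximum(p.scores, 0.0)
    # the zeroed track is no longer a strict +1/-1 binary encoding
    source = "cross_scores" if p.source == "dotbracket_binary" else p.source
    return p.with_scores(scores, id=f"{p.id}|ds_only", source=source)


def shuffle_profile(
    p: StructureProfile,
    mode: str = "block",
    block_len: int = SHUFFLE_BLOCK_LEN_DEFAULT,
    seed: int = 0,
) -> StructureProfile:
    """Return a seeded random permutation of the profile's scores.

    ``pointwise`` permutes individual positions; ``block`` (default) splits
    the track into near-equal contiguous blocks of about ``block_len``
    nucleotides and permutes the blocks, preserving local autocorrelation.
    The multiset of scores is conserved in both modes.
    """
    if mode not in ("pointwise", "block"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "pointwise":
        shuffled = rng.permutation(p.scores)
    else:
        if block_len > len(p):
            raise ValueError(f"block_len {block_len} exceeds profile length {len(p)}")
        n_blocks = max(1, round(len(p) / block_len))
        blocks = np.array_split(p.scores, n_blocks)
        order = rng.permutation(len(blocks))
        shuffled = np.concatenate([blocks[i] for i in order])
    return StructureProfile(
        id=f"{p.id}|shuffled", scores=shuffled, source=p.source, sequence=None
    )


def smooth_profile(p: StructureProfile, window: int = SMOOTH_WINDOW_DEFAULT) -> StructureProfile:
    """Centered moving average with edge truncation (window shrinks at ends).

    Intended for visualization/reporting only -- distances are always
    computed on the raw track.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be an odd positive integer")
    if window > len(p):
        raise ValueError(f"window {window} exceeds profile length {len(p)}")
    if window == 1:
        return p
    kernel = np.ones(window)
    sums = np.convolve(p.scores, kernel, mode="same")
    counts = np.convolve(np.ones(len(p)), kernel, mode="same")
    return p.with_scores(sums / counts, id=f"{p.id}|smoothed")
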