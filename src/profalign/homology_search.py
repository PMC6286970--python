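"""Locating structural domains: fragmented scans and dataset-mode ranking.

Two search instruments sit on top of open-begin/end warping:

* **Fragmented scan** -- the query profile is cut into non-overlapping
  windows (200 nt by default, the conventional size for structural domains
  in large RNAs) and each window is searched within the target.  This finds
  *unknown* conserved domains without assuming the whole molecules align.
* **Dataset scan** -- one query is ranked against a whole collection of
  profiles (e.g. every lincRNA of an organism); for each pair the shorter
  profile is searched within the longer one and targets are ordered by
  normalized distance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dtw_core import AlignmentResult, dtw_obe
from .profile_io import StructureProfile
from .significance import NullDistribution, empirical_pvalue

__all__ = [
    "FragmentHit",
    "ScanReport",
    "fragment_query",
    "fragmented_obe_scan",
    "dataset_scan",
    "hits_to_tsv",
    "hits_to_bed",
    "FRAGMENT_WINDOW_DEFAULT",
    "MIN_FRAGMENT_INPUT",
    "TOP_K_DEFAULT",
]

#: Non-overlapping fragment window (nt).
FRAGMENT_WINDOW_DEFAULT = 200
#: Below this query length a fragmented scan is of questionable value.
MIN_FRAGMENT_INPUT = 600
#: Full alignments retained for the best-ranked targets in dataset mode.
TOP_K_DEFAULT = 20


@dataclass(frozen=True)
class FragmentHit:
    """Best open-begin/end match of one query fragment inside a target."""

    fragment_index: int
    query_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    normalized_distance: float
    p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "fragment_index": self.fragment_index,
            "query_start": self.query_interval[0],
            "query_end": self.query_interval[1],
            "ref_start": self.ref_interval[0],
            "ref_end": self.ref_interval[1],
            "normalized_distance": self.normalized_distance,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class RankedTarget:
    """One target's entry in a dataset-mode report."""

    target_id: str
    normalized_distance: float
    ref_interval: tuple[int, int]
    p_value: float | None = None
    alignment: AlignmentResult | None = None  # retained for top-k only


@dataclass(frozen=True)
class ScanReport:
    """Ranked dataset-mode report (ascending distance, ties by target id)."""

    query_id: str
    hits: tuple[RankedTarget, ...]
    mode: str = "obe"
    normalization: str = "sum_lengths"
    top_k: int = TOP_K_DEFAULT

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("target_id\tnormalized_distance\tref_start\tref_end\tp_value\n")
            for h in self.hits:
                pv = "" if h.p_value is None else repr(h.p_value)
                fh.write(
                    f"{h.target_id}\t{h.normalized_distance!r}\t"
                    f"{h.ref_interval[0]}\t{h.ref_interval[1]}\t{pv}\n"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "query_id": self.query_id,
            "mode": self.mode,
            "normalization": self.normalization,
            "top_k": self.top_k,
            "hits": [
                {
                    "target_id": h.target_id,
                    "normalized_distance": h.normalized_distance,
                    "ref_interval": list(h.ref_interval),
                    "p_value": h.p_value,
                    "alignment": h.alignment.to_dict() if h.alignment else None,
                }
                for h in self.hits
            ],
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def fragment_query(p: StructureProfile, window: int = FRAGMENT_WINDOW_DEFAULT
                   ) -> list[tuple[int, int]]:
    """Cut a profile into consecutive non-overlapping windows.

    Returns 1-based inclusive intervals that tile 1..N exactly.  A trailing
    remainder of at least half a window is kept as its own (short) final
    fragment; a smaller remainder is merged into the previous fragment.
    Profiles shorter than the window give a single fragment with a warning,
    as do profiles below the recommended 600 nt minimum.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(p)
    if n < MIN_FRAGMENT_INPUT:
        warnings.warn(
            f"profile {p.id!r} is {n} nt; fragmentation is recommended for "
            f">= {MIN_FRAGMENT_INPUT} nt inputs",
            UserWarning,
            stacklevel=2,
        )
    if n <= window:
        return [(1, n)]
    n_full = n // window
    remainder = n - n_full * window
    intervals = [(k * window + 1, (k + 1) * window) for k in range(n_full)]
    if remainder == 0:
        return intervals
    if remainder >= window / 2:
        intervals.append((n_full * window + 1, n))
    else:
        start, _ = intervals[-1]
        intervals[-1] = (start, n)
    return intervals


def fragmented_obe_scan(
    query: StructureProfile,
    target: StructureProfile,
    window: int = FRAGMENT_WINDOW_DEFAULT,
    nulls: NullDistribution | None = None,
    normalization: str = "sum_lengths",
) -> list[FragmentHit]:
    """Search every query fragment within the target via open-begin/end DTW."""
    hits = []
    for k, (start, end) in enumerate(fragment_query(query, window)):
        frag = StructureProfile(
            id=f"{query.id}[{start}-{end}]",
            scores=query.scores[start - 1: end],
            source=query.source,
        )
        res = dtw_obe(frag, target, norm=normalization)
        pval = (
            empirical_pvalue(res.normalized_distance, len(frag), len(target), nulls)
            if nulls is not None
            else None
        )
        hits.append(
            FragmentHit(
                fragment_index=k,
                query_interval=(start, end),
                ref_interval=res.ref_interval,
                normalized_distance=res.normalized_distance,
                p_value=pval,
            )
        )
    return hits


def dataset_scan(
    query: StructureProfile,
    targets: list[StructureProfile],
    nulls: NullDistribution | None = None,
    top_k: int = TOP_K_DEFAULT,
    normalization: str = "sum_lengths",
) -> ScanReport:
    """Rank a query against a collection of profiles.

    For each pair the shorter profile is searched within the longer via
    open-begin/end DTW.  Hits are sorted by ascending normalized distance
    (ties by target id); full alignments are retained for the best
    ``top_k`` targets, distances only for the rest.
    """
    if not targets:
        raise ValueError("empty target collection")
    scored: list[tuple[float, str, AlignmentResult, float | None]] = []
    for t in targets:
        res = dtw_obe(query, t, norm=normalization)
        pval = (
            empirical_pvalue(res.normalized_distance, len(query), len(t), nulls)
            if nulls is not None
            else None
        )
        scored.append((res.normalized_distance, t.id, res, pval))
    scored.sort(key=lambda x: (x[0], x[1]))
    hits = tuple(
        RankedTarget(
            target_id=tid,
            normalized_distance=dist,
            ref_interval=res.ref_interval,
            p_value=pval,
            alignment=res if rank < top_k else None,
        )
        for rank, (dist, tid, res, pval) in enumerate(scored)
    )
    return ScanReport(
        query_id=query.id, hits=hits, normalization=normalization, top_k=top_k
    )


def hits_to_tsv(hits: list[FragmentHit], path: str | Path) -> None:
    """Write fragment hits as the downloadable scan table."""
    with open(path, "w") as fh:
        fh.write(
            "fragment_index\tquery_start\tquery_end\tref_start\tref_end\t"
            "normalized_distance\tp_value\n"
        )
        for h in hits:
            pv = "" if h.p_value is None else repr(h.p_value)
            fh.write(
                f"{h.fragment_index}\t{h.query_interval[0]}\t{h.query_interval[1]}\t"
                f"{h.ref_interval[0]}\t{h.ref_interval[1]}\t"
                f"{h.normalized_distance!r}\t{pv}\n"
            )


def hits_to_bed(hits: list[FragmentHit], target_id: str, path: str | Path) -> None:
    """Export matched target intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for h in hits:
            start0 = h.ref_interval[0] - 1
            end0 = h.ref_interval[1]
            name = f"fragment_{h.fragment_index}"
            fh.write(f"{target_id}\t{start0}\t{end0}\t{name}\t"
                     f"{h.normalized_distance:.6f}\n")
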