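"""Gapless homology search of mature miRNAs against EST reads.

The scan replaces a heuristic word-seeded search with an exhaustive
ungapped scan: every full-query-length window on either strand is scored
by Hamming distance, and windows with at most ``max_mm`` mismatches
qualify.  ``N`` matches nothing (it always counts as a mismatch).
Coordinates are 0-based half-open on the forward strand of the read;
mismatch positions are reported 1-based along the query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import ESTRead, ReferenceMiRNA, revcomp

QUERY_LEN_RANGE = (20, 24)
DEFAULT_MAX_MM = 3

_ORD = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_N_BYTE = ord("N")


@dataclass(frozen=True)
class HomologyHit:
    """One qualifying gapless alignment of a mature miRNA on a read."""

    query_id: str
    est_id: str
    est_start: int  # 0-based half-open, forward strand
    est_end: int
    strand: str  # "+" | "-"
    aln_len: int
    mismatches: int
    mismatch_positions: tuple[int, ...]  # 1-based along the query
    aligned_est_subseq: str


def _scan_one_strand(
    q: np.ndarray, s: np.ndarray, max_mm: int
) -> list[tuple[int, int, np.ndarray]]:
    """Qualifying (start, mismatches, mismatch_mask) windows, forward sense."""
    L, n = q.size, s.size
    if n < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(s, L)
    neq = (windows != q) | (windows == _N_BYTE) | (q == _N_BYTE)
    counts = neq.sum(axis=1)
    out = []
    for start in np.nonzero(counts <= max_mm)[0]:
        out.append((int(start), int(counts[start]), neq[start]))
    return out


def gapless_scan(
    query: str, subject: str, max_mm: int = DEFAULT_MAX_MM, query_id: str = "query",
    est_id: str = "subject",
) -> list[HomologyHit]:
    """All full-query-length windows of ``subject`` (either strand) within
    ``max_mm`` Hamming distance of ``query``.

    The query length must be 20-24 nt (mature miRNA range) and ``max_mm``
    at most 3.  For minus-strand hits the window coordinates stay on the
    forward read and mismatch positions are mapped back onto the query.
    """
    L = len(query)
    if not (QUERY_LEN_RANGE[0] <= L <= QUERY_LEN_RANGE[1]):
        raise ValueError(f"query length {L} outside {QUERY_LEN_RANGE}")
    if not (0 <= max_mm <= 3):
        raise ValueError("max_mm must be between 0 and 3")
    s = _encode(subject)
    hits: list[HomologyHit] = []
    q_fwd = _encode(query)
    for start, mm, mask in _scan_one_strand(q_fwd, s, max_mm):
        hits.append(
            HomologyHit(
                query_id=query_id,
                est_id=est_id,
                est_start=start,
                est_end=start + L,
                strand="+",
                aln_len=L,
                mismatches=mm,
                mismatch_positions=tuple(int(p) + 1 for p in np.nonzero(mask)[0]),
                aligned_est_subseq=subject[start : start + L],
            )
        )
    q_rc = _encode(revcomp(query))
    for start, mm, mask in _scan_one_strand(q_rc, s, max_mm):
        # window position k (0-based, on revcomp(query)) aligns query base
        # L-1-k; 1-based query position = L - k
        qpos = tuple(sorted(L - int(p) for p in np.nonzero(mask)[0]))
        hits.append(
            HomologyHit(
                query_id=query_id,
                est_id=est_id,
                est_start=start,
                est_end=start + L,
                strand="-",
                aln_len=L,
                mismatches=mm,
                mismatch_positions=qpos,
                aligned_est_subseq=subject[start : start + L],
            )
        )
    hits.sort(key=lambda h: (h.est_start, 0 if h.strand == "+" else 1))
    return hits


def _hit_rank(h: HomologyHit) -> tuple:
    # fewest mismatches, then longest, then leftmost, then strand +
    return (h.mismatches, -h.aln_len, h.est_start, 0 if h.strand == "+" else 1,
            h.query_id)


def scan_library(
    refs: Sequence[ReferenceMiRNA],
    ests: Sequence[ESTRead],
    max_mm: int = DEFAULT_MAX_MM,
) -> dict[str, list[HomologyHit]]:
    """Scan every reference mature against every read; keep, per
    (family, read), only the best hit.

    Returns hits grouped by family, each list deterministically sorted by
    (read id, start).  The reference set should already be deduplicated and
    the reads contaminant-filtered.
    """
    if not refs:
        warnings.warn("empty reference set; no hits possible")
        return {}
    by_family: dict[str, dict[str, HomologyHit]] = {}
    for est in ests:
        s = _encode(est.seq)
        for ref in refs:
            L = len(ref.mature_seq)
            if est.length < L:
                continue
            for hit in gapless_scan(
                ref.mature_seq, est.seq, max_mm, query_id=ref.id, est_id=est.id
            ):
                fam = by_family.setdefault(ref.family, {})
                prev = fam.get(est.id)
                if prev is None or _hit_rank(hit) < _hit_rank(prev):
                    fam[est.id] = hit
    return {
        family: sorted(d.values(), key=lambda h: (h.est_id, h.est_start))
        for family, d in sorted(by_family.items())
    }


@dataclass(frozen=True)
class Candidate:
    """A unique precursor-candidate window, possibly shared by families."""

    est_id: str
    est_start: int
    est_end: int
    strand: str
    families: tuple[str, ...]
    hits: tuple[HomologyHit, ...]

    @property
    def best_hit(self) -> HomologyHit:
        return min(self.hits, key=_hit_rank)


def collapse_redundant(hits_by_family: dict[str, list[HomologyHit]]) -> list[Candidate]:
    """Merge hits with identical (read, window, strand) across families.

    Mirrors redundancy elimination among selected EST windows: two families
    whose mature sequences align to the same window of the same read yield
    one candidate carrying both family labels.  Idempotent.
    """
    grouped: dict[tuple, dict[str, HomologyHit]] = {}
    for family, hits in hits_by_family.items():
        for h in hits:
            key = (h.est_id, h.est_start, h.est_end, h.strand)
            grouped.setdefault(key, {})[family] = h
    out = []
    for (est_id, start, end, strand), fam_hits in sorted(grouped.items()):
        families = tuple(sorted(fam_hits))
        out.append(
            Candidate(
                est_id=est_id,
                est_start=start,
                est_end=end,
                strand=strand,
                families=families,
                hits=tuple(fam_hits[f] for f in families),
            )
        )
    return out
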