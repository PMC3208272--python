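"""Sequence I/O, normalization, reference deduplication and contaminant screening.

All sequences are held internally as uppercase RNA over ``{A, C, G, U, N}``;
DNA (``T``) is accepted on input only and converted.  FASTA parsing and
writing go through Biopython's :mod:`Bio.SeqIO`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and map DNA T to RNA U.

    Raises ``ValueError`` on symbols outside ``{A,C,G,T,U,N}`` (case
    insensitive).
    """
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA symbols in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceMiRNA:
    """A species-annotated mature miRNA, the query unit of homology search."""

    id: str
    species: str
    family: str
    mature_seq: str
    precursor_seq: str | None = None

    def __post_init__(self) -> None:
        if not (set(self.mature_seq) <= RNA_ALPHABET):
            raise ValueError(f"{self.id}: mature sequence is not normalized RNA")


@dataclass(frozen=True)
class ESTRead:
    """One transcript read; ``library`` labels the reproductive mode."""

    id: str
    seq: str
    library: str = "unknown"  # "sexual" | "apomictic" | "unknown"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        if not (set(self.seq) <= RNA_ALPHABET):
            raise ValueError(f"{self.id}: sequence is not normalized RNA")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class FastaRecord:
    """A minimal id/sequence pair as read from FASTA."""

    id: str
    seq: str
    description: str = ""


def read_fasta(path: str | Path, alphabet_policy: str = "rna") -> list[FastaRecord]:
    """Read FASTA records, normalizing sequences per the alphabet policy.

    ``alphabet_policy='rna'`` maps T->U and folds case to upper; ``'raw'``
    keeps sequences verbatim.  Ids are preserved; duplicate ids are suffixed
    ``_2, _3, ...`` with a warning; empty-sequence records are dropped with a
    logged reason.  Input order is preserved.
    """
    if alphabet_policy not in ("rna", "raw"):
        raise ValueError(f"unknown alphabet policy {alphabet_policy!r}")
    out: list[FastaRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            logger.warning("dropping record %s: empty sequence", rec.id)
            continue
        if alphabet_policy == "rna":
            seq = normalize_rna(seq)
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            warnings.warn(f"duplicate FASTA id {rid!r}; renamed to {new_id!r}")
            rid = new_id
        else:
            seen[rid] = 1
        out.append(FastaRecord(id=rid, seq=seq, description=rec.description))
    return out


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    """Write records (anything with ``.id`` and ``.seq``) as FASTA."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def parse_reference_fasta(path: str | Path) -> list[ReferenceMiRNA]:
    """Read a mature-miRNA reference FASTA with PMRD/miRBase-style headers.

    Header convention: ``>id`` where the id begins with a species code and a
    family token, e.g. ``ath-miR156a``.  Unparseable headers fall back to
    species ``unk`` / family = id.
    """
    refs = []
    for rec in read_fasta(path):
        species, family = "unk", rec.id
        parts = rec.id.split("-")
        if len(parts) >= 2 and 3 <= len(parts[0]) <= 5:
            species = parts[0].lower()
            fam = parts[1]
            # strip letter/number variant suffixes: miR156a -> miR156
            core = fam.rstrip("abcdefghijklmnopqrstuvwxyz*")
            family = core if core else fam
        refs.append(
            ReferenceMiRNA(id=rec.id, species=species, family=family, mature_seq=rec.seq)
        )
    return refs


def dedup_mirnas(
    refs: Sequence[ReferenceMiRNA],
) -> tuple[list[ReferenceMiRNA], dict[str, str]]:
    """Collapse reference miRNAs sharing an identical mature sequence.

    Mirrors the removal of duplicated miRNAs shared between species in a
    multi-species reference set.  The kept record for each distinct mature
    sequence is the first after a deterministic sort by ``(species, id)`` so
    the result is independent of input order.  Returns ``(kept, removed_map)``
    where ``removed_map`` maps each removed record id to the kept record id.
    """
    order = sorted(refs, key=lambda r: (r.species, r.id))
    kept_by_seq: dict[str, ReferenceMiRNA] = {}
    removed: dict[str, str] = {}
    for r in order:
        if r.mature_seq not in kept_by_seq:
            kept_by_seq[r.mature_seq] = r
        else:
            removed[r.id] = kept_by_seq[r.mature_seq].id
    # preserve the deterministic (species, id) order of kept records
    kept = [r for r in order if kept_by_seq[r.mature_seq] is r]
    return kept, removed


@dataclass
class RemovalRecord:
    """Why a read was excluded by contaminant screening."""

    read_id: str
    reason: str
    contaminant_id: str
    position: int  # 0-based position of the shared k-mer on the read


def _kmer_index(records: Sequence, k: int) -> dict[str, str]:
    """Map every k-mer (both strands) of the contaminant db to a source id."""
    index: dict[str, str] = {}
    for rec in records:
        for s in (rec.seq, revcomp(rec.seq)):
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" not in kmer:
                    index.setdefault(kmer, rec.id)
    return index


def filter_contaminants(
    ests: Sequence[ESTRead],
    contaminant_db: Sequence,
    k: int = 20,
) -> tuple[list[ESTRead], list[RemovalRecord]]:
    """Exclude reads sharing an exact >= k-mer with a tRNA/rRNA database.

    A read is removed iff it shares an exact substring of at least ``k``
    nucleotides (either strand) with any contaminant record.  With an empty
    database this is the identity (with a warning).  ``kept + removed``
    partitions the input.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not contaminant_db:
        warnings.warn("empty contaminant database; no reads removed")
        return list(ests), []
    index = _kmer_index(contaminant_db, k)
    kept: list[ESTRead] = []
    removed: list[RemovalRecord] = []
    for est in ests:
        hit = None
        for i in range(est.length - k + 1):
            src = index.get(est.seq[i : i + k])
            if src is not None:
                hit = (i, src)
                break
        if hit is None:
            kept.append(est)
        else:
            removed.append(
                RemovalRecord(
                    read_id=est.id,
                    reason=f"exact {k}-mer match to contaminant",
                    contaminant_id=hit[1],
                    position=hit[0],
                )
            )
    return kept, removed


def removal_report(removed: Sequence[RemovalRecord], path: str | Path) -> None:
    """Write the contaminant-removal audit as TSV."""
    with open(path, "w") as fh:
        fh.write("read_id\treason\tcontaminant_id\tposition\n")
        for r in removed:
            fh.write(f"{r.read_id}\t{r.reason}\t{r.contaminant_id}\t{r.position}\n")
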