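"""Synthetic flower-EST libraries, reference sets and expression data with
known ground truth.

The generator emulates 454-style flower cDNA libraries from one sexual and
one apomictic genotype: read lengths between 51 and 478 nt with ~80% of
reads near 200 nt, planted hairpin precursors of 66-233 nt whose one arm
carries a 20-24 nt mature miRNA, truncated (single-arm) precursors,
verbatim tRNA/rRNA contaminant segments, and homopolymer
insertion/deletion noise within runs of length >= 2 (the dominant 454
error mode).  Background reads are random nucleotides with a configurable
A+U bias (default 0.55, matching the A+U range observed in plant
precursor tables).  Tag-count tables follow a per-library multinomial
model over lognormal tag abundances; Ct tables add Gaussian noise to a
planted log2 effect.

All randomness flows from one seeded generator; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .sequence_io import ESTRead, ReferenceMiRNA, revcomp, write_fasta

_WOBBLE_PARTNERS = {"A": "U", "C": "G", "G": "CU", "U": "AG"}
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic libraries."""

    n_reads: int = 500
    read_length_range: tuple[int, int] = (51, 478)
    read_length_mode: int = 200
    mode_fraction: float = 0.8  # fraction of reads drawn near the mode
    n_planted: int = 25
    mature_length_range: tuple[int, int] = (20, 24)
    precursor_length_range: tuple[int, int] = (66, 233)
    mismatch_count_per_arm: int = 0
    loop_length: int = 8
    contaminant_fraction: float = 0.0
    truncation_fraction: float = 0.0
    homopolymer_indel_rate: float = 0.0
    au_bias: float = 0.55
    planted_ns_max: int = 0  # substitutions between planted mature and reference
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "contaminant_fraction",
            "truncation_fraction",
            "homopolymer_indel_rate",
            "mode_fraction",
            "au_bias",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("read_length_range", "mature_length_range", "precursor_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if self.n_planted > self.n_reads:
            raise ValueError("n_planted exceeds n_reads")
        if not (0 <= self.mismatch_count_per_arm <= 3):
            raise ValueError("mismatch_count_per_arm must be 0-3")
        if self.loop_length < 3:
            raise ValueError("loop_length must be >= 3")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("read_length_range", "mature_length_range", "precursor_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PlantedPrecursor:
    read_id: str
    family: str
    mature_seq: str
    precursor_span: tuple[int, int]  # 0-based half-open on the read
    mature_span: tuple[int, int]
    arm: str
    library: str
    ns: tuple = ()  # SubstitutionRecords vs the reference mature
    noise_affected: bool = False


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic libraries."""

    planted_precursors: list[PlantedPrecursor] = field(default_factory=list)
    contaminant_ids: list[str] = field(default_factory=list)
    truncated_ids: list[str] = field(default_factory=list)
    de_tags: list[tuple[str, int, str, float]] = field(default_factory=list)
    n_unique_references: int | None = None


def _random_seq(rng: np.random.Generator, n: int, au_bias: float = 0.5) -> str:
    p_au = au_bias / 2.0
    p_gc = (1.0 - au_bias) / 2.0
    return "".join(
        rng.choice(np.array(list("AUGC")), size=n, p=[p_au, p_au, p_gc, p_gc])
    )


def make_hairpin_precursor(
    mature: str,
    arm: str = "5p",
    loop_len: int = 8,
    n_arm_mismatches: int = 0,
    seed: int | np.random.Generator = 0,
    target_length: int | None = None,
    flank_len: int = 5,
    au_bias: float = 0.55,
) -> tuple[str, tuple[int, int]]:
    """Build a hairpin precursor whose requested arm carries ``mature``.

    Layout: flank + stem + loop + reverse-complement stem + flank, with the
    mature-bearing stem on the 5' or 3' side of the terminal loop.  The
    complementary stem carries exactly ``n_arm_mismatches`` non-pairing
    positions (never within 3 nt of a stem end, never opposite the mature's
    first/last two bases).  ``target_length`` stretches the stem with extra
    complementary sequence to reach a desired precursor length.  Returns
    the precursor and the mature's 0-based half-open span.
    """
    if not (20 <= len(mature) <= 24):
        raise ValueError("mature length must be 20-24 nt")
    if set(mature) - set("ACGU"):
        raise ValueError("mature contains non-ACGU symbols")
    if loop_len < 3:
        raise ValueError("loop length must be >= 3")
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    if not (0 <= n_arm_mismatches <= 3):
        raise ValueError("n_arm_mismatches must be 0-3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    min_len = len(mature) * 2 + loop_len + 2 * flank_len
    if target_length is None:
        target_length = min_len
    ext_total = max(0, (target_length - min_len) // 2)
    ext5 = ext_total // 2
    ext3 = ext_total - ext5
    # Rejection-sample the non-mature parts so the realized precursor A+U
    # stays within the acceptance band (the stem's complement mirrors the
    # stem's A+U count, so the stem composition dominates).  Best effort:
    # an extreme mature composition may leave the band unreachable.
    n_other = 2 * (ext5 + ext3) + loop_len + 2 * flank_len
    n_total = 2 * (ext5 + ext3 + len(mature)) + loop_len + 2 * flank_len
    au_mature = 2 * sum(1 for c in mature if c in "AU")
    for _ in range(50):
        ext5_seq = _random_seq(rng, ext5, au_bias)
        ext3_seq = _random_seq(rng, ext3, au_bias)
        probe = ext5_seq + ext3_seq
        au_other = 2 * sum(1 for c in probe if c in "AU")
        # loop and flanks drawn later shift this estimate only slightly
        frac = (au_mature + au_other + au_bias * (loop_len + 2 * flank_len)) / n_total
        if 0.44 <= frac <= 0.66 or n_other == 0:
            break
    stem = ext5_seq + mature + ext3_seq
    mature_off_in_stem = ext5

    comp = [_COMP[c] for c in stem[::-1]]  # reverse complement, list form
    n_stem = len(stem)
    protected = set()
    for k in range(n_stem):
        stem_pos = n_stem - 1 - k  # comp position k pairs stem position stem_pos
        near_end = stem_pos < 3 or stem_pos >= n_stem - 3
        near_mature_edge = (
            mature_off_in_stem <= stem_pos < mature_off_in_stem + 2
            or mature_off_in_stem + len(mature) - 2
            <= stem_pos
            < mature_off_in_stem + len(mature)
        )
        if near_end or near_mature_edge:
            protected.add(k)
    free = [k for k in range(n_stem) if k not in protected]
    mm_pos = rng.choice(np.array(free), size=n_arm_mismatches, replace=False) if n_arm_mismatches else []
    for k in mm_pos:
        stem_base = stem[n_stem - 1 - int(k)]
        # choose a base that neither Watson-Crick nor wobble pairs the partner
        options = [
            b for b in "ACGU" if b not in _WOBBLE_PARTNERS[stem_base]
        ]
        options = [b for b in options if b != comp[int(k)]]
        comp[int(k)] = str(rng.choice(np.array(options)))
    comp_stem = "".join(comp)

    loop = _random_seq(rng, loop_len, au_bias)
    flank5 = _random_seq(rng, flank_len, au_bias)
    flank3 = _random_seq(rng, flank_len, au_bias)
    # comp_stem position k pairs stem position n_stem-1-k in either layout
    if arm == "5p":
        seq = flank5 + stem + loop + comp_stem + flank3
        m0 = flank_len + mature_off_in_stem
    else:
        seq = flank5 + comp_stem + loop + stem + flank3
        m0 = flank_len + n_stem + loop_len + mature_off_in_stem
    return seq, (m0, m0 + len(mature))


def gen_reference_set(
    n_species: int,
    n_families: int,
    duplicate_rate: float = 0.0,
    seed: int = 0,
    au_range: tuple[float, float] = (0.45, 0.65),
) -> tuple[list[ReferenceMiRNA], int]:
    """Generate a species-annotated mature-miRNA reference set.

    One unique mature sequence per family; a ``duplicate_rate`` fraction of
    the emitted entries are exact copies attributed to a different species
    (the redundancy that deduplication removes).  Returns the records and
    the true unique-sequence count.
    """
    if n_species < 1 or n_families < 1:
        raise ValueError("counts must be >= 1")
    if not (0.0 <= duplicate_rate < 1.0):
        raise ValueError("duplicate_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    species = [f"sp{j:02d}" for j in range(n_species)]
    refs: list[ReferenceMiRNA] = []
    seqs: list[tuple[str, str]] = []
    for i in range(n_families):
        fam = f"simR{i + 1}"
        L = int(rng.integers(20, 25))
        au = float(rng.uniform(*au_range))
        # realized (not just expected) A+U fraction kept inside au_range so
        # that hairpins planted around these matures satisfy the
        # composition criterion
        for _ in range(100):
            seq = _random_seq(rng, L, au)
            frac = sum(1 for c in seq if c in "AU") / L
            if au_range[0] <= frac <= au_range[1]:
                break
        sp = species[int(rng.integers(0, n_species))]
        refs.append(
            ReferenceMiRNA(
                id=f"{sp}-{fam}", species=sp, family=fam, mature_seq=seq
            )
        )
        seqs.append((fam, seq))
    n_dup = round(duplicate_rate * n_families / (1.0 - duplicate_rate))
    for d in range(n_dup):
        fam, seq = seqs[int(rng.integers(0, len(seqs)))]
        donor = next(r for r in refs if r.family == fam)
        others = [s for s in species if s != donor.species] or species
        sp = others[int(rng.integers(0, len(others)))]
        refs.append(
            ReferenceMiRNA(
                id=f"{sp}-{fam}-dup{d + 1}", species=sp, family=fam, mature_seq=seq
            )
        )
    n_unique = len({r.mature_seq for r in refs})
    return refs, n_unique


def _read_length(rng: np.random.Generator, cfg: SimConfig) -> int:
    lo, hi = cfg.read_length_range
    if rng.random() < cfg.mode_fraction:
        val = int(round(rng.normal(cfg.read_length_mode, 25)))
    else:
        val = int(rng.integers(lo, hi + 1))
    return int(np.clip(val, lo, hi))


def _apply_homopolymer_indels(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int]]]:
    """Insert/delete one base inside homopolymer runs >= 2 at a per-base
    rate; returns the noisy sequence and (position, shift) edits."""
    if rate <= 0:
        return seq, []
    out: list[str] = []
    edits: list[tuple[int, int]] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        run = seq[i : j + 1]
        if len(run) >= 2:
            for k in range(len(run)):
                if rng.random() < rate:
                    if rng.random() < 0.5:
                        run = run + run[0]  # insertion
                        edits.append((i, +1))
                    elif len(run) > 1:
                        run = run[:-1]  # deletion
                        edits.append((i, -1))
        out.append(run)
        i = j + 1
    return "".join(out), edits


def gen_est_library(
    config: SimConfig,
    references: Sequence[ReferenceMiRNA] | None = None,
    contaminants: Sequence | None = None,
) -> tuple[list[ESTRead], SimTruth, list[ReferenceMiRNA]]:
    """Generate sexual + apomictic EST reads with planted precursors.

    Planted reads embed ``make_hairpin_precursor`` output built from the
    supplied reference matures (or a self-generated reference set, which is
    returned either way).  Truncated precursors carry only the
    mature-bearing arm and loop.  Contaminant reads are verbatim segments
    of the contaminant records.  Homopolymer indels are applied after
    planting; truth spans of affected reads are flagged.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if references is None:
        references, n_unique = gen_reference_set(
            n_species=3, n_families=max(10, config.n_planted), seed=int(rng.integers(2**31))
        )
    else:
        n_unique = len({r.mature_seq for r in references})
    usable_refs = [
        r
        for r in references
        if config.mature_length_range[0] <= len(r.mature_seq) <= config.mature_length_range[1]
    ]
    if config.n_planted > 0 and not usable_refs:
        raise ValueError("no reference matures within the mature length range")

    truth = SimTruth(n_unique_references=n_unique)
    reads: list[ESTRead] = []
    n_contaminant = int(round(config.contaminant_fraction * config.n_reads))
    n_truncated = int(round(config.truncation_fraction * config.n_reads))
    n_background = config.n_reads - config.n_planted - n_contaminant - n_truncated
    if n_background < 0:
        raise ValueError("planted + contaminant + truncated reads exceed n_reads")

    if contaminants is None and n_contaminant > 0:
        contaminants = _default_contaminant_db(rng)

    counter = 0

    def next_id(prefix: str, library: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}_{library[:3]}_{counter:05d}"

    def library_of(idx: int) -> str:
        return "sexual" if idx % 2 == 0 else "apomictic"

    # planted precursor reads
    from .ns_stability import detect_ns  # local import to avoid a cycle

    for p in range(config.n_planted):
        library = library_of(p)
        ref = usable_refs[int(rng.integers(0, len(usable_refs)))]
        mature = ref.mature_seq
        ns_records: tuple = ()
        if config.planted_ns_max > 0:
            k = int(rng.integers(0, config.planted_ns_max + 1))
            if k:
                pos = rng.choice(len(mature), size=k, replace=False)
                chars = list(mature)
                for q in pos:
                    alts = [b for b in "ACGU" if b != chars[int(q)]]
                    chars[int(q)] = str(rng.choice(np.array(alts)))
                mature = "".join(chars)
                ns_records = tuple(detect_ns(mature, ref.mature_seq))
        arm = "5p" if rng.random() < 0.5 else "3p"
        lo, hi = config.precursor_length_range
        target = int(rng.integers(lo, min(hi, 160) + 1))
        prec, (pm0, pm1) = make_hairpin_precursor(
            mature,
            arm=arm,
            loop_len=config.loop_length,
            n_arm_mismatches=config.mismatch_count_per_arm,
            seed=rng,
            target_length=target,
            au_bias=config.au_bias,
        )
        read_len = max(_read_length(rng, config), len(prec) + 10)
        pad_total = read_len - len(prec)
        pad5 = int(rng.integers(0, pad_total + 1))
        seq = (
            _random_seq(rng, pad5, config.au_bias)
            + prec
            + _random_seq(rng, pad_total - pad5, config.au_bias)
        )
        rid = next_id("planted", library)
        noisy_seq, edits = _apply_homopolymer_indels(
            seq, config.homopolymer_indel_rate, rng
        )
        prec_span = (pad5, pad5 + len(prec))
        mature_span = (pad5 + pm0, pad5 + pm1)
        affected = any(pos < mature_span[1] for pos, _ in edits)
        if edits:
            shift_before = lambda x: sum(s for pos, s in edits if pos < x)
            prec_span = (
                prec_span[0] + shift_before(prec_span[0]),
                prec_span[1] + shift_before(prec_span[1]),
            )
            mature_span = (
                mature_span[0] + shift_before(mature_span[0]),
                mature_span[1] + shift_before(mature_span[1]),
            )
        reads.append(ESTRead(id=rid, seq=noisy_seq, library=library))
        truth.planted_precursors.append(
            PlantedPrecursor(
                read_id=rid,
                family=ref.family,
                mature_seq=mature,
                precursor_span=prec_span,
                mature_span=mature_span,
                arm=arm,
                library=library,
                ns=ns_records,
                noise_affected=affected,
            )
        )

    # truncated precursors: mature-bearing arm + loop only, no complement
    for t in range(n_truncated):
        library = library_of(config.n_planted + t)
        ref = usable_refs[int(rng.integers(0, len(usable_refs)))] if usable_refs else None
        if ref is None:
            break
        mature = ref.mature_seq
        # a truncated precursor is a cDNA that ends before the complementary
        # arm: mature-bearing arm + loop, then the read stops
        arm_seq = (
            _random_seq(rng, 10, config.au_bias)
            + mature
            + _random_seq(rng, config.loop_length, config.au_bias)
        )
        pad5 = int(rng.integers(10, 31))
        pad3 = int(rng.integers(0, 11))
        seq = (
            _random_seq(rng, pad5, config.au_bias)
            + arm_seq
            + _random_seq(rng, pad3, config.au_bias)
        )
        if len(seq) < config.read_length_range[0]:
            seq = seq + _random_seq(
                rng, config.read_length_range[0] - len(seq), config.au_bias
            )
        seq, _ = _apply_homopolymer_indels(seq, config.homopolymer_indel_rate, rng)
        rid = next_id("trunc", library)
        reads.append(ESTRead(id=rid, seq=seq, library=library))
        truth.truncated_ids.append(rid)

    # contaminant reads: verbatim segments of contaminant records
    for c in range(n_contaminant):
        library = library_of(c)
        src = contaminants[int(rng.integers(0, len(contaminants)))]
        seg_len = min(
            len(src.seq), max(60, _read_length(rng, config) // 2)
        )
        start = int(rng.integers(0, len(src.seq) - seg_len + 1))
        rid = next_id("contam", library)
        reads.append(ESTRead(id=rid, seq=src.seq[start : start + seg_len], library=library))
        truth.contaminant_ids.append(rid)

    # background reads
    for b in range(n_background):
        library = library_of(b)
        rid = next_id("bg", library)
        seq = _random_seq(rng, _read_length(rng, config), config.au_bias)
        seq, _ = _apply_homopolymer_indels(seq, config.homopolymer_indel_rate, rng)
        reads.append(ESTRead(id=rid, seq=seq, library=library))

    return reads, truth, list(references)


def _default_contaminant_db(rng: np.random.Generator):
    """A small synthetic tRNA/rRNA-like database (random sequences with
    structured labels; stand-ins for Rfam/GtRNAdb records)."""
    from .sequence_io import FastaRecord

    db = []
    for i in range(5):
        db.append(FastaRecord(id=f"rRNA_syn_{i+1}", seq=_random_seq(rng, 400, 0.48)))
    for i in range(10):
        db.append(FastaRecord(id=f"tRNA_syn_{i+1}", seq=_random_seq(rng, 75, 0.5)))
    return db


def gen_tag_counts(
    n_tags: int,
    n_stages: int = 4,
    planted: Sequence[tuple[int, int, str, float]] = (),
    depth: int = 100_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Tag x library count table over stages x {sexual, apomictic}.

    Baseline tag abundances are lognormal and shared across libraries;
    counts per library are multinomial at the given sequencing ``depth``.
    ``planted`` lists (tag index, stage, mode, fold) expression changes:
    the tag's expected abundance in that (stage, mode) library is
    multiplied by ``fold``.  Returns the table and truth.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_tags)
    tags = [f"tag{i:05d}" for i in range(n_tags)]
    modes = ("sexual", "apomictic")
    truth = SimTruth()
    cols = {}
    for stage in range(1, n_stages + 1):
        for mode in modes:
            weights = base.copy()
            for idx, st, md, fold in planted:
                if fold <= 0:
                    raise ValueError("fold changes must be > 0")
                if not (1 <= st <= n_stages) or md not in modes:
                    raise ValueError("planted tag references invalid stage/mode")
                if st == stage and md == mode:
                    weights[idx] *= fold
            p = weights / weights.sum()
            cols[f"{mode}_s{stage}"] = rng.multinomial(depth, p)
    for idx, st, md, fold in planted:
        if fold != 1.0:
            truth.de_tags.append((tags[idx], st, md, float(fold)))
    df = pd.DataFrame(cols, index=pd.Index(tags, name="tag"))
    return df, truth


def gen_qpcr(
    n_samples: int,
    effect_log2: float = 0.0,
    replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    base_ct_target: float = 26.0,
    base_ct_reference: float = 20.0,
) -> tuple[pd.DataFrame, dict]:
    """Ct triplicates for a target and a ubiquitin-like reference gene.

    Sample ``cal`` is the calibrator (no effect); samples ``s1..sN`` carry
    the planted effect: their target Ct is shifted by ``-effect_log2`` so
    the expected recovered fold change is ``2**effect_log2``.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    samples = ["cal"] + [f"s{i + 1}" for i in range(n_samples)]
    for sample in samples:
        shift = 0.0 if sample == "cal" else -effect_log2
        for gene, base in (("target", base_ct_target), ("reference", base_ct_reference)):
            mu = base + (shift if gene == "target" else 0.0)
            cts = mu + rng.normal(0.0, noise_sd, size=replicates)
            rows.append(
                {"sample": sample, "gene": gene}
                | {f"ct{k + 1}": float(c) for k, c in enumerate(cts)}
            )
    truth = {"calibrator": "cal", "expected_fold": float(2.0**effect_log2)}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_simulation(
    outdir: str | Path,
    config: SimConfig,
    references: Sequence[ReferenceMiRNA] | None = None,
) -> SimTruth:
    """Run the library generator and write FASTA/TSV/YAML artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads, truth, refs = gen_est_library(config, references=references)
    for library in ("sexual", "apomictic"):
        write_fasta(
            [r for r in reads if r.library == library],
            outdir / f"{library}.fasta",
        )

    class _Rec:
        def __init__(self, id: str, seq: str) -> None:
            self.id, self.seq = id, seq

    write_fasta([_Rec(r.id, r.mature_seq) for r in refs], outdir / "references.fasta")
    rows = [
        {
            "read_id": p.read_id,
            "family": p.family,
            "mature_seq": p.mature_seq,
            "precursor_start": p.precursor_span[0],
            "precursor_end": p.precursor_span[1],
            "mature_start": p.mature_span[0],
            "mature_end": p.mature_span[1],
            "arm": p.arm,
            "library": p.library,
            "noise_affected": p.noise_affected,
        }
        for p in truth.planted_precursors
    ]
    pd.DataFrame(
        rows,
        columns=[
            "read_id", "family", "mature_seq", "precursor_start", "precursor_end",
            "mature_start", "mature_end", "arm", "library", "noise_affected",
        ],
    ).to_csv(outdir / "truth_planted.tsv", sep="\t", index=False)
    pd.DataFrame({"read_id": truth.contaminant_ids}).to_csv(
        outdir / "truth_contaminants.tsv", sep="\t", index=False
    )
    pd.DataFrame({"read_id": truth.truncated_ids}).to_csv(
        outdir / "truth_truncated.tsv", sep="\t", index=False
    )
    config.to_yaml(outdir / "sim_config.yaml")
    return truth
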