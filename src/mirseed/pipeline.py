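"""End-to-end orchestration: discovery, stability testing and expression
analyses under one configuration with deterministic seeds.

Internal coordinates are 0-based half-open; report writers convert to
1-based inclusive, the convention of biology tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .folding import PARAMETER_VERSION
from .hairpin import (
    CandidateWindowPolicy,
    PrecursorRecord,
    evaluate_candidate,
)
from .homology import collapse_redundant, scan_library
from .ns_stability import (
    CorrectionResult,
    classify_corrections,
    detect_ns,
    paired_stability_test,
)
from .sequence_io import (
    ESTRead,
    dedup_mirnas,
    filter_contaminants,
    parse_reference_fasta,
    read_fasta,
    removal_report,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_STAGE_FAILURE = 3


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; round-trips through YAML."""

    refs: str | None = None
    ests: str | None = None
    contaminants: str | None = None
    counts: str | None = None
    qpcr: str | None = None
    microarray_families: str | None = None
    out_dir: str = "mirseed_out"
    max_mm: int = 3
    mfe_max: float = -10.0
    au_range: tuple[float, float] = (40.0, 70.0)
    mature_len: tuple[int, int] = (20, 24)
    gap_tolerance: int = 6
    contaminant_k: int = 20
    mfei_report_only: bool = True
    alpha: float = 0.05
    backend: str = "builtin"
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.max_mm <= 3):
            raise ValueError("max_mm must be 0-3")
        if self.mfe_max > 0:
            raise ValueError("mfe_max must be <= 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if tuple(self.mature_len) != (20, 24):
            raise ValueError("mature length window is fixed at 20-24 nt")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("au_range", "mature_len"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _policy(config: PipelineConfig) -> CandidateWindowPolicy:
    return CandidateWindowPolicy(
        mfe_max=config.mfe_max,
        au_range=tuple(config.au_range),
        gap_tolerance=config.gap_tolerance,
        backend=config.backend,
    )


def discover(
    refs,
    ests: Sequence[ESTRead],
    contaminant_db=(),
    config: PipelineConfig | None = None,
):
    """Run sequence_io -> homology -> hairpin analysis in memory.

    Returns ``(records, removed, audit)``: per-candidate PrecursorRecords
    (accepted and rejected), the contaminant-removal list, and an audit of
    per-stage counts.
    """
    if config is None:
        config = PipelineConfig()
    config.validate()
    kept_refs, removed_map = dedup_mirnas(refs)
    usable = [
        r
        for r in kept_refs
        if config.mature_len[0] <= len(r.mature_seq) <= config.mature_len[1]
    ]
    kept, removed = filter_contaminants(ests, contaminant_db, k=config.contaminant_k)
    hits = scan_library(usable, kept, max_mm=config.max_mm)
    candidates = collapse_redundant(hits)
    est_by_id = {e.id: e for e in kept}
    policy = _policy(config)
    records: list[PrecursorRecord] = []
    for cand in candidates:
        est = est_by_id[cand.est_id]
        rec = evaluate_candidate(
            est, cand.best_hit, policy, family="/".join(cand.families)
        )
        records.append(rec)
    audit = {
        "n_refs_in": len(refs),
        "n_refs_unique": len(kept_refs),
        "n_refs_usable": len(usable),
        "n_reads_in": len(ests),
        "n_reads_kept": len(kept),
        "n_reads_removed": len(removed),
        "n_family_hits": sum(len(v) for v in hits.values()),
        "n_candidates": len(candidates),
        "n_accepted": sum(r.accepted for r in records),
    }
    return records, removed, audit


def _records_table(records: Sequence[PrecursorRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "family": r.family,
                "mature_seq": r.mature_seq,
                "est_id": r.est_id,
                "strand": r.strand,
                # 1-based inclusive coordinates in reports
                "precursor_start1": r.precursor_span[0] + 1,
                "precursor_end1": r.precursor_span[1],
                "NN": r.nn,
                "ARM": r.arm or "-",
                "AU_pct": round(r.au_pct, 2),
                "MFE": round(r.mfe, 2),
                "AMFE": round(r.amfe, 2) if r.amfe is not None else "-",
                "MFEI": round(r.mfei, 3) if r.mfei is not None else "-",
                "mismatches": r.mismatches,
                "accepted": r.accepted,
                "failure_reasons": "; ".join(r.failure_reasons),
            }
        )
    return pd.DataFrame(rows)


def run_discovery(config: PipelineConfig) -> dict:
    """File-level discovery stage: read inputs, run, emit reports."""
    config.validate()
    for name in ("refs", "ests"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"missing input for {name!r}: {path}")
    refs = parse_reference_fasta(config.refs)
    raw_reads = read_fasta(config.ests)
    ests = [ESTRead(id=r.id, seq=r.seq) for r in raw_reads]
    contaminant_db = (
        read_fasta(config.contaminants) if config.contaminants else []
    )
    records, removed, audit = discover(refs, ests, contaminant_db, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = _records_table(records)
    table.to_csv(out / "candidates.tsv", sep="\t", index=False)
    with open(out / "structures.txt", "w") as fh:
        for r in records:
            fh.write(f">{r.est_id} {r.family}\n{r.precursor_seq}\n{r.dot_bracket}\n")
    removal_report(removed, out / "removed_reads.tsv")
    manifest = {
        "tool": "mirseed",
        "version": __version__,
        "fold_parameters": PARAMETER_VERSION,
        "seed": config.seed,
        "thresholds": {
            "max_mm": config.max_mm,
            "mfe_max": config.mfe_max,
            "au_range": list(config.au_range),
            "mature_len": list(config.mature_len),
            "gap_tolerance": config.gap_tolerance,
            "contaminant_k": config.contaminant_k,
            "mfei_report_only": config.mfei_report_only,
            "alpha": config.alpha,
            "backend": config.backend,
        },
        "audit": audit,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if not records:
        warnings.warn("no candidates found; empty report written")
    return manifest


def ns_test_from_records(
    records: Sequence[PrecursorRecord],
    refs,
    backend: str = "builtin",
) -> dict:
    """Detect NSs of accepted candidates vs their family references, run the
    correction experiment on each, and test pooled stability."""
    from .ns_stability import correction_experiment

    ref_by_family: dict[str, str] = {}
    for r in refs:
        ref_by_family.setdefault(r.family, r.mature_seq)
    results: list[CorrectionResult] = []
    for rec in records:
        if not rec.accepted:
            continue
        fam = rec.family.split("/")[0]
        ref_mature = ref_by_family.get(fam)
        if ref_mature is None or len(ref_mature) != len(rec.mature_seq):
            continue
        subs = detect_ns(rec.mature_seq, ref_mature)
        if not subs:
            continue
        m0 = rec.precursor_seq.find(rec.mature_seq)
        if m0 < 0:
            continue
        results.append(
            correction_experiment(
                rec.precursor_seq,
                (m0, m0 + len(rec.mature_seq)),
                subs,
                backend=backend,
                precursor_id=f"{rec.family}:{rec.est_id}",
            )
        )
    summary: dict = {"n_with_ns": len(results)}
    summary["calls"] = classify_corrections(results)
    if sum(1 for r in results if r.delta != 0.0) >= 2:
        test = paired_stability_test(results)
        summary["wilcoxon"] = {
            "n_pairs": test.n_pairs,
            "statistic": test.statistic,
            "p_value": test.p_value,
            "direction": test.direction,
        }
    return summary


def run_full(config: PipelineConfig) -> dict:
    """Discovery plus NS stability, target prediction and expression stages.

    Stages whose inputs are absent are skipped with a note; a stage raising
    an error aborts with the stage name while earlier outputs remain on
    disk.
    """
    summary: dict = {}
    stage = "discovery"
    try:
        manifest = run_discovery(config)
        summary["discovery"] = manifest["audit"]
        refs = parse_reference_fasta(config.refs)
        raw_reads = read_fasta(config.ests)
        ests = [ESTRead(id=r.id, seq=r.seq) for r in raw_reads]
        contaminant_db = (
            read_fasta(config.contaminants) if config.contaminants else []
        )
        records, _, _ = discover(refs, ests, contaminant_db, config)

        stage = "ns-test"
        summary["ns_stability"] = ns_test_from_records(
            records, refs, backend=config.backend
        )

        stage = "expression"
        if config.counts and Path(config.counts).exists():
            from .expression import diff_expression

            counts = pd.read_csv(config.counts, sep="\t", index_col=0)
            flagged = []
            for tag in counts.index:
                for comp in diff_expression(counts, tag):
                    if comp.p_value <= config.alpha and comp.direction:
                        flagged.append(
                            {
                                "tag": comp.tag,
                                "stage": comp.stage,
                                "direction": comp.direction,
                                "p_value": comp.p_value,
                            }
                        )
            summary["differential_tags"] = flagged
        if config.qpcr and Path(config.qpcr).exists():
            from .expression import ddct

            qpcr = pd.read_csv(config.qpcr, sep="\t")
            calibrator = str(qpcr["sample"].iloc[0])
            rel = ddct(qpcr, calibrator)
            summary["qpcr"] = [
                {"sample": r.sample, "fold": r.fold, "ddct": r.ddct} for r in rel
            ]
        if config.microarray_families and Path(config.microarray_families).exists():
            from .expression import compare_family_sets

            with open(config.microarray_families) as fh:
                array_fams = [line.strip() for line in fh if line.strip()]
            bio_fams = sorted({r.family.split("/")[0] for r in records if r.accepted})
            comp = compare_family_sets(bio_fams, array_fams)
            summary["family_sets"] = comp.counts
    except FileNotFoundError:
        raise
    except Exception as e:  # pragma: no cover - stage failure path
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
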