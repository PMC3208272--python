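"""Target prediction, microarray detection calls, family-set comparison,
tag-count differential expression and ΔΔCt relative quantification.

Target prediction scans transcripts for gapless complementary sites of a
mature miRNA with a weighted mismatch budget: a G:U wobble pair costs
``gu_weight`` (default 0.5) and any other non-Watson-Crick column costs 1,
with a total budget of 3.  Tag-count comparisons between reproductive
modes use a 2x2 Fisher exact test on pooled per-mode counts (tag vs
library remainder).  Relative qPCR expression follows the comparative
ΔΔCt method against a housekeeping reference gene and a calibrator
sample: fold = 2^-ΔΔCt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import revcomp

DEFAULT_GU_WEIGHT = 0.5
DEFAULT_MAX_WEIGHTED_MM = 3.0


@dataclass(frozen=True)
class TargetHit:
    """A complementary site of a miRNA on a transcript."""

    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based half-open on the transcript
    site_end: int
    weighted_mismatches: float
    gu_pairs: int


def predict_targets(
    mirna: str,
    transcripts: Mapping[str, str] | Sequence,
    max_weighted_mm: float = DEFAULT_MAX_WEIGHTED_MM,
    gu_weight: float = DEFAULT_GU_WEIGHT,
    mirna_id: str = "mirna",
) -> list[TargetHit]:
    """Find gapless complementary sites within the weighted mismatch budget.

    ``transcripts`` maps id -> sequence (or is an iterable of objects with
    ``id``/``seq``).  The site length equals the miRNA length; a window
    qualifies when sum(column costs) <= ``max_weighted_mm`` where a
    Watson-Crick pair costs 0, a G:U wobble ``gu_weight`` and anything else
    (including N) 1.
    """
    if isinstance(transcripts, Mapping):
        items = transcripts.items()
    else:
        items = [(t.id, t.seq) for t in transcripts]
    L = len(mirna)
    m = np.frombuffer(mirna.encode(), dtype=np.uint8)
    G, U, A, C, N = (ord(c) for c in "GUACN")
    hits: list[TargetHit] = []
    for tid, seq in items:
        if len(seq) < L:
            continue
        # align the miRNA antiparallel to each window: with trc the reverse
        # complement of the window, position k pairs mirna[k] with the
        # target base complement(trc[k]); WC pair <=> mirna[k] == trc[k];
        # G:U wobble <=> (mirna G, trc A) or (mirna U, trc C)
        full_rc = revcomp(seq)
        rc = np.frombuffer(full_rc.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(rc, L)
        wc = windows == m
        wobble = ((m == G) & (windows == A)) | ((m == U) & (windows == C))
        anyn = (windows == N) | (m == N)
        cost = np.where(wc & ~anyn, 0.0, np.where(wobble & ~anyn, gu_weight, 1.0))
        totals = cost.sum(axis=1)
        n = len(seq)
        for widx in np.nonzero(totals <= max_weighted_mm)[0]:
            # window widx on the reverse complement covers forward
            # coordinates [n - widx - L, n - widx)
            start = n - int(widx) - L
            hits.append(
                TargetHit(
                    mirna_id=mirna_id,
                    transcript_id=tid,
                    site_start=start,
                    site_end=start + L,
                    weighted_mismatches=float(totals[widx]),
                    gu_pairs=int((wobble[widx] & ~anyn[widx]).sum()),
                )
            )
    hits.sort(key=lambda h: (h.transcript_id, h.site_start))
    return hits


# ---------------------------------------------------------------------------
# Microarray detection calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MicroarraySpot:
    """Replicate signals and quality statistics for one probe."""

    probe_id: str
    signals: tuple[float, ...]
    background_sd: float | None
    cv: float
    channel_p: float  # Cy3 vs Cy5 difference p-value


@dataclass(frozen=True)
class DetectionCall:
    probe_id: str
    detected: bool
    failed_clauses: tuple[str, ...]


def microarray_detect(spots: Sequence[MicroarraySpot]) -> list[DetectionCall]:
    """Apply the detection rule: mean signal > 3 x background SD, spot
    CV < 0.5 and channel p < 0.01; every failed clause is reported.

    Probes with missing background are skipped with a warning.
    """
    calls: list[DetectionCall] = []
    for spot in spots:
        if spot.background_sd is None:
            warnings.warn(f"probe {spot.probe_id}: missing background; skipped")
            continue
        failed = []
        if not np.mean(spot.signals) > 3.0 * spot.background_sd:
            failed.append("signal <= 3 x background SD")
        if not spot.cv < 0.5:
            failed.append("CV >= 0.5")
        if not spot.channel_p < 0.01:
            failed.append("channel p >= 0.01")
        calls.append(
            DetectionCall(
                probe_id=spot.probe_id,
                detected=not failed,
                failed_clauses=tuple(failed),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Family-set algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySetComparison:
    both: tuple[str, ...]
    a_only: tuple[str, ...]
    b_only: tuple[str, ...]
    union: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "union": len(self.union),
        }


def compare_family_sets(
    set_a: Iterable[str],
    set_b: Iterable[str],
    merge_map: Mapping[str, str] | None = None,
) -> FamilySetComparison:
    """Set algebra between two family lists (e.g. bioinformatic vs
    microarray detections).

    ``merge_map`` renames families before comparison so that labels such as
    miR156 and miR157 can be treated as one family when a combined-family
    convention is used; the same map is applied to both sets.
    """
    def norm(s: Iterable[str]) -> set[str]:
        out = set()
        for f in s:
            out.add(merge_map.get(f, f) if merge_map else f)
        return out

    a, b = norm(set_a), norm(set_b)
    return FamilySetComparison(
        both=tuple(sorted(a & b)),
        a_only=tuple(sorted(a - b)),
        b_only=tuple(sorted(b - a)),
        union=tuple(sorted(a | b)),
    )


# ---------------------------------------------------------------------------
# Tag-count differential expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageComparison:
    tag: str
    stage: int
    count_sexual: int
    count_apomictic: int
    total_sexual: int
    total_apomictic: int
    p_value: float
    direction: str | None  # mode with the higher normalized count


def diff_expression(
    counts: pd.DataFrame,
    tag: str,
    stage: int | None = None,
    method: str = "fisher",
) -> list[StageComparison]:
    """Compare a tag's counts between modes, per developmental stage.

    ``counts`` is a tag x library DataFrame whose columns are named
    ``{mode}_s{stage}`` (e.g. ``sexual_s2``); counts are pooled per mode at
    each stage and tested with a two-sided Fisher exact test of the 2x2
    table (tag count vs library remainder).  ``method='audic-claverie'``
    substitutes the Audic–Claverie two-sided tail probability.  Returns one
    comparison per stage (or only the requested stage).
    """
    if method not in ("fisher", "audic-claverie"):
        raise ValueError(f"unknown method {method!r}")
    lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        raise ValueError("zero library size")
    stages = sorted(
        {int(c.rsplit("_s", 1)[1]) for c in counts.columns}
    )
    if stage is not None:
        stages = [stage]
    out = []
    for st in stages:
        sex_cols = [c for c in counts.columns if c.startswith("sexual") and c.endswith(f"_s{st}")]
        apo_cols = [c for c in counts.columns if c.startswith("apomictic") and c.endswith(f"_s{st}")]
        if not sex_cols or not apo_cols:
            raise ValueError(f"stage {st} missing a mode")
        a = int(counts.loc[tag, sex_cols].sum())
        b = int(lib_sizes[sex_cols].sum()) - a
        c = int(counts.loc[tag, apo_cols].sum())
        d = int(lib_sizes[apo_cols].sum()) - c
        if method == "fisher":
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        else:
            p = _audic_claverie_p(a, c, a + b, c + d)
        prop_sex = a / (a + b)
        prop_apo = c / (c + d)
        if prop_sex == prop_apo:
            direction = None
        else:
            direction = "sexual" if prop_sex > prop_apo else "apomictic"
        out.append(
            StageComparison(
                tag=tag, stage=st, count_sexual=a, count_apomictic=c,
                total_sexual=a + b, total_apomictic=c + d,
                p_value=float(p), direction=direction,
            )
        )
    return out


def _audic_claverie_p(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic–Claverie tail probability for tag counts x, y in
    libraries of sizes n1, n2 (beta-binomial form of the AC statistic)."""
    # P(Y = y | x) under AC equals a negative-binomial-like kernel; use the
    # conditional binomial form: given x + y, Y ~ Binom(x + y, n2/(n1+n2))
    n = x + y
    pr = n2 / (n1 + n2)
    lo = stats.binom.cdf(y, n, pr)
    hi = stats.binom.sf(y - 1, n, pr)
    return float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# TF-to-EST matching
# ---------------------------------------------------------------------------


def ungapped_alignment_score(a: str, b: str) -> int:
    """Best ungapped local alignment score (+1 match, -1 mismatch).

    Scans every diagonal and returns the maximum contiguous-segment score
    (Kadane per offset).  An identity-scored stand-in for a bit-score
    homology threshold when matching transcription-factor genes to EST
    contigs.
    """
    ea = np.frombuffer(a.encode(), dtype=np.uint8)
    eb = np.frombuffer(b.encode(), dtype=np.uint8)
    best = 0
    for off in range(-(len(b) - 1), len(a)):
        ai = max(0, off)
        bi = max(0, -off)
        L = min(len(a) - ai, len(b) - bi)
        if L <= best:  # this diagonal cannot beat the current best
            continue
        scores = np.where(ea[ai : ai + L] == eb[bi : bi + L], 1, -1)
        run = 0
        for s in scores:
            run = max(0, run + int(s))
            if run > best:
                best = run
    return best


def match_tf_to_ests(
    tf_seq: str, ests: Sequence, min_score: int = 100
) -> list[str]:
    """Ids of EST records whose ungapped identity score with the TF gene
    reaches ``min_score``."""
    return [e.id for e in ests if ungapped_alignment_score(tf_seq, e.seq) >= min_score]


def tag_matches_tf(tag: str, tf_seq: str) -> bool:
    """True iff the expression tag matches the TF sequence exactly (100%
    identity, full tag length, either strand)."""
    return tag in tf_seq or revcomp(tag) in tf_seq


# ---------------------------------------------------------------------------
# Comparative ΔΔCt quantification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelExpression:
    sample: str
    dct: float
    ddct: float
    fold: float  # 2 ** (-ddct)
    dct_sd: float


def ddct(records: pd.DataFrame, calibrator_sample: str) -> list[RelExpression]:
    """Comparative ΔΔCt relative quantification.

    ``records`` has columns ``sample``, ``gene`` ("target" | "reference")
    and replicate columns ``ct1, ct2, ...``.  ΔCt = mean(Ct_target) -
    mean(Ct_reference) per sample; ΔΔCt subtracts the calibrator sample's
    ΔCt; fold change = 2^-ΔΔCt.  Samples missing the reference gene are
    rejected.  Replicate SD of ΔCt is propagated as sqrt(sd_t^2 + sd_r^2).
    """
    ct_cols = [c for c in records.columns if c.startswith("ct")]
    if len(ct_cols) < 2:
        raise ValueError("need at least 2 Ct replicates")
    per_sample: dict[str, dict[str, tuple[float, float]]] = {}
    for _, row in records.iterrows():
        cts = np.array([float(row[c]) for c in ct_cols])
        per_sample.setdefault(str(row["sample"]), {})[str(row["gene"])] = (
            float(cts.mean()),
            float(cts.std(ddof=1)),
        )
    for sample, genes in per_sample.items():
        if "reference" not in genes:
            raise ValueError(f"sample {sample!r} missing the reference gene")
        if "target" not in genes:
            raise ValueError(f"sample {sample!r} missing the target gene")
    if calibrator_sample not in per_sample:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not present")

    def delta_ct(sample: str) -> tuple[float, float]:
        t_mean, t_sd = per_sample[sample]["target"]
        r_mean, r_sd = per_sample[sample]["reference"]
        return t_mean - r_mean, float(np.hypot(t_sd, r_sd))

    cal_dct, _ = delta_ct(calibrator_sample)
    out = []
    for sample in per_sample:
        dct_val, sd = delta_ct(sample)
        dd = dct_val - cal_dct
        out.append(
            RelExpression(
                sample=sample, dct=dct_val, ddct=dd, fold=float(2.0 ** (-dd)),
                dct_sd=sd,
            )
        )
    return out
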