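"""Hairpin parsing, precursor metrics (NN, arm, A+U%, MFE, AMFE, MFEI) and
the five acceptance criteria for candidate pre-miRNAs.

A candidate stem-loop is accepted when (1) its homology hit carries at most
three mismatches to the reference mature miRNA, (2) the mature sequence lies
wholly on one arm of the hairpin, (3) the fold has MFE <= -10 kcal/mol,
(4) the precursor A+U content is within 40-70%, and (5) the mature span
overlaps neither the terminal loop nor a multiloop and contains at most a
configurable number of unpaired bases.

Metric conventions: AMFE = |MFE| / NN * 100 (positive magnitude, kcal/mol
per 100 nt) and MFEI = AMFE / (G+C%) with G+C% = 100 - A+U%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .folding import FoldResult, fold_mfe
from .homology import HomologyHit
from .sequence_io import ESTRead, revcomp

DEFAULT_MFE_MAX = -10.0  # kcal/mol, criterion (3)
DEFAULT_AU_RANGE = (40.0, 70.0)  # percent, criterion (4)
DEFAULT_GAP_TOLERANCE = 6  # unpaired bases allowed in the mature span
DEFAULT_WINDOW_EXTENSIONS = (20, 60, 100)  # symmetric retry windows, nt


def au_percent(seq: str) -> float:
    """A+U content of a sequence, in percent."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(1 for c in seq if c in "AU") / len(seq)


def compute_amfe(mfe: float, nn: int) -> float:
    """Adjusted MFE: |MFE| per 100 nt of precursor (kcal/mol per 100 nt)."""
    if nn < 1:
        raise ValueError("precursor length must be >= 1")
    if mfe > 0:
        raise ValueError("MFE must be <= 0")
    return abs(mfe) / nn * 100.0


def compute_mfei(amfe: float, au_pct: float) -> float:
    """Minimal folding energy index: AMFE / (G+C%), G+C% = 100 - A+U%."""
    if not (0.0 <= au_pct < 100.0):
        raise ValueError("A+U% must be in [0, 100); MFEI undefined at G+C=0")
    return amfe / (100.0 - au_pct)


@dataclass(frozen=True)
class HairpinReport:
    """Arm assignment of a mature span within a folded structure."""

    arm: str | None  # "5p" | "3p" | None when undefined
    unpaired_in_span: int
    loop_overlap: bool  # mature touches a terminal (hairpin) loop
    multiloop_overlap: bool  # mature touches a multiloop or the exterior


def _position_classes(fold: FoldResult) -> str:
    """Classify every position: S stem, H hairpin loop, I bulge/internal,
    M multiloop, E exterior."""
    n = len(fold.seq)
    pairs = fold.pairs
    partner = fold.pair_map
    cls = ["E"] * n
    for i, j in pairs:
        cls[i] = cls[j] = "S"

    def children_of(i: int, j: int):
        kids = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return kids

    for i, j in pairs:
        kids = children_of(i, j)
        if not kids:
            tag = "H"
        elif len(kids) == 1:
            tag = "I"
        else:
            tag = "M"
        # assign unpaired positions directly enclosed by (i, j)
        k = i + 1
        while k < j:
            if k in partner:
                k = partner[k] + 1
            else:
                cls[k] = tag
                k += 1
    return "".join(cls)


def parse_hairpin(fold: FoldResult, mature_span: tuple[int, int]) -> HairpinReport:
    """Locate the mature miRNA relative to the terminal loop of its stem.

    ``mature_span`` is 0-based half-open on ``fold.seq``.  The arm is "5p"
    when every paired mature base precedes its partner (the span lies before
    the terminal loop) and "3p" when every one follows it.  A span touching
    a hairpin loop, a multiloop or the exterior, or straddling the loop, has
    no defined arm and is flagged.
    """
    s, e = mature_span
    if not (0 <= s < e <= len(fold.seq)):
        raise ValueError("mature span outside the folded sequence")
    cls = _position_classes(fold)
    span_cls = cls[s:e]
    loop_overlap = "H" in span_cls
    multi_overlap = ("M" in span_cls) or ("E" in span_cls)
    unpaired = sum(1 for c in span_cls if c != "S")
    partner = fold.pair_map
    votes = set()
    for k in range(s, e):
        if k in partner:
            votes.add("5p" if partner[k] > k else "3p")
    arm: str | None = None
    if not loop_overlap and not multi_overlap and len(votes) == 1:
        arm = votes.pop()
    return HairpinReport(
        arm=arm,
        unpaired_in_span=unpaired,
        loop_overlap=loop_overlap,
        multiloop_overlap=multi_overlap,
    )


CRITERIA_NAMES = (
    "mismatches <= 3",
    "mature on one arm of a stable stem-loop",
    "MFE <= -10 kcal/mol",
    "precursor A+U% in [40, 70]",
    "no loop or gap in the mature miRNA",
)


@dataclass
class PrecursorRecord:
    """One candidate-precursor report row (NN, ARM, A+U%, AMFE, MFEI)."""

    family: str
    mature_seq: str
    est_id: str
    precursor_seq: str
    precursor_span: tuple[int, int]  # 0-based half-open on the forward read
    strand: str
    nn: int
    arm: str | None
    au_pct: float
    mfe: float
    amfe: float | None
    mfei: float | None
    criteria: tuple[bool, bool, bool, bool, bool]
    failure_reasons: tuple[str, ...]
    mismatches: int
    dot_bracket: str = ""

    @property
    def accepted(self) -> bool:
        return all(self.criteria)


@dataclass
class CandidateWindowPolicy:
    """How candidate precursor windows are extracted around a homology hit.

    The full read is folded first; if the criteria fail, symmetric windows
    of +/- ``extensions`` nt around the hit are retried and the passing
    window with the most negative MFE is kept.
    """

    extensions: tuple[int, ...] = DEFAULT_WINDOW_EXTENSIONS
    mfe_max: float = DEFAULT_MFE_MAX
    au_range: tuple[float, float] = DEFAULT_AU_RANGE
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE
    backend: str = "builtin"


def _evaluate_window(
    est: ESTRead,
    hit: HomologyHit,
    span: tuple[int, int],
    policy: CandidateWindowPolicy,
    family: str,
) -> PrecursorRecord:
    w0, w1 = span
    window = est.seq[w0:w1]
    # mature coordinates within the window, in folding orientation
    if hit.strand == "+":
        precursor = window
        m0 = hit.est_start - w0
        m1 = hit.est_end - w0
    else:
        precursor = revcomp(window)
        m0 = w1 - hit.est_end
        m1 = w1 - hit.est_start
    mature = precursor[m0:m1]
    fold = fold_mfe(precursor, backend=policy.backend)
    report = parse_hairpin(fold, (m0, m1))
    nn = len(precursor)
    au = au_percent(precursor)
    c1 = hit.mismatches <= 3
    c2 = report.arm is not None
    c3 = fold.delta_g <= policy.mfe_max
    c4 = policy.au_range[0] <= au <= policy.au_range[1]
    c5 = (
        not report.loop_overlap
        and not report.multiloop_overlap
        and report.unpaired_in_span <= policy.gap_tolerance
    )
    flags = (c1, c2, c3, c4, c5)
    reasons = []
    if not c1:
        reasons.append("more than 3 mismatches to the reference mature")
    if not c2 or not c3:
        reasons.append("no stable stem-loop")
    if not c4:
        reasons.append(f"precursor A+U {au:.2f}% outside [40, 70]")
    if not c5 and c2:
        reasons.append("loop or gap within the mature miRNA")
    amfe = compute_amfe(fold.delta_g, nn) if fold.delta_g <= 0 else None
    mfei = compute_mfei(amfe, au) if (amfe is not None and au < 100.0) else None
    return PrecursorRecord(
        family=family,
        mature_seq=mature,
        est_id=est.id,
        precursor_seq=precursor,
        precursor_span=(w0, w1),
        strand=hit.strand,
        nn=nn,
        arm=report.arm,
        au_pct=au,
        mfe=fold.delta_g,
        amfe=amfe,
        mfei=mfei,
        criteria=flags,
        failure_reasons=tuple(reasons),
        mismatches=hit.mismatches,
        dot_bracket=fold.dot_bracket,
    )


def evaluate_candidate(
    est: ESTRead,
    hit: HomologyHit,
    policy: CandidateWindowPolicy | None = None,
    family: str | None = None,
) -> PrecursorRecord:
    """Fold candidate precursor windows around a homology hit and score them.

    Returns the record of the first passing window (full read, then the
    policy's symmetric extensions) choosing among passing windows the one
    with the most negative MFE; when no window passes, the full-read record
    with its failure reasons is returned.  Failures are data, not errors.
    """
    if policy is None:
        policy = CandidateWindowPolicy()
    if family is None:
        family = hit.query_id
    if not (0 <= hit.est_start < hit.est_end <= est.length):
        raise ValueError("hit does not lie on the read")
    full = _evaluate_window(est, hit, (0, est.length), policy, family)
    if full.accepted:
        return full
    passing: list[PrecursorRecord] = []
    for ext in policy.extensions:
        w0 = max(0, hit.est_start - ext)
        w1 = min(est.length, hit.est_end + ext)
        if (w0, w1) == (0, est.length):
            continue
        rec = _evaluate_window(est, hit, (w0, w1), policy, family)
        if rec.accepted:
            passing.append(rec)
    if passing:
        return min(passing, key=lambda r: r.mfe)
    return full
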