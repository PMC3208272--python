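"""Nucleotide-substitution (NS) detection and the hairpin-stability
"correction" experiment.

A *Boechera* mature miRNA that differs from its conserved homolog at up to
three positions carries NS records (reference nt / observed nt).  The
correction experiment folds each precursor twice — once with the native
mature sequence and once with the NS positions reverted to the reference
nucleotides (or, in the reverse direction, a reference precursor given the
*Boechera* nucleotides) — and compares the two free energies.  A one-sided
Wilcoxon signed-rank test over the paired differences asks whether the
native hairpins are systematically more stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .folding import fold_mfe

NEUTRAL_TOL = 0.05  # kcal/mol; half the precision of one printed decimal


@dataclass(frozen=True)
class SubstitutionRecord:
    """One substituted position along a mature miRNA (1-based)."""

    position: int
    ref_nt: str
    obs_nt: str

    def __post_init__(self) -> None:
        if self.ref_nt == self.obs_nt:
            raise ValueError("ref and observed nucleotides are identical")
        for nt in (self.ref_nt, self.obs_nt):
            if nt not in "ACGU":
                raise ValueError(f"invalid nucleotide {nt!r}")


def detect_ns(obs_mature: str, ref_mature: str) -> list[SubstitutionRecord]:
    """Per-position comparison of an observed mature against its reference.

    Both sequences must have equal length (the pipeline's alignments are
    gapless); returns an empty list when identical.
    """
    if len(obs_mature) != len(ref_mature):
        raise ValueError("gapped comparison is out of scope: unequal lengths")
    return [
        SubstitutionRecord(position=i + 1, ref_nt=r, obs_nt=o)
        for i, (o, r) in enumerate(zip(obs_mature, ref_mature))
        if o != r
    ]


def ns_spectrum(
    records: Iterable[tuple[str, SubstitutionRecord]],
) -> dict[str, dict[str, dict[str, float]]]:
    """Frequency of substituted-away reference nucleotides per library mode.

    ``records`` yields (mode, SubstitutionRecord) pairs, mode being e.g.
    "sexual" or "apomictic".  Returns, per mode, counts and frequencies over
    A/C/G/U (frequencies sum to 1 within a mode; empty input gives an empty
    table).
    """
    counts: dict[str, dict[str, int]] = {}
    for mode, rec in records:
        mode_counts = counts.setdefault(mode, {nt: 0 for nt in "ACGU"})
        mode_counts[rec.ref_nt] += 1
    out: dict[str, dict[str, dict[str, float]]] = {}
    for mode, c in counts.items():
        total = sum(c.values())
        out[mode] = {
            "counts": {nt: float(c[nt]) for nt in "ACGU"},
            "frequencies": {
                nt: (c[nt] / total if total else 0.0) for nt in "ACGU"
            },
        }
    return out


def correct_precursor(
    precursor: str,
    mature_span: tuple[int, int],
    subs: Sequence[SubstitutionRecord],
    direction: str = "to_reference",
) -> str:
    """Apply (or reverse-apply) NS corrections within the mature span.

    ``to_reference`` replaces the observed nucleotide with the reference one
    at each substituted position (the precursor must carry the observed
    mature); ``to_boechera`` does the converse on a reference precursor.
    Length is preserved; applying one direction then the other is the
    identity.
    """
    if direction not in ("to_reference", "to_boechera"):
        raise ValueError(f"unknown direction {direction!r}")
    s, e = mature_span
    if not (0 <= s < e <= len(precursor)):
        raise ValueError("mature span outside precursor")
    chars = list(precursor)
    for sub in subs:
        idx = s + sub.position - 1
        if not (s <= idx < e):
            raise ValueError(f"substitution position {sub.position} outside span")
        have, want = (
            (sub.obs_nt, sub.ref_nt)
            if direction == "to_reference"
            else (sub.ref_nt, sub.obs_nt)
        )
        if chars[idx] != have:
            raise ValueError(
                f"precursor has {chars[idx]} at mature position {sub.position}, "
                f"expected {have}"
            )
        chars[idx] = want
    return "".join(chars)


@dataclass(frozen=True)
class CorrectionResult:
    """Natural vs corrected hairpin free energies for one precursor."""

    precursor_id: str
    n_subs: int
    dg_natural: float
    dg_corrected: float

    @property
    def delta(self) -> float:
        """dg_natural - dg_corrected; negative = natural more stable."""
        return self.dg_natural - self.dg_corrected

    @property
    def call(self) -> str:
        d = self.delta
        if d < -NEUTRAL_TOL:
            return "stabilizing"
        if d > NEUTRAL_TOL:
            return "destabilizing"
        return "neutral"


def correction_experiment(
    precursor: str,
    mature_span: tuple[int, int],
    subs: Sequence[SubstitutionRecord],
    backend: str = "builtin",
    precursor_id: str = "precursor",
    direction: str = "to_reference",
) -> CorrectionResult:
    """Fold the natural and NS-corrected precursor with one backend and
    compare their free energies."""
    corrected = correct_precursor(precursor, mature_span, subs, direction)
    dg_nat = fold_mfe(precursor, backend=backend).delta_g
    dg_cor = fold_mfe(corrected, backend=backend).delta_g
    return CorrectionResult(
        precursor_id=precursor_id,
        n_subs=len(subs),
        dg_natural=dg_nat,
        dg_corrected=dg_cor,
    )


@dataclass(frozen=True)
class StabilityTestResult:
    """One-sided Wilcoxon signed-rank outcome for paired ΔG differences."""

    n_pairs: int  # non-zero differences
    n_dropped_zero: int
    statistic: float  # W+: rank sum of positive differences
    p_value: float
    direction: str = "natural-more-stable"
    degenerate: bool = False


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """P(W+ <= w_plus) under the exact tie-aware null.

    Ranks may be midranks (multiples of 0.5); they are doubled to integers
    and the null distribution of the doubled rank sum is built by
    convolution over the 2^n equiprobable sign assignments.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    return float(counts[: w2 + 1].sum())


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def paired_stability_test(
    results: Sequence[CorrectionResult] | Sequence[float],
    exact_max_n: int = 25,
) -> StabilityTestResult:
    """One-sided Wilcoxon signed-rank test that natural hairpins are more
    stable than corrected ones (differences tend negative).

    Accepts CorrectionResults or raw delta values.  Zero differences are
    dropped; tied magnitudes receive midranks.  The null is exact (tie
    aware) for n <= ``exact_max_n`` and a normal approximation with
    continuity and tie correction above.  All-zero input is degenerate with
    p = 1.
    """
    deltas = np.array(
        [r.delta if isinstance(r, CorrectionResult) else float(r) for r in results],
        dtype=float,
    )
    # subtraction of printed one-decimal energies leaves ~1e-15 noise that
    # would break exact ties; round well below data precision
    deltas = np.round(deltas, 9)
    nonzero = deltas[deltas != 0.0]
    n_dropped = len(deltas) - len(nonzero)
    n = len(nonzero)
    if n == 0:
        return StabilityTestResult(
            n_pairs=0, n_dropped_zero=n_dropped, statistic=0.0, p_value=1.0,
            degenerate=True,
        )
    if n < 2:
        raise ValueError("need at least 2 non-zero differences")
    mags = np.abs(nonzero)
    ranks = _midranks(mags)
    w_plus = float(ranks[nonzero > 0].sum())
    if n <= exact_max_n:
        p = _signed_rank_exact_p(w_plus, ranks)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction
        _, tie_counts = np.unique(mags, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mean + 0.5) / math.sqrt(var)
        p = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
    return StabilityTestResult(
        n_pairs=n, n_dropped_zero=n_dropped, statistic=w_plus, p_value=min(p, 1.0)
    )


def classify_corrections(
    results: Sequence[CorrectionResult],
) -> dict[str, int]:
    """Count stabilizing / destabilizing / neutral calls."""
    out = {"stabilizing": 0, "destabilizing": 0, "neutral": 0}
    for r in results:
        out[r.call] += 1
    return out
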