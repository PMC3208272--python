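# Methods

## Overview

`mirseed` chains four stages: sequence intake (normalization, reference
deduplication, tRNA/rRNA screening), gapless homology search of mature
miRNAs against EST reads, hairpin analysis of candidate precursors, and
downstream analyses (NS-stability experiment, target prediction,
tag-count differential expression, ΔΔCt quantification).  A synthetic
generator supplies every input with ground truth.

## Sequence intake

Sequences are held as uppercase RNA over `{A,C,G,U,N}`; DNA is converted
on input.  Reference deduplication keeps one record per distinct mature
sequence, choosing the first after a `(species, id)` sort so results do
not depend on input order.  Contaminant screening removes a read iff it
shares an exact k-mer (default k = 20, either strand) with any record of
the contaminant database; "exact match" length is a free parameter
because full-length vs local identity is genuinely open — k = 20 means a
read containing any full-length mature-miRNA-sized fragment of a
tRNA/rRNA is excluded.

## Homology search

The scanner is exhaustive rather than word-seeded: every window of length
|query| on either strand is scored by Hamming distance, and windows with
≤ 3 mismatches qualify (N never matches).  Query lengths are restricted to
20–24 nt, so the qualifying-alignment length range follows from the query
set.  Exhaustiveness guarantees the hit set is a superset of any seeded
heuristic at these thresholds; library sizes here are desk-scale, so no
indexing is needed.  Per (family, read) only the best hit is kept —
fewest mismatches, then longest, then leftmost, then plus strand, then
query id — a deterministic rule chosen because multiple same-family hits
on one read represent one locus.  Candidates sharing an identical
(read, window, strand) across families are merged into one record that
carries all family labels.

## Folding model (parameter table `mirseed-1`)

The built-in backend is an exact dynamic program minimizing a
nearest-neighbor free energy over nested structures:

- stacking free energies for the six canonical pairs (AU, UA, CG, GC,
  GU, UG), symmetric under strand flip by construction;
- hairpin, bulge and internal-loop initiation penalties tabulated for
  small sizes and extrapolated as `E(n) = E(n0) + 1.08 ln(n/n0)` kcal/mol
  (Jacobson–Stockmayer at 37 °C);
- internal-loop asymmetry 0.5 kcal/mol per unit, capped at 3.0;
- affine multiloops: 3.4 kcal/mol closing + 0.4 per branch, unpaired
  bases free;
- hairpin loops ≥ 3 nt; interior loops ≤ 30 unpaired bases; no dangles,
  terminal-AU or coaxial terms; sequences < 8 nt report ΔG = 0.

Energies are integers in 0.01 kcal/mol throughout, so the DP and the
exhaustive-enumeration oracle used in tests agree exactly, not within a
float tolerance.  Ties are broken toward fewer pairs by minimizing the
lexicographic pair `(energy, n_pairs)` packed into one integer; among
equal-(energy, pairs) structures a fixed traceback order decides.  The
table is a self-consistent Turner-style set; it is *not* a bit-exact
reproduction of mfold 3.2 or ViennaRNA energies, and cross-backend
agreement is checked as a rank correlation (Spearman ρ > 0.8 on random
sequences), which is the property the pipeline's accept/reject decisions
depend on.  `structure_energy` evaluates the same model on an explicit
structure and is shared by the enumeration oracle; the oracle's
independence lies in enumerating structures rather than recursing over
the DP decomposition.

The DP inner loops are JIT-compiled with numba when importable; the same
source runs as plain Python otherwise.

## Hairpin analysis

Each position of a fold is classified as stem, hairpin loop,
bulge/internal, multiloop or exterior by loop decomposition.  The mature
span's arm is 5p/3p when every paired base precedes/follows its partner
and the span touches no hairpin loop, multiloop or exterior region;
anything else is flagged with no arm.  Criterion 5's "no loop or gap" is
enforced as: gap-freedom at the alignment stage (the scanner is gapless),
no terminal-loop or multiloop overlap structurally, and at most 6
unpaired bases within the mature (strict zero would reject genuinely
bulged matures).  Criterion 4's A+U window is applied to the precursor
window, matching how precursor tables report composition.

Window policy: the full read is folded first; if the criteria fail,
symmetric windows of ±20, ±60 and ±100 nt around the hit are retried and
the passing window with the most negative MFE is kept.  The exact
precursor boundaries used in the original tables are unrecoverable, so
the policy is explicit and configurable; a consequence is that `NN` for
an accepted candidate can be the full read length when the read itself
already passes.

AMFE is defined with positive magnitude (`|MFE|/NN×100`) and
MFEI = AMFE/(G+C%); both conventions were fixed by checking the published
tables' internal consistency (seven rows reproduce to printed precision).
MFEI is reported rather than filtered because published precursor sets
include values down to 0.400.

## NS stability experiment

Substitutions are per-position differences between equal-length matures.
`correct_precursor` rewrites only the mature span (both directions:
observed→reference on a native precursor, or reference→observed on a
reference precursor); `correction_experiment` folds both variants with
the *same* backend — mixed backends would confound parameter-table
differences with the substitution effect.  Calls use a neutrality
tolerance of 0.05 kcal/mol, half the precision of one printed decimal.

The pooled test is a one-sided Wilcoxon signed-rank (alternative: native
hairpins more stable, i.e. differences tend negative).  Zeros are
dropped, tied magnitudes mid-ranked; the null is exact for n ≤ 25 (tie
aware, built by convolution over doubled ranks) and a normal
approximation with continuity and tie correction above.  Differences are
rounded at 10⁻⁹ before ranking so that subtraction noise on one-decimal
inputs cannot split true ties.  A paired t-test is not offered as a
default because the ΔG differences are few and not plausibly normal; the
signed-rank choice is documented here since the analysis tradition leaves
the test unnamed.

## Expression analyses

- **Targets:** gapless antiparallel scan; column cost 0 for Watson–Crick,
  `gu_weight` (default 0.5) for G:U, 1 otherwise; budget 3.  Setting
  `gu_weight=1` recovers a plain three-mismatch rule and always yields a
  subset of the 0.5-weight hits.
- **Microarray calls:** the detection rule consumes a supplied per-probe
  channel p-value; the underlying channel test is vendor-defined and out
  of scope.
- **Tag counts:** per stage, counts are pooled per reproductive mode and
  tested with a two-sided Fisher exact 2×2 (tag vs library remainder);
  Audic–Claverie is available by flag.  Fisher was chosen as the default
  because it is exact at small counts.
- **ΔΔCt:** ΔCt = mean Ct(target) − mean Ct(reference) per sample;
  ΔΔCt subtracts the calibrator sample; fold = 2^−ΔΔCt.  Replicate SD is
  propagated in quadrature.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical skeleton of 454 flower libraries:
read lengths clipped to [51, 478] with ~80% drawn from a normal around
200 nt; planted precursors of 66–233 nt built as
flank + stem + loop + complement-stem with the mature on the requested
arm; truncated precursors as short reads ending after the loop (a cDNA
that stops before the complementary arm); contaminants as verbatim
segments of a (synthetic, clearly labelled) tRNA/rRNA database; and
homopolymer insertions/deletions confined to runs ≥ 2 nt, the dominant
454 error mode.  Background composition uses an A+U bias of 0.55 — the
published precursor range (A+U 41.96–63.46%) motivates the default, but
the true library composition is unstated, so the bias is a knob, not a
claim.  Designed arm mismatches never sit within 3 nt of a stem end or
opposite the mature's edges, and the non-mature parts are
rejection-sampled so the realized precursor A+U stays inside the
acceptance band — otherwise the generator's own truth would violate the
criteria it is meant to exercise.

Expression data: tag counts are multinomial per library over shared
lognormal abundances with multiplicative planted effects; Ct tables add
i.i.d. Gaussian noise to a planted log2 shift on the target gene.

Not emulated: flowgram-level 454 error structure, transcriptome-level
expression realism, chimeric reads, and sequence-level homology between
contaminants and real Rfam/GtRNAdb entries.  Passing the recovery tests
therefore demonstrates the pipeline's correctness under its stated
acceptance rules, not its sensitivity on real libraries with unknown
error profiles.

## Problem sizes and determinism

Default study conditions: 500-read libraries with 25 planted precursors
for end-to-end recovery; 1000 random sequences ≤ 28 nt for the
folding-oracle equivalence; 500 random query/subject pairs for the
scanner oracle; 1000 null tags at depth 10⁵ for type-I calibration; 20
qPCR samples at noise 0.2 Ct (averaged over 12 replicate simulations in
the recovery check, since the shared calibrator's noise otherwise
dominates a single run).  All randomness flows from explicit
`numpy.random.default_rng` generators; identical configurations produce
byte-identical output files.

## Known limitations

- Absolute ΔG values differ from mfold 3.2 / ViennaRNA by design; only
  orderings and threshold decisions are comparable across backends.
- Lonely (unstacked) pairs are permitted by the model, though they are
  never energetically favorable.
- The window policy can report a precursor longer than the biological
  one when the surrounding read already folds acceptably.
- The contaminant screen is exact-match only; diverged rRNA fragments
  pass it.
- TF-to-EST matching maps a "bit score ≥ 100" convention onto an ungapped
  identity score (+1/−1, threshold 100); the two scales agree only
  approximately, and the threshold is exposed as a parameter.
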