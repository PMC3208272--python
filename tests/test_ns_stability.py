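"""NS detection, correction experiment bookkeeping and the signed-rank test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mirseed.ns_stability import (
    CorrectionResult,
    SubstitutionRecord,
    _midranks,
    classify_corrections,
    correct_precursor,
    correction_experiment,
    detect_ns,
    ns_spectrum,
    paired_stability_test,
)
from mirseed.synthetic import make_hairpin_precursor


def test_detect_ns_matches_characterwise_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(20, 25))
        ref = "".join(rng.choice(list("ACGU"), n))
        obs = list(ref)
        k = int(rng.integers(0, 4))
        pos = rng.choice(n, size=k, replace=False)
        for p in pos:
            obs[p] = {"A": "C", "C": "G", "G": "U", "U": "A"}[obs[p]]
        obs = "".join(obs)
        recs = detect_ns(obs, ref)
        expect = [(i + 1, r, o) for i, (o, r) in enumerate(zip(obs, ref)) if o != r]
        assert [(r.position, r.ref_nt, r.obs_nt) for r in recs] == expect


def test_detect_ns_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        detect_ns("ACGU", "ACG")


def test_ns_spectrum_frequencies_sum_to_one():
    recs = [
        ("sexual", SubstitutionRecord(1, "U", "A")),
        ("sexual", SubstitutionRecord(5, "U", "C")),
        ("apomictic", SubstitutionRecord(2, "G", "A")),
    ]
    spec = ns_spectrum(recs)
    assert spec["sexual"]["frequencies"]["U"] == 1.0
    assert sum(spec["apomictic"]["frequencies"].values()) == pytest.approx(1.0)
    assert ns_spectrum([]) == {}


def test_correction_is_involutive_and_local():
    mature = "UGACAGAAGAGAGAGAGCAC"
    prec, span = make_hairpin_precursor(mature, seed=3, target_length=80)
    subs = [SubstitutionRecord(position=5, ref_nt="U", obs_nt=mature[4])]
    assert mature[4] != "U"
    corrected = correct_precursor(prec, span, subs, "to_reference")
    diff = [i for i, (a, b) in enumerate(zip(prec, corrected)) if a != b]
    assert diff == [span[0] + 4]
    assert correct_precursor(corrected, span, subs, "to_boechera") == prec
    assert correct_precursor(prec, span, [], "to_reference") == prec


def test_correction_experiment_classification_tolerance():
    r = CorrectionResult("x", 1, dg_natural=-21.6, dg_corrected=-19.3)
    assert r.delta == pytest.approx(-2.3) and r.call == "stabilizing"
    r2 = CorrectionResult("y", 1, dg_natural=-55.9, dg_corrected=-56.8)
    assert r2.delta == pytest.approx(0.9) and r2.call == "destabilizing"
    r3 = CorrectionResult("z", 0, dg_natural=-20.0, dg_corrected=-20.0)
    assert r3.call == "neutral"


def test_correction_experiment_folds_both_with_same_backend():
    mature = "UGACAGAAGAGAGAGAGCAC"
    prec, span = make_hairpin_precursor(mature, seed=5, target_length=90)
    res = correction_experiment(prec, span, [], precursor_id="p")
    assert res.dg_natural == res.dg_corrected and res.call == "neutral"


def brute_force_signed_rank_p(deltas):
    d = np.asarray([x for x in deltas if x != 0.0])
    ranks = _midranks(np.abs(d))
    wobs = ranks[d > 0].sum()
    hits = 0
    for signs in itertools.product((1, -1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        hits += w <= wobs + 1e-12
    return hits / 2 ** len(d)


def test_signed_rank_exact_p_matches_enumeration(rng):
    for _ in range(20):
        n = int(rng.integers(4, 11))
        d = np.round(rng.normal(0, 2, size=n), 1)
        d = d[d != 0]
        if len(d) < 2:
            continue
        mine = paired_stability_test(d).p_value
        brute = brute_force_signed_rank_p(d)
        assert mine == pytest.approx(brute, abs=1e-12)


def test_signed_rank_agrees_with_scipy_without_ties(rng):
    d = rng.normal(0, 1, size=15)
    mine = paired_stability_test(d).p_value
    ref = stats.wilcoxon(d, alternative="less", method="exact").pvalue
    assert mine == pytest.approx(float(ref), rel=1e-9)


def test_signed_rank_invariant_under_input_permutation(rng):
    d = list(rng.normal(0, 2, size=12))
    p1 = paired_stability_test(d).p_value
    p2 = paired_stability_test(list(reversed(d))).p_value
    assert p1 == p2


def test_all_zero_deltas_degenerate():
    res = paired_stability_test([0.0, 0.0, 0.0])
    assert res.degenerate and res.p_value == 1.0 and res.n_pairs == 0


def test_normal_approximation_close_to_exact_at_boundary(rng):
    d = rng.normal(-0.5, 1.0, size=24)
    exact = paired_stability_test(d, exact_max_n=25).p_value
    approx = paired_stability_test(d, exact_max_n=10).p_value
    assert approx == pytest.approx(exact, abs=0.01)


def test_classify_corrections_counts():
    res = [
        CorrectionResult("a", 1, -20.0, -18.0),
        CorrectionResult("b", 1, -20.0, -22.0),
        CorrectionResult("c", 1, -20.0, -20.0),
    ]
    assert classify_corrections(res) == {
        "stabilizing": 1,
        "destabilizing": 1,
        "neutral": 1,
    }
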