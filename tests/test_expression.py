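"""Target prediction, detection calls, set algebra, DE and ΔΔCt."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirseed.expression import (
    MicroarraySpot,
    compare_family_sets,
    ddct,
    diff_expression,
    microarray_detect,
    predict_targets,
)
from mirseed.sequence_io import revcomp
from mirseed.synthetic import gen_qpcr, gen_tag_counts


def naive_target_scan(mirna, seq, max_mm, gu_weight):
    L = len(mirna)
    out = []
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        cost = 0.0
        for k in range(L):
            m = mirna[k]
            t = window[L - 1 - k]  # antiparallel alignment
            if "N" in (m, t):
                cost += 1.0
            elif comp[m] == t:
                pass
            elif (m, t) in (("G", "U"), ("U", "G")):
                cost += gu_weight
            else:
                cost += 1.0
        if cost <= max_mm:
            out.append((start, cost))
    return sorted(out)


def test_exact_complement_site_found():
    mirna = "UGACAGAAGAGAGAGAGCAC"
    tx = {"t1": "GGGG" + revcomp(mirna) + "AAAA"}
    hits = predict_targets(mirna, tx)
    assert len(hits) == 1
    h = hits[0]
    assert (h.site_start, h.site_end, h.weighted_mismatches) == (4, 24, 0.0)


def test_four_hard_mismatches_rejected():
    mirna = "UGACAGAAGAGAGAGAGCAC"
    site = list(revcomp(mirna))
    for k in (2, 6, 10, 14):
        site[k] = {"A": "C", "C": "A", "G": "U", "U": "G"}[site[k]]
    hits = predict_targets(mirna, {"t": "".join(site)})
    assert hits == []


def test_target_scan_matches_naive_oracle(rng):
    for _ in range(25):
        L = int(rng.integers(20, 25))
        mirna = "".join(rng.choice(list("ACGU"), L))
        seq = "".join(rng.choice(list("ACGU"), int(rng.integers(L, 200))))
        got = sorted(
            (h.site_start, h.weighted_mismatches)
            for h in predict_targets(mirna, {"t": seq})
        )
        assert got == naive_target_scan(mirna, seq, 3.0, 0.5)


def test_gu_weight_one_is_subset_of_half(rng):
    mirna = "".join(rng.choice(list("ACGU"), 21))
    seq = "".join(rng.choice(list("ACGU"), 500))
    strict = {
        (h.site_start) for h in predict_targets(mirna, {"t": seq}, gu_weight=1.0)
    }
    lenient = {
        (h.site_start) for h in predict_targets(mirna, {"t": seq}, gu_weight=0.5)
    }
    assert strict <= lenient


def test_microarray_detection_rule():
    spots = [
        MicroarraySpot("p1", (100.0, 110.0, 90.0), background_sd=10.0, cv=0.1,
                       channel_p=0.001),
        MicroarraySpot("p2", (100.0, 110.0, 90.0), background_sd=10.0, cv=0.6,
                       channel_p=0.001),
        MicroarraySpot("p3", (20.0, 25.0, 15.0), background_sd=10.0, cv=0.2,
                       channel_p=0.001),
        MicroarraySpot("p4", (100.0, 110.0, 90.0), background_sd=10.0, cv=0.1,
                       channel_p=0.05),
    ]
    calls = {c.probe_id: c for c in microarray_detect(spots)}
    assert calls["p1"].detected
    assert not calls["p2"].detected and "CV >= 0.5" in calls["p2"].failed_clauses
    assert not calls["p3"].detected
    assert not calls["p4"].detected and "channel p >= 0.01" in calls["p4"].failed_clauses


def test_microarray_missing_background_skipped():
    spots = [MicroarraySpot("p", (1.0, 2.0), background_sd=None, cv=0.1, channel_p=0.001)]
    with pytest.warns(UserWarning):
        assert microarray_detect(spots) == []


def test_family_set_algebra():
    comp = compare_family_sets({"a", "b", "c"}, {"b", "c", "d"})
    assert comp.counts == {"both": 2, "a_only": 1, "b_only": 1, "union": 4}
    same = compare_family_sets({"x"}, {"x"})
    assert same.counts["a_only"] == 0 == same.counts["b_only"]
    disjoint = compare_family_sets({"a"}, {"b"})
    assert disjoint.counts["union"] == 2


def test_family_merge_map_applied_to_both_sets():
    comp = compare_family_sets(
        {"miR156", "miR160"}, {"miR157"}, merge_map={"miR157": "miR156"}
    )
    assert comp.counts == {"both": 1, "a_only": 1, "b_only": 0, "union": 2}


def _null_counts():
    return pd.DataFrame(
        {
            "sexual_s1": [50, 50], "apomictic_s1": [50, 50],
            "sexual_s2": [50, 50], "apomictic_s2": [50, 50],
        },
        index=pd.Index(["t1", "t2"], name="tag"),
    )


def test_identical_proportions_give_p_one_no_direction():
    comps = diff_expression(_null_counts(), "t1")
    for c in comps:
        assert c.p_value == 1.0 and c.direction is None


def test_fisher_matches_hypergeometric_oracle():
    counts = pd.DataFrame(
        {"sexual_s1": [5, 99995 - 5], "apomictic_s1": [50, 99995 - 50]},
        index=pd.Index(["tag", "rest"], name="tag"),
    )
    c = diff_expression(counts, "tag", stage=1)[0]
    assert c.direction == "apomictic" and c.p_value < 0.05
    # two-sided Fisher equals summing hypergeometric point masses <= observed
    a, b = 5, 99990
    cc, d = 50, 99945
    M, n, N = a + b + cc + d, a + b, a + cc
    rv = stats.hypergeom(M, n, N)
    pmf_obs = rv.pmf(a)
    support = np.arange(max(0, N - (cc + d)), min(n, N) + 1)
    p_oracle = rv.pmf(support)[rv.pmf(support) <= pmf_obs * (1 + 1e-12)].sum()
    assert c.p_value == pytest.approx(float(p_oracle), rel=1e-6)


def test_audic_claverie_available_and_sane():
    counts = pd.DataFrame(
        {"sexual_s1": [5, 99990], "apomictic_s1": [50, 99945]},
        index=pd.Index(["tag", "rest"], name="tag"),
    )
    c = diff_expression(counts, "tag", stage=1, method="audic-claverie")[0]
    assert 0 < c.p_value < 0.05


def test_planted_tag_flagged_significant():
    counts, truth = gen_tag_counts(200, planted=[(3, 2, "apomictic", 10.0)],
                                   depth=100_000, seed=5)
    c = diff_expression(counts, "tag00003", stage=2)[0]
    assert c.p_value <= 0.05 and c.direction == "apomictic"
    assert truth.de_tags == [("tag00003", 2, "apomictic", 10.0)]


def test_unit_fold_changes_leave_truth_empty():
    _, truth = gen_tag_counts(50, planted=[(1, 1, "sexual", 1.0)], depth=1000, seed=0)
    assert truth.de_tags == []


def test_tf_matching_by_identity_score(rng):
    from mirseed.expression import (
        match_tf_to_ests,
        tag_matches_tf,
        ungapped_alignment_score,
    )
    from mirseed.sequence_io import ESTRead

    shared = "".join(rng.choice(list("ACGU"), 120))
    tf = "".join(rng.choice(list("ACGU"), 40)) + shared
    est_hit = ESTRead(id="hit", seq=shared + "".join(rng.choice(list("ACGU"), 30)))
    est_miss = ESTRead(id="miss", seq="".join(rng.choice(list("ACGU"), 200)))
    assert ungapped_alignment_score(tf, est_hit.seq) >= 120
    assert match_tf_to_ests(tf, [est_hit, est_miss], min_score=100) == ["hit"]
    tag = shared[10:36]
    assert tag_matches_tf(tag, tf)
    assert tag_matches_tf(revcomp(tag), tf)
    assert not tag_matches_tf("ACGU" * 7, tf)


def _qpcr_frame(rows):
    return pd.DataFrame(rows)


def test_ddct_identities():
    qpcr, _ = gen_qpcr(3, effect_log2=0.0, noise_sd=0.0, seed=0)
    rel = {r.sample: r for r in ddct(qpcr, "cal")}
    for r in rel.values():
        assert r.fold == pytest.approx(1.0)
    qpcr2, _ = gen_qpcr(2, effect_log2=1.0, noise_sd=0.0, seed=0)
    rel2 = {r.sample: r for r in ddct(qpcr2, "cal")}
    assert rel2["s1"].fold == pytest.approx(2.0)
    assert rel2["s1"].ddct == pytest.approx(-1.0)


def test_ddct_invariant_to_global_ct_shift():
    qpcr, _ = gen_qpcr(2, effect_log2=1.5, noise_sd=0.1, seed=4)
    base = {r.sample: r.fold for r in ddct(qpcr, "cal")}
    shifted = qpcr.copy()
    mask = shifted["sample"] == "s1"
    for col in ("ct1", "ct2", "ct3"):
        shifted.loc[mask, col] += 3.0  # both genes of s1 shift together
    after = {r.sample: r.fold for r in ddct(shifted, "cal")}
    assert after["s1"] == pytest.approx(base["s1"])


def test_ddct_rejects_missing_reference():
    df = pd.DataFrame(
        [{"sample": "cal", "gene": "target", "ct1": 20.0, "ct2": 20.1, "ct3": 19.9}]
    )
    with pytest.raises(ValueError):
        ddct(df, "cal")
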