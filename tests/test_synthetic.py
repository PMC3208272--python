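"""Generator invariants: determinism, length laws, truth consistency."""

import numpy as np
import pytest

from mirseed.folding import fold_mfe
from mirseed.hairpin import au_percent, parse_hairpin
from mirseed.synthetic import (
    SimConfig,
    gen_est_library,
    gen_qpcr,
    gen_reference_set,
    gen_tag_counts,
    make_hairpin_precursor,
    write_simulation,
)


def test_hairpin_mature_fully_paired_without_mismatches():
    mature = "UGACAGAAGAGAGAGAGCAC"
    prec, (m0, m1) = make_hairpin_precursor(mature, arm="5p", loop_len=6,
                                            n_arm_mismatches=0, seed=0)
    assert prec[m0:m1] == mature
    fold = fold_mfe(prec)
    paired = sum(1 for k in range(m0, m1) if k in fold.pair_map)
    assert paired == len(mature)
    rep = parse_hairpin(fold, (m0, m1))
    assert rep.arm == "5p"


def test_hairpin_3p_arm_places_mature_after_loop():
    mature = "UGACAGAAGAGAGAGAGCAC"
    prec, (m0, m1) = make_hairpin_precursor(mature, arm="3p", loop_len=6, seed=0)
    assert m0 > len(prec) // 2
    rep = parse_hairpin(fold_mfe(prec), (m0, m1))
    assert rep.arm == "3p"


def test_hairpin_mismatches_leave_most_mature_paired():
    mature = "UGACAGAAGAGAGAGAGCAC"
    prec, (m0, m1) = make_hairpin_precursor(mature, loop_len=8,
                                            n_arm_mismatches=3, seed=2,
                                            target_length=90)
    fold = fold_mfe(prec)
    paired = sum(1 for k in range(m0, m1) if k in fold.pair_map)
    assert paired >= len(mature) - 3 - 3  # 3 designed mismatches + slack


def test_hairpin_input_validation():
    with pytest.raises(ValueError):
        make_hairpin_precursor("ACGT" * 5)  # DNA symbol
    with pytest.raises(ValueError):
        make_hairpin_precursor("ACGU" * 5, loop_len=2)
    with pytest.raises(ValueError):
        make_hairpin_precursor("ACGU" * 3)  # too short


def test_reference_set_unique_count_matches_truth():
    refs, n_unique = gen_reference_set(3, 10, duplicate_rate=0.5, seed=1)
    assert n_unique == len({r.mature_seq for r in refs})
    refs0, n0 = gen_reference_set(2, 8, duplicate_rate=0.0, seed=2)
    assert n0 == len(refs0)


def test_library_lengths_within_bounds_and_mode_heavy():
    cfg = SimConfig(n_reads=300, n_planted=10, seed=4)
    reads, truth, _ = gen_est_library(cfg)
    lengths = np.array([r.length for r in reads])
    assert lengths.min() >= 51 and lengths.max() <= 478
    near_mode = np.abs(lengths - 200) <= 60
    assert near_mode.mean() > 0.6
    for p in truth.planted_precursors:
        span = p.precursor_span[1] - p.precursor_span[0]
        assert 66 <= span <= 233


def test_simulation_outputs_byte_identical_for_same_seed(tmp_path):
    cfg = SimConfig(n_reads=40, n_planted=4, contaminant_fraction=0.1,
                    truncation_fraction=0.1, homopolymer_indel_rate=0.001, seed=9)
    a, b = tmp_path / "a", tmp_path / "b"
    write_simulation(a, cfg)
    write_simulation(b, cfg)
    for name in ("sexual.fasta", "apomictic.fasta", "references.fasta",
                 "truth_planted.tsv", "sim_config.yaml"):
        assert (a / name).read_bytes() == (b / name).read_bytes(), name


def test_planted_truth_ids_exist_and_spans_lie_on_reads():
    cfg = SimConfig(n_reads=80, n_planted=8, truncation_fraction=0.05, seed=5)
    reads, truth, _ = gen_est_library(cfg)
    by_id = {r.id: r for r in reads}
    for p in truth.planted_precursors:
        read = by_id[p.read_id]
        s, e = p.precursor_span
        assert 0 <= s < e <= read.length
        ms, me = p.mature_span
        assert s <= ms < me <= e
        assert read.seq[ms:me] == p.mature_seq
    for rid in truth.truncated_ids:
        assert rid in by_id


def test_planted_precursors_pass_all_criteria_at_zero_noise():
    cfg = SimConfig(n_reads=60, n_planted=12, seed=6)
    reads, truth, _ = gen_est_library(cfg)
    by_id = {r.id: r for r in reads}
    for p in truth.planted_precursors:
        seq = by_id[p.read_id].seq[p.precursor_span[0] : p.precursor_span[1]]
        fold = fold_mfe(seq)
        m0 = p.mature_span[0] - p.precursor_span[0]
        m1 = p.mature_span[1] - p.precursor_span[0]
        rep = parse_hairpin(fold, (m0, m1))
        assert rep.arm == p.arm
        assert fold.delta_g <= -10.0
        assert 40.0 <= au_percent(seq) <= 70.0
        assert rep.unpaired_in_span <= 6


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        SimConfig(n_reads=10, n_planted=20).validate()
    with pytest.raises(ValueError):
        SimConfig(contaminant_fraction=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(loop_length=2).validate()


def test_homopolymer_noise_flags_affected_truth():
    cfg = SimConfig(n_reads=40, n_planted=10, homopolymer_indel_rate=0.05, seed=8)
    reads, truth, _ = gen_est_library(cfg)
    by_id = {r.id: r for r in reads}
    # spans must still lie on the read even after indel shifts
    for p in truth.planted_precursors:
        read = by_id[p.read_id]
        assert 0 <= p.precursor_span[0] < p.precursor_span[1] <= read.length
    assert any(p.noise_affected for p in truth.planted_precursors)


def test_qpcr_noiseless_folds_exact():
    qpcr, truth = gen_qpcr(4, effect_log2=0.0, noise_sd=0.0, seed=0)
    assert truth["expected_fold"] == 1.0
    qpcr2, truth2 = gen_qpcr(4, effect_log2=1.0, noise_sd=0.0, seed=0)
    assert truth2["expected_fold"] == 2.0
    with pytest.raises(ValueError):
        gen_qpcr(2, noise_sd=-0.1)
    with pytest.raises(ValueError):
        gen_qpcr(2, replicates=1)


def test_tag_counts_reject_bad_inputs():
    with pytest.raises(ValueError):
        gen_tag_counts(10, depth=0)
    with pytest.raises(ValueError):
        gen_tag_counts(10, planted=[(0, 9, "sexual", 2.0)])
    with pytest.raises(ValueError):
        gen_tag_counts(10, planted=[(0, 1, "sexual", -2.0)])
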