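"""Folding DP correctness: enumeration oracle, model invariants, backends."""

import functools
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirseed import folding as F


def enumerate_structures(seq):
    """All nested pair sets with canonical pairs and hairpin loops >= 3.

    Independent of the DP: plain recursive enumeration over intervals.
    """
    codes = F.encode(seq)
    n = len(seq)

    @functools.lru_cache(maxsize=None)
    def gen(i, j):
        if i >= j:
            return [()]
        res = list(gen(i + 1, j))
        for k in range(i + 4, j + 1):
            if F.PAIR_MATRIX[codes[i], codes[k]] >= 0:
                for left in gen(i + 1, k - 1):
                    for right in gen(k + 1, j):
                        res.append(((i, k),) + left + right)
        return res

    return gen(0, n - 1)


def brute_force_mfe(seq):
    """Minimum of structure_energy over every enumerable structure."""
    best = 0.0
    for pairs in enumerate_structures(seq):
        try:
            e = F.structure_energy(seq, pairs)
        except ValueError:
            continue
        if e < best:
            best = e
    return best


def test_stack_table_is_symmetric():
    """E(p1, p2) must equal E(rev p2, rev p1): a helix read 5'->3' on either
    strand has one energy."""
    for a in range(6):
        for b in range(6):
            ra, rb = F._REV_PT[b], F._REV_PT[a]
            assert F.STACK[a, b] == F.STACK[ra, rb]


def test_unpairable_sequence_is_unstructured():
    r = F.fold_mfe_builtin("A" * 20)
    assert r.dot_bracket == "." * 20 and r.delta_g == 0.0


def test_short_sequence_reported_unstructured():
    r = F.fold_mfe_builtin("GGGCCCC")
    assert r.delta_g == 0.0 and set(r.dot_bracket) == {"."}


def test_simple_stem_loop():
    r = F.fold_mfe_builtin("GGGGAAAACCCC")
    assert r.dot_bracket == "((((....))))"
    assert r.delta_g == brute_force_mfe("GGGGAAAACCCC")


def test_invalid_symbols_rejected():
    with pytest.raises(ValueError):
        F.fold_mfe_builtin("ACGTACGTACGT")  # DNA must be normalized first


def test_dp_matches_enumeration_on_random_sequences():
    rng = random.Random(2024)
    for _ in range(120):
        n = rng.randint(8, 26)
        seq = "".join(rng.choice("ACGU") for _ in range(n))
        r = F.fold_mfe_builtin(seq)
        assert r.delta_g == pytest.approx(brute_force_mfe(seq), abs=0)
        if r.pairs:
            assert F.structure_energy(seq, r.pairs) == pytest.approx(r.delta_g)


def test_reported_structure_is_valid_and_consistent(rng):
    for _ in range(40):
        n = int(rng.integers(10, 120))
        seq = "".join(rng.choice(list("ACGU"), n))
        r = F.fold_mfe_builtin(seq)
        assert len(r.dot_bracket) == n
        pairs = r.pairs  # raises on unbalanced brackets
        for i, j in pairs:
            assert F.PAIR_MATRIX[F._CODE[seq[i]], F._CODE[seq[j]]] >= 0
            assert j - i - 1 >= F.MIN_HAIRPIN
        if pairs:
            assert F.structure_energy(seq, pairs) == pytest.approx(r.delta_g)
        assert r.delta_g <= 0.0


def test_appending_unpairable_flanks_preserves_mfe():
    """Exterior unpaired bases are free, so N flanks change nothing."""
    seq = "GGGAGGGGAAAACCCCAAGCCC"
    base = F.fold_mfe_builtin(seq).delta_g
    flanked = F.fold_mfe_builtin("N" * 10 + seq + "N" * 10).delta_g
    assert flanked == base


@given(st.text(alphabet="ACGU", min_size=8, max_size=22))
def test_delta_g_never_positive_and_deterministic(seq):
    a = F.fold_mfe_builtin(seq)
    b = F.fold_mfe_builtin(seq)
    assert a == b
    assert a.delta_g <= 0.0


def test_vienna_backend_agrees_in_rank(rng):
    """Cross-backend check: energies come from different parameter tables,
    so agreement is ordinal (Spearman), not numeric."""
    from scipy import stats

    seqs = []
    for _ in range(25):
        n = int(rng.integers(40, 90))
        seqs.append("".join(rng.choice(list("ACGU"), n)))
    mine = [F.fold_mfe(s, backend="builtin").delta_g for s in seqs]
    vienna = [F.fold_mfe(s, backend="vienna").delta_g for s in seqs]
    rho = stats.spearmanr(mine, vienna).statistic
    assert rho > 0.8


def test_structure_energy_rejects_invalid_structures():
    seq = "GGGGAAAACCCCAAAA"
    with pytest.raises(ValueError):
        F.structure_energy(seq, [(0, 3)])  # hairpin loop < 3
    with pytest.raises(ValueError):
        F.structure_energy(seq, [(0, 15)])  # G-A is not a pair
    with pytest.raises(ValueError):
        F.structure_energy(seq, [(0, 11), (1, 13)])  # crossing
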