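"""Minimum-free-energy RNA secondary structure prediction.

The built-in backend is an exact Zuker-style dynamic program over a
versioned nearest-neighbor parameter table (``mirseed-1``): stacking free
energies for the six canonical pairs (AU, UA, CG, GC, GU, UG), tabulated
hairpin/bulge/internal-loop initiation penalties with Jacobson–Stockmayer
log extrapolation, a Ninio-style internal-loop asymmetry term, and an
affine multiloop model.  Interior loops are limited to 30 unpaired bases
(the standard practical cap); hairpin loops must contain at least three
unpaired bases; N never pairs.  There are no dangling-end or coaxial
stacking terms, so unpaired bases in exterior loops and multiloops are
energetically free — appending bases that cannot pair leaves the MFE
unchanged.

All energies are handled as integers in units of 0.01 kcal/mol; energy
ties are broken toward structures with fewer base pairs by minimizing the
lexicographic tuple ``(energy, n_pairs)`` (packed into one integer score),
and remaining ties by a fixed traceback order.  ``structure_energy``
evaluates the same model on an explicit structure, which is what the
exhaustive-enumeration oracle in the test-suite minimizes over.

An external backend ("vienna", RNAfold via subprocess) is pluggable for
cross-checks; agreement across backends is a ranking property, not an
energy identity, because the parameter tables differ.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .sequence_io import RNA_ALPHABET

PARAMETER_VERSION = "mirseed-1"

MIN_HAIRPIN = 3  # unpaired bases in a hairpin loop
MAX_INTERIOR = 30  # total unpaired bases in a bulge/internal loop
MIN_FOLD_LEN = 8  # shorter sequences are reported unstructured
_MAXLEN = 1024  # longest sequence the loop tables cover

# ---------------------------------------------------------------------------
# Parameter table (units: 0.01 kcal/mol)
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_BASES = "ACGUN"

# pair-type order: 0 CG, 1 GC, 2 GU, 3 UG, 4 AU, 5 UA
_PT = {(1, 2): 0, (2, 1): 1, (2, 3): 2, (3, 2): 3, (0, 3): 4, (3, 0): 5}
_REV_PT = np.array([1, 0, 3, 2, 5, 4])  # pair type of the flipped pair

PAIR_MATRIX = np.full((5, 5), -1, dtype=np.int64)
for (a, b), t in _PT.items():
    PAIR_MATRIX[a, b] = t

# Stacking free energies for 5'ij3'/3'i'j'5' helices, indexed
# [closing pair type][inner pair type].  Only one member of each symmetry
# class (p1,p2) ~ (rev p2, rev p1) is listed; the full matrix is completed
# by that symmetry and verified by a unit test.
_STACK_UNIQUE = {
    (0, 0): -330, (0, 1): -340, (1, 0): -240,
    (0, 2): -140, (0, 3): -210, (0, 4): -210, (0, 5): -220,
    (1, 2): -250, (1, 3): -150, (1, 4): -220, (1, 5): -240,
    (2, 2): -50, (2, 3): 130, (3, 2): 30,
    (2, 4): -130, (2, 5): -140, (3, 4): -100, (3, 5): -60,
    (4, 4): -90, (4, 5): -110, (5, 4): -130,
}

STACK = np.zeros((6, 6), dtype=np.int64)
for a in range(6):
    for b in range(6):
        key = (a, b)
        alt = (int(_REV_PT[b]), int(_REV_PT[a]))
        val = _STACK_UNIQUE.get(key, _STACK_UNIQUE.get(alt))
        if val is None:
            raise AssertionError(f"stacking table incomplete for {key}")
        STACK[a, b] = val

_JS = 108  # 1.75 * RT at 37C, 0.01 kcal/mol per ln unit


def _extrapolate(table: dict[int, int], anchor: int, max_n: int) -> np.ndarray:
    arr = np.zeros(max_n + 1, dtype=np.int64)
    for n in range(1, max_n + 1):
        if n in table:
            arr[n] = table[n]
        elif n > anchor:
            arr[n] = table[anchor] + round(_JS * math.log(n / anchor))
        else:
            arr[n] = 10_000  # size below the table's domain: forbidden
    return arr


HAIRPIN = _extrapolate(
    {3: 540, 4: 560, 5: 570, 6: 540, 7: 600, 8: 550, 9: 640}, 9, _MAXLEN
)
BULGE = _extrapolate({1: 380, 2: 280, 3: 320, 4: 360, 5: 400, 6: 440}, 6, _MAXLEN)
INTERNAL = _extrapolate({2: 170, 3: 180, 4: 200, 5: 220, 6: 250}, 6, _MAXLEN)

NINIO = 50  # per unit of internal-loop asymmetry
NINIO_MAX = 300
ML_CLOSE = 340  # multiloop closing penalty
ML_BRANCH = 40  # per branch helix (the closing pair counts as one)
ML_UNPAIRED = 0

INF = np.int64(1) << 50
_PAIR_SCALE = 512  # score = energy * 512 + n_pairs; n_pairs < 512 always


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-RNA symbol {e.args[0]!r}") from None


def loop_energy(u1: int, u2: int, pt_outer: int, pt_inner: int) -> int:
    """Energy (0.01 kcal/mol) of the two-sided loop between nested pairs."""
    if u1 == 0 and u2 == 0:
        return int(STACK[pt_outer, pt_inner])
    u = u1 + u2
    if u > MAX_INTERIOR:
        raise ValueError("interior loop exceeds the 30-base cap")
    if u1 == 0 or u2 == 0:
        return int(BULGE[u])
    return int(INTERNAL[u]) + min(NINIO_MAX, NINIO * abs(u1 - u2))


# ---------------------------------------------------------------------------
# Dynamic program (numba-jitted when available)
# ---------------------------------------------------------------------------


def _fill_tables(codes, PAIR_MATRIX, STACK, HAIRPIN, BULGE, INTERNAL):
    n = codes.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            pt = PAIR_MATRIX[codes[i], codes[j]]
            if pt >= 0:
                u = j - i - 1
                best = HAIRPIN[u] * _PAIR_SCALE + 1
                # stack / bulge / internal loop closed by (i, j)
                kmax = min(i + MAX_INTERIOR + 1, j - 4)
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    lmin = max(k + 4, j - 1 - (MAX_INTERIOR - u1))
                    for l in range(lmin, j):
                        v = V[k, l]
                        if v >= INF:
                            continue
                        u2 = j - l - 1
                        if u1 == 0 and u2 == 0:
                            pt2 = PAIR_MATRIX[codes[k], codes[l]]
                            e = STACK[pt, pt2]
                        elif u1 == 0 or u2 == 0:
                            e = BULGE[u1 + u2]
                        else:
                            asym = NINIO * abs(u1 - u2)
                            if asym > NINIO_MAX:
                                asym = NINIO_MAX
                            e = INTERNAL[u1 + u2] + asym
                        cand = e * _PAIR_SCALE + v + 1
                        if cand < best:
                            best = cand
                # multiloop closed by (i, j)
                for k in range(i + 1, j - 1):
                    a = WM[i + 1, k]
                    if a >= INF:
                        continue
                    b = WM[k + 1, j - 1]
                    if b >= INF:
                        continue
                    cand = (ML_CLOSE + ML_BRANCH) * _PAIR_SCALE + a + b + 1
                    if cand < best:
                        best = cand
                V[i, j] = best
            # WM: at least one branch inside a multiloop
            wm = INF
            if V[i, j] < INF:
                wm = V[i, j] + ML_BRANCH * _PAIR_SCALE
            if WM[i + 1, j] + ML_UNPAIRED < wm:
                wm = WM[i + 1, j] + ML_UNPAIRED
            if WM[i, j - 1] + ML_UNPAIRED < wm:
                wm = WM[i, j - 1] + ML_UNPAIRED
            for k in range(i + 1, j):
                a = WM[i, k - 1]
                if a >= INF:
                    continue
                b = WM[k, j]
                if b >= INF:
                    continue
                if a + b < wm:
                    wm = a + b
            if wm < WM[i, j]:
                WM[i, j] = wm
    W = np.zeros(n, dtype=np.int64)
    for j in range(n):
        w = W[j - 1] if j > 0 else np.int64(0)
        for i in range(0, j - 3):
            v = V[i, j]
            if v >= INF:
                continue
            prev = W[i - 1] if i > 0 else np.int64(0)
            if prev + v < w:
                w = prev + v
        W[j] = w
    return V, WM, W


try:  # pragma: no cover - exercised implicitly
    import numba

    _fill_tables_jit = numba.njit(cache=True)(_fill_tables)
except Exception:  # pragma: no cover
    _fill_tables_jit = _fill_tables


def _traceback(codes, V, WM, W) -> list[tuple[int, int]]:
    """Recover one optimal structure; choices follow a fixed scan order."""
    n = codes.shape[0]
    pairs: list[tuple[int, int]] = []
    stack: list[tuple] = [("W", n - 1)]
    while stack:
        task = stack.pop()
        if task[0] == "W":
            j = task[1]
            while j >= 4:
                if W[j] == W[j - 1]:
                    j -= 1
                    continue
                found = False
                for i in range(0, j - 3):
                    v = V[i, j]
                    if v >= INF:
                        continue
                    prev = W[i - 1] if i > 0 else 0
                    if prev + v == W[j]:
                        stack.append(("V", i, j))
                        j = i - 1
                        found = True
                        break
                if not found:  # pragma: no cover
                    raise AssertionError("traceback failed at W")
        elif task[0] == "V":
            i, j = task[1], task[2]
            pairs.append((i, j))
            pt = PAIR_MATRIX[codes[i], codes[j]]
            target = V[i, j]
            u = j - i - 1
            if HAIRPIN[u] * _PAIR_SCALE + 1 == target:
                continue
            done = False
            kmax = min(i + MAX_INTERIOR + 1, j - 4)
            for k in range(i + 1, kmax + 1):
                u1 = k - i - 1
                lmin = max(k + 4, j - 1 - (MAX_INTERIOR - u1))
                for l in range(lmin, j):
                    v = V[k, l]
                    if v >= INF:
                        continue
                    u2 = j - l - 1
                    if u1 == 0 and u2 == 0:
                        e = int(STACK[pt, PAIR_MATRIX[codes[k], codes[l]]])
                    elif u1 == 0 or u2 == 0:
                        e = int(BULGE[u1 + u2])
                    else:
                        e = int(INTERNAL[u1 + u2]) + min(
                            NINIO_MAX, NINIO * abs(u1 - u2)
                        )
                    if e * _PAIR_SCALE + v + 1 == target:
                        stack.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for k in range(i + 1, j - 1):
                a, b = WM[i + 1, k], WM[k + 1, j - 1]
                if a >= INF or b >= INF:
                    continue
                if (ML_CLOSE + ML_BRANCH) * _PAIR_SCALE + a + b + 1 == target:
                    stack.append(("M", i + 1, k))
                    stack.append(("M", k + 1, j - 1))
                    done = True
                    break
            if not done:  # pragma: no cover - DP/traceback mismatch guard
                raise AssertionError("traceback failed at V")
        else:  # "M"
            i, j = task[1], task[2]
            target = WM[i, j]
            if V[i, j] < INF and V[i, j] + ML_BRANCH * _PAIR_SCALE == target:
                stack.append(("V", i, j))
                continue
            if WM[i + 1, j] + ML_UNPAIRED == target:
                stack.append(("M", i + 1, j))
                continue
            if WM[i, j - 1] + ML_UNPAIRED == target:
                stack.append(("M", i, j - 1))
                continue
            done = False
            for k in range(i + 1, j):
                a, b = WM[i, k - 1], WM[k, j]
                if a >= INF or b >= INF:
                    continue
                if a + b == target:
                    stack.append(("M", i, k - 1))
                    stack.append(("M", k, j))
                    done = True
                    break
            if not done:  # pragma: no cover
                raise AssertionError("traceback failed at WM")
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Public surface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldResult:
    """A sequence with its predicted structure and free energy."""

    seq: str
    dot_bracket: str
    delta_g: float  # kcal/mol, <= 0; 0 for unstructured

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pairs_from_dot_bracket(self.dot_bracket)

    @property
    def pair_map(self) -> dict[int, int]:
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m


def pairs_from_dot_bracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return sorted(pairs)


def dot_bracket_from_pairs(n: int, pairs) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def fold_mfe_builtin(seq: str) -> FoldResult:
    """Fold with the built-in nearest-neighbor dynamic program."""
    if not (set(seq) <= RNA_ALPHABET):
        raise ValueError("sequence must be normalized RNA over {A,C,G,U,N}")
    n = len(seq)
    if n < MIN_FOLD_LEN:
        return FoldResult(seq=seq, dot_bracket="." * n, delta_g=0.0)
    if n > _MAXLEN:
        raise ValueError(f"sequence longer than {_MAXLEN} nt")
    codes = encode(seq)
    V, WM, W = _fill_tables_jit(codes, PAIR_MATRIX, STACK, HAIRPIN, BULGE, INTERNAL)
    score = int(min(W[n - 1], 0))
    if score == 0:
        return FoldResult(seq=seq, dot_bracket="." * n, delta_g=0.0)
    pairs = _traceback(codes, V, WM, W)
    npairs = score % _PAIR_SCALE
    energy = (score - npairs) // _PAIR_SCALE
    assert npairs == len(pairs)
    return FoldResult(
        seq=seq, dot_bracket=dot_bracket_from_pairs(n, pairs), delta_g=energy / 100.0
    )


def structure_energy(seq: str, pairs) -> float:
    """Free energy (kcal/mol) of an explicit nested structure under mirseed-1.

    Raises ``ValueError`` for structures outside the model: non-canonical
    pairs, crossing pairs, hairpin loops < 3, interior loops > 30 unpaired.
    """
    codes = encode(seq)
    n = len(seq)
    plist = sorted(pairs)
    seen: set[int] = set()
    for i, j in plist:
        if not (0 <= i < j < n):
            raise ValueError("pair out of range")
        if i in seen or j in seen:
            raise ValueError("position paired twice")
        seen.update((i, j))
        if PAIR_MATRIX[codes[i], codes[j]] < 0:
            raise ValueError(f"non-canonical pair at ({i},{j})")
        if j - i - 1 < MIN_HAIRPIN:
            raise ValueError("hairpin loop shorter than 3")
    for a, b in plist:
        for c, d in plist:
            if a < c < b < d:
                raise ValueError("crossing pairs (pseudoknot)")

    partner = {}
    for i, j in plist:
        partner[i] = j
        partner[j] = i

    def children_of(i: int, j: int) -> list[tuple[int, int]]:
        """Pairs directly enclosed by (i, j), left to right."""
        kids = []
        k = i + 1
        while k < j:
            if k in partner:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return kids

    total = 0
    for i, j in plist:
        kids = children_of(i, j)
        pt = int(PAIR_MATRIX[codes[i], codes[j]])
        if not kids:
            total += int(HAIRPIN[j - i - 1])
        elif len(kids) == 1:
            (k, l) = kids[0]
            u1, u2 = k - i - 1, j - l - 1
            total += loop_energy(u1, u2, pt, int(PAIR_MATRIX[codes[k], codes[l]]))
        else:
            total += ML_CLOSE + ML_BRANCH * (1 + len(kids))
    return total / 100.0


# -- external backend -------------------------------------------------------


def fold_mfe_vienna(seq: str) -> FoldResult:
    """Fold with ViennaRNA's RNAfold command-line program."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold executable not found on PATH")
    proc = subprocess.run(
        [exe, "--noPS", "--noconv"],
        input=seq + "\n",
        capture_output=True,
        text=True,
        check=True,
    )
    lines = proc.stdout.strip().splitlines()
    struct_line = lines[-1]
    db = struct_line.split(None, 1)[0]
    energy = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return FoldResult(seq=seq, dot_bracket=db, delta_g=energy)


BACKENDS = {
    "builtin": fold_mfe_builtin,
    "vienna": fold_mfe_vienna,
}


@lru_cache(maxsize=4096)
def _fold_cached(seq: str, backend: str) -> FoldResult:
    return BACKENDS[backend](seq)


def fold_mfe(seq: str, backend: str = "builtin") -> FoldResult:
    """Fold ``seq`` and return the minimum-free-energy nested structure.

    ``backend`` selects the folding engine (``builtin`` or ``vienna``).
    Results are deterministic and memoized per (sequence, backend).
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown folding backend {backend!r}")
    return _fold_cached(seq, backend)
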