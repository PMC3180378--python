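"""Nested secondary-structure prediction by weighted base-pair maximisation.

This is a Nussinov-style dynamic program: the score (called mfe here) of
a structure is the sum of its pair weights, GC -3, AU -2, GU -1, in
declared units — deliberately *not* a nearest-neighbour thermodynamic
model, so the values are not comparable to kcal/mol from thermodynamic
folders.  The minimum hairpin loop is 3 nt and pseudoknots are excluded
by construction.  Tie-breaking is deterministic: at each subproblem the
closing pair (smallest outer index) is preferred, then the smallest
bifurcation point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: pair weights in declared (negative) units
PAIR_SCORES = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}
MIN_LOOP = 3
MIN_FOLD_LEN = 40
MAX_FOLD_LEN = 400

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_SCORE_MAT = np.zeros((4, 4))
for (a, b), s in PAIR_SCORES.items():
    _SCORE_MAT[_ENC[a], _ENC[b]] = s


def pair_score(a: str, b: str) -> float:
    """Weight of pairing bases a-b (0.0 when not pairable); T == U."""
    return _SCORE_MAT[_ENC[a], _ENC[b]] if a in _ENC and b in _ENC else 0.0


@dataclass
class FoldResult:
    sequence: str
    structure: str  # dot-bracket
    mfe: float
    pairs: list[tuple[int, int]]

    def partner(self) -> dict[int, int]:
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


def _fill_numpy(pmat: np.ndarray) -> np.ndarray:
    n = pmat.shape[0]
    E = np.zeros((n, n))
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            # bifurcation includes leaving i or j unpaired (k=i, k=j-1)
            best = float(np.min(E[i, i:j] + E[i + 1 : j + 1, j]))
            if d > MIN_LOOP and pmat[i, j] < 0:
                cand = E[i + 1, j - 1] + pmat[i, j]
                if cand < best:
                    best = cand
            E[i, j] = best
    return E


try:  # optional JIT: identical recurrence, much faster on long windows
    from numba import njit

    @njit(cache=True)
    def _fill_jit(pmat):  # pragma: no cover - numerically identical to numpy path
        n = pmat.shape[0]
        E = np.zeros((n, n))
        for d in range(1, n):
            for i in range(0, n - d):
                j = i + d
                best = 1e18
                for k in range(i, j):
                    v = (E[i, k] if k > i else 0.0) + E[k + 1, j]
                    if v < best:
                        best = v
                if d > MIN_LOOP and pmat[i, j] < 0:
                    cand = E[i + 1, j - 1] + pmat[i, j]
                    if cand < best:
                        best = cand
                E[i, j] = best
        return E

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _fill(seq: str) -> np.ndarray:
    idx = np.array([_ENC[c] for c in seq])
    pmat = _SCORE_MAT[idx[:, None], idx[None, :]]
    if _HAVE_NUMBA and len(seq) >= 60:
        return _fill_jit(pmat)
    return _fill_numpy(pmat)


def _traceback(seq: str, E: np.ndarray) -> list[tuple[int, int]]:
    n = len(seq)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    eps = 1e-9
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        e = E[i, j]
        if e == 0.0:  # empty structure is optimal here
            continue
        ps = pair_score(seq[i], seq[j])
        if j - i > MIN_LOOP and ps < 0 and abs(e - (E[i + 1, j - 1] + ps)) < eps:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            left = E[i, k] if k > i else 0.0
            if abs(e - (left + E[k + 1, j])) < eps:
                if k > i:
                    stack.append((i, k))
                stack.append((k + 1, j))
                break
    return sorted(pairs)


def fold_rna(sequence: str, *, allow_short: bool = False) -> FoldResult:
    """Optimal nested structure of an RNA/DNA sequence.

    Length must lie in [40, 400] (the excision-window range) unless
    ``allow_short`` is set, which is used by the enumeration cross-checks.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if not allow_short and not MIN_FOLD_LEN <= n <= MAX_FOLD_LEN:
        raise ValueError(f"sequence length {n} outside [{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]")
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence length {n} outside [{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]")
    if any(c not in "ACGU" for c in seq):
        raise ValueError("sequence must be ACGU/ACGT")
    if n < 2:
        return FoldResult(seq, "." * n, 0.0, [])
    E = _fill(seq)
    pairs = _traceback(seq, E)
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return FoldResult(seq, "".join(db), float(E[0, n - 1]), pairs)
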