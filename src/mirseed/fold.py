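"""RNA secondary-structure prediction for precursor evaluation.

Two engines behind one interface:

* ``builtin`` — base-pair maximization (Nussinov-style dynamic program)
  over the canonical pair set {A:U, G:C, G:U} with a minimum hairpin-loop
  length.  Deterministic, dependency-free, and exact for the "maximum
  number of pairs" objective.
* ``vienna`` — minimum-free-energy folding through the ViennaRNA bindings
  (the classical RNAfold model).  Used when thermodynamic realism matters;
  downstream logic consumes only the dot-bracket either way.

The built-in traceback is deterministic: at each subproblem it prefers
pairing the outermost bases when co-optimal, then leaving the right end
unpaired, then the leftmost co-optimal pairing partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqs import to_rna

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# A:U, G:C and the G:U wobble
_CAN_PAIR = np.zeros((5, 5), dtype=bool)
for _a, _b in [(0, 3), (1, 2), (2, 3)]:
    _CAN_PAIR[_a, _b] = _CAN_PAIR[_b, _a] = True

DEFAULT_MIN_LOOP = 3


@dataclass
class FoldResult:
    """A folded sequence: dot-bracket, pair table and engine score."""

    sequence: str
    structure: str
    pair_table: list[int] = field(repr=False)  # partner index or -1
    score: float  # base pairs (builtin) or free energy kcal/mol (vienna)
    engine: str = "builtin"

    @property
    def n_pairs(self) -> int:
        return sum(1 for p in self.pair_table if p >= 0) // 2


def encode(seq: str) -> np.ndarray:
    """RNA string -> integer codes; characters outside ACGU get code 4 (unpairable)."""
    return np.array([_CODE.get(c, 4) for c in to_rna(seq)], dtype=np.int64)


def pairs_to_dotbracket(pair_table: list[int]) -> str:
    out = ["."] * len(pair_table)
    for i, j in enumerate(pair_table):
        if j > i:
            out[i], out[j] = "(", ")"
    return "".join(out)


def dotbracket_to_pairs(structure: str) -> list[int]:
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pt


def max_pairs_matrix(codes: np.ndarray, min_loop: int = DEFAULT_MIN_LOOP) -> np.ndarray:
    """Fill the base-pair maximization DP.

    Returns D of shape (n+1, n+1) where D[i, j+1] is the maximum number of
    pairs formable on the subsequence [i, j] (so D[i, i] = 0, empty).
    """
    n = len(codes)
    D = np.zeros((n + 1, n + 1), dtype=np.int32)
    if n == 0:
        return D
    pairable = _CAN_PAIR[codes[:, None], codes[None, :]]
    idx = np.arange(n)
    for j in range(min_loop + 1, n):
        ks = np.flatnonzero(pairable[:, j][: j - min_loop])
        unpaired = D[:j, j]
        if ks.size:
            # pair (k, j): D[i, k-1..] + D[k+1, j-1] + 1, valid for i <= k
            c = D[ks + 1, j] + 1
            vals = np.where(idx[:j, None] <= ks[None, :], D[:j][:, ks] + c, -1)
            D[:j, j + 1] = np.maximum(unpaired, vals.max(axis=1))
        else:
            D[:j, j + 1] = unpaired
    return D


def _traceback(codes: np.ndarray, D: np.ndarray, min_loop: int) -> list[int]:
    n = len(codes)
    pt = [-1] * n
    pairable = _CAN_PAIR[codes[:, None], codes[None, :]]
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        val = D[i, j + 1]
        if val == 0:
            continue
        # prefer closing the outermost pair when co-optimal (zips helices)
        if pairable[i, j] and D[i + 1, j] + 1 == val:
            pt[i], pt[j] = j, i
            stack.append((i + 1, j - 1))
            continue
        if D[i, j] == val:  # j unpaired
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j - min_loop):
            if pairable[k, j] and D[i, k] + D[k + 1, j] + 1 == val:
                pt[k], pt[j] = j, k
                stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
    return pt


def fold_builtin(sequence: str, min_loop: int = DEFAULT_MIN_LOOP) -> FoldResult:
    """Maximum-base-pair structure with deterministic traceback."""
    rna = to_rna(sequence)
    codes = encode(rna)
    D = max_pairs_matrix(codes, min_loop)
    pt = _traceback(codes, D, min_loop)
    return FoldResult(
        sequence=rna,
        structure=pairs_to_dotbracket(pt),
        pair_table=pt,
        score=float(D[0, len(rna)]) if len(rna) else 0.0,
        engine="builtin",
    )


def fold_vienna(sequence: str) -> FoldResult:
    """Minimum-free-energy structure via the ViennaRNA bindings."""
    import RNA

    rna = to_rna(sequence)
    structure, mfe = RNA.fold(rna)
    return FoldResult(
        sequence=rna,
        structure=structure,
        pair_table=dotbracket_to_pairs(structure),
        score=float(mfe),
        engine="vienna",
    )


def fold(sequence: str, min_loop: int = DEFAULT_MIN_LOOP, engine: str = "builtin") -> FoldResult:
    if engine == "builtin":
        return fold_builtin(sequence, min_loop)
    if engine == "vienna":
        return fold_vienna(sequence)
    raise ValueError(f"unknown folding engine: {engine!r}")
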