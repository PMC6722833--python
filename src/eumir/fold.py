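"""Pseudo-energy RNA secondary structure by maximum-weight nested pairing.

A Nussinov-style dynamic programme replaces a full nearest-neighbour
thermodynamic model: each admissible base pair carries a fixed weight
(G:C = -3, A:U = -2, G:U = -1, pseudo-kcal/mol), pairings must be
nested (no pseudoknots) and hairpin loops hold at least ``min_loop``
unpaired bases.  The optimal total weight is reported as a pseudo-MFE;
it is never positive.  Traceback is deterministic: at equal energy a
base is paired rather than left unpaired, and the leftmost admissible
partner wins.  An external folder can be plugged in downstream via
dot-bracket input, but this DP is the tested default.
"""

from __future__ import annotations

import re

import numpy as np

DEFAULT_WEIGHTS = {"GC": -3.0, "AU": -2.0, "GU": -1.0}

_MIN_FOLD_LEN = 60
_MAX_FOLD_LEN = 300

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def _weight_matrix(weights: dict[str, float]) -> np.ndarray:
    w = np.zeros((5, 5))
    pairs = {
        ("G", "C"): weights["GC"],
        ("A", "T"): weights["AU"],
        ("G", "T"): weights["GU"],
    }
    for (a, b), val in pairs.items():
        w[_IDX[a], _IDX[b]] = val
        w[_IDX[b], _IDX[a]] = val
    return w


def max_weight_pairing(seq: str, min_loop: int = 3,
                       weights: dict[str, float] | None = None
                       ) -> tuple[str, float]:
    """Optimal nested pairing of ``seq``; returns (dot-bracket, energy).

    Core DP without length restrictions; :func:`fold_pseudo_mfe` is the
    bounds-checked public entry point for precursor-sized sequences.
    """
    weights = weights or DEFAULT_WEIGHTS
    n = len(seq)
    if n == 0:
        return "", 0.0
    code = np.array([_IDX[c] for c in seq.upper().replace("U", "T")])
    wmat = _weight_matrix(weights)
    pairw = wmat[code[:, None], code[None, :]]  # (n, n) pair weights
    gap = min_loop + 1

    # E[i, j] = best energy of subsequence [i, j] inclusive, padded so
    # that out-of-range lookups E[i, i-1] and E[j+1, j] read as 0.
    E = np.zeros((n + 1, n + 1))
    for i in range(n - gap - 1, -1, -1):
        for j in range(i + gap, n):
            ks = np.arange(i + gap, j + 1)
            vals = pairw[i, ks] + E[i + 1, ks - 1] + E[ks + 1, j]
            vals[pairw[i, ks] == 0.0] = np.inf
            E[i, j] = min(E[i + 1, j], vals.min(initial=np.inf))

    # deterministic traceback: prefer pairing, then leftmost partner
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < gap:
            continue
        paired = False
        for k in range(i + gap, j + 1):
            if pairw[i, k] == 0.0:
                continue
            if pairw[i, k] + E[i + 1, k - 1] + E[k + 1, j] == E[i, j]:
                structure[i], structure[k] = "(", ")"
                stack.append((k + 1, j))
                stack.append((i + 1, k - 1))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return "".join(structure), float(E[0, n - 1])


def fold_pseudo_mfe(seq: str, min_loop: int = 3,
                    weights: dict[str, float] | None = None
                    ) -> tuple[str, float]:
    """Fold a precursor-length sequence (60-300 nt); see module docs."""
    if not _MIN_FOLD_LEN <= len(seq) <= _MAX_FOLD_LEN:
        raise ValueError(
            f"sequence length {len(seq)} outside "
            f"[{_MIN_FOLD_LEN}, {_MAX_FOLD_LEN}]"
        )
    return max_weight_pairing(seq, min_loop=min_loop, weights=weights)


def hairpin_loops(structure: str) -> list[tuple[int, int]]:
    """0-based half-open intervals of terminal (hairpin) loop regions."""
    return [
        (m.start() + 1, m.end() - 1)
        for m in re.finditer(r"\(\.*\)", structure)
    ]


def paired_flags(structure: str) -> np.ndarray:
    return np.array([c != "." for c in structure])
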