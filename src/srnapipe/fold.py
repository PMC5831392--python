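"""Minimum-free-energy RNA secondary structure prediction.

A pseudoknot-free folding dynamic programme over the simple pair/loop
energy model of :mod:`srnapipe.thermo`.  Structures are restricted to
canonical pairs (G:C, A:U, G:U) with hairpin loops of at least
``MIN_HAIRPIN_LOOP`` unpaired bases, enforced by forbidding any pair
spanning fewer than ``MIN_HAIRPIN_LOOP + 1`` positions.

The energy of a structure is

    sum of pair energies
    + LOOP_PENALTY * (number of maximal unpaired runs enclosed by a pair)

with exterior (unenclosed) unpaired bases free.  ``fold_rna`` returns the
global minimum over all admissible structures together with one optimal
structure in dot-bracket notation.  Because the empty structure has energy
zero, the MFE is never positive.
"""

from __future__ import annotations

import math

from .thermo import LOOP_PENALTY, MIN_HAIRPIN_LOOP, pair_energy

_MIN_SPAN = MIN_HAIRPIN_LOOP + 1  # minimum j - i for a pair (i, j)
_EPS = 1e-7


def fold_rna(seq: str) -> tuple[str, float]:
    """Fold an RNA sequence to its minimum free energy structure.

    Parameters
    ----------
    seq:
        RNA sequence over the alphabet ACGU (case-insensitive).

    Returns
    -------
    (structure, mfe):
        Dot-bracket string of one optimal structure and its energy in
        kcal/mol (always <= 0).

    Raises
    ------
    ValueError
        If the sequence is empty or contains characters outside ACGU.
    """
    s = seq.upper()
    if not s:
        raise ValueError("cannot fold an empty sequence")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"invalid RNA alphabet characters: {sorted(bad)}")

    n = len(s)
    INF = math.inf
    # V[i][j]: min energy of segment i..j given that (i, j) is a pair.
    V = [[INF] * n for _ in range(n)]
    # I0/I1[i][j]: min energy of segment i..j lying inside an enclosing
    # loop; I1 means the position just left of i is already unpaired (the
    # current single-stranded run is open, so leaving i unpaired is free),
    # I0 means leaving i unpaired starts a new run (costs LOOP_PENALTY).
    I0 = [[0.0] * n for _ in range(n)]
    I1 = [[0.0] * n for _ in range(n)]

    def inner(i: int, j: int, run_open: bool) -> float:
        if i > j:
            return 0.0
        return I1[i][j] if run_open else I0[i][j]

    for i in range(n - 1, -1, -1):
        Vi = V[i]
        for j in range(i, n):
            if j - i >= _MIN_SPAN:
                e = pair_energy(s[i], s[j])
                if e is not None:
                    Vi[j] = e + inner(i + 1, j - 1, False)
            best0 = LOOP_PENALTY + inner(i + 1, j, True)
            best1 = inner(i + 1, j, True)
            for k in range(i + _MIN_SPAN, j + 1):
                vik = Vi[k]
                if vik < INF:
                    cand = vik + inner(k + 1, j, False)
                    if cand < best0:
                        best0 = cand
                    if cand < best1:
                        best1 = cand
            I0[i][j] = best0
            I1[i][j] = best1

    # Exterior: unpaired bases are free.
    W = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        best = W[i + 1]
        for k in range(i + _MIN_SPAN, n):
            if V[i][k] < INF:
                cand = V[i][k] + W[k + 1]
                if cand < best:
                    best = cand
        W[i] = best

    structure = ["."] * n

    def trace_v(i: int, j: int) -> None:
        structure[i] = "("
        structure[j] = ")"
        trace_inner(i + 1, j - 1, False)

    def trace_inner(i: int, j: int, run_open: bool) -> None:
        while i <= j:
            cur = inner(i, j, run_open)
            placed = False
            for k in range(i + _MIN_SPAN, j + 1):
                if V[i][k] < INF and abs(V[i][k] + inner(k + 1, j, False) - cur) < _EPS:
                    trace_v(i, k)
                    i = k + 1
                    run_open = False
                    placed = True
                    break
            if not placed:
                open_cost = 0.0 if run_open else LOOP_PENALTY
                assert abs(open_cost + inner(i + 1, j, True) - cur) < _EPS
                i += 1
                run_open = True

    i = 0
    while i < n:
        if abs(W[i] - W[i + 1]) < _EPS:
            i += 1
            continue
        for k in range(i + _MIN_SPAN, n):
            if V[i][k] < INF and abs(V[i][k] + W[k + 1] - W[i]) < _EPS:
                trace_v(i, k)
                i = k + 1
                break
        else:  # pragma: no cover - defensive; optimum must decompose
            raise AssertionError("traceback failed")

    return "".join(structure), W[0]


def structure_energy(seq: str, pairs: set[tuple[int, int]]) -> float:
    """Energy of an explicit structure (pairs as 0-based (i, j), i < j).

    Used as the independent scoring half of the exhaustive-enumeration
    oracle; shares only the published constants with the DP above.
    """
    s = seq.upper()
    n = len(s)
    paired = [False] * n
    energy = 0.0
    for i, j in pairs:
        e = pair_energy(s[i], s[j])
        if e is None:
            raise ValueError(f"non-canonical pair {s[i]}:{s[j]} at ({i},{j})")
        paired[i] = paired[j] = True
        energy += e
    enclosed = [False] * n
    for i, j in pairs:
        for p in range(i + 1, j):
            enclosed[p] = True
    in_run = False
    for p in range(n):
        if not paired[p] and enclosed[p]:
            if not in_run:
                energy += LOOP_PENALTY
                in_run = True
        else:
            in_run = False
    return energy
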