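"""Independent brute-force oracles used to validate the package.

These reimplement the checked quantities by enumeration or exact
rational arithmetic, sharing only the published model constants with
the package — never its algorithms.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

from srnapipe.thermo import LOOP_PENALTY, MIN_HAIRPIN_LOOP, PAIR_ENERGY

_MIN_SPAN = MIN_HAIRPIN_LOOP + 1


def enumerate_structures(seq: str) -> list[frozenset[tuple[int, int]]]:
    """All pseudoknot-free structures over canonical pairs with hairpin
    loops >= MIN_HAIRPIN_LOOP, as sets of 0-based (i, j) pairs."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[frozenset, ...]:
        if i >= j:
            return (frozenset(),)
        out = list(rec(i + 1, j))
        for k in range(i + _MIN_SPAN, j + 1):
            if (seq[i], seq[k]) in PAIR_ENERGY:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(left | right | {(i, k)})
        return tuple(out)

    return list(rec(0, n - 1))


def oracle_structure_energy(seq: str, pairs: frozenset[tuple[int, int]]) -> float:
    """Direct energy of an explicit structure: pair terms plus one loop
    penalty per maximal unpaired run enclosed by at least one pair."""
    energy = sum(PAIR_ENERGY[(seq[i], seq[j])] for i, j in pairs)
    n = len(seq)
    paired = {p for ij in pairs for p in ij}
    enclosed = [any(i < p < j for i, j in pairs) for p in range(n)]
    prev_in_run = False
    for p in range(n):
        in_run = p not in paired and enclosed[p]
        if in_run and not prev_in_run:
            energy += LOOP_PENALTY
        prev_in_run = in_run
    return energy


def oracle_mfe(seq: str) -> float:
    """Minimum energy over all enumerated structures (empty included)."""
    return min(oracle_structure_energy(seq, s) for s in enumerate_structures(seq))


def ac_pmf_exact(y: int, x: int, n1: int, n2: int) -> Fraction:
    """Exact rational Audic-Claverie conditional probability p(y|x)."""
    r = Fraction(n2, n1)
    return r**y * comb(x + y, y) / (1 + r) ** (x + y + 1)


def ac_test_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Exact rational two-sided Audic-Claverie p-value."""
    lower = sum(ac_pmf_exact(t, x, n1, n2) for t in range(0, y + 1))
    upper = 1 - lower + ac_pmf_exact(y, x, n1, n2)
    return min(Fraction(1), 2 * min(lower, upper))


def hypergeom_upper_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact rational upper-tail hypergeometric probability P(X >= k)."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return acc


_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def oracle_seed_sites(mirna: str, transcript: str) -> list[tuple[int, str]]:
    """Position-by-position complementarity check for canonical sites.

    Walks every transcript position and tests Watson-Crick pairing of
    miRNA positions 2-8 (and the position-1 A rule) base by base.
    Returns 1-based (position, site_type) tuples.
    """
    m, t = mirna.replace("T", "U"), transcript.replace("T", "U")
    sites = []
    for p in range(len(t)):
        # transcript base at p + (7 - q) pairs miRNA position q+2 (q = 0..6)
        def pairs_through(n_bases: int, start: int) -> bool:
            for q in range(n_bases):
                tp = start + (n_bases - 1 - q)
                if tp >= len(t):
                    return False
                if _COMPLEMENT.get(t[tp]) != m[q + 1]:
                    return False
            return True

        if p + 7 <= len(t) and pairs_through(7, p):
            if p + 7 < len(t) and t[p + 7] == "A":
                sites.append((p + 1, "8mer"))
            else:
                sites.append((p + 1, "7mer-m8"))
        elif (
            p + 6 < len(t)
            and pairs_through(6, p)
            and t[p + 6] == "A"
        ):
            sites.append((p + 1, "7mer-A1"))
    return sites


def oracle_coverage_match(a: str, b: str, min_cov: int, max_mismatch: int) -> bool:
    """Brute-force: does any ungapped alignment window of >= min_cov
    bases have <= max_mismatch mismatches?"""
    for offset in range(-(len(a) - 1), len(b)):
        lo, hi = max(0, -offset), min(len(a), len(b) - offset)
        for w_start in range(lo, hi - min_cov + 1):
            for w_end in range(w_start + min_cov, hi + 1):
                mm = sum(
                    a[i] != b[i + offset] for i in range(w_start, w_end)
                )
                if mm <= max_mismatch:
                    return True
    return False
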