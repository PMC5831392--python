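"""Shared nucleic-acid constants and small sequence utilities.

The energy model used throughout the package (hairpin folding and
miRNA:target duplex scoring) is deliberately simple and fully documented:
each canonical base pair contributes a fixed stabilizing energy

    G:C  -3.0 kcal/mol
    A:U  -2.0 kcal/mol
    G:U  -1.0 kcal/mol  (wobble)

and every maximal single-stranded run enclosed by at least one base pair
costs a flat entropic penalty of +0.5 kcal/mol.  Unpaired bases outside
any pair (the exterior loop) are free.  The model is coarse compared with
nearest-neighbour parameter sets, but it is exactly computable by dynamic
programming and exactly checkable by exhaustive structure enumeration,
which is what the test suite does.
"""

from __future__ import annotations

#: Stabilizing energy (kcal/mol) per canonical base pair.
PAIR_ENERGY: dict[tuple[str, str], float] = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

#: Entropic penalty (kcal/mol) per enclosed single-stranded run.
LOOP_PENALTY: float = 0.5

#: Minimum number of unpaired bases in a hairpin loop.
MIN_HAIRPIN_LOOP: int = 3

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def pair_energy(a: str, b: str) -> float | None:
    """Energy of pairing RNA bases `a` and `b`, or None if they cannot pair."""
    return PAIR_ENERGY.get((a, b))


def as_rna(seq: str) -> str:
    """Uppercase a sequence and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def as_dna(seq: str) -> str:
    """Uppercase a sequence and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return seq.upper().translate(_RNA_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_DNA_COMPLEMENT)[::-1]
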