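"""miRNA target prediction by seed matching and duplex hybridization energy.

Two independent criteria are combined by intersection, the way dual-tool
prediction pipelines take the overlap of a seed-based and an
energy-based predictor:

* seed match: the transcript carries a canonical site pairing miRNA
  positions 2-8 (7mer-m8), positions 2-7 with an A opposite position 1
  (7mer-A1), or both (8mer).  G:U wobble is not allowed in the seed.
* hybridization energy: some site has a miRNA:transcript duplex energy
  at or below the cutoff (default -20 kcal/mol) under the shared pair
  constants, with G:U wobble allowed in the duplex body.

A gene is a candidate target of a miRNA iff both criteria hold for at
least one site.  Site-type classification replaces trained context
scores, which require feature weights that cannot be reproduced here;
the seed/energy intersection is the operative filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .thermo import LOOP_PENALTY, as_rna, pair_energy, revcomp_rna


@dataclass
class TargetSite:
    """A predicted miRNA binding site on a transcript."""

    mirna_id: str
    gene_id: str
    position: int  # 1-based start of the seed-paired segment on the transcript
    site_type: str  # "8mer" | "7mer-m8" | "7mer-A1"
    duplex_energy: float | None = None


def seed_scan(
    mirna: str,
    transcript: str,
    mirna_id: str = "",
    gene_id: str = "",
    mode: str = "canonical",
) -> list[TargetSite]:
    """Scan a transcript for seed-matched sites of a miRNA.

    ``mode="canonical"`` (default) reports 8mer, 7mer-m8 and 7mer-A1
    sites; ``mode="any7"`` additionally reports any position where 7
    contiguous transcript bases are Watson-Crick complementary to 7
    contiguous miRNA bases within positions 1-8 (reported as "7mer-m8").
    All qualifying positions are reported, scanning 5'->3'.
    """
    if mode not in ("canonical", "any7"):
        raise ValueError(f"unknown seed mode {mode!r}")
    m = as_rna(mirna)
    t = as_rna(transcript)
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt for seed matching")
    seed7 = revcomp_rna(m[1:8])  # pairs miRNA positions 2-8
    seed6 = revcomp_rna(m[1:7])  # pairs miRNA positions 2-7
    sites: list[TargetSite] = []
    for p in range(len(t) - 6):
        window7 = t[p : p + 7]
        if window7 == seed7:
            next_a = p + 7 < len(t) and t[p + 7] == "A"
            site_type = "8mer" if next_a else "7mer-m8"
            sites.append(TargetSite(mirna_id, gene_id, p + 1, site_type))
        elif (
            t[p : p + 6] == seed6 and p + 6 < len(t) and t[p + 6] == "A"
        ):
            sites.append(TargetSite(mirna_id, gene_id, p + 1, "7mer-A1"))
    if mode == "any7":
        reported = {s.position for s in sites}
        for first in range(0, 2):  # 7-windows within miRNA positions 1-8
            window = revcomp_rna(m[first : first + 7])
            for p in range(len(t) - 6):
                if t[p : p + 7] == window and p + 1 not in reported:
                    sites.append(TargetSite(mirna_id, gene_id, p + 1, "7mer-m8"))
                    reported.add(p + 1)
    sites.sort(key=lambda s: s.position)
    return sites


def _ungapped_duplex_energy(m: str, rs: str) -> float:
    """Best energy over ungapped antiparallel alignments of miRNA ``m``
    against the reversed site ``rs``; interior non-paired runs cost
    LOOP_PENALTY each, pairs outside the first/last paired column do not
    exist by construction."""
    best = 0.0
    lm, ls = len(m), len(rs)
    for offset in range(-(lm - 1), ls):
        lo = max(0, -offset)
        hi = min(lm, ls - offset)
        if hi - lo <= 0:
            continue
        pair_e = [pair_energy(m[i], rs[i + offset]) for i in range(lo, hi)]
        # Trim to span between first and last pair; charge a loop penalty
        # per maximal interior run of unpaired columns.
        paired_idx = [i for i, e in enumerate(pair_e) if e is not None]
        if not paired_idx:
            continue
        energy = sum(e for e in pair_e if e is not None)
        in_run = False
        for i in range(paired_idx[0], paired_idx[-1] + 1):
            if pair_e[i] is None:
                if not in_run:
                    energy += LOOP_PENALTY
                    in_run = True
            else:
                in_run = False
        best = min(best, energy)
    return best


def duplex_energy(mirna: str, site_region: str) -> float:
    """Minimum hybridization energy of a miRNA against a target region.

    Considers all ungapped antiparallel alignments plus alignments with a
    single bulge (one contiguous deletion in the target strand, penalized
    LOOP_PENALTY).  Returns 0.0 when no complementarity exists.
    """
    m = as_rna(mirna)
    s = as_rna(site_region)
    if not m or not s:
        raise ValueError("empty sequence")
    rs = s[::-1]  # antiparallel: miRNA 5'->3' vs site 3'->5'
    best = _ungapped_duplex_energy(m, rs)
    max_bulge = max(0, len(s) - len(m))
    for bulge in range(1, max_bulge + 1):
        for cut in range(1, len(rs) - bulge):
            rs_bulged = rs[:cut] + rs[cut + bulge :]
            energy = _ungapped_duplex_energy(m, rs_bulged) + LOOP_PENALTY
            best = min(best, energy)
    return min(best, 0.0)


def _site_region(transcript: str, site: TargetSite, mirna_len: int) -> str:
    """Transcript segment expected to pair the full miRNA at a site.

    The seed pairs at the site; the miRNA 3' end pairs upstream, so the
    region extends upstream of the seed segment by the remaining miRNA
    length plus a small slack for bulges.
    """
    t = transcript
    seed_len = 8 if site.site_type == "8mer" else 7
    end = min(len(t), site.position - 1 + seed_len)
    start = max(0, end - (mirna_len + 4))
    return t[start:end]


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    energy_cutoff: float = -20.0,
    seed_mode: str = "canonical",
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Predict candidate target genes for a set of miRNAs.

    A gene is a candidate target of a miRNA iff it has at least one seed
    site and at least one site whose duplex energy is <= energy_cutoff
    (the intersection of the seed-based and energy-based predictions).

    Returns
    -------
    (target_sets, site_table):
        target_sets: miRNA id -> set of candidate gene ids;
        site_table: all seed sites with their duplex energies.
    """
    if not transcripts:
        raise ValueError("no transcripts supplied")
    target_sets: dict[str, set[str]] = {mid: set() for mid in mirnas}
    rows = []
    for mirna_id, mseq in mirnas.items():
        m = as_rna(mseq)
        for gene_id, tseq in transcripts.items():
            t = as_rna(tseq)
            sites = seed_scan(m, t, mirna_id, gene_id, mode=seed_mode)
            if not sites:
                continue
            passes = False
            for site in sites:
                region = _site_region(t, site, len(m))
                site.duplex_energy = duplex_energy(m, region)
                if site.duplex_energy <= energy_cutoff:
                    passes = True
                rows.append(
                    (
                        mirna_id,
                        gene_id,
                        site.position,
                        site.site_type,
                        site.duplex_energy,
                    )
                )
            if passes:
                target_sets[mirna_id].add(gene_id)
    site_table = pd.DataFrame(
        rows, columns=["mirna", "gene", "position", "site_type", "energy"]
    )
    return target_sets, site_table


def target_union(target_sets: Mapping[str, set[str]]) -> set[str]:
    """Non-redundant union of candidate target genes across miRNAs."""
    union: set[str] = set()
    for genes in target_sets.values():
        union |= genes
    return union


def degree_summary(target_sets: Mapping[str, set[str]]) -> tuple[pd.Series, pd.Series]:
    """Per-miRNA target counts and per-gene regulator counts."""
    per_mirna = pd.Series(
        {mid: len(genes) for mid, genes in target_sets.items()}, dtype="int64"
    ).sort_index()
    gene_counts: dict[str, int] = {}
    for genes in target_sets.values():
        for g in genes:
            gene_counts[g] = gene_counts.get(g, 0) + 1
    per_gene = pd.Series(gene_counts, dtype="int64").sort_index()
    return per_mirna, per_gene
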