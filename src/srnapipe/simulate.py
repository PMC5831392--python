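"""Synthetic small-RNA study generator with full ground truth.

Generates every input the pipeline consumes — a genome with planted
miRNA loci, per-library FASTQ reads with controlled contamination,
annotation tables, transcripts with planted target sites, and
interaction tables with planted hubs — together with a ground-truth
ledger recording exactly what was planted, so that every downstream
stage can be checked against construction.

Design points:

* Contamination categories are mutually exclusive (one defect per read)
  and every emitted read is verified against the actual QC classifier at
  generation time, so the generator's per-category ledger matches the
  filter cascade's tallies exactly by construction.
* Per-miRNA counts are Poisson (matching the conditional-Poisson test's
  sampling assumption) with an optional gamma-Poisson overdispersion
  knob that defaults off.  Differential miRNAs have their mean
  multiplied by ``de_fold`` in one designated library.
* Planted precursor loci are perfect inverted repeats (stem = the full
  mature, loop of non-pairing bases), which fold far below the -18
  kcal/mol acceptance threshold under the package energy model.
* Transcripts of designated target genes carry a planted site that is
  the full reverse complement of the miRNA (an 8mer seed site with
  strong duplex energy); accidental canonical seed sites of
  differential miRNAs in non-target transcripts are mutated away so the
  predicted target sets equal the planted ones exactly.

Everything is driven by one integer seed; fixed seed implies
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .identify import MirnaAnnotation
from .qc import CATEGORIES, classify_read
from .targets import seed_scan
from .thermo import as_dna, as_rna, revcomp_dna, revcomp_rna

#: Illumina small-RNA kit adapters.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    The defaults describe a desk-scale three-library study: contamination
    rates proportioned like a typical small-RNA accounting table, mature
    lengths peaking at 22 nt, Poisson counts with mean 200 and planted
    four-fold differential miRNAs.
    """

    seed: int = 0
    n_libraries: int = 3
    library_names: tuple[str, ...] = ("duodenum", "cecum", "colon")
    n_known_mirnas: int = 30
    n_novel_loci: int = 6
    n_genes: int = 240
    n_reads_per_library: int = 20000
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    contamination_rates: dict[str, float] = field(
        default_factory=lambda: {
            "no_3_adapter": 0.0094,
            "insert_null": 0.0007,
            "adapter5_contaminant": 0.0003,
            "short_lt18": 0.0245,
            "polyA": 0.0005,
        }
    )
    ncrna_rates: dict[str, float] = field(
        default_factory=lambda: {
            "rRNA": 0.05,
            "tRNA": 0.03,
            "snRNA": 0.01,
            "snoRNA": 0.01,
        }
    )
    de_fraction: float = 0.2
    de_fold: float = 4.0
    mean_count: float = 200.0
    overdispersion: float = 0.0
    mature_length_weights: dict[int, float] = field(
        default_factory=lambda: {20: 0.08, 21: 0.20, 22: 0.42, 23: 0.20, 24: 0.10}
    )
    chrom_lengths: tuple[int, ...] = (30000, 20000)
    targets_per_de_mirna: int = 5
    target_pool_size: int = 35
    n_terms: int = 15
    n_enriched_terms: int = 2
    conserved_novel_fraction: float = 0.34

    def validate(self) -> None:
        if self.n_libraries != len(self.library_names):
            raise ValueError("library_names must match n_libraries")
        for cat in self.contamination_rates:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown contamination category {cat!r}")
        rates = list(self.contamination_rates.values()) + list(self.ncrna_rates.values())
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if sum(self.contamination_rates.values()) >= 1:
            raise ValueError("contamination rates must sum to < 1")
        if self.de_fraction > 0 and self.de_fold < 2:
            raise ValueError("de_fold must be >= 2 when de_fraction > 0")
        if self.n_known_mirnas < 1:
            raise ValueError("need at least one known miRNA")
        if self.mean_count <= 0:
            raise ValueError("mean_count must be positive")
        if abs(sum(self.mature_length_weights.values()) - 1.0) > 1e-9:
            raise ValueError("mature_length_weights must sum to 1")


@dataclass
class NovelLocus:
    locus_id: str
    chrom: str
    strand: str
    start: int
    end: int
    precursor_seq: str  # RNA
    mature_seq: str  # RNA
    conserved: bool


@dataclass
class SimulatedGenome:
    genome: dict[str, str]
    annotations: list[MirnaAnnotation]
    novel_loci: list[NovelLocus]
    ncrna_sources: pd.DataFrame  # columns: id, class, sequence (DNA)


@dataclass
class GroundTruth:
    """What the generator planted, for cross-checks downstream."""

    per_category_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    ncrna_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    clean_read_totals: dict[str, int] = field(default_factory=dict)
    mirna_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    novel_star_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_de: list[dict] = field(default_factory=list)
    planted_novel: list[str] = field(default_factory=list)
    planted_conserved: list[str] = field(default_factory=list)
    mature_length_mode: int = 22
    #: Realized modal clean-insert length per library (small fixtures can
    #: drift from the configured distribution mode).
    clean_length_modes: dict[str, int] = field(default_factory=dict)
    planted_targets: dict[str, list[str]] = field(default_factory=dict)
    planted_enriched_terms: list[str] = field(default_factory=list)
    planted_hubs: list[str] = field(default_factory=list)
    expected_network_nodes: int = 0
    expected_interaction_edges: int = 0
    expected_regulatory_edges: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class AnnotationBundle:
    transcripts: dict[str, str]  # gene id -> DNA sequence
    annotation: pd.DataFrame  # gene, term, term_name, namespace
    fpkm: pd.DataFrame  # gene, fpkm
    ppi: pd.DataFrame  # gene_a, gene_b, combined_score


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: SimulatedGenome
    reads: dict[str, list[tuple[str, str, str]]]  # library -> (id, seq, qual)
    tables: AnnotationBundle
    truth: GroundTruth


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _seed_patterns(mature: str) -> tuple[str, str]:
    """Canonical site motifs of a mature miRNA on a target transcript:
    the 7mer seed match (positions 2-8) and the 6mer+A match."""
    m = as_rna(mature)
    return revcomp_rna(m[1:8]), revcomp_rna(m[1:7]) + "A"


def _planted_site_rna(mature: str) -> str:
    """The planted target site: full reverse complement of positions
    2..end followed by an A opposite position 1 (an 8mer site)."""
    m = as_rna(mature)
    return revcomp_rna(m[1:]) + "A"


def _random_mature(
    rng: np.random.Generator, config: SimulationConfig, existing: set[str]
) -> str:
    """Draw a mature miRNA (RNA) satisfying the generator's guarantees:

    length from the configured distribution, moderate A content (stays
    clear of the polyA filter), GC fraction >= 0.35 (foldability), at
    most 4 G/C in seed positions 2-8 (a bare seed duplex stays above the
    -20 kcal/mol target-energy cutoff), a clean QC classification of the
    corresponding adaptered read, and no cross-talk between planted
    target sites: no mature's canonical seed motif occurs inside another
    mature's planted site, so scrubbing accidental sites can never touch
    a planted one.
    """
    lengths = sorted(config.mature_length_weights)
    weights = np.array([config.mature_length_weights[l] for l in lengths])
    weights = weights / weights.sum()
    for _ in range(10000):
        n = int(rng.choice(lengths, p=weights))
        seq = as_rna(_random_dna(rng, n))
        if seq in existing:
            continue
        if seq.count("A") / n >= 0.6:
            continue
        gc = (seq.count("G") + seq.count("C")) / n
        if gc < 0.35:
            continue
        if seq[1:8].count("G") + seq[1:8].count("C") > 4:
            continue
        read = as_dna(seq) + config.adapter3
        if classify_read(read, config.adapter3, config.adapter5)[0] != "clean":
            continue
        star_read = as_dna(revcomp_rna(seq)) + config.adapter3
        if classify_read(star_read, config.adapter3, config.adapter5)[0] != "clean":
            continue
        site_new = _planted_site_rna(seq)
        s7_new, s6a_new = _seed_patterns(seq)
        clash = False
        for other in existing:
            s7, s6a = _seed_patterns(other)
            if s7 in site_new or s6a in site_new:
                clash = True
                break
            site_other = _planted_site_rna(other)
            if s7_new in site_other or s6a_new in site_other:
                clash = True
                break
        if clash:
            continue
        return seq
    raise RuntimeError("could not draw a valid mature sequence")


def _hairpin_precursor(rng: np.random.Generator, mature: str) -> str:
    """Perfect inverted repeat: mature arm + non-pairing loop + reverse
    complement arm.  The full-stem structure bounds the MFE well below
    the hairpin acceptance threshold.  The loop stays within the default
    read-cluster gap so mature- and star-arm reads cluster together."""
    loop_len = int(rng.integers(8, 11))
    loop = "".join(np.array(list("AC"))[rng.integers(0, 2, loop_len)])
    return mature + loop + revcomp_rna(mature)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build the genome with planted known precursors, novel hairpin loci
    and ncRNA source sequences; coordinates are 1-based inclusive."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    existing: set[str] = set()

    known: list[tuple[str, str, str]] = []  # id, precursor RNA, mature RNA
    for i in range(config.n_known_mirnas):
        mature = _random_mature(rng, config, existing)
        existing.add(mature)
        known.append((f"mir-{i + 1:03d}", _hairpin_precursor(rng, mature), mature))

    n_conserved = math.ceil(config.conserved_novel_fraction * config.n_novel_loci)
    novel: list[tuple[str, str, str, bool]] = []
    for i in range(config.n_novel_loci):
        mature = _random_mature(rng, config, existing)
        existing.add(mature)
        novel.append(
            (
                f"novel-locus-{i + 1:02d}",
                _hairpin_precursor(rng, mature),
                mature,
                i < n_conserved,
            )
        )

    ncrna_rows = []
    for cls in config.ncrna_rates:
        for j in range(2):
            ncrna_rows.append(
                (f"{cls}-{j + 1}", cls, _random_dna(rng, int(rng.integers(120, 181))))
            )
    ncrna_sources = pd.DataFrame(ncrna_rows, columns=["id", "class", "sequence"])

    # Lay elements into chromosomes round-robin with random spacers.
    elements: list[tuple[str, str, str]] = []  # (kind, element_id, dna on + strand)
    strands: dict[str, str] = {}
    for eid, pre, _mat in known:
        strands[eid] = "+" if rng.random() < 0.5 else "-"
        dna = as_dna(pre)
        elements.append(("known", eid, dna if strands[eid] == "+" else revcomp_dna(dna)))
    for eid, pre, _mat, _cons in novel:
        strands[eid] = "+" if rng.random() < 0.5 else "-"
        dna = as_dna(pre)
        elements.append(("novel", eid, dna if strands[eid] == "+" else revcomp_dna(dna)))
    for _, row in ncrna_sources.iterrows():
        strands[row["id"]] = "+"
        elements.append(("ncrna", row["id"], row["sequence"]))

    n_chrom = len(config.chrom_lengths)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    cursors: dict[str, int] = {c: 0 for c in chrom_names}
    positions: dict[str, tuple[str, int, int]] = {}
    for i, (_kind, eid, dna) in enumerate(elements):
        chrom = chrom_names[i % n_chrom]
        gap = int(rng.integers(80, 201))
        parts[chrom].append(_random_dna(rng, gap))
        cursors[chrom] += gap
        start = cursors[chrom] + 1
        parts[chrom].append(dna)
        cursors[chrom] += len(dna)
        positions[eid] = (chrom, start, cursors[chrom])
    genome: dict[str, str] = {}
    for chrom, target_len in zip(chrom_names, config.chrom_lengths):
        used = cursors[chrom]
        if used > target_len:
            raise ValueError(
                f"planted loci exceed configured length of {chrom} "
                f"({used} > {target_len})"
            )
        parts[chrom].append(_random_dna(rng, target_len - used))
        genome[chrom] = "".join(parts[chrom])

    annotations = []
    for eid, pre, mat in known:
        chrom, start, end = positions[eid]
        annotations.append(
            MirnaAnnotation(
                precursor_id=eid,
                precursor_seq=pre,
                matures=[(f"{eid}-5p", 1, len(mat))],
                family=f"fam-{(int(eid.split('-')[1]) - 1) % 10}",
                chrom=chrom,
                strand=strands[eid],
                start=start,
                end=end,
            )
        )
    novel_loci = []
    for eid, pre, mat, cons in novel:
        chrom, start, end = positions[eid]
        novel_loci.append(
            NovelLocus(eid, chrom, strands[eid], start, end, pre, mat, cons)
        )
    return SimulatedGenome(genome, annotations, novel_loci, ncrna_sources)


def simulate_counts(
    config: SimulationConfig,
    mirna_ids: list[str],
    rng: np.random.Generator,
    de_eligible: list[str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-miRNA per-library expression counts with planted fold changes.

    Counts are Poisson with mean ``mean_count`` (gamma-Poisson when
    ``overdispersion`` > 0); ``ceil(de_fraction * n_eligible)`` of the
    shuffled eligible ids get their mean multiplied by ``de_fold`` in one
    rotating library.
    """
    libs = list(config.library_names)
    eligible = list(mirna_ids if de_eligible is None else de_eligible)
    n_de = math.ceil(config.de_fraction * len(eligible))
    order = [str(x) for x in rng.permutation(eligible)]
    planted = []
    means = pd.DataFrame(config.mean_count, index=mirna_ids, columns=libs, dtype=float)
    for i, mid in enumerate(order[:n_de]):
        up_lib = libs[i % len(libs)]
        means.loc[mid, up_lib] *= config.de_fold
        planted.append({"mirna": mid, "up_in": up_lib, "fold": config.de_fold})
    lam = means.to_numpy()
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        lam = rng.gamma(shape, lam / shape)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=mirna_ids, columns=libs), planted


def _fragment_reads(
    rng: np.random.Generator,
    config: SimulationConfig,
    source: str,
    n: int,
    forbidden: list[str],
) -> list[str]:
    """Draw n clean-classifying adaptered fragments of a source sequence
    that do not occur in any forbidden reference (RNA space)."""
    out = []
    for _ in range(n):
        for _try in range(2000):
            length = int(rng.integers(20, 25))
            if length >= len(source):
                continue
            start = int(rng.integers(0, len(source) - length + 1))
            frag = source[start : start + length]
            frag_rna = as_rna(frag)
            if any(frag_rna in ref for ref in forbidden):
                continue
            read = frag + config.adapter3
            if classify_read(read, config.adapter3, config.adapter5)[0] != "clean":
                continue
            out.append(read)
            break
        else:
            raise RuntimeError("could not draw a valid ncRNA fragment")
    return out


def _contaminant_read(
    rng: np.random.Generator, config: SimulationConfig, category: str, matures: list[str]
) -> str:
    for _ in range(2000):
        if category == "no_3_adapter":
            read = _random_dna(rng, int(rng.integers(25, 36)))
        elif category == "insert_null":
            read = config.adapter3
        elif category == "adapter5_contaminant":
            mat = matures[int(rng.integers(0, len(matures)))]
            read = config.adapter5 + as_dna(mat) + config.adapter3
        elif category == "short_lt18":
            read = _random_dna(rng, int(rng.integers(8, 18))) + config.adapter3
        elif category == "polyA":
            read = "A" * int(rng.integers(20, 25)) + config.adapter3
        else:
            raise ValueError(f"unknown category {category!r}")
        if classify_read(read, config.adapter3, config.adapter5)[0] == category:
            return read
    raise RuntimeError(f"could not draw a {category} read")


def simulate_reads(
    config: SimulationConfig, sim_genome: SimulatedGenome
) -> tuple[dict[str, list[tuple[str, str, str]]], GroundTruth]:
    """Emit per-library reads and the exact generation ledger.

    Clean-category reads are mature (or ncRNA-fragment) sequences with
    the 3' adapter appended; each contamination category is emitted at
    ``round(rate * n_reads_per_library)`` reads per library, one defect
    per read, verified against the QC classifier.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    truth = GroundTruth()
    truth.mature_length_mode = max(
        config.mature_length_weights, key=config.mature_length_weights.get
    )

    mature_by_id: dict[str, str] = {}
    for ann in sim_genome.annotations:
        for mid, s, e in ann.matures:
            mature_by_id[mid] = ann.precursor_seq[s - 1 : e]
    for locus in sim_genome.novel_loci:
        mature_by_id[locus.locus_id] = locus.mature_seq
    mirna_ids = list(mature_by_id)

    # Fold changes are planted on known matures only; novel loci express
    # flat so novel discovery and DE recovery stay independent checks.
    known_ids = [mid for ann in sim_genome.annotations for mid, _s, _e in ann.matures]
    counts, planted = simulate_counts(config, mirna_ids, rng, de_eligible=known_ids)
    truth.planted_de = planted
    truth.planted_novel = [loc.locus_id for loc in sim_genome.novel_loci]
    truth.planted_conserved = [
        loc.locus_id for loc in sim_genome.novel_loci if loc.conserved
    ]

    forbidden_refs = [ann.precursor_seq for ann in sim_genome.annotations] + [
        loc.precursor_seq for loc in sim_genome.novel_loci
    ]
    sources_by_class: dict[str, list[str]] = {}
    for _, row in sim_genome.ncrna_sources.iterrows():
        sources_by_class.setdefault(row["class"], []).append(row["sequence"])
    class_order = [c for c in ("rRNA", "tRNA", "snRNA", "snoRNA") if c in sources_by_class]

    reads_per_lib: dict[str, list[tuple[str, str, str]]] = {}
    all_matures = list(mature_by_id.values())
    novel_ids = {loc.locus_id for loc in sim_genome.novel_loci}
    star_fraction = 0.15
    for lib in config.library_names:
        seqs: list[str] = []
        clean_total = 0
        lib_counts: dict[str, int] = {}
        star_counts: dict[str, int] = {}
        for mid in mirna_ids:
            c = int(counts.loc[mid, lib])
            lib_counts[mid] = c
            seqs.extend([as_dna(mature_by_id[mid]) + config.adapter3] * c)
            clean_total += c
            if mid in novel_ids:
                # Star-arm reads: the 3p product of the hairpin, present
                # at a minor fraction of the guide strand as in real
                # small-RNA libraries; they bridge read clusters across
                # the loop so the whole precursor is excised.
                n_star = round(star_fraction * c)
                star_counts[mid] = n_star
                star = as_dna(revcomp_rna(mature_by_id[mid])) + config.adapter3
                seqs.extend([star] * n_star)
                clean_total += n_star
        truth.mirna_counts[lib] = lib_counts
        truth.novel_star_counts[lib] = star_counts

        nc_counts: dict[str, int] = {}
        higher: list[str] = list(forbidden_refs)
        for cls in class_order:
            n_cls = round(config.ncrna_rates[cls] * config.n_reads_per_library)
            nc_counts[cls] = n_cls
            pool = sources_by_class[cls]
            for i in range(n_cls):
                src = pool[i % len(pool)]
                seqs.extend(_fragment_reads(rng, config, src, 1, higher))
            higher = higher + [as_rna(s) for s in pool]
            clean_total += n_cls
        truth.ncrna_counts[lib] = nc_counts

        cat_counts: dict[str, int] = {}
        for cat in CATEGORIES:
            n_cat = round(config.contamination_rates.get(cat, 0.0) * config.n_reads_per_library)
            cat_counts[cat] = n_cat
            for _ in range(n_cat):
                seqs.append(_contaminant_read(rng, config, cat, all_matures))
        truth.per_category_counts[lib] = cat_counts
        truth.clean_read_totals[lib] = clean_total
        insert_lengths: dict[int, int] = {}
        for s in seqs[: len(seqs) - sum(cat_counts.values())]:
            n = len(s) - len(config.adapter3)
            insert_lengths[n] = insert_lengths.get(n, 0) + 1
        truth.clean_length_modes[lib] = max(
            sorted(insert_lengths), key=lambda n: insert_lengths[n]
        )

        order = rng.permutation(len(seqs))
        reads_per_lib[lib] = [
            (f"{lib}_read_{i + 1}", seqs[j], "I" * len(seqs[j]))
            for i, j in enumerate(order)
        ]
    return reads_per_lib, truth


def simulate_annotation_tables(
    config: SimulationConfig,
    de_mirnas: Mapping[str, str],
    truth: GroundTruth | None = None,
) -> AnnotationBundle:
    """Transcripts with planted target sites, term annotation, expressed
    background and interaction tables with planted hubs.

    ``de_mirnas`` maps differential miRNA ids to mature sequences (RNA).
    Ground-truth fields (planted targets/terms/hubs and expected network
    arithmetic) are filled into ``truth`` when given.
    """
    config.validate()
    if config.n_genes < 50:
        raise ValueError("need at least 50 genes")
    rng = np.random.default_rng([config.seed, 4])
    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    transcripts = {g: _random_dna(rng, int(rng.integers(400, 601))) for g in genes}

    de_ids = list(de_mirnas)
    pool_size = min(config.target_pool_size, len(de_ids) * config.targets_per_de_mirna)
    pool = [genes[i] for i in sorted(rng.choice(len(genes), pool_size, replace=False))]
    planted_targets: dict[str, list[str]] = {}
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in genes}
    if pool:
        dealt = [str(x) for x in rng.permutation(pool)]
        cursor = 0
        for mid in de_ids:
            chosen = []
            for _ in range(config.targets_per_de_mirna):
                chosen.append(dealt[cursor % len(dealt)])
                cursor += 1
            planted_targets[mid] = sorted(set(chosen))

    for mid, mat in de_mirnas.items():
        site = as_dna(revcomp_rna(as_rna(mat)[1:]) + "A")
        for gene in planted_targets.get(mid, []):
            t = transcripts[gene]
            for _try in range(500):
                pos = int(rng.integers(30, len(t) - len(site) - 30))
                span = (pos, pos + len(site))
                if all(span[1] <= s or span[0] >= e for s, e in occupied[gene]):
                    break
            else:
                raise RuntimeError("could not place a target site")
            transcripts[gene] = t[: span[0]] + site + t[span[1] :]
            occupied[gene].append(span)

    # Remove accidental canonical seed sites of DE miRNAs from non-target
    # transcripts so predicted target sets equal the planted ones.
    for mid, mat in de_mirnas.items():
        targets = set(planted_targets.get(mid, []))
        for gene in genes:
            if gene in targets:
                continue
            for _round in range(50):
                sites = seed_scan(mat, transcripts[gene])
                if not sites:
                    break
                t = transcripts[gene]
                for site in sites:
                    # Mutate a window position outside planted spans; one
                    # always exists because no mature's seed motif occurs
                    # inside another's planted site (generation guarantee).
                    window = range(site.position - 1, min(site.position + 6, len(t)))
                    free = [
                        p
                        for p in window
                        if not any(s <= p < e for s, e in occupied[gene])
                    ]
                    if not free:
                        raise RuntimeError(
                            "accidental seed site fully inside a planted span"
                        )
                    p = free[len(free) // 2]
                    old = t[p]
                    new = "C" if old != "C" else "G"
                    t = t[:p] + new + t[p + 1 :]
                transcripts[gene] = t
            else:
                raise RuntimeError("could not scrub accidental seed sites")

    namespaces = ["biological_process", "cellular_component", "molecular_function"]
    ann_rows = []
    planted_terms = []
    for i in range(config.n_enriched_terms):
        term = f"TERM:P{i + 1:03d}"
        planted_terms.append(term)
        n_in = math.ceil(0.8 * len(pool))
        members = [pool[j] for j in sorted(rng.choice(len(pool), n_in, replace=False))]
        members += [genes[j] for j in rng.choice(len(genes), 5, replace=False)]
        for g in sorted(set(members)):
            ann_rows.append((g, term, f"planted term {i + 1}", namespaces[i % 3]))
    path_term = "PATH:P001"
    planted_terms.append(path_term)
    n_in = math.ceil(0.7 * len(pool))
    members = [pool[j] for j in sorted(rng.choice(len(pool), n_in, replace=False))]
    for g in members:
        ann_rows.append((g, path_term, "planted pathway", "pathway"))
    for i in range(config.n_terms):
        term = f"TERM:R{i + 1:03d}"
        size = int(rng.integers(10, 26))
        members = [genes[j] for j in sorted(rng.choice(len(genes), size, replace=False))]
        for g in members:
            ann_rows.append((g, term, f"random term {i + 1}", namespaces[i % 3]))
    for i in range(3):
        term = f"PATH:R{i + 1:03d}"
        size = int(rng.integers(10, 26))
        members = [genes[j] for j in sorted(rng.choice(len(genes), size, replace=False))]
        for g in members:
            ann_rows.append((g, term, f"random pathway {i + 1}", "pathway"))
    annotation = pd.DataFrame(
        ann_rows, columns=["gene", "term", "term_name", "namespace"]
    ).drop_duplicates(["gene", "term"])

    fpkm_values = rng.uniform(0.2, 50.0, len(genes))
    fpkm = pd.DataFrame({"gene": genes, "fpkm": fpkm_values})
    fpkm.loc[fpkm["gene"].isin(pool), "fpkm"] = np.maximum(
        fpkm.loc[fpkm["gene"].isin(pool), "fpkm"], 2.0
    )

    # Interaction table: hubs with dominant degree among pool genes, every
    # pool gene with at least one surviving edge, plus sub-cutoff and
    # out-of-pool noise edges that the network filter must discard.
    n_hubs = math.ceil(0.05 * len(pool)) if pool else 0
    hubs = pool[:n_hubs]
    edges: dict[tuple[str, str], float] = {}

    def add_edge(a: str, b: str, score: float) -> None:
        if a == b:
            return
        key = (min(a, b), max(a, b))
        edges[key] = max(edges.get(key, 0.0), score)

    hub_degree = min(len(pool) - 1, 25)
    for hub in hubs:
        others = [g for g in pool if g != hub]
        chosen = [others[j] for j in rng.choice(len(others), hub_degree, replace=False)]
        for g in chosen:
            add_edge(hub, g, float(rng.uniform(0.45, 0.99)))
    non_hubs = [g for g in pool if g not in hubs]
    for g in non_hubs:
        partners = [h for h in non_hubs if h != g]
        if not partners:
            continue
        for _ in range(int(rng.integers(1, 3))):
            p = partners[int(rng.integers(0, len(partners)))]
            add_edge(g, p, float(rng.uniform(0.41, 0.9)))
    for _ in range(10):  # below the score cutoff
        a, b = (pool[j] for j in rng.choice(len(pool), 2, replace=False))
        add_edge(a, b, float(rng.uniform(0.05, 0.39)))
    outside = [g for g in genes if g not in pool]
    for _ in range(10):  # touching non-candidate genes
        a = outside[int(rng.integers(0, len(outside)))]
        b = genes[int(rng.integers(0, len(genes)))]
        add_edge(a, b, float(rng.uniform(0.5, 0.95)))
    ppi = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(edges.items())],
        columns=["gene_a", "gene_b", "combined_score"],
    )

    if truth is not None:
        truth.planted_targets = {m: sorted(g) for m, g in planted_targets.items()}
        truth.planted_enriched_terms = planted_terms
        truth.planted_hubs = sorted(hubs)
        pool_set = set(pool)
        surviving = {
            (a, b)
            for (a, b), s in edges.items()
            if s >= 0.4 and a in pool_set and b in pool_set
        }
        kept_genes = {g for e in surviving for g in e}
        kept_mirnas = {
            m for m, gs in planted_targets.items() if set(gs) & kept_genes
        }
        truth.expected_network_nodes = len(kept_genes) + len(kept_mirnas)
        truth.expected_interaction_edges = len(surviving)
        truth.expected_regulatory_edges = sum(
            len(set(gs) & kept_genes) for m, gs in planted_targets.items()
        )
    return AnnotationBundle(transcripts, annotation, fpkm, ppi)


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """Run the whole generator; optionally write every input file.

    Files written under ``outdir``: genome.fasta, annotations.gff3,
    precursors.fasta, matures.fasta, xref_matures.fasta, ncrna.tsv,
    <library>.fastq, transcripts.fasta, annotation.tsv, fpkm.tsv,
    ppi.tsv, truth.json.
    """
    sim_genome = simulate_genome(config)
    reads, truth = simulate_reads(config, sim_genome)
    de_ids = [p["mirna"] for p in truth.planted_de]
    mature_by_id = {}
    for ann in sim_genome.annotations:
        for mid, s, e in ann.matures:
            mature_by_id[mid] = ann.precursor_seq[s - 1 : e]
    tables = simulate_annotation_tables(
        config, {mid: mature_by_id[mid] for mid in de_ids}, truth
    )
    dataset = SimulatedDataset(config, sim_genome, reads, tables, truth)
    if outdir is not None:
        write_dataset(dataset, Path(outdir))
    return dataset


def _write_fasta(records: Mapping[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_dataset(dataset: SimulatedDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_fasta(dataset.genome.genome, outdir / "genome.fasta")
    _write_fasta(
        {a.precursor_id: as_dna(a.precursor_seq) for a in dataset.genome.annotations},
        outdir / "precursors.fasta",
    )
    matures = {}
    for a in dataset.genome.annotations:
        for mid, s, e in a.matures:
            matures[mid] = as_dna(a.precursor_seq[s - 1 : e])
    _write_fasta(matures, outdir / "matures.fasta")
    _write_fasta(
        {
            f"xref-{loc.locus_id}": as_dna(loc.mature_seq)
            for loc in dataset.genome.novel_loci
            if loc.conserved
        },
        outdir / "xref_matures.fasta",
    )
    with open(outdir / "annotations.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for a in dataset.genome.annotations:
            fh.write(
                f"{a.chrom}\tsrnapipe\tmiRNA_primary_transcript\t{a.start}\t{a.end}\t."
                f"\t{a.strand}\t.\tID={a.precursor_id}\n"
            )
            for mid, s, e in a.matures:
                if a.strand == "+":
                    gs, ge = a.start + s - 1, a.start + e - 1
                else:
                    gs, ge = a.end - e + 1, a.end - s + 1
                fh.write(
                    f"{a.chrom}\tsrnapipe\tmiRNA\t{gs}\t{ge}\t.\t{a.strand}\t.\t"
                    f"ID={mid};Derives_from={a.precursor_id}\n"
                )
    dataset.genome.ncrna_sources.to_csv(outdir / "ncrna.tsv", sep="\t", index=False)
    for lib, reads in dataset.reads.items():
        with open(outdir / f"{lib}.fastq", "w") as fh:
            for rid, seq, qual in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    _write_fasta(dataset.tables.transcripts, outdir / "transcripts.fasta")
    dataset.tables.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    dataset.tables.fpkm.to_csv(outdir / "fpkm.tsv", sep="\t", index=False)
    dataset.tables.ppi.to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    dataset.truth.to_json(outdir / "truth.json")
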