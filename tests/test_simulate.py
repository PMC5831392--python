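"""Generator determinism, construction guarantees, planted-effect sizes."""

import numpy as np
import pytest

from conftest import small_sim_config
from srnapipe.simulate import (
    SimulationConfig,
    simulate_all,
    simulate_annotation_tables,
    simulate_counts,
    simulate_genome,
)
from srnapipe.thermo import as_rna, revcomp_dna


def test_config_validation():
    with pytest.raises(ValueError, match="sum to < 1"):
        SimulationConfig(
            contamination_rates={"no_3_adapter": 0.6, "short_lt18": 0.5}
        ).validate()
    with pytest.raises(ValueError, match="de_fold"):
        SimulationConfig(de_fraction=0.2, de_fold=1.5).validate()
    with pytest.raises(ValueError, match="unknown contamination"):
        SimulationConfig(contamination_rates={"bogus": 0.1}).validate()
    with pytest.raises(ValueError, match="exceed"):
        simulate_genome(small_sim_config(chrom_lengths=(400, 300)))


def test_genome_determinism(tmp_path):
    cfg = small_sim_config(seed=5)
    d1 = simulate_all(cfg, tmp_path / "a")
    d2 = simulate_all(small_sim_config(seed=5), tmp_path / "b")
    assert (tmp_path / "a/genome.fasta").read_bytes() == (
        tmp_path / "b/genome.fasta"
    ).read_bytes()
    for lib in cfg.library_names:
        assert (tmp_path / f"a/{lib}.fastq").read_bytes() == (
            tmp_path / f"b/{lib}.fastq"
        ).read_bytes()
    assert d1.truth.planted_de == d2.truth.planted_de


def test_different_seeds_differ():
    g1 = simulate_genome(small_sim_config(seed=1))
    g2 = simulate_genome(small_sim_config(seed=2))
    assert g1.genome["chr1"] != g2.genome["chr1"]


def test_annotated_precursors_extract_verbatim(dataset):
    genome = dataset.genome.genome
    for ann in dataset.genome.annotations:
        segment = genome[ann.chrom][ann.start - 1 : ann.end]
        if ann.strand == "-":
            segment = revcomp_dna(segment)
        assert as_rna(segment) == ann.precursor_seq
    for locus in dataset.genome.novel_loci:
        segment = genome[locus.chrom][locus.start - 1 : locus.end]
        if locus.strand == "-":
            segment = revcomp_dna(segment)
        assert as_rna(segment) == locus.precursor_seq


def test_expected_locus_count(dataset):
    cfg = dataset.config
    assert len(dataset.genome.annotations) == cfg.n_known_mirnas
    assert len(dataset.genome.novel_loci) == cfg.n_novel_loci


def test_category_ledger_counts_emitted_reads(dataset):
    """Generator ledger equals what was actually emitted per category."""
    cfg = dataset.config
    for lib, reads in dataset.reads.items():
        ledger = dataset.truth.per_category_counts[lib]
        for cat, rate in cfg.contamination_rates.items():
            assert ledger[cat] == round(rate * cfg.n_reads_per_library)
        total_clean = dataset.truth.clean_read_totals[lib]
        assert len(reads) == total_clean + sum(ledger.values())


def test_zero_contamination_passes_everything():
    from srnapipe.qc import filter_reads

    cfg = small_sim_config(
        seed=3,
        contamination_rates={c: 0.0 for c in ("no_3_adapter", "insert_null", "polyA")},
    )
    ds = simulate_all(cfg)
    for lib, reads in ds.reads.items():
        _clean, report = filter_reads(
            ((r, s) for r, s, _q in reads), cfg.adapter3, cfg.adapter5
        )
        assert report.clean_reads == report.high_quality_reads


def test_planted_fold_change_holds_in_expectation():
    """Across seeds, planted miRNAs show >= 2-fold empirical counts."""
    ok = 0
    total = 0
    for seed in range(20):
        cfg = SimulationConfig(seed=seed, de_fraction=0.1, de_fold=4.0, mean_count=200)
        rng = np.random.default_rng([seed, 2])
        ids = [f"m{i}" for i in range(30)]
        counts, planted = simulate_counts(cfg, ids, rng)
        for p in planted:
            up = p["up_in"]
            others = [c for c in counts.columns if c != up]
            for other in others:
                total += 1
                if counts.loc[p["mirna"], up] >= 2 * max(
                    1, counts.loc[p["mirna"], other]
                ):
                    ok += 1
    assert total > 0
    assert ok / total >= 0.9


def test_annotation_tables_planted_structures():
    cfg = small_sim_config(seed=21)
    ds = simulate_all(cfg)
    truth = ds.truth
    tables = ds.tables
    # planted targets exist and all pool genes expressed above background cutoff
    pool = {g for gs in truth.planted_targets.values() for g in gs}
    fpkm = tables.fpkm.set_index("gene")["fpkm"]
    assert (fpkm.loc[sorted(pool)] > 1.0).all()
    # every planted hub has dominant interaction degree among pool genes
    surviving = tables.ppi[tables.ppi["combined_score"] >= 0.4]
    degree = {}
    for _, row in surviving.iterrows():
        for g in (row["gene_a"], row["gene_b"]):
            if g in pool:
                degree[g] = degree.get(g, 0) + 1
    hub_min = min(degree[h] for h in truth.planted_hubs)
    non_hub_max = max(
        (d for g, d in degree.items() if g not in truth.planted_hubs), default=0
    )
    assert hub_min > non_hub_max


def test_all_scores_below_cutoff_kill_every_edge():
    import pandas as pd

    from srnapipe.network import build_network

    ppi = pd.DataFrame(
        {"gene_a": ["g1", "g2"], "gene_b": ["g2", "g3"], "combined_score": [0.39, 0.39]}
    )
    G = build_network({"mir": {"g1", "g2", "g3"}}, ppi)
    assert G.number_of_edges() == 0


def test_annotation_tables_require_enough_genes():
    with pytest.raises(ValueError, match="50 genes"):
        simulate_annotation_tables(small_sim_config(n_genes=10), {})
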