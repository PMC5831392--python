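"""Filter cascade, accounting arithmetic, length distribution, mapping."""

import pytest

from conftest import ADAPTER3, ADAPTER5
from srnapipe.qc import (
    AccountingReport,
    CleanReadSet,
    classify_read,
    filter_reads,
    length_distribution,
    map_reads,
    read_fastq,
)
from srnapipe.thermo import revcomp_dna

INSERT = "ACGGTTCAGCTGCAAGCTCAAG"  # 22 nt, clean


@pytest.mark.parametrize(
    "read,expected",
    [
        (INSERT + ADAPTER3, "clean"),
        ("GCTGACCTGAAGGCTCATGCACGTGGATCC", "no_3_adapter"),
        (ADAPTER3, "insert_null"),
        (ADAPTER5 + INSERT + ADAPTER3, "adapter5_contaminant"),
        ("ACGGTTCAGCT" + ADAPTER3, "short_lt18"),
        ("A" * 20 + ADAPTER3, "polyA"),
        # 70% adenine is exactly at the poly-A boundary
        ("A" * 14 + "CGCGCG" + ADAPTER3, "polyA"),
        ("A" * 13 + "CGCGCGC" + ADAPTER3, "clean"),
    ],
)
def test_classify_read_categories(read, expected):
    category, _insert = classify_read(read, ADAPTER3, ADAPTER5)
    assert category == expected


def test_adapter_found_with_one_mismatch():
    mutated = ADAPTER3[:10] + ("A" if ADAPTER3[10] != "A" else "C") + ADAPTER3[11:]
    category, insert = classify_read(INSERT + mutated, ADAPTER3, ADAPTER5)
    assert category == "clean"
    assert insert == INSERT


def test_filter_reads_accounting_partition():
    reads = [
        ("r1", INSERT + ADAPTER3),
        ("r2", ADAPTER3),
        ("r3", "A" * 20 + ADAPTER3),
        ("r4", "ACGT" + ADAPTER3),
        ("r5", INSERT + ADAPTER3),
    ]
    clean, report = filter_reads(reads, ADAPTER3, ADAPTER5)
    assert report.high_quality_reads == 5
    assert report.clean_reads == 2
    assert clean.counts == {INSERT: 2}
    assert report.high_quality_reads == report.clean_reads + sum(report.removed.values())
    # order invariance: tallies identical under permutation
    _clean2, report2 = filter_reads(reads[::-1], ADAPTER3, ADAPTER5)
    assert report2.removed == report.removed
    assert report2.clean_reads == report.clean_reads


def test_filter_tallies_match_generator_ledger(dataset):
    sim = dataset.config
    for lib, reads in dataset.reads.items():
        clean, report = filter_reads(
            ((rid, seq) for rid, seq, _q in reads), sim.adapter3, sim.adapter5
        )
        assert report.removed == dataset.truth.per_category_counts[lib]
        assert report.clean_reads == dataset.truth.clean_read_totals[lib]
        assert clean.total == dataset.truth.clean_read_totals[lib]


def test_accounting_report_percent_rounding():
    report = AccountingReport.from_tallies(
        28_493_897,
        {
            "no_3_adapter": 268_000,
            "insert_null": 19_580,
            "adapter5_contaminant": 9_650,
            "short_lt18": 697_631,
            "polyA": 145,
        },
        mapped_reads=16_733_785,
    )
    assert report.clean_reads == 27_498_891
    assert report.clean_percent == 96.51
    assert report.mapped_percent == 60.85


def test_length_distribution():
    clean = CleanReadSet({"A" * 22: 100})
    assert length_distribution(clean) == {22: (100, 100.0)}
    clean = CleanReadSet({"C" * 21: 50, "G" * 22: 50})
    dist = length_distribution(clean)
    assert dist[21] == (50, 50.0) and dist[22] == (50, 50.0)
    with pytest.raises(ValueError):
        length_distribution(CleanReadSet({}))


def test_modal_length_matches_generator_mode(dataset):
    sim = dataset.config
    for lib, reads in dataset.reads.items():
        clean, _report = filter_reads(
            ((rid, seq) for rid, seq, _q in reads), sim.adapter3, sim.adapter5
        )
        dist = length_distribution(clean)
        modal = max(dist, key=lambda length: dist[length][0])
        assert modal == dataset.truth.clean_length_modes[lib]
        assert sum(pct for _c, pct in dist.values()) == pytest.approx(100.0)


def test_map_reads_both_strands():
    genome = {"chr1": "TTTT" + INSERT + "GGGG" + revcomp_dna(INSERT) + "CCCC"}
    clean = CleanReadSet({INSERT: 3, "N" * 22: 1})
    assignments, per_chrom, mapped = map_reads(clean, genome)
    assert mapped == 3  # counted once despite two loci
    hits = assignments[assignments["seq"] == INSERT]
    assert len(hits) == 2
    plus = hits[hits["strand"] == "+"].iloc[0]
    assert (plus["start"], plus["end"]) == (5, 26)  # 1-based inclusive
    assert set(hits["strand"]) == {"+", "-"}
    assert per_chrom["chr1"] == 3


def test_map_reads_rejects_empty_genome():
    with pytest.raises(ValueError):
        map_reads(CleanReadSet({INSERT: 1}), {})


def test_collapsed_fasta_roundtrip(tmp_path):
    clean = CleanReadSet({INSERT: 5, "GGCCTTAAGGCCTTAAGGCC": 2})
    path = tmp_path / "clean.fasta"
    clean.write_fasta(path)
    assert CleanReadSet.read_fasta(path).counts == clean.counts
    text = path.read_text()
    assert text.startswith(">seq_1_x5\n")


def test_malformed_fastq_aborts_with_record_number(tmp_path):
    path = tmp_path / "bad.fastq"
    path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\nIIII\n")
    with pytest.raises(ValueError, match="record 2"):
        list(read_fastq(path))


def test_fastq_roundtrip_through_filter(tmp_path):
    reads = [("r%d" % i, INSERT + ADAPTER3) for i in range(10)]
    path = tmp_path / "reads.fastq"
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    clean, report = filter_reads(read_fastq(path), ADAPTER3, ADAPTER5)
    assert report.clean_reads == 10
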