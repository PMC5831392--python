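"""Known-miRNA assignment, classification, novel prediction, comparison."""

import numpy as np
import pandas as pd
import pytest

from oracles import oracle_coverage_match
from srnapipe.identify import (
    MirnaAnnotation,
    assign_known,
    classify_ncrna,
    compare_novel_sets,
    predict_novel,
)
from srnapipe.qc import CleanReadSet, filter_reads, map_reads
from srnapipe.thermo import as_dna, as_rna

MATURE = "ACGGUUCAGCUGCAAGCUCAAG"  # 22 nt
LOOP = "CACACACA"
PRECURSOR = MATURE + LOOP + "CUUGAGCUUGCAGCUGAACCGU"  # perfect hairpin


def make_annotation(precursor_id="mir-x") -> MirnaAnnotation:
    return MirnaAnnotation(
        precursor_id=precursor_id,
        precursor_seq=PRECURSOR,
        matures=[(f"{precursor_id}-5p", 1, len(MATURE))],
    )


def test_mature_interval_must_lie_in_precursor():
    with pytest.raises(ValueError, match="outside precursor"):
        MirnaAnnotation("mir-bad", MATURE, matures=[("m", 1, len(MATURE) + 5)])


def test_read_identical_to_mature_is_assigned():
    clean = {"lib": CleanReadSet({as_dna(MATURE): 25})}
    cm, assignments = assign_known(clean, [make_annotation()], min_reads=10)
    assert cm.counts.loc["mir-x-5p", "lib"] == 25
    assert list(assignments["mature_id"]) == ["mir-x-5p"]


def test_fifteen_base_overlap_is_rejected():
    """A read present in the precursor but overlapping the mature by only
    15 bases must not count; verified against every possible offset."""
    # read covers precursor positions 8..37 -> overlap with mature (1..22) = 15
    read = PRECURSOR[7:37]
    read_dna = as_dna(read)
    # brute-force: enumerate all occurrences and their overlaps
    overlaps = []
    for off in range(len(PRECURSOR) - len(read) + 1):
        if PRECURSOR[off : off + len(read)] == read:
            r_start, r_end = off + 1, off + len(read)
            overlaps.append(min(r_end, 22) - max(r_start, 1) + 1)
    assert overlaps and max(overlaps) == 15
    clean = {"lib": CleanReadSet({read_dna: 50})}
    cm, _a = assign_known(clean, [make_annotation()], min_reads=10)
    assert cm.counts.loc["mir-x-5p", "lib"] == 0


def test_sixteen_base_overlap_is_accepted():
    read = PRECURSOR[6:36]  # overlap 16
    clean = {"lib": CleanReadSet({as_dna(read): 50})}
    cm, _a = assign_known(clean, [make_annotation()], min_reads=10)
    assert cm.counts.loc["mir-x-5p", "lib"] == 50


def test_low_count_floor_is_per_library():
    clean = {
        "a": CleanReadSet({as_dna(MATURE): 9}),
        "b": CleanReadSet({as_dna(MATURE): 10}),
    }
    cm, _a = assign_known(clean, [make_annotation()], min_reads=10)
    assert cm.counts.loc["mir-x-5p", "a"] == 0
    assert cm.counts.loc["mir-x-5p", "b"] == 10


def test_multi_mature_read_counts_fractionally():
    ann = MirnaAnnotation(
        precursor_id="mir-two",
        precursor_seq=PRECURSOR,
        matures=[("mir-two-5p", 1, 22), ("mir-two-alt", 3, 24)],
    )
    read = PRECURSOR[2:24]  # inside both mature windows with >= 16 overlap
    clean = {"lib": CleanReadSet({as_dna(read): 40})}
    cm, _a = assign_known(clean, [ann], min_reads=10)
    assert cm.counts.loc["mir-two-5p", "lib"] == 20
    assert cm.counts.loc["mir-two-alt", "lib"] == 20
    cm_each, _a = assign_known(clean, [ann], min_reads=10, multi_mode="each")
    assert cm_each.counts.loc["mir-two-5p", "lib"] == 40


def test_assignment_is_input_order_independent():
    seqs = {as_dna(MATURE): 30, as_dna(PRECURSOR[6:36]): 12, "ACGT" * 6: 5}
    cm1, _ = assign_known({"lib": CleanReadSet(dict(seqs))}, [make_annotation()])
    cm2, _ = assign_known(
        {"lib": CleanReadSet(dict(reversed(list(seqs.items()))))}, [make_annotation()]
    )
    pd.testing.assert_frame_equal(cm1.counts, cm2.counts)


def test_classify_ncrna_priority_and_conservation():
    table = pd.DataFrame(
        {
            "id": ["r1", "t1"],
            "class": ["rRNA", "tRNA"],
            "sequence": ["GGCCAAGGTTCCAAGGTTCCAAGG", "GGCCAAGGTTCCAAGGTTCCAAGG"],
        }
    )
    clean = CleanReadSet(
        {
            "GGCCAAGGTTCCAAGGTTCC": 7,  # in both tables -> rRNA by priority
            as_dna(MATURE): 5,  # in a precursor -> miRNA
            "TTTTGGGGCCCCAAAATTTT": 3,  # nowhere -> unannotated
        }
    )
    tallies, classes = classify_ncrna(clean, table, [make_annotation()])
    assert tallies["rRNA"] == 7
    assert tallies["miRNA"] == 5
    assert tallies["unannotated"] == 3
    assert sum(tallies.values()) == clean.total
    assert classes["GGCCAAGGTTCCAAGGTTCC"] == "rRNA"


def test_classification_tallies_match_generator_ledger(dataset):
    sim = dataset.config
    for lib, reads in dataset.reads.items():
        clean, _report = filter_reads(
            ((rid, seq) for rid, seq, _q in reads), sim.adapter3, sim.adapter5
        )
        tallies, _classes = classify_ncrna(
            clean, dataset.genome.ncrna_sources, dataset.genome.annotations
        )
        for cls, expected in dataset.truth.ncrna_counts[lib].items():
            assert tallies[cls] == expected
        expected_mirna = sum(
            c
            for mid, c in dataset.truth.mirna_counts[lib].items()
            if not mid.startswith("novel")
        )
        assert tallies["miRNA"] == expected_mirna


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACGGUUCAGCUGCAAGCUCAAG", "ACGGUUCAGCUGCAAGCUCAAG", True),  # identical
        # single mismatch inside an 18-base overlap of a 24-mer
        ("ACGGUUCAGCUGCAAGCU", "GGGACGGUUCAGCAGCAAGCUCAA", True),
    ],
)
def test_compare_novel_sets_examples(a, b, expected):
    pairs = compare_novel_sets({"a": a}, {"b": b})
    assert (len(pairs) == 1) is expected


def test_compare_novel_sets_two_mismatches_everywhere_unmatched():
    a = "ACGGUUCAGCUGCAAGCUCAAG"
    b = list(a)
    b[5] = "A" if a[5] != "A" else "C"  # mismatches at positions 6 and 17
    b[16] = "A" if a[16] != "A" else "C"
    b = "".join(b)
    assert not oracle_coverage_match(a, b, 18, 1)
    assert len(compare_novel_sets({"a": a}, {"b": b})) == 0


def test_compare_novel_sets_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    bases = list("ACGU")
    for _ in range(40):
        a = "".join(rng.choice(bases, int(rng.integers(18, 25))))
        if rng.random() < 0.5:
            b = list(a)
            for _k in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, len(b)))
                b[p] = bases[int(rng.integers(0, 4))]
            b = "".join(b)
        else:
            b = "".join(rng.choice(bases, int(rng.integers(18, 25))))
        expected = oracle_coverage_match(a, b, 18, 1)
        got = len(compare_novel_sets({"a": a}, {"b": b})) == 1
        assert got == expected, (a, b)


def _novel_prediction(dataset):
    sim = dataset.config
    pooled = CleanReadSet({})
    for lib, reads in dataset.reads.items():
        clean, _ = filter_reads(
            ((rid, seq) for rid, seq, _q in reads), sim.adapter3, sim.adapter5
        )
        for seq, count in clean.counts.items():
            pooled.counts[seq] = pooled.counts.get(seq, 0) + count
    _tallies, classes = classify_ncrna(
        pooled, dataset.genome.ncrna_sources, dataset.genome.annotations
    )
    assignments, _pc, _m = map_reads(pooled, dataset.genome.genome)
    unann_seqs = {s for s, cls in classes.items() if cls == "unannotated"}
    unann = assignments[assignments["seq"].isin(unann_seqs)]
    xref = {
        loc.locus_id: loc.mature_seq
        for loc in dataset.genome.novel_loci
        if loc.conserved
    }
    return predict_novel(unann, pooled.counts, dataset.genome.genome, xref_matures=xref)


def test_predict_novel_recovers_all_planted_loci(dataset):
    candidates = _novel_prediction(dataset)
    planted_matures = {as_rna(loc.mature_seq) for loc in dataset.genome.novel_loci}
    predicted_matures = {c.mature_seq for c in candidates}
    assert predicted_matures == planted_matures  # 100% recovery, no extras
    for c in candidates:
        assert c.mfe <= -18.0
        assert c.support >= 10
    conserved = {
        as_rna(loc.mature_seq)
        for loc in dataset.genome.novel_loci
        if loc.conserved
    }
    for c in candidates:
        assert (c.label == "conserved") == (c.mature_seq in conserved)


def test_predict_novel_rejects_weak_hairpin():
    # An A/C-only region cannot pair at all: reads cluster but fold to 0
    locus = "AC" * 40
    genome = {"chr1": "A" * 30 + locus + "A" * 30}
    read = locus[10:32]
    assignments = pd.DataFrame(
        [{"seq": read, "count": 50, "chrom": "chr1", "strand": "+", "start": 41, "end": 62}]
    )
    candidates = predict_novel(assignments, {read: 50}, genome)
    assert candidates == []
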