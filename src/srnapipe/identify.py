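"""Known-miRNA assignment, small-RNA classification and novel miRNA discovery.

Known-miRNA quantification follows a coverage rule: a clean read counts
toward a mature miRNA iff the read occurs in the annotated precursor with
zero mismatches and its interval on the precursor overlaps the mature
interval by at least 16 identical bases (any offset is allowed as long as
the overlap holds).  miRNAs supported by fewer than ``min_reads`` reads
in a library are zeroed in that library as likely false positives.

Novel miRNA discovery clusters unannotated mapped reads (gap <=
``cluster_gap``), excises each cluster with flanking genomic sequence,
folds the excised region and accepts it as a hairpin candidate iff the
minimum free energy is at or below the threshold (default -18 kcal/mol)
and the most abundant supporting read (the candidate mature) sits wholly
on one hairpin arm with at least 16 of its bases inside the stem.
Candidates whose mature matches a supplied cross-species mature
reference by the same 16-base rule are labeled "conserved"; the rest are
"novel".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diffexpr import CountMatrix
from .fold import fold_rna
from .qc import CleanReadSet
from .thermo import as_rna, revcomp_dna


@dataclass
class MirnaAnnotation:
    """A miRNA precursor with one or more mature products.

    ``matures`` holds ``(mature_id, start, end)`` with 1-based inclusive
    coordinates on the precursor.  Genomic coordinates are 1-based
    inclusive on the declared strand's chromosome.
    """

    precursor_id: str
    precursor_seq: str  # RNA alphabet
    matures: list[tuple[str, int, int]]
    family: str = ""
    chrom: str = ""
    strand: str = "+"
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        self.precursor_seq = as_rna(self.precursor_seq)
        n = len(self.precursor_seq)
        for mid, s, e in self.matures:
            if not (1 <= s <= e <= n):
                raise ValueError(
                    f"mature {mid!r} interval [{s}, {e}] outside precursor "
                    f"{self.precursor_id!r} (length {n})"
                )

    def mature_seq(self, mature_id: str) -> str:
        for mid, s, e in self.matures:
            if mid == mature_id:
                return self.precursor_seq[s - 1 : e]
        raise KeyError(mature_id)


@dataclass
class HairpinCandidate:
    """A predicted miRNA precursor hairpin."""

    candidate_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive genomic
    end: int
    seq: str  # RNA, 5'->3' on the annotated strand
    structure: str
    mfe: float
    mature_start: int  # 1-based inclusive on seq
    mature_end: int
    supporting_reads: dict[str, float] = field(default_factory=dict)
    label: str = "novel"  # "novel" | "conserved"

    @property
    def mature_seq(self) -> str:
        return self.seq[self.mature_start - 1 : self.mature_end]

    @property
    def support(self) -> float:
        return sum(self.supporting_reads.values())


def _mature_hits(read_rna: str, ann: MirnaAnnotation, min_overlap: int) -> list[str]:
    """Mature ids covered >= min_overlap bases by any exact occurrence of
    the read in the precursor."""
    hits: set[str] = set()
    pre = ann.precursor_seq
    pos = pre.find(read_rna)
    while pos != -1:
        r_start, r_end = pos + 1, pos + len(read_rna)  # 1-based inclusive
        for mid, m_start, m_end in ann.matures:
            overlap = min(r_end, m_end) - max(r_start, m_start) + 1
            if overlap >= min_overlap:
                hits.add(mid)
        pos = pre.find(read_rna, pos + 1)
    return sorted(hits)


def assign_known(
    clean_sets: Mapping[str, CleanReadSet],
    annotations: Sequence[MirnaAnnotation],
    min_reads: int = 10,
    min_overlap: int = 16,
    multi_mode: str = "fractional",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Count clean reads against annotated mature miRNAs.

    Parameters
    ----------
    clean_sets:
        Mapping of library name -> collapsed clean reads.
    annotations:
        Precursor/mature annotations.
    min_reads:
        Per-library floor: mature miRNAs with a summed count below this
        in a library are zeroed in that library.
    multi_mode:
        ``"fractional"`` (default) splits a read matching k matures
        1/k to each, conserving total counts; ``"each"`` counts it fully
        to every matched mature.

    Returns the count matrix and a per-read assignment table.
    """
    if not annotations:
        raise ValueError("no annotations supplied")
    if multi_mode not in ("fractional", "each"):
        raise ValueError(f"unknown multi_mode {multi_mode!r}")
    mature_ids: list[str] = []
    for ann in annotations:
        for mid, _s, _e in ann.matures:
            mature_ids.append(mid)
    if len(set(mature_ids)) != len(mature_ids):
        raise ValueError("duplicate mature ids across annotations")

    libraries = list(clean_sets)
    counts = pd.DataFrame(0.0, index=mature_ids, columns=libraries)
    assignment_rows = []
    # Assignment depends only on the read sequence; cache across libraries.
    cache: dict[str, list[str]] = {}
    for lib, clean in clean_sets.items():
        for seq, count in clean.counts.items():
            read_rna = as_rna(seq)
            if read_rna not in cache:
                matched: list[str] = []
                for ann in annotations:
                    matched.extend(_mature_hits(read_rna, ann, min_overlap))
                cache[read_rna] = sorted(set(matched))
            matched = cache[read_rna]
            if not matched:
                continue
            weight = count / len(matched) if multi_mode == "fractional" else count
            for mid in matched:
                counts.loc[mid, lib] += weight
                assignment_rows.append((lib, seq, count, mid, weight))

    counts[counts < min_reads] = 0.0
    totals = {lib: clean_sets[lib].total for lib in libraries}
    cm = CountMatrix(counts, totals, strict_totals=multi_mode == "fractional")
    assignments = pd.DataFrame(
        assignment_rows, columns=["library", "seq", "count", "mature_id", "weight"]
    )
    return cm, assignments


#: Fixed classification priority for small-RNA annotation classes.
NCRNA_PRIORITY: tuple[str, ...] = (
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
)


def classify_ncrna(
    clean: CleanReadSet,
    ncrna_table: pd.DataFrame,
    annotations: Sequence[MirnaAnnotation] = (),
) -> tuple[dict[str, int], dict[str, str]]:
    """Classify clean reads into small-RNA annotation categories.

    Each unique read is assigned to exactly one category by fixed
    priority (miRNA > rRNA > tRNA > snRNA > snoRNA > repeat >
    unannotated); a read belongs to a class if it occurs exactly within
    any sequence of that class.  Known-miRNA membership is occurrence in
    any annotated precursor.  Tallies conserve the clean-read total.

    ``ncrna_table`` needs columns ``id``, ``class``, ``sequence``.
    """
    for col in ("id", "class", "sequence"):
        if col not in ncrna_table.columns:
            raise ValueError(f"ncRNA table missing column {col!r}")
    by_class: dict[str, list[str]] = {}
    for _, row in ncrna_table.iterrows():
        by_class.setdefault(str(row["class"]), []).append(as_rna(str(row["sequence"])))
    precursors = [ann.precursor_seq for ann in annotations]

    tallies = {cls: 0 for cls in NCRNA_PRIORITY}
    tallies["unannotated"] = 0
    read_class: dict[str, str] = {}
    for seq, count in clean.counts.items():
        read_rna = as_rna(seq)
        assigned = "unannotated"
        for cls in NCRNA_PRIORITY:
            pool = precursors if cls == "miRNA" else by_class.get(cls, [])
            if any(read_rna in ref for ref in pool):
                assigned = cls
                break
        tallies[assigned] += count
        read_class[seq] = assigned
    assert sum(tallies.values()) == clean.total
    return tallies, read_class


def _matches_by_coverage(
    a: str, b: str, min_cov: int, max_mismatch: int
) -> bool:
    """True iff some ungapped alignment of a against b contains a window
    of >= min_cov bases with <= max_mismatch mismatches."""
    la, lb = len(a), len(b)
    for offset in range(-(la - 1), lb):
        # a[i] aligns b[i + offset]
        lo = max(0, -offset)
        hi = min(la, lb - offset)
        if hi - lo < min_cov:
            continue
        mismatch = [a[i] != b[i + offset] for i in range(lo, hi)]
        window = sum(mismatch[:min_cov])
        if window <= max_mismatch:
            return True
        for i in range(min_cov, len(mismatch)):
            window += mismatch[i] - mismatch[i - min_cov]
            if window <= max_mismatch:
                return True
    return False


def compare_novel_sets(
    set_a: Mapping[str, str],
    set_b: Mapping[str, str],
    min_cov: int = 18,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Cross-study comparison of two novel mature miRNA sets.

    A pair (a, b) is reported iff some ungapped alignment of the two
    sequences covers at least ``min_cov`` bases with at most
    ``max_mismatch`` mismatches; the relation is symmetric.  Inputs map
    id -> mature sequence.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    rows = []
    for id_a, seq_a in set_a.items():
        ra = as_rna(seq_a)
        for id_b, seq_b in set_b.items():
            if _matches_by_coverage(ra, as_rna(seq_b), min_cov, max_mismatch):
                rows.append((id_a, id_b))
    return pd.DataFrame(rows, columns=["id_a", "id_b"])


def _mature_on_one_arm(structure: str, start: int, end: int, min_stem: int = 16) -> bool:
    """Arm rule: the candidate mature (1-based inclusive on the hairpin
    sequence) must contain brackets of only one orientation, with the
    span from its first to last paired base >= min_stem."""
    sub = structure[start - 1 : end]
    if "(" in sub and ")" in sub:
        return False
    paired = [i for i, c in enumerate(sub) if c in "()"]
    if not paired:
        return False
    return paired[-1] - paired[0] + 1 >= min_stem


def predict_novel(
    assignments: pd.DataFrame,
    read_counts: Mapping[str, int],
    genome: Mapping[str, str],
    mfe_threshold: float = -18.0,
    cluster_gap: int = 10,
    flank: int = 20,
    max_precursor: int = 300,
    mature_min: int = 18,
    mature_max: int = 26,
    min_overlap: int = 16,
    xref_matures: Mapping[str, str] | None = None,
) -> list[HairpinCandidate]:
    """Predict miRNA precursor hairpins from unannotated mapped reads.

    Parameters
    ----------
    assignments:
        Mapping table of unannotated reads (columns seq, chrom, strand,
        start, end; 1-based inclusive forward-strand coordinates) as
        produced by :func:`srnapipe.qc.map_reads`, restricted by the
        caller to reads not assigned to any annotation class.
    read_counts:
        Read sequence -> clean-read count.
    xref_matures:
        Optional cross-species mature reference (id -> sequence) used to
        split accepted candidates into "conserved" vs "novel".

    Clusters of reads (inter-read gap <= cluster_gap on the same
    chromosome/strand) are excised with ``flank`` nt on each side (window
    capped at ``max_precursor``), folded, and accepted iff the MFE is <=
    ``mfe_threshold`` and the most abundant read is a valid mature on one
    arm.  Supporting reads are re-counted against the accepted precursor
    with the same coverage rule as known-miRNA assignment.
    """
    candidates: list[HairpinCandidate] = []
    if assignments.empty:
        return candidates
    idx = 0
    for (chrom, strand), group in assignments.groupby(["chrom", "strand"]):
        group = group.sort_values(["start", "end"])
        clusters: list[list[pd.Series]] = []
        current: list[pd.Series] = []
        current_end = -(10**9)
        for _, row in group.iterrows():
            if current and row["start"] - current_end - 1 > cluster_gap:
                clusters.append(current)
                current = []
            current.append(row)
            current_end = max(current_end, int(row["end"]))
        if current:
            clusters.append(current)

        chrom_seq = genome[chrom].upper()
        for cluster in clusters:
            c_start = min(int(r["start"]) for r in cluster)
            c_end = max(int(r["end"]) for r in cluster)
            w_start = max(1, c_start - flank)
            w_end = min(len(chrom_seq), c_end + flank)
            if w_end - w_start + 1 > max_precursor:
                center = (c_start + c_end) // 2
                w_start = max(1, center - max_precursor // 2)
                w_end = min(len(chrom_seq), w_start + max_precursor - 1)
            window_dna = chrom_seq[w_start - 1 : w_end]
            if strand == "-":
                window_dna = revcomp_dna(window_dna)
            window_rna = as_rna(window_dna)
            structure, mfe = fold_rna(window_rna)
            if mfe > mfe_threshold:
                continue

            # Candidate mature: most abundant supporting read.
            reads = sorted(
                {str(r["seq"]) for r in cluster},
                key=lambda s: (-read_counts.get(s, 0), s),
            )
            top = reads[0]
            if not (mature_min <= len(top) <= mature_max):
                continue
            pos = window_rna.find(as_rna(top))
            if pos == -1:
                continue
            m_start, m_end = pos + 1, pos + len(top)
            if not _mature_on_one_arm(structure, m_start, m_end, min_overlap):
                continue

            mature_rna = window_rna[m_start - 1 : m_end]
            support: dict[str, float] = {}
            for seq in reads:
                read_rna = as_rna(seq)
                rpos = window_rna.find(read_rna)
                while rpos != -1:
                    overlap = min(rpos + len(seq), m_end) - max(rpos + 1, m_start) + 1
                    if overlap >= min_overlap:
                        support[seq] = float(read_counts.get(seq, 0))
                        break
                    rpos = window_rna.find(read_rna, rpos + 1)

            label = "novel"
            if xref_matures:
                for ref_seq in xref_matures.values():
                    if _matches_by_coverage(
                        mature_rna, as_rna(ref_seq), min_overlap, 0
                    ):
                        label = "conserved"
                        break
            idx += 1
            candidates.append(
                HairpinCandidate(
                    candidate_id=f"raw-{idx:03d}",
                    chrom=chrom,
                    strand=strand,
                    start=w_start,
                    end=w_end,
                    seq=window_rna,
                    structure=structure,
                    mfe=mfe,
                    mature_start=m_start,
                    mature_end=m_end,
                    supporting_reads=support,
                    label=label,
                )
            )
    # A hairpin is its own reverse complement's hairpin: the same locus
    # yields mirror candidates on both strands.  Deduplicate on the
    # candidate mature sequence, keeping the best-supported one.
    best: dict[str, HairpinCandidate] = {}
    order: list[str] = []
    for c in candidates:
        key = c.mature_seq
        if key not in best:
            best[key] = c
            order.append(key)
        elif c.support > best[key].support:
            best[key] = c
    deduped = [best[k] for k in order]
    for i, c in enumerate(deduped, start=1):
        c.candidate_id = f"candidate-{i:03d}"
    return deduped


def candidates_to_frame(candidates: Iterable[HairpinCandidate]) -> pd.DataFrame:
    rows = [
        {
            "candidate_id": c.candidate_id,
            "chrom": c.chrom,
            "strand": c.strand,
            "start": c.start,
            "end": c.end,
            "mfe": c.mfe,
            "mature_seq": c.mature_seq,
            "support": c.support,
            "label": c.label,
            "structure": c.structure,
            "seq": c.seq,
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "candidate_id",
            "chrom",
            "strand",
            "start",
            "end",
            "mfe",
            "mature_seq",
            "support",
            "label",
            "structure",
            "seq",
        ],
    )
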