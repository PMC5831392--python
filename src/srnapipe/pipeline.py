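"""End-to-end pipeline orchestration, configuration and report validation.

Stages run in a fixed order — simulate (or load inputs), read QC and
mapping, small-RNA classification, known-miRNA quantification, novel
hairpin prediction, pairwise differential expression, target
prediction, term enrichment, network construction — each consuming only
the declared outputs of earlier stages.  Every stage threshold defaults
to the analysis' standard printed value (min read length 18, low-count
floor 10, hairpin MFE -18 kcal/mol, fold change 2, corrected alpha
0.01, duplex energy -20 kcal/mol, FDR 0.1, interaction score 0.4, hub
fraction 0.05), so a default run is the full analysis on synthetic
data.  The pipeline is a pure function of (inputs, config, seed):
rerunning with the same configuration produces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import diffexpr, enrichment, identify, network, qc, simulate, targets

logger = logging.getLogger("srnapipe")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``simulate`` holds the synthetic-study parameters; its seed is tied
    to the pipeline seed.  All stage thresholds are overridable.
    """

    outdir: str = "srnapipe_out"
    seed: int = 0
    min_len: int = 18
    min_reads: int = 10
    mfe_threshold: float = -18.0
    min_fold: float = 2.0
    alpha: float = 0.01
    pseudocount: float = 0.01
    energy_cutoff: float = -20.0
    seed_mode: str = "canonical"
    fdr_cutoff: float = 0.1
    fdr_method: str = "fdr_bh"
    score_cutoff: float = 0.4
    hub_fraction: float = 0.05
    cluster_gap: int = 10
    flank: int = 20
    alternative: str = "two-sided"
    write_inputs: bool = True
    simulate: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            unknown = set(self.simulate) - {
                f.name for f in dataclasses.fields(simulate.SimulationConfig)
            }
            if unknown:
                raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
            self.simulate = simulate.SimulationConfig(**self.simulate)
        self.simulate.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        data = dataclasses.asdict(self)
        data.pop("outdir")
        payload = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: simulate.SimulatedDataset
    reports: dict[str, qc.AccountingReport]
    clean_sets: dict[str, qc.CleanReadSet]
    classification: dict[str, dict[str, int]]
    count_matrix: diffexpr.CountMatrix
    candidates: list[identify.HairpinCandidate]
    de_results: dict[str, pd.DataFrame]
    target_sets: dict[str, set[str]]
    site_table: pd.DataFrame
    enrichment_table: pd.DataFrame
    graph: Any
    summary: dict


def validate_accounting(report: qc.AccountingReport) -> dict:
    """Check the internal arithmetic of an accounting report.

    Passes iff high_quality - sum(removed) equals the stated clean-read
    count and the recomputed percentages match the stated ones to two
    decimals.  Returns per-check booleans plus a list of issues.
    """
    issues: list[str] = []
    expected_clean = report.high_quality_reads - sum(report.removed.values())
    clean_ok = expected_clean == report.clean_reads
    if not clean_ok:
        issues.append(
            f"clean reads stated {report.clean_reads} but tallies give {expected_clean}"
        )
    pct = round(100.0 * report.clean_reads / report.high_quality_reads, 2)
    pct_ok = abs(pct - report.clean_percent) < 0.005
    if not pct_ok:
        issues.append(f"clean percent stated {report.clean_percent} but is {pct}")
    mapped_ok: bool | None = None
    if report.mapped_reads is not None and report.mapped_percent is not None:
        mpct = round(100.0 * report.mapped_reads / report.clean_reads, 2)
        mapped_ok = abs(mpct - report.mapped_percent) < 0.005
        if not mapped_ok:
            issues.append(f"mapped percent stated {report.mapped_percent} but is {mpct}")
    return {
        "clean_arithmetic": clean_ok,
        "clean_percent": pct_ok,
        "mapped_percent": mapped_ok,
        "passed": clean_ok and pct_ok and mapped_ok is not False,
        "issues": issues,
    }


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorator


@_stage("simulate")
def _run_simulate(config: PipelineConfig, outdir: Path) -> simulate.SimulatedDataset:
    inputs_dir = outdir / "inputs" if config.write_inputs else None
    return simulate.simulate_all(config.simulate, inputs_dir)


@_stage("qc")
def _run_qc(config: PipelineConfig, dataset, outdir: Path):
    sim = config.simulate
    clean_sets: dict[str, qc.CleanReadSet] = {}
    reports: dict[str, qc.AccountingReport] = {}
    length_tables = {}
    for lib, reads in dataset.reads.items():
        stream = ((rid, seq) for rid, seq, _q in reads)
        clean, report = qc.filter_reads(
            stream, sim.adapter3, sim.adapter5, min_len=config.min_len
        )
        _assignments, per_chrom, mapped = qc.map_reads(clean, dataset.genome.genome)
        report = qc.AccountingReport.from_tallies(
            report.high_quality_reads,
            report.removed,
            raw_reads=report.raw_reads,
            mapped_reads=mapped,
        )
        clean_sets[lib] = clean
        reports[lib] = report
        length_tables[lib] = qc.length_distribution(clean)
        report.to_tsv(outdir / f"accounting_{lib}.tsv")
        per_chrom.rename("reads").to_frame().to_csv(
            outdir / f"chromosome_tally_{lib}.tsv", sep="\t"
        )
        clean.write_fasta(outdir / f"clean_{lib}.fasta")
    pd.DataFrame(
        [
            (lib, length, count, round(pct, 4))
            for lib, table in length_tables.items()
            for length, (count, pct) in table.items()
        ],
        columns=["library", "length", "count", "percent"],
    ).to_csv(outdir / "length_distribution.tsv", sep="\t", index=False)
    return clean_sets, reports


@_stage("identify")
def _run_identify(config: PipelineConfig, dataset, clean_sets, outdir: Path):
    annotations = dataset.genome.annotations
    cm_known, _assign = identify.assign_known(
        clean_sets, annotations, min_reads=config.min_reads
    )

    pooled = qc.CleanReadSet({})
    for clean in clean_sets.values():
        for seq, count in clean.counts.items():
            pooled.counts[seq] = pooled.counts.get(seq, 0) + count
    ncrna_table = dataset.genome.ncrna_sources
    classification = {}
    for lib, clean in clean_sets.items():
        tallies, _classes = identify.classify_ncrna(clean, ncrna_table, annotations)
        classification[lib] = tallies
    _tallies, pooled_classes = identify.classify_ncrna(pooled, ncrna_table, annotations)

    assignments, _per_chrom, _mapped = qc.map_reads(pooled, dataset.genome.genome)
    unannotated_seqs = {s for s, cls in pooled_classes.items() if cls == "unannotated"}
    unann = assignments[assignments["seq"].isin(unannotated_seqs)]
    xref = {
        f"xref-{loc.locus_id}": loc.mature_seq
        for loc in dataset.genome.novel_loci
        if loc.conserved
    }
    candidates = identify.predict_novel(
        unann,
        pooled.counts,
        dataset.genome.genome,
        mfe_threshold=config.mfe_threshold,
        cluster_gap=config.cluster_gap,
        flank=config.flank,
        xref_matures=xref or None,
    )
    identify.candidates_to_frame(candidates).to_csv(
        outdir / "hairpin_candidates.tsv", sep="\t", index=False
    )
    pd.DataFrame(classification).to_csv(outdir / "classification.tsv", sep="\t")

    if candidates:
        novel_annotations = [
            identify.MirnaAnnotation(
                precursor_id=c.candidate_id,
                precursor_seq=c.seq,
                matures=[(f"{c.candidate_id}-mature", c.mature_start, c.mature_end)],
                chrom=c.chrom,
                strand=c.strand,
                start=c.start,
                end=c.end,
            )
            for c in candidates
        ]
        cm_novel, _a = identify.assign_known(
            clean_sets, novel_annotations, min_reads=config.min_reads
        )
        counts = pd.concat([cm_known.counts, cm_novel.counts])
    else:
        counts = cm_known.counts
    cm = diffexpr.CountMatrix(counts, cm_known.library_totals)
    cm.to_tsv(outdir / "count_matrix.tsv")
    return cm, candidates, classification


@_stage("diffexp")
def _run_diffexp(config: PipelineConfig, cm, outdir: Path):
    libs = list(cm.counts.columns)
    de_results = {}
    for lib_a, lib_b in itertools.combinations(libs, 2):
        key = f"{lib_a}_vs_{lib_b}"
        result = diffexpr.call_differential(
            cm,
            (lib_a, lib_b),
            alpha=config.alpha,
            min_fold=config.min_fold,
            pseudocount=config.pseudocount,
            alternative=config.alternative,
        )
        result.to_csv(outdir / f"de_{key}.tsv", sep="\t", index=False)
        de_results[key] = result
    return de_results


@_stage("targets")
def _run_targets(config: PipelineConfig, dataset, cm, candidates, de_results, outdir: Path):
    significant = set()
    for result in de_results.values():
        significant |= set(result.loc[result["significant"], "mirna"])
    mature_by_id = {}
    for ann in dataset.genome.annotations:
        for mid, s, e in ann.matures:
            mature_by_id[mid] = ann.precursor_seq[s - 1 : e]
    for c in candidates:
        mature_by_id[f"{c.candidate_id}-mature"] = c.mature_seq
    de_mirnas = {mid: mature_by_id[mid] for mid in sorted(significant) if mid in mature_by_id}
    target_sets, site_table = targets.predict_targets(
        de_mirnas,
        dataset.tables.transcripts,
        energy_cutoff=config.energy_cutoff,
        seed_mode=config.seed_mode,
    )
    site_table.to_csv(outdir / "target_sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(m, g) for m, gs in target_sets.items() for g in sorted(gs)],
        columns=["mirna", "gene"],
    ).to_csv(outdir / "target_sets.tsv", sep="\t", index=False)
    return target_sets, site_table


@_stage("enrich")
def _run_enrich(config: PipelineConfig, dataset, target_sets, outdir: Path):
    candidates = targets.target_union(target_sets)
    fpkm = dataset.tables.fpkm
    background = set(fpkm.loc[fpkm["fpkm"] > 1.0, "gene"])
    table = enrichment.enrich(
        candidates & background,
        dataset.tables.annotation,
        background=background,
        fdr_cutoff=config.fdr_cutoff,
        method=config.fdr_method,
    )
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return table


@_stage("network")
def _run_network(config: PipelineConfig, dataset, target_sets, outdir: Path):
    G = network.build_network(
        target_sets, dataset.tables.ppi, score_cutoff=config.score_cutoff
    )
    if network.gene_nodes(G):
        hubs, hub_mirnas = network.find_hubs(G, fraction=config.hub_fraction)
    else:
        hubs, hub_mirnas = [], []
    network.export_network(G, outdir / "network")
    return G, hubs, hub_mirnas


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write per-stage reports plus a summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    dataset = _run_simulate(config, outdir)
    clean_sets, reports = _run_qc(config, dataset, outdir)
    cm, candidates, classification = _run_identify(config, dataset, clean_sets, outdir)
    de_results = _run_diffexp(config, cm, outdir)
    target_sets, site_table = _run_targets(
        config, dataset, cm, candidates, de_results, outdir
    )
    enrich_table = _run_enrich(config, dataset, target_sets, outdir)
    G, hubs, hub_mirnas = _run_network(config, dataset, target_sets, outdir)

    summary: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "parameters": {
            "min_len": config.min_len,
            "min_reads": config.min_reads,
            "mfe_threshold": config.mfe_threshold,
            "min_fold": config.min_fold,
            "alpha": config.alpha,
            "energy_cutoff": config.energy_cutoff,
            "fdr_cutoff": config.fdr_cutoff,
            "score_cutoff": config.score_cutoff,
            "hub_fraction": config.hub_fraction,
        },
        "accounting": {
            lib: {
                "raw_reads": r.raw_reads,
                "high_quality_reads": r.high_quality_reads,
                "removed": r.removed,
                "clean_reads": r.clean_reads,
                "clean_percent": r.clean_percent,
                "mapped_reads": r.mapped_reads,
                "mapped_percent": r.mapped_percent,
                "validation": validate_accounting(r),
            }
            for lib, r in reports.items()
        },
        "classification": classification,
        "novel": {
            "n_candidates": len(candidates),
            "n_conserved": sum(1 for c in candidates if c.label == "conserved"),
            "n_novel": sum(1 for c in candidates if c.label == "novel"),
        },
        "differential_expression": {
            key: diffexpr.de_partition(result) for key, result in de_results.items()
        },
        "targets": {
            "n_de_mirnas_with_targets": sum(1 for g in target_sets.values() if g),
            "n_candidate_target_genes": len(targets.target_union(target_sets)),
        },
        "enrichment": {
            "n_tested_terms": int(len(enrich_table)),
            "n_significant_terms": int(enrich_table["significant"].sum())
            if len(enrich_table)
            else 0,
        },
        "network": {
            "n_nodes": G.number_of_nodes(),
            "n_edges": G.number_of_edges(),
            "n_gene_nodes": len(network.gene_nodes(G)),
            "n_mirna_nodes": len(network.mirna_nodes(G)),
            "hub_genes": hubs,
            "hub_mirnas": hub_mirnas,
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return PipelineResult(
        config=config,
        dataset=dataset,
        reports=reports,
        clean_sets=clean_sets,
        classification=classification,
        count_matrix=cm,
        candidates=candidates,
        de_results=de_results,
        target_sets=target_sets,
        site_table=site_table,
        enrichment_table=enrich_table,
        graph=G,
        summary=summary,
    )
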