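"""End-to-end orchestration: simulate → classify → epitopes → phylo →
express → summarize, with a combined report and a machine-readable JSON
sidecar of all summary numbers.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import anatomy, classify, epitopes, expression, phylo, simulate, summary
from .formats import (SequenceRecord, write_catalogue_tsv, write_fasta,
                      write_fastq, write_gff3)

log = logging.getLogger("gliadinkit")


@dataclass
class PipelineConfig:
    seed: int
    out_dir: Path
    n_genes: int = 40
    stages: tuple = ("simulate", "classify", "epitopes", "phylo", "express", "summarize")
    n_reads: int = 20_000
    bootstrap_replicates: int = 200
    log_level: str = "INFO"
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        data["out_dir"] = Path(data["out_dir"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns (and writes) the report sidecar.

    Each stage writes its artifact under ``out_dir``; a stage failure raises
    with the stage named, keeping earlier partial outputs on disk.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    sim_cfg = simulate.SimulationConfig(
        seed=config.seed, n_genes=config.n_genes, n_reads=config.n_reads,
        **config.sim_overrides)
    state: dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "classify": _stage_classify,
        "epitopes": _stage_epitopes,
        "phylo": _stage_phylo,
        "express": _stage_express,
        "summarize": _stage_summarize,
    }
    for name in config.stages:
        if name not in stage_fns:
            raise ValueError(f"unknown stage {name!r}")
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            section = stage_fns[name](sim_cfg, config, state, out)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        log.info("stage %s: done in %.2fs", name, elapsed)
        report["stages"][name] = {"seconds": round(elapsed, 3), **section}
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise RuntimeError(f"stage {stage!r} needs the simulate stage enabled")
    return state[key]


def _stage_simulate(sim_cfg, config, state, out) -> dict:
    cohort = simulate.simulate_cohort(sim_cfg)
    state["cohort"] = cohort
    write_fasta(cohort.genes, out / "genes.fasta")
    write_fasta(cohort.parents, out / "references.fasta")
    return {
        "n_genes": len(cohort.genes),
        "true_pseudogenes": sum(1 for t in cohort.truths
                                if t.true_status == "pseudogene"),
    }


def _stage_classify(sim_cfg, config, state, out) -> dict:
    cohort = _require(state, "cohort", "classify")
    results = classify.classify_cohort(cohort.genes, cohort.parents,
                                       sim_cfg.te_library)
    state["results"] = results
    write_catalogue_tsv([r.row for r in results], out / "catalogue.tsv")
    # event table as GFF3 on (TE-excised) gene coordinates
    from .formats import FeatureInterval
    feats = []
    for r in results:
        for e in r.events:
            start = 3 * e.position if e.kind == "stop_codon" else max(e.position, 0)
            end = start + (3 if e.kind == "stop_codon" else 1)
            end = min(end, len(r.excised_gene.seq)) or 1
            start = min(start, end - 1)
            kind = "TE" if e.kind == "TE_insertion" else "CDS"
            feats.append(FeatureInterval(r.row.gene_id, start, end, "+", kind,
                                         e.kind))
    write_gff3(feats, out / "events.gff3")
    truth = {t.gene_id: t.true_status for t in cohort.truths}
    correct = sum(1 for r in results if r.row.status == truth[r.row.gene_id])
    return {"status_accuracy": correct / len(results),
            "pseudogenes_called": sum(1 for r in results
                                      if r.row.status == "pseudogene")}


def _stage_epitopes(sim_cfg, config, state, out) -> dict:
    cohort = _require(state, "cohort", "epitopes")
    proteins = []
    for parent in cohort.parents:
        prot = anatomy.translate(parent, "truncate_at_stop")
        proteins.append(prot)
    matrix, near = epitopes.epitope_profile(proteins)
    matrix.to_csv(out / "epitope_profile.tsv", sep="\t")
    return {
        "proteins_scanned": len(proteins),
        "total_exact_hits": int(matrix.drop(columns="has_cluster").to_numpy().sum()),
        "mismatch1_hits": len(near),
    }


def _stage_phylo(sim_cfg, config, state, out) -> dict:
    aln = simulate.simulate_clade_alignment(seed=sim_cfg.seed)
    tree = phylo.bootstrap_support(aln, "p_distance",
                                   config.bootstrap_replicates, seed=sim_cfg.seed)
    phylo.write_newick(tree, out / "tree.nwk")
    supports = [c.support for c in _internal(tree.root) if c.support is not None]
    return {"n_taxa": len(aln), "min_support": min(supports) if supports else None}


def _internal(node):
    for c in node.children:
        if not c.is_leaf:
            yield c
            yield from _internal(c)


def _stage_express(sim_cfg, config, state, out) -> dict:
    cohort = _require(state, "cohort", "express")
    reads = simulate.simulate_reads(cohort.genes, cohort.truths, sim_cfg)
    write_fastq(reads[:1000], out / "reads_head.fastq")  # artifact sample
    assignments = expression.assign_reads(reads, cohort.genes, seed=sim_cfg.seed)
    pseudo = {t.gene_id for t in cohort.truths if t.true_status == "pseudogene"}
    records = expression.fpkm(assignments, cohort.genes, pseudo)
    catalogue = ([r.row for r in state["results"]]
                 if "results" in state else None)
    if catalogue:
        table, summ = expression.expression_report(records, catalogue,
                                                   n_reads_total=len(reads))
        table.to_csv(out / "expression.tsv", sep="\t", index=False)
    else:
        summ = {"total_assigned_reads": assignments.n_assigned}
    return {k: v for k, v in summ.items() if v is not None}


def _stage_summarize(sim_cfg, config, state, out) -> dict:
    results = _require(state, "results", "summarize")
    rows = [r.row for r in results]
    s = summary.summarize_catalogue(rows)
    (Path(out) / "summary.txt").write_text(summary.summary_text(s) + "\n")
    return {
        "genes_per_genome": s.genes_per_genome,
        "pseudogenes_per_genome": s.pseudogenes_per_genome,
        "intact_genes": s.intact_genes,
        "total_stops": s.total_stops,
        "stops_next_to_q": s.stops_next_to_q,
        "pseudogenes_with_stop": s.pseudogenes_with_stop,
    }
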