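"""Catalogue aggregation, locus gene-density metrics, and shared-TE orthology.

Shared transposable-element insertions mark segments that predate the
separation of two homologous loci: a gene pair carrying the same element at
the same gene-relative position, or flanked by intergenic TE runs sharing
ordered labels, is called orthologous.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .formats import FeatureInterval, GeneCatalogueRow, SequenceRecord


@dataclass
class CatalogueSummary:
    genes_per_genome: dict
    pseudogenes_per_genome: dict
    pseudogene_fraction_per_genome: dict
    intact_genes: int
    total_pseudogenes: int
    total_stops: int
    stops_next_to_q: int  # strict adjacency column sum
    stops_in_polyq_region: Optional[int]  # only known from event-level data
    pseudogenes_with_stop: int


def summarize_catalogue(rows: Sequence[GeneCatalogueRow],
                        stops_in_polyq_region: Optional[int] = None) -> CatalogueSummary:
    """Aggregate a gene catalogue into the headline per-genome statistics."""
    genomes = sorted({r.genome for r in rows})
    genes = {g: sum(1 for r in rows if r.genome == g) for g in genomes}
    pseudo = {g: sum(1 for r in rows if r.genome == g and r.status == "pseudogene")
              for g in genomes}
    frac = {g: (pseudo[g] / genes[g] if genes[g] else 0.0) for g in genomes}
    return CatalogueSummary(
        genes_per_genome=genes,
        pseudogenes_per_genome=pseudo,
        pseudogene_fraction_per_genome=frac,
        intact_genes=sum(1 for r in rows if r.status == "intact"),
        total_pseudogenes=sum(pseudo.values()),
        total_stops=sum(r.n_stop for r in rows),
        stops_next_to_q=sum(r.n_stop_next_to_Q for r in rows),
        stops_in_polyq_region=stops_in_polyq_region,
        pseudogenes_with_stop=sum(
            1 for r in rows if r.status == "pseudogene" and r.n_stop >= 1),
    )


def summary_text(s: CatalogueSummary) -> str:
    lines = []
    for g in s.genes_per_genome:
        lines.append(
            f"genome {g}: {s.genes_per_genome[g]} genes, "
            f"{s.pseudogenes_per_genome[g]} pseudogenes "
            f"({100 * s.pseudogene_fraction_per_genome[g]:.0f}%)"
        )
    lines.append(f"intact genes: {s.intact_genes}")
    lines.append(f"total internal stop codons: {s.total_stops}")
    lines.append(f"stop codons next to Q (strict adjacency): {s.stops_next_to_q}")
    if s.stops_in_polyq_region is not None:
        lines.append(f"stop codons inside poly-Q regions: {s.stops_in_polyq_region}")
    lines.append(
        f"pseudogenes with >=1 stop: {s.pseudogenes_with_stop} "
        f"of {s.total_pseudogenes}"
    )
    return "\n".join(lines)


def gene_density(span_bp: int, n_genes: int) -> float:
    """Locus span per gene, in kb/gene (span / 1000 / genes)."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if span_bp <= 0:
        raise ValueError("span must be positive")
    return span_bp / 1000 / n_genes


@dataclass
class OrthologyCall:
    gene_a: str
    gene_b: str
    evidence: list  # shared TE labels with positional agreement
    confidence: str = "shared_te"

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("orthology call requires evidence")


def _genes_and_tes(features: Sequence[FeatureInterval]):
    genes = sorted((f for f in features if f.kind == "gene"), key=lambda f: f.start)
    tes = sorted((f for f in features if f.kind == "TE"), key=lambda f: f.start)
    return genes, tes


def _intragenic_tes(gene: FeatureInterval, tes: Sequence[FeatureInterval]):
    """TEs inside the gene, positioned relative to the gene start."""
    return [(t.label, t.start - gene.start) for t in tes
            if t.start >= gene.start and t.end <= gene.end]


def _flanking_labels(gene: FeatureInterval, genes, tes) -> list[str]:
    """Ordered TE labels in the intergenic regions adjacent to the gene."""
    idx = genes.index(gene)
    lo = genes[idx - 1].end if idx > 0 else 0
    hi = genes[idx + 1].start if idx + 1 < len(genes) else float("inf")
    return [t.label for t in tes
            if (lo <= t.start and t.end <= gene.start)
            or (gene.end <= t.start and t.start < hi)]


def _ordered_shared(a: list[str], b: list[str]) -> list[str]:
    """Longest common subsequence of two label lists."""
    m, n = len(a), len(b)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m):
        for j in range(n):
            dp[i + 1][j + 1] = (dp[i][j] + 1 if a[i] == b[j]
                                else max(dp[i][j + 1], dp[i + 1][j]))
    out = []
    i, j = m, n
    while i > 0 and j > 0:
        if a[i - 1] == b[j - 1] and dp[i][j] == dp[i - 1][j - 1] + 1:
            out.append(a[i - 1])
            i -= 1
            j -= 1
        elif dp[i - 1][j] >= dp[i][j - 1]:
            i -= 1
        else:
            j -= 1
    return out[::-1]


def shared_te_orthology(features_a: Sequence[FeatureInterval],
                        features_b: Sequence[FeatureInterval],
                        position_tolerance: int = 30,
                        min_shared_te: int = 2) -> list[OrthologyCall]:
    """Call orthologous gene pairs between two annotated homologous loci.

    A pair is called when (i) both genes carry a TE of the same label at the
    same gene-relative position within ``position_tolerance`` bp, or (ii)
    their flanking intergenic regions share ≥ ``min_shared_te`` TE labels in
    the same order.
    """
    genes_a, tes_a = _genes_and_tes(features_a)
    genes_b, tes_b = _genes_and_tes(features_b)
    calls = []
    for ga in genes_a:
        intra_a = _intragenic_tes(ga, tes_a)
        flank_a = _flanking_labels(ga, genes_a, tes_a)
        for gb in genes_b:
            evidence = []
            intra_b = _intragenic_tes(gb, tes_b)
            for label_a, off_a in intra_a:
                for label_b, off_b in intra_b:
                    if label_a == label_b and abs(off_a - off_b) <= position_tolerance:
                        evidence.append(f"intra-CDS {label_a} @+{off_a}")
            if not evidence:
                shared = _ordered_shared(flank_a,
                                         _flanking_labels(gb, genes_b, tes_b))
                if len(shared) >= min_shared_te:
                    evidence = [f"flanking {l}" for l in shared]
            if evidence:
                calls.append(OrthologyCall(ga.label or ga.seq_id,
                                           gb.label or gb.seq_id, evidence))
    return calls
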