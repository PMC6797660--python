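"""Locus-scale views: gene density and shared-TE orthology inference.

Shared transposable-element insertions mark genes that were already
duplicated before two homologous loci separated. The script simulates two
loci where exactly one gene pair shares an intra-CDS TE at the same
gene-relative position and shows the orthology caller recovering it, then
prints gene-density numbers for two locus spans.
"""
from gliadinkit import (SimulationConfig, gene_density, shared_te_orthology,
                        simulate_homologous_loci)

cfg = SimulationConfig(seed=31, n_genes=4)
(locus_a, feats_a), (locus_b, feats_b), (gene_a, gene_b) = \
    simulate_homologous_loci(cfg)
print(f"locus A: {len(locus_a.seq):,} bp, locus B: {len(locus_b.seq):,} bp")
print(f"designed orthologous pair: {gene_a} <-> {gene_b}")

calls = shared_te_orthology(feats_a, feats_b)
for c in calls:
    print(f"called: {c.gene_a} <-> {c.gene_b}  evidence: {c.evidence}")

# gene density: locus span per gene, in kb
genes_a = [f for f in feats_a if f.kind == "gene"]
span = genes_a[-1].end - genes_a[0].start
print(f"\nsimulated locus A density: one gene per "
      f"{gene_density(span, len(genes_a)):.1f} kb")
print(f"700 kb with 10 genes: one gene per {gene_density(700_000, 10):.0f} kb")
print(f"2.5 Mb with 24 genes: one gene per {gene_density(2_500_000, 24):.1f} kb")
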