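# Methods

## The system being modelled

α-Gliadin genes at a *Gli-2* locus are intronless CDSs encoding a signal
peptide (cleaved from the mature protein), a proline/glutamine-rich
repetitive domain that carries the celiac-disease T-cell epitopes, two
poly-glutamine tracts separated by a short unique domain, and a conserved
C-terminal domain. The poly-Q tracts are microsatellites of CAA/CAG codons.
Two consequences drive everything in this package: (i) a single C→T
transition at base 1 of CAA/CAG produces TAA/TAG, so premature stop codons
arise easily and preferentially inside or next to glutamine runs; (ii) the
tandemly duplicated copies at a locus are highly similar, so read mapping for
expression must be unusually stringent and orthology between homologous loci
is best anchored on shared transposable-element (TE) insertions rather than
on sequence similarity alone.

## Pseudogene classification

A gene is compared to a panel of intact full-ORF references:

1. **Gap events.** Runs of ≥10 N are typed `gap` (unassembled region).
2. **TE excision.** Local alignment (match +2, mismatch −3, gap open −5,
   extend −2) against a TE library; intervals with ≥0.8 identity over
   ≥100 bp are excised iteratively — removing an inner element first makes a
   nested outer element contiguous, so nests resolve in successive passes.
   Overlapping calls are merged. The excised length is the catalogue length.
3. **Reference choice.** The reference with the smallest semi-global (infix)
   edit distance to the excised gene wins, ties broken by input order. Infix
   rather than end-to-end distance matters: a terminally truncated gene would
   otherwise be pulled toward whichever reference happens to be short, since
   the missing end dominates an end-to-end distance.
4. **Event alignment.** The excised gene is aligned to the chosen reference
   with affine gaps and *free end gaps*. Penalized end gaps fragment the
   terminal overhang of a truncated gene into spurious internal indels;
   semi-global alignment keeps the shared region contiguous. ≥15 bp of
   reference unaligned at an end is a terminal deletion; each internal indel
   with length mod 3 ≠ 0 is one frameshift.
5. **Stop detection in the reference frame.** The query is projected onto
   reference coordinates (insertions dropped, deletions become N), and every
   internal stop codon in that frame is an event, excluding the reference's
   own terminal stop. `next_to_Q` is true when an adjacent in-frame codon is
   CAA/CAG; `q_to_stop_transition` is true when the stop is TAA (TAG) and the
   aligned reference codon is CAA (CAG) — i.e. one C→T at base 1 explains it.
   Without a reference, frame 0 of the gene itself is scanned (agrees with
   the guided count on substitution-only genes; reference-frame counting
   means stops are reported at reference codon indices even for frameshifted
   or truncated genes).
6. **Call.** `pseudogene` iff at least one event was detected.

Two stop-context tallies exist in the literature-style summaries: strict
adjacency (the count aggregated per gene) and overlap with a poly-Q region;
the shipped catalogue carries only the strict column, and its column sum (35)
differs from the narrative total (33) quoted alongside it — the package
reports the column sum and does not force either total.

`align_global` itself defaults to strict global scoring (gap of length L
costs open + (L−1)·extend); the classifier passes `end_gaps_free=True`.

## Epitope scanning

Exact and 1-mismatch Hamming matching of 9-mer epitopes over every window;
overlapping occurrences of the same epitope each count (required for
33-mer-like regions). A cluster is any maximal region in which a window of
≤33 residues fully contains ≥6 exact hits from ≥2 distinct epitopes;
overlapping qualifying windows are merged. The four DQ2.5 nine-mers are
built in; other epitopes (e.g. the DQ8 class, whose sequence the built-in
set deliberately omits) come from YAML config.

## Phylogeny

p-distance (default) or Jukes–Cantor, with pairwise deletion of gap/N
columns; JC is undefined at p ≥ 0.75 and errors naming the pair. The
substitution model behind published α-gliadin trees is typically unstated,
so no published topology is treated as a target; p-distance is the default
for robustness at these shallow divergences. Neighbor-joining follows
Saitou–Nei with the Q-criterion; the first row-major minimum breaks ties, so
trees are deterministic. Negative branch estimates are clamped to 0 and
flagged (`clamped`). Bootstrap resamples alignment columns with replacement;
support on an internal edge is the percentage of replicate NJ trees
containing the same bipartition (replicates with undefined distances are
skipped). Multiple alignment is an input, not a feature: genes differing by
poly-Q tract length need a real aligner, and any external MSA tool's output
FASTA is accepted.

## Expression

The mapping contract is "similarity ≥ 0.99 over ≥ 0.9 of the read, mismatch
cost 2, indel cost 3", operationalized as: the full read is aligned to a gene
infix (free end gaps on the gene only) under scores match 0 / mismatch −2 /
gap −3, i.e. the alignment minimizes 2·mismatches + 3·indels; identity is
matches / alignment columns within the read span and coverage is read bases
aligned to gene bases / read length. An edlib edit-distance prefilter
discards read–gene pairs that provably cannot reach the identity threshold
(an alignment at identity ≥ s has at most ⌊(1−s)/s·L⌋ unit edits; the filter
adds a +2 cushion), and a 15-mer index shortlists candidate genes, so exact
alignment runs only on plausible pairs. Cost ties across genes follow the
ambiguity policy: `discard` (default, conservative), `split` (fractional
counts), or seeded `random`. FPKM = assigned × 10⁹ / (total_assigned ×
length); one single-end read is one fragment. `estimate_abundance_ratio`
corrects for effective length (L − read_length + 1 start positions) when
recovering the pseudogene abundance multiplier.

## Synthetic data

The generator emits genes on the canonical grammar: 20-residue signal
peptide, `VRVP` mature N-terminus, 8–12 seven-residue repeat units with the
requested epitopes inserted (default: the α1a and α3 nine-mers, the A-genome
pattern), Poly Q I of 9–41 Q, a fixed unique domain, Poly Q II of 6–32 Q, and
a constant C-terminus ending `GIFGTN`. The poly-Q ranges are the spans
observed across the nine deposited intact wild-emmer proteins. Q codons use
CAA:CAG = 2:1 (configurable; no empirical ratio is published). The repetitive
domain is terminated by a non-Q-ending unit so the designed run lengths are
exactly recoverable.

Lesions are injected per gene with probabilities p_stop_gain = 0.5 (count
1 + Poisson(0.8)), p_other_point = 0.3 (benign substitutions, never creating
or destroying stops), p_frameshift = 0.25 (1–2 bp indel), p_truncation = 0.2
(30–300 bp, 5′-biased 70:30), p_te_insertion = 0.1 (occasionally nested) —
yielding ~70–75% pseudogenes and a lesion mix resembling a real catalogue
(stop gains dominant, truncations mostly 5′, a minority of TE disruptions).
Every stop gain is a C→T at base 1 of a CAA/CAG codon. Placement rules keep
ground truth unambiguous under alignment: frameshift indels stay ≥15 bp from
injected stops and outside CAA/CAG runs (an indel inside a microsatellite
slides freely between equivalent optima — slippage, which this simulator
explicitly does not model), TE insertions stay ≥30 bp from the CDS ends, and
truth events removed by a truncation are dropped.

Reads: fragment counts are multinomial with weights abundance ×
(L − read_length + 1); pseudogene abundance carries a δ = 0.1 multiplier
(nonsense-mediated decay proxy); uniform start positions; per-base
substitution errors at 0.002. Defaults: 100 bp single-end, 50,000 reads.
All operations are deterministic under a fixed seed.

What the simulator does **not** emulate — hence what passing tests do not
show about real data: microsatellite slippage and poly-Q homogenization,
sequence evolution along a phylogeny (cohort genes are grammar siblings, not
descendants of a tree; the two-clade alignment generator used for bootstrap
checks is substitution-only), indel sequencing errors, paired-end or spliced
reads, TE target-site duplications, and reversion of pseudogenes.

## Problem sizes

The default analysis cohort is 200 genes (the catalogue-scale study is 40);
expression checks use 50,000 reads over a 30-gene panel; bootstrap checks use
200 replicates over 10 taxa × 600 bp. These sizes give binomial standard
errors small enough that the label-recovery and δ-recovery checks are
informative while the whole suite stays interactive.

## Known limitations

- Stop counting is reference-frame: stops visible only in a frameshifted
  query frame are not enumerated (the gene is already a pseudogene via the
  frameshift event itself).
- TE detection requires a library; fragments below 100 bp or under 80%
  identity pass silently. Excision boundaries inherit the local-alignment
  optimum, which can shift by the length of a junction micro-homology
  (the excised sequence is identical either way).
- `gene_density` is span/genes; published per-genome densities for these
  loci do not all follow from any printed span/count division, so density
  output is a computation, not a reconciliation.
- The orthology caller's thresholds (30 bp gene-relative position tolerance,
  ≥2 ordered shared flanking labels) operationalize what is narrative
  reasoning in locus studies; both are parameters.
- Single-end FPKM only; no multi-locus normalization across gene families.
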