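"""Scan proteins for celiac-disease T-cell epitopes and 33-mer-like clusters.

Uses the four canonical DQ2.5 nine-mers. The engineered 33-residue region
contains six overlapping copies of three epitopes — the structure of the
highly immunogenic α-gliadin 33-mer — and is reported as one cluster.
"""
from gliadinkit import (DEFAULT_EPITOPES, SequenceRecord, detect_clusters,
                        scan_protein)

mer33 = "LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF"
protein = SequenceRecord("demo", "MVRVPVPQLQ" + mer33 + "AQGSVQPQQL")

exact = scan_protein(protein, DEFAULT_EPITOPES, max_mismatch=0)
print("exact hits:")
for h in exact:
    print(f"  {h.epitope_name:<22} at {h.start}")

clusters = detect_clusters(exact)
for c in clusters:
    print(f"\ncluster [{c.window.start},{c.window.end}): "
          f"{c.n_overlapping_hits} overlapping hits from "
          f"{len(c.distinct_epitopes)} distinct epitopes")

# mismatch-tolerant scan: the natural P→T variant escapes the exact scan
variant = SequenceRecord("variant", "GSGSG" + "PTPQPQLPY" + "GSGSG")
print("\nP→T variant, exact scan:", scan_protein(variant, DEFAULT_EPITOPES, 0))
for h in scan_protein(variant, DEFAULT_EPITOPES, 1):
    print(f"mismatch-1 hit: {h.epitope_name} mutated_residues={h.mutated_residues}")
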