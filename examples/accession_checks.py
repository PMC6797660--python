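"""Checks against the nine deposited intact α-gliadin gene sequences.

These checks need the real GenBank sequences (MK333911–MK333918 and
MK358822), which are not shipped with the package; download them yourself
(e.g. with NCBI efetch) into one nucleotide FASTA and run:

    python examples/accession_checks.py deposited.fasta

Expected on the deposited set: the Td-α-B4 CDS has a glutamine-codon
fraction that rounds to 40%, and the largest Poly Q I glutamine count across
the nine deduced proteins is 41 (Td-α-B2).
"""
import sys
import warnings

from gliadinkit import (find_orf, polyq_profile, read_fasta, segment_domains,
                        translate)
from gliadinkit.formats import SequenceRecord

if len(sys.argv) != 2:
    sys.exit(__doc__)

records = read_fasta(sys.argv[1])
print(f"{'record':<30}{'polyQ I':>8}{'polyQ II':>9}{'Q-codon %':>10}")
results = {}
for rec in records:
    orf = find_orf(rec)
    cds = SequenceRecord(rec.id, rec.seq[orf.start:orf.end]) if orf else rec
    protein = translate(cds, "truncate_at_stop")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = segment_domains(protein)
    prof = polyq_profile(protein, seg, cds)
    results[rec.id] = prof
    print(f"{rec.id:<30}{prof.nQ_polyQ_I:>8}{prof.nQ_polyQ_II:>9}"
          f"{100 * prof.q_fraction_cds:>10.1f}")

max_q1 = max(results.values(), key=lambda p: p.nQ_polyQ_I)
print(f"\nmaximum Poly Q I count: {max_q1.nQ_polyQ_I} (expected 41, Td-α-B2)")
b4 = [p for rid, p in results.items() if "B4" in rid]
if b4:
    print(f"Td-α-B4 Q-codon fraction: {100 * b4[0].q_fraction_cds:.0f}% (expected 40%)")
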