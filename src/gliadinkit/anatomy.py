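"""Gene anatomy: ORF finding, translation, and α-gliadin domain segmentation.

α-Gliadins share a stereotyped layout: a ~20-residue signal peptide, a
proline/glutamine-rich repetitive domain, a first poly-glutamine tract
(Poly Q I), a short non-repetitive unique domain, a second tract (Poly Q II)
and a conserved C-terminal domain. Glutamine is encoded by CAA and CAG, so
the poly-Q tracts are CAA/CAG microsatellites at the DNA level.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from .formats import FeatureInterval, SequenceRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
GLUTAMINE_CODONS = frozenset({"CAA", "CAG"})

DEFAULT_SIGNAL_LEN = 20      # fixed-length signal peptide boundary
DEFAULT_MIN_RUN = 5          # minimum Q residues for a poly-Q region
DEFAULT_MAX_INTERRUPTIONS = 1  # non-Q residues merged into a run
MIN_ORF_CODONS = 50


def translate(cds: SequenceRecord, stop_policy: str = "read_through_mark") -> SequenceRecord:
    """Translate a CDS with the standard code.

    ``read_through_mark`` renders internal stops as '*' (pseudogene proteins
    stay alignable) and requires length divisible by 3; ``truncate_at_stop``
    translates up to the first stop. Non-ACGT characters become 'X' with a
    warning.
    """
    if stop_policy not in {"read_through_mark", "truncate_at_stop"}:
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    seq = cds.seq
    if not seq:
        raise ValueError("empty CDS")
    if stop_policy == "read_through_mark" and len(seq) % 3 != 0:
        raise ValueError(
            f"{cds.id}: length {len(seq)} not divisible by 3 under read_through_mark"
        )
    n_codons = len(seq) // 3
    aa = []
    warned = False
    for i in range(n_codons):
        codon = seq[3 * i: 3 * i + 3]
        if set(codon) - set("ACGT"):
            if not warned:
                warnings.warn(f"{cds.id}: ambiguous codon(s) translated as X")
                warned = True
            aa.append("X")
        else:
            aa.append(str(Seq(codon).translate()))
    protein = "".join(aa)
    if stop_policy == "truncate_at_stop":
        protein = protein.split("*")[0]
        if not protein:
            raise ValueError(f"{cds.id}: translation empty after stop truncation")
    return SequenceRecord(cds.id, protein, cds.description)


def find_orf(gene: SequenceRecord, min_orf_codons: int = MIN_ORF_CODONS) -> Optional[FeatureInterval]:
    """Longest ATG-initiated, stop-terminated ORF on the + strand.

    Returns a CDS interval including the terminal stop codon, or None when no
    ORF reaches ``min_orf_codons`` (codons counted including the stop).
    Ties go to the leftmost start.
    """
    seq = gene.seq
    best: Optional[tuple[int, int]] = None
    for frame in range(3):
        i = frame
        open_start: Optional[int] = None
        while i + 3 <= len(seq):
            codon = seq[i:i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in STOP_CODONS:
                length = i + 3 - open_start
                if best is None or length > best[1] - best[0]:
                    best = (open_start, i + 3)
                open_start = None
            i += 3
    if best is None or (best[1] - best[0]) // 3 < min_orf_codons:
        return None
    return FeatureInterval(gene.id, best[0], best[1], "+", "CDS", f"{gene.id}_CDS")


def q_runs(protein: str, min_run: int = DEFAULT_MIN_RUN,
           max_interruptions: int = DEFAULT_MAX_INTERRUPTIONS,
           flank: int = 3) -> list[tuple[int, int]]:
    """Maximal glutamine runs, merging runs separated by one non-Q residue.

    Two Q-runs separated by a single non-Q residue are merged when both
    flanks hold at least ``flank`` glutamines (applied up to
    ``max_interruptions`` times per merged region). Only merged regions with
    ≥ ``min_run`` glutamines qualify.
    """
    raw: list[tuple[int, int]] = []
    i = 0
    while i < len(protein):
        if protein[i] == "Q":
            j = i
            while j < len(protein) and protein[j] == "Q":
                j += 1
            raw.append((i, j))
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    interruptions: list[int] = []
    for s, e in raw:
        if (merged and s - merged[-1][1] == 1
                and interruptions[-1] < max_interruptions
                and merged[-1][1] - merged[-1][0] >= flank  # rough left flank
                and e - s >= flank):
            merged[-1][1] = e
            interruptions[-1] += 1
        else:
            merged.append([s, e])
            interruptions.append(0)
    out = []
    for (s, e), k in zip(merged, interruptions):
        if (e - s) - k >= min_run:  # count of actual Q residues
            out.append((s, e))
    return out


@dataclass
class DomainSegmentation:
    """α-Gliadin domain layout on protein coordinates."""

    signal_peptide: FeatureInterval
    repetitive_domain: Optional[FeatureInterval]
    polyQ_I: Optional[FeatureInterval]
    unique_I: Optional[FeatureInterval]
    polyQ_II: Optional[FeatureInterval]
    c_terminal: Optional[FeatureInterval]
    n_terminal_motif: str = ""
    c_terminal_motif: str = ""
    incomplete: bool = False  # fewer than two qualifying poly-Q runs


@dataclass
class PolyQProfile:
    nQ_polyQ_I: int
    nQ_polyQ_II: int
    q_fraction_cds: float


def segment_domains(protein: SequenceRecord,
                    signal_len: int = DEFAULT_SIGNAL_LEN,
                    min_run: int = DEFAULT_MIN_RUN,
                    max_interruptions: int = DEFAULT_MAX_INTERRUPTIONS) -> DomainSegmentation:
    """Segment an intact α-gliadin protein into its canonical domains.

    Poly Q I is the first maximal qualifying Q-run after the signal peptide,
    Poly Q II the next. Raises on proteins with internal '*' (pseudogene
    translations are not segmentable).
    """
    seq = protein.seq
    if "*" in seq[:-1]:
        raise ValueError(f"{protein.id}: internal stop — not an intact protein")
    if len(seq) <= signal_len + 11:
        raise ValueError(f"{protein.id}: too short to segment")
    pid = protein.id
    signal = FeatureInterval(pid, 0, signal_len, "+", "gene", "signal_peptide")
    runs = [(s, e) for s, e in q_runs(seq, min_run, max_interruptions)
            if s >= signal_len]
    polyq1 = polyq2 = None
    incomplete = False
    if runs:
        s, e = runs[0]
        polyq1 = FeatureInterval(pid, s, e, "+", "polyQ_I", "polyQ_I")
    if len(runs) >= 2:
        s, e = runs[1]
        polyq2 = FeatureInterval(pid, s, e, "+", "polyQ_II", "polyQ_II")
    else:
        incomplete = True
        warnings.warn(f"{protein.id}: fewer than two qualifying poly-Q runs")
    rep = (FeatureInterval(pid, signal_len, polyq1.start, "+", "gene", "repetitive_domain")
           if polyq1 and polyq1.start > signal_len else None)
    uniq = (FeatureInterval(pid, polyq1.end, polyq2.start, "+", "gene", "unique_I")
            if polyq1 and polyq2 and polyq2.start > polyq1.end else None)
    cterm = (FeatureInterval(pid, polyq2.end, len(seq), "+", "gene", "c_terminal")
             if polyq2 and polyq2.end < len(seq) else None)
    mature = seq[signal_len:].rstrip("*")
    return DomainSegmentation(
        signal_peptide=signal, repetitive_domain=rep, polyQ_I=polyq1,
        unique_I=uniq, polyQ_II=polyq2, c_terminal=cterm,
        n_terminal_motif=mature[:4], c_terminal_motif=mature[-7:],
        incomplete=incomplete,
    )


def polyq_profile(protein: SequenceRecord, seg: DomainSegmentation,
                  cds: SequenceRecord) -> PolyQProfile:
    """Q counts inside the poly-Q intervals and the CDS Q-codon fraction."""
    n_codons = len(cds.seq) // 3
    if len(cds.seq) % 3 != 0 or n_codons < len(protein.seq.rstrip("*")):
        raise ValueError(
            f"{protein.id}: CDS length {len(cds.seq)} inconsistent with "
            f"protein length {len(protein.seq)}"
        )
    def count_q(iv: Optional[FeatureInterval]) -> int:
        if iv is None:
            return 0
        return protein.seq[iv.start:iv.end].count("Q")
    codons = [cds.seq[3 * i: 3 * i + 3] for i in range(n_codons)]
    nq = sum(1 for c in codons if c in GLUTAMINE_CODONS)
    return PolyQProfile(
        nQ_polyQ_I=count_q(seg.polyQ_I),
        nQ_polyQ_II=count_q(seg.polyQ_II),
        q_fraction_cds=nq / n_codons,
    )


def terminal_motifs(protein: SequenceRecord, signal_len: int = 0) -> tuple[str, str]:
    """First four and last seven residues of the (mature) protein."""
    seq = protein.seq[signal_len:].rstrip("*")
    if len(seq) < 11:
        raise ValueError(f"{protein.id}: protein shorter than 11 residues")
    return seq[:4], seq[-7:]
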