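"""Pseudogene classification: mutation-event detection against intact references.

A gene is called a pseudogene when it carries at least one lesion relative to
an intact full-ORF reference: an internal in-frame stop codon, a frameshift
indel, a terminal truncation, a transposable-element insertion into the CDS,
or an assembly gap (a run of N). Internal stops are annotated with their
glutamine context: premature stops in these glutamine-rich genes arise
predominantly from C→T transitions at the first base of CAA/CAG codons,
yielding TAA/TAG.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
from Bio import Align

from .anatomy import GLUTAMINE_CODONS, STOP_CODONS
from .formats import GeneCatalogueRow, SequenceRecord

GAP_MIN_N = 10  # a run of >=10 N is an unassembled gap


@dataclass
class MutationEvent:
    """A single detected lesion in a gene."""

    kind: str  # stop_codon | frameshift | deletion_5prime | deletion_3prime | TE_insertion | gap
    position: int  # codon index for stops, base offset otherwise
    detail: str = ""
    stop_codon_seq: Optional[str] = None
    next_to_Q: bool = False
    q_to_stop_transition: bool = False

    def __post_init__(self) -> None:
        if self.kind != "stop_codon":
            assert self.stop_codon_seq is None, "stop fields only on stop events"
        if self.q_to_stop_transition:
            assert self.stop_codon_seq in {"TAA", "TAG"}


@dataclass
class AlignmentParams:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    te_min_identity: float = 0.8
    te_min_length: int = 100
    truncation_min_bp: int = 15

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if not (0 < self.te_min_identity <= 1):
            raise ValueError("te_min_identity must be in (0, 1]")


@dataclass
class PairwiseAlignment:
    """Gapped query/reference rows plus the alignment score."""

    query: str
    reference: str
    score: float

    def __post_init__(self) -> None:
        assert len(self.query) == len(self.reference)


def _aligner(params: AlignmentParams, mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    return a


def align_global(query: SequenceRecord, reference: SequenceRecord,
                 params: AlignmentParams | None = None,
                 end_gaps_free: bool = False) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (open + (L-1)·extend).

    With ``end_gaps_free`` terminal gaps score zero (semi-global): used when
    comparing truncated genes to a full-length reference, so the shared
    region aligns contiguously and the reference overhang stays terminal.
    Deterministic: the aligner's first-reported optimum is used.
    """
    params = params or AlignmentParams()
    if not query.seq or not reference.seq:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(params, "global")
    if end_gaps_free:
        try:
            aligner.end_deletion_score = 0.0
            aligner.end_insertion_score = 0.0
        except AttributeError:  # biopython < 1.88 names
            aligner.query_end_gap_score = 0.0
            aligner.target_end_gap_score = 0.0
    aln = aligner.align(query.seq, reference.seq)[0]
    return PairwiseAlignment(query=str(aln[0]), reference=str(aln[1]), score=aln.score)


def detect_te_insertions(gene: SequenceRecord,
                         te_library: Sequence[SequenceRecord],
                         params: AlignmentParams | None = None
                         ) -> tuple[SequenceRecord, list[MutationEvent]]:
    """Find and excise TE insertions by local alignment against a library.

    Intervals matching a library element at ≥ te_min_identity over
    ≥ te_min_length bp are excised iteratively (handles nested insertions:
    once an inner element is removed the flanking element becomes contiguous
    and is found on the next pass). Overlapping/adjacent calls are merged.
    The excised sequence's length is the gene's catalogue length.
    """
    params = params or AlignmentParams()
    if not te_library:
        return gene, []
    work = gene.seq
    removed: list[tuple[int, int, str]] = []  # intervals in *current* coords
    local = _aligner(params, "local")
    for _ in range(20):  # bounded: each pass removes one element
        best = None
        for te in te_library:
            if len(work) < params.te_min_length:
                break
            aln = local.align(work, te.seq)
            if len(aln) == 0:
                continue
            top = aln[0]
            (gstart, gend) = (top.aligned[0][0][0], top.aligned[0][-1][1])
            cols = sum(1 for a, b in zip(str(top[0]), str(top[1])))
            matches = sum(1 for a, b in zip(str(top[0]), str(top[1]))
                          if a == b and a != "-")
            length = gend - gstart
            identity = matches / max(cols, 1)
            if length >= params.te_min_length and identity >= params.te_min_identity:
                if best is None or top.score > best[0]:
                    best = (top.score, gstart, gend, te.id, identity)
        if best is None:
            break
        _, gstart, gend, te_id, identity = best
        removed.append((gstart, gend, te_id))
        work = work[:gstart] + work[gend:]
    if not removed:
        return gene, []
    # Map removed intervals back to original coordinates in excision order and
    # merge overlapping/adjacent blocks.
    original: list[tuple[int, int, str]] = []
    for gstart, gend, te_id in removed:
        o_start = gstart
        for ps, pe, _ in sorted(original):
            if ps <= o_start:
                o_start += pe - ps
            else:
                break
        original.append((o_start, o_start + (gend - gstart), te_id))
    original.sort()
    merged: list[list] = []
    for s, e, te_id in original:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2].append(te_id)
        else:
            merged.append([s, e, [te_id]])
    events = [
        MutationEvent(kind="TE_insertion", position=s,
                      detail="+".join(ids) + f" [{s},{e})")
        for s, e, ids in merged
    ]
    excised = SequenceRecord(gene.id, work, gene.description)
    return excised, events


def detect_gaps(gene: SequenceRecord) -> list[MutationEvent]:
    """Runs of ≥10 N mark unassembled regions."""
    return [
        MutationEvent(kind="gap", position=m.start(),
                      detail=f"{m.end() - m.start()} N")
        for m in re.finditer(r"N{%d,}" % GAP_MIN_N, gene.seq)
    ]


def _end_gap_lengths(row: str) -> tuple[int, int]:
    lead = len(row) - len(row.lstrip("-"))
    trail = len(row) - len(row.rstrip("-"))
    return lead, trail


def detect_truncations(aln: PairwiseAlignment,
                       params: AlignmentParams | None = None) -> list[MutationEvent]:
    """Terminal reference overhangs ≥ truncation_min_bp → deletion events."""
    params = params or AlignmentParams()
    lead, trail = _end_gap_lengths(aln.query)
    events = []
    if lead >= params.truncation_min_bp:
        events.append(MutationEvent(kind="deletion_5prime", position=0,
                                    detail=f"{lead} bp of reference missing at 5' end"))
    if trail >= params.truncation_min_bp:
        events.append(MutationEvent(kind="deletion_3prime",
                                    position=len(aln.query.replace('-', '')),
                                    detail=f"{trail} bp of reference missing at 3' end"))
    return events


def detect_frameshifts(aln: PairwiseAlignment) -> list[MutationEvent]:
    """Internal indels whose length mod 3 ≠ 0 each yield one frameshift."""
    events = []
    qlead, qtrail = _end_gap_lengths(aln.query)
    rlead, rtrail = _end_gap_lengths(aln.reference)
    lo = max(qlead, rlead)
    hi = len(aln.query) - max(qtrail, rtrail)
    qpos = len(aln.query[:lo].replace("-", ""))
    i = lo
    while i < hi:
        if aln.query[i] == "-" or aln.reference[i] == "-":
            row = aln.query if aln.query[i] == "-" else aln.reference
            j = i
            while j < hi and row[j] == "-":
                j += 1
            length = j - i
            if length % 3 != 0:
                which = "deletion" if row is aln.query else "insertion"
                events.append(MutationEvent(
                    kind="frameshift", position=qpos,
                    detail=f"{length} bp {which}",
                ))
            qpos += len(aln.query[i:j].replace("-", ""))
            i = j
        else:
            qpos += 1
            i += 1
    return events


def repair_to_reference(aln: PairwiseAlignment) -> str:
    """Project the query onto reference coordinates.

    Query insertions are dropped and reference positions unmatched by the
    query become N; the result has the reference's length and reading frame,
    so internal stops can be counted in the reference frame even for
    frameshifted or truncated genes.
    """
    out = []
    for q, r in zip(aln.query, aln.reference):
        if r == "-":
            continue
        out.append(q if q != "-" else "N")
    return "".join(out)


def stop_context(cds: SequenceRecord | str, stop_codon_index: int,
                 reference: SequenceRecord | str | None = None
                 ) -> tuple[bool, bool]:
    """Glutamine context of an in-frame stop codon.

    next_to_Q: the immediately preceding or following in-frame codon encodes
    glutamine (CAA/CAG). q_to_stop_transition: the stop is TAA (resp. TAG)
    and the aligned reference codon is CAA (resp. CAG) — i.e. a single C→T at
    codon base 1 created it.
    """
    seq = cds.seq if isinstance(cds, SequenceRecord) else cds
    n_codons = len(seq) // 3
    if not (0 <= stop_codon_index < n_codons):
        raise IndexError(f"codon index {stop_codon_index} out of range")
    codon = seq[3 * stop_codon_index: 3 * stop_codon_index + 3]
    prev_c = seq[3 * (stop_codon_index - 1): 3 * stop_codon_index] \
        if stop_codon_index > 0 else ""
    next_c = seq[3 * (stop_codon_index + 1): 3 * (stop_codon_index + 2)]
    next_to_q = prev_c in GLUTAMINE_CODONS or next_c in GLUTAMINE_CODONS
    q_to_stop = False
    if reference is not None and codon in {"TAA", "TAG"}:
        rseq = reference.seq if isinstance(reference, SequenceRecord) else reference
        ref_codon = rseq[3 * stop_codon_index: 3 * stop_codon_index + 3]
        q_to_stop = (codon == "TAA" and ref_codon == "CAA") or \
                    (codon == "TAG" and ref_codon == "CAG")
    return next_to_q, q_to_stop


def detect_premature_stops(cds: SequenceRecord,
                           frame_ref: PairwiseAlignment | None = None,
                           reference: SequenceRecord | None = None
                           ) -> list[MutationEvent]:
    """Internal in-frame stop codons, excluding the terminal stop.

    With ``frame_ref`` (an alignment of the TE-excised gene to an intact
    reference) the reading frame is taken from the reference via
    :func:`repair_to_reference`; otherwise frame 0 of the CDS is scanned.
    Codons containing N are skipped.
    """
    if frame_ref is not None:
        scan = repair_to_reference(frame_ref)
        ref_seq = frame_ref.reference.replace("-", "")
    else:
        scan = cds.seq
        ref_seq = None
    n_codons = len(scan) // 3
    # terminal codon: reference's own stop position (ref-guided) or the last
    # complete codon when it is a stop (frame 0).
    terminal_idx = None
    if ref_seq is not None:
        if ref_seq[3 * (len(ref_seq) // 3 - 1):3 * (len(ref_seq) // 3)] in STOP_CODONS:
            terminal_idx = len(ref_seq) // 3 - 1
    elif n_codons and scan[3 * (n_codons - 1): 3 * n_codons] in STOP_CODONS:
        terminal_idx = n_codons - 1
    events = []
    for idx in range(n_codons):
        codon = scan[3 * idx: 3 * idx + 3]
        if codon not in STOP_CODONS or idx == terminal_idx:
            continue
        next_to_q, q_to_stop = stop_context(scan, idx, ref_seq)
        events.append(MutationEvent(
            kind="stop_codon", position=idx, detail=codon,
            stop_codon_seq=codon, next_to_Q=next_to_q,
            q_to_stop_transition=q_to_stop,
        ))
    return events


@dataclass
class ClassificationResult:
    row: GeneCatalogueRow
    events: list[MutationEvent]
    excised_gene: SequenceRecord
    reference_id: Optional[str] = None


def _pick_reference(gene: SequenceRecord,
                    references: Sequence[SequenceRecord]) -> SequenceRecord:
    """Closest intact reference by semi-global edit distance (ties: input order).

    The shorter sequence is matched as an infix of the longer so that a
    terminally truncated gene is compared over its shared region rather than
    penalized for the missing end.
    """
    best, best_d = None, None
    for ref in references:
        k = -1 if best_d is None else best_d  # prune once a good match exists
        if len(gene.seq) <= len(ref.seq):
            d = edlib.align(gene.seq, ref.seq, mode="HW", k=k)["editDistance"]
        else:
            d = edlib.align(ref.seq, gene.seq, mode="HW", k=k)["editDistance"]
        if d == -1:
            continue
        if best_d is None or d < best_d:
            best, best_d = ref, d
    return best


def classify_gene(gene: SequenceRecord,
                  references: Sequence[SequenceRecord] = (),
                  te_library: Sequence[SequenceRecord] = (),
                  params: AlignmentParams | None = None,
                  genome: str | None = None) -> ClassificationResult:
    """Catalogue one gene: detect all lesion types and call intact/pseudogene.

    With no references, stop detection runs reference-free in frame 0 and
    truncations/frameshifts cannot be called.
    """
    params = params or AlignmentParams()
    if genome is None:
        genome = "B" if re.search(r"[-_]B", gene.id) else "A"
    events: list[MutationEvent] = []
    events.extend(detect_gaps(gene))
    excised, te_events = detect_te_insertions(gene, te_library, params)
    events.extend(te_events)
    reference_id = None
    if references:
        ref = _pick_reference(excised, references)
        reference_id = ref.id
        aln = align_global(excised, ref, params, end_gaps_free=True)
        events.extend(detect_truncations(aln, params))
        events.extend(detect_frameshifts(aln))
        events.extend(detect_premature_stops(excised, frame_ref=aln))
    else:
        events.extend(detect_premature_stops(excised))
    stop_events = [e for e in events if e.kind == "stop_codon"]
    row = GeneCatalogueRow(
        gene_id=gene.id,
        genome=genome,
        length_bp=len(excised.seq),
        mutation_types=frozenset(e.kind for e in events),
        n_stop=len(stop_events),
        n_stop_next_to_Q=sum(1 for e in stop_events if e.next_to_Q),
    )
    return ClassificationResult(row=row, events=events,
                                excised_gene=excised, reference_id=reference_id)


def classify_cohort(genes: Sequence[SequenceRecord],
                    references: Sequence[SequenceRecord] = (),
                    te_library: Sequence[SequenceRecord] = (),
                    params: AlignmentParams | None = None
                    ) -> list[ClassificationResult]:
    return [classify_gene(g, references, te_library, params) for g in genes]
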