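"""Mutation-event detection and pseudogene classification."""
from itertools import product

import numpy as np
import pytest

from gliadinkit import (AlignmentParams, SequenceRecord, SimulationConfig,
                        align_global, classify_gene, default_te_library,
                        detect_frameshifts, detect_premature_stops,
                        detect_te_insertions, detect_truncations,
                        simulate_intact_gene, stop_context, translate)
from gliadinkit.classify import PairwiseAlignment, detect_gaps

BASES = "ACGT"


def gotoh_score(a: str, b: str, match=2.0, mismatch=-3.0, open_=-5.0, ext=-2.0):
    """Independent affine-gap global alignment score (textbook Gotoh DP).

    Gap of length L costs open + (L-1)*ext, matching the package convention.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext,
                          X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def test_align_global_identical_sequences():
    r = SequenceRecord("a", "ACGTACGTAC")
    aln = align_global(r, SequenceRecord("b", r.seq))
    assert "-" not in aln.query and "-" not in aln.reference
    assert aln.score == len(r.seq) * 2.0


def test_align_global_single_deletion_one_gap_column():
    aln = align_global(SequenceRecord("a", "ACGTCGTAC"),
                       SequenceRecord("b", "ACGTACGTAC"))
    assert aln.query.count("-") == 1 and aln.reference.count("-") == 0


def test_align_global_matches_independent_dp_oracle():
    rng = np.random.default_rng(123)
    for _ in range(20):
        a = "".join(rng.choice(list(BASES), size=int(rng.integers(5, 31))))
        b = "".join(rng.choice(list(BASES), size=int(rng.integers(5, 31))))
        aln = align_global(SequenceRecord("a", a), SequenceRecord("b", b))
        assert aln.score == pytest.approx(gotoh_score(a, b))


def test_empty_sequence_rejected_at_construction():
    with pytest.raises(ValueError, match="empty"):
        SequenceRecord("a", "")


def _intact(seed=5):
    cfg = SimulationConfig(seed=seed, n_genes=1)
    gene, _ = simulate_intact_gene(cfg, cfg.rng())
    return gene


def test_te_excision_single_insertion():
    gene = _intact()
    lib = default_te_library()
    te = lib[0]
    pos = 200
    disrupted = SequenceRecord(gene.id, gene.seq[:pos] + te.seq + gene.seq[pos:])
    excised, events = detect_te_insertions(disrupted, lib)
    assert [e.kind for e in events] == ["TE_insertion"]
    assert te.id in events[0].detail
    assert len(excised.seq) == len(gene.seq)
    assert excised.seq == gene.seq


def test_te_excision_no_hits_passthrough():
    gene = _intact()
    excised, events = detect_te_insertions(gene, default_te_library())
    assert events == [] and excised.seq == gene.seq


def test_te_excision_nested_restores_protein():
    gene = _intact(seed=9)
    lib = default_te_library()
    outer, inner = lib[2], lib[4]
    te_seq = outer.seq[:250] + inner.seq + outer.seq[250:]
    pos = 150
    disrupted = SequenceRecord(gene.id, gene.seq[:pos] + te_seq + gene.seq[pos:])
    excised, events = detect_te_insertions(disrupted, lib)
    assert excised.seq == gene.seq
    assert translate(excised, "read_through_mark").seq == \
           translate(gene, "read_through_mark").seq
    assert all(e.kind == "TE_insertion" for e in events)


def test_truncation_detection_designed():
    ref = _intact(seed=6)
    query = SequenceRecord("q", ref.seq[100:])
    aln = align_global(query, ref, end_gaps_free=True)
    events = detect_truncations(aln)
    assert [e.kind for e in events] == ["deletion_5prime"]


def test_truncation_full_coverage_empty():
    ref = _intact(seed=6)
    aln = align_global(ref, ref)
    assert detect_truncations(aln) == []


@pytest.mark.parametrize("gaps,expected", [
    ([("ins", 1)], 1),            # one 1-bp insertion -> one frameshift
    ([("del", 3)], 0),            # in-frame deletion -> none
    ([("del", 2), ("del", 1)], 2),
    ([("ins", 2), ("del", 3), ("ins", 4)], 2),
])
def test_frameshift_indel_length_mod3(gaps, expected):
    ref = _intact(seed=7)
    seq = ref.seq
    offset = 0
    rng = np.random.default_rng(0)
    positions = sorted(rng.choice(np.arange(100, len(seq) - 100), size=len(gaps),
                                  replace=False), reverse=True)
    for (kind, length), pos in zip(gaps, positions):
        if kind == "del":
            seq = seq[:pos] + seq[pos + length:]
        else:
            seq = seq[:pos] + "T" * length + seq[pos:]
    aln = align_global(SequenceRecord("q", seq), ref, end_gaps_free=True)
    events = detect_frameshifts(aln)
    assert len(events) == expected


def test_premature_stops_terminal_excluded():
    cds = SequenceRecord("x", "ATGCAATAACAGTGA")
    events = detect_premature_stops(cds)
    assert len(events) == 1
    assert events[0].position == 2 and events[0].stop_codon_seq == "TAA"
    assert events[0].next_to_Q  # flanked by CAA and CAG


def test_premature_stops_intact_gene_zero():
    gene = _intact(seed=8)
    assert detect_premature_stops(gene) == []


def test_stop_context_next_to_q():
    seq = "ATG" + "CAA" + "TAA" + "CAG" + "TGA"
    assert stop_context(seq, 2) == (True, False)
    assert stop_context(seq, 2, "ATG" + "CAA" + "CAA" + "CAG" + "TGA") == (True, True)


def test_stop_context_tga_never_q_transition():
    seq = "ATGCAATGACAGTGA"
    next_to_q, q_to_stop = stop_context(seq, 2, "ATGCAACAACAGTGA")
    assert next_to_q and not q_to_stop


def test_stop_context_index_out_of_range():
    with pytest.raises(IndexError):
        stop_context("ATGTAA", 5)


def test_single_c_to_t_reachable_stops_exhaustive():
    """Brute force over all 64 codons: one C→T at any base of a glutamine
    codon reaches exactly {TAA, TAG}; no other stop is reachable."""
    codons = ["".join(c) for c in product(BASES, repeat=3)]
    stops = {"TAA", "TAG", "TGA"}
    reachable = set()
    for codon in ("CAA", "CAG"):
        for i, base in enumerate(codon):
            if base == "C":
                mut = codon[:i] + "T" + codon[i + 1:]
                if mut in stops:
                    reachable.add(mut)
    assert reachable == {"TAA", "TAG"}
    assert len(codons) == 64
    # and no non-Q codon is wrongly treated: TGA cannot arise from CAA/CAG
    assert "TGA" not in reachable


def test_gap_events_n_runs():
    gene = SequenceRecord("g", "ACGT" * 10 + "N" * 12 + "ACGT" * 10)
    events = detect_gaps(gene)
    assert [e.kind for e in events] == ["gap"]
    assert detect_gaps(SequenceRecord("g", "ACGTN" * 20)) == []


def test_classify_unmutated_gene_intact():
    gene = _intact(seed=10)
    ref = SequenceRecord("ref", gene.seq)
    res = classify_gene(gene, [ref], default_te_library())
    assert res.row.status == "intact" and res.events == []


def test_classify_engineered_frameshift_plus_stops():
    """A gene engineered with one frameshift and multiple C→T stop gains
    reproduces the catalogue row fields (frameshift + stop_codon, n, next-Q)."""
    gene = _intact(seed=12)
    ref = SequenceRecord("ref", gene.seq)
    seq = gene.seq
    n_codons = len(seq) // 3
    q_idx = [i for i in range(2, n_codons - 2)
             if seq[3 * i:3 * i + 3] in {"CAA", "CAG"}]
    chosen = q_idx[2:18:2]  # 8 stop gains
    for i in chosen:
        seq = seq[:3 * i] + "T" + seq[3 * i + 1:]
    # count how many end up adjacent to a Q codon
    expected_next = 0
    for i in chosen:
        prev_c, next_c = seq[3 * (i - 1):3 * i], seq[3 * (i + 1):3 * (i + 2)]
        expected_next += prev_c in {"CAA", "CAG"} or next_c in {"CAA", "CAG"}
    seq = seq[:30] + seq[31:]  # 1-bp frameshift deletion well before the stops?
    mutated = SequenceRecord("mut", seq)
    res = classify_gene(mutated, [ref], default_te_library())
    assert res.row.status == "pseudogene"
    assert res.row.mutation_types == {"frameshift", "stop_codon"}
    assert res.row.n_stop == 8
    assert res.row.n_stop_next_to_Q == expected_next
    assert all(e.q_to_stop_transition for e in res.events
               if e.kind == "stop_codon")


def test_reference_free_matches_guided_on_clean_genes(small_cohort):
    """Substitution-only pseudogenes: frame-0 and reference-guided stop
    counts agree."""
    cfg, cohort = small_cohort
    checked = 0
    for gene, truth in zip(cohort.genes, cohort.truths):
        kinds = {e.kind for e in truth.injected_events}
        if kinds and kinds <= {"stop_codon"}:
            free = classify_gene(gene)
            guided = classify_gene(gene, cohort.parents, cfg.te_library)
            assert free.row.n_stop == guided.row.n_stop
            checked += 1
    assert checked >= 1


def test_stop_count_conservation(acceptance_cohort):
    """n_stop equals the number of stop events for every classified gene."""
    from gliadinkit import classify_cohort
    cfg, cohort = acceptance_cohort
    results = classify_cohort(cohort.genes[:40], cohort.parents, cfg.te_library)
    for r in results:
        stops = [e for e in r.events if e.kind == "stop_codon"]
        assert r.row.n_stop == len(stops)
        assert r.row.n_stop_next_to_Q <= r.row.n_stop
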