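"""Synthetic α-gliadin-like genes, mutated cohorts, loci and read sets.

The generator emits genes with the canonical two-poly-Q-domain architecture
(signal peptide, epitope-bearing repetitive domain, Poly Q I, unique domain,
Poly Q II, conserved C-terminus ending GIFGTN), then injects the lesion types
seen in prolamin pseudogenes: C→T stop gains at CAA/CAG glutamine codons,
frameshift indels, terminal truncations and transposable-element insertions.
Pseudogene transcript abundance is depressed by a multiplier δ, emulating
nonsense-mediated decay. Every operation is deterministic under a fixed seed
and returns ground-truth records.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .anatomy import GLUTAMINE_CODONS, STOP_CODONS
from .classify import MutationEvent
from .formats import FeatureInterval, SequenceRecord

SIGNAL_PEPTIDE = "MKTFLILALLAIVATTATTA"  # fixed 20-residue signal
N_TERMINAL_UNIT = "VRVP"                 # mature N-terminus
UNIQUE_DOMAIN = "SNIQVDPSGEVQWPQSKPFP"   # non-repetitive spacer between poly-Q tracts
C_TERMINAL = "ILRTLPTMCNVYIPPYCSTTIAPFGIFGTN"

REPEAT_UNITS = ("PQPQPFP", "PQPQLPY", "QLPYPQP", "PQQPYPQ")

# residues per repeat unit stay below the poly-Q qualifying run length, so
# segmentation only ever sees the two designed tracts


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    out: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        out.setdefault(aa, []).append(codon)
    for aa in out:
        out[aa].sort()
    return out


_CODONS = _codon_map()


def default_te_library() -> list[SequenceRecord]:
    """Five synthetic elements with terminal-repeat decorations.

    Labels (Ada, Manor, Sabrina, Fatima, Inga) are mnemonic family names
    only — the sequences are random.
    """
    rng = np.random.default_rng(97531)
    bases = np.array(list("ACGT"))
    lib = []
    for name, length in [("Ada", 450), ("Manor", 380), ("Sabrina", 600),
                         ("Fatima", 300), ("Inga", 150)]:
        core = "".join(rng.choice(bases, size=length - 24))
        tir = "".join(rng.choice(bases, size=12))
        rc = tir[::-1].translate(str.maketrans("ACGT", "TGCA"))
        lib.append(SequenceRecord(name, tir + core + rc, "synthetic TE"))
    return lib


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort."""

    seed: int
    n_genes: int = 40
    n_repeat_units: tuple = (8, 12)
    polyQ_I_range: tuple = (9, 41)
    polyQ_II_range: tuple = (6, 32)
    epitope_placement: tuple = ("PFPQPQLPY", "FRPQQPYPQ")
    caa_fraction: float = 2 / 3  # CAA:CAG = 2:1 in poly-Q runs
    # per-gene lesion probabilities
    p_stop_gain: float = 0.5
    stop_gain_extra_mean: float = 0.8  # extra stops ~ Poisson on top of one
    p_other_point: float = 0.3
    p_frameshift: float = 0.25
    p_truncation: float = 0.2
    p_te_insertion: float = 0.1
    te_library: Optional[list] = None
    # expression model
    intact_abundance: float = 100.0
    pseudogene_delta: float = 0.1
    read_length: int = 100
    n_reads: int = 50_000
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        for name in ("p_stop_gain", "p_other_point", "p_frameshift",
                     "p_truncation", "p_te_insertion", "pseudogene_delta",
                     "error_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("polyQ_I_range", "polyQ_II_range", "n_repeat_units"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range {lo}..{hi} is infeasible")
        if self.te_library is None:
            self.te_library = default_te_library()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthRecord:
    gene_id: str
    true_status: str  # intact | pseudogene
    injected_events: list = field(default_factory=list)
    true_polyQ: tuple = (0, 0)
    planted_epitopes: tuple = ()
    true_abundance: float = 0.0

    def __post_init__(self) -> None:
        if self.true_status == "intact" and self.injected_events:
            raise ValueError("intact truth cannot carry events")


def _reverse_translate(protein: str, cfg: SimulationConfig,
                       rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        if aa == "Q":
            codons.append("CAA" if rng.random() < cfg.caa_fraction else "CAG")
        else:
            choices = _CODONS[aa]
            codons.append(choices[int(rng.integers(len(choices)))])
    return "".join(codons)


def simulate_intact_gene(cfg: SimulationConfig, rng: np.random.Generator,
                         gene_id: str = "sim-g0") -> tuple[SequenceRecord, TruthRecord]:
    """One intact CDS: ATG start, single terminal stop, designed poly-Q runs."""
    q1 = int(rng.integers(cfg.polyQ_I_range[0], cfg.polyQ_I_range[1] + 1))
    q2 = int(rng.integers(cfg.polyQ_II_range[0], cfg.polyQ_II_range[1] + 1))
    n_units = int(rng.integers(cfg.n_repeat_units[0], cfg.n_repeat_units[1] + 1))
    units = [REPEAT_UNITS[int(rng.integers(len(REPEAT_UNITS)))]
             for _ in range(n_units)]
    for ep in cfg.epitope_placement:
        units.insert(int(rng.integers(1, len(units) + 1)), ep)
    units.append("PQPQPFP")  # non-Q terminus keeps the designed run exact
    protein = (SIGNAL_PEPTIDE + N_TERMINAL_UNIT + "".join(units)
               + "Q" * q1 + UNIQUE_DOMAIN + "Q" * q2 + C_TERMINAL)
    cds = _reverse_translate(protein, cfg, rng) + "TGA"
    record = SequenceRecord(gene_id, cds, "synthetic intact alpha-gliadin-like gene")
    truth = TruthRecord(gene_id=gene_id, true_status="intact",
                        true_polyQ=(q1, q2),
                        planted_epitopes=tuple(cfg.epitope_placement),
                        true_abundance=cfg.intact_abundance)
    return record, truth


def _q_codon_indices(seq: str) -> list[int]:
    n = len(seq) // 3
    return [i for i in range(2, n - 2) if seq[3 * i:3 * i + 3] in GLUTAMINE_CODONS]


def apply_mutations(gene: SequenceRecord, cfg: SimulationConfig,
                    rng: np.random.Generator) -> tuple[SequenceRecord, TruthRecord]:
    """Inject lesions per the configured rates; truth records every event.

    Stop gains are C→T at base 1 of a CAA/CAG codon (→ TAA/TAG). Lesions are
    placed at non-interfering positions (indels ≥15 bp from injected stops,
    insertions away from CDS ends) so ground truth stays unambiguous; events
    removed again by a truncation are dropped from the truth.
    """
    seq = gene.seq
    events: list[MutationEvent] = []

    # benign point substitutions (not lesions; never create or destroy stops)
    if rng.random() < cfg.p_other_point:
        for _ in range(1 + int(rng.poisson(1.0))):
            n = len(seq) // 3
            idx = int(rng.integers(1, n - 1))
            codon = seq[3 * idx:3 * idx + 3]
            if codon in STOP_CODONS:
                continue
            pos_in = int(rng.integers(3))
            for base in "ACGT":
                cand = codon[:pos_in] + base + codon[pos_in + 1:]
                if cand != codon and cand not in STOP_CODONS:
                    seq = seq[:3 * idx] + cand + seq[3 * idx + 3:]
                    break

    # C→T stop gains at glutamine codons
    stop_codon_idx: list[int] = []
    if rng.random() < cfg.p_stop_gain:
        k = 1 + int(rng.poisson(cfg.stop_gain_extra_mean))
        qpos = _q_codon_indices(seq)
        rng.shuffle(qpos)
        for idx in sorted(qpos[:k]):
            codon = seq[3 * idx:3 * idx + 3]
            seq = seq[:3 * idx] + "T" + seq[3 * idx + 1:]
            stop_codon_idx.append(idx)
    # glutamine context evaluated on the fully substituted sequence
    for idx in stop_codon_idx:
        codon = seq[3 * idx:3 * idx + 3]
        prev_c = seq[3 * (idx - 1):3 * idx]
        next_c = seq[3 * (idx + 1):3 * (idx + 2)]
        events.append(MutationEvent(
            kind="stop_codon", position=idx, detail="injected C->T stop gain",
            stop_codon_seq=codon,
            next_to_Q=prev_c in GLUTAMINE_CODONS or next_c in GLUTAMINE_CODONS,
            q_to_stop_transition=True,
        ))

    # current base coordinate of each event, updated through later indels so
    # truncation removal is decided exactly
    base_of = {id(ev): 3 * ev.position for ev in events if ev.kind == "stop_codon"}

    def near_stop(base_pos: int, margin: int = 15) -> bool:
        return any(abs(base_pos - b) <= margin for b in base_of.values())

    # base positions inside CAA/CAG microsatellite runs (≥2 consecutive Q
    # codons): indels there slide freely under alignment (slippage, which the
    # simulator does not model), so frameshifts are placed outside them
    q_run_bases: set[int] = set()
    run_start = None
    n_codons = len(seq) // 3
    for i in range(n_codons + 1):
        is_q = i < n_codons and seq[3 * i:3 * i + 3] in GLUTAMINE_CODONS
        if is_q and run_start is None:
            run_start = i
        elif not is_q and run_start is not None:
            if i - run_start >= 2:
                q_run_bases.update(range(3 * run_start - 15, 3 * i + 15))
            run_start = None

    # frameshift indel (1 or 2 bp), kept clear of injected stops
    if rng.random() < cfg.p_frameshift:
        pos = int(rng.integers(30, len(seq) - 30))
        for _ in range(50):
            if not near_stop(pos) and pos not in q_run_bases:
                break
            pos = int(rng.integers(30, len(seq) - 30))
        length = int(rng.integers(1, 3))
        if rng.random() < 0.5:
            seq = seq[:pos] + seq[pos + length:]
            detail = f"{length} bp deletion"
            shift = -length
        else:
            ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
            seq = seq[:pos] + ins + seq[pos:]
            detail = f"{length} bp insertion"
            shift = length
        for key, b in base_of.items():
            if b >= pos:
                base_of[key] = b + shift
        fs_event = MutationEvent(kind="frameshift", position=pos, detail=detail)
        events.append(fs_event)
        base_of[id(fs_event)] = pos

    # terminal truncation
    if rng.random() < cfg.p_truncation:
        t = int(rng.integers(30, min(300, len(seq) // 3) + 1))
        if rng.random() < 0.7:
            kind = "deletion_5prime"
            removed = range(0, t)
            seq = seq[t:]
        else:
            kind = "deletion_3prime"
            removed = range(len(seq) - t, len(seq))
            seq = seq[:len(seq) - t]
        surviving = []
        for ev in events:
            base = base_of.get(id(ev), 0)
            span = range(base, base + 3) if ev.kind == "stop_codon" else [base]
            if any(b in removed for b in span):
                continue
            surviving.append(ev)
        events = surviving
        events.append(MutationEvent(kind=kind, position=0 if kind.endswith("5prime") else len(seq),
                                    detail=f"{t} bp removed"))

    # transposable-element insertion (occasionally nested)
    if rng.random() < cfg.p_te_insertion and cfg.te_library:
        te = cfg.te_library[int(rng.integers(len(cfg.te_library)))]
        te_seq = te.seq
        labels = te.id
        if rng.random() < 0.3 and len(cfg.te_library) > 1:
            others = [t for t in cfg.te_library if t.id != te.id]
            inner = others[int(rng.integers(len(others)))]
            at = int(rng.integers(30, len(te_seq) - 30))
            te_seq = te_seq[:at] + inner.seq + te_seq[at:]
            labels = f"{te.id}+{inner.id}"
        pos = int(rng.integers(30, len(seq) - 30))
        seq = seq[:pos] + te_seq + seq[pos:]
        events.append(MutationEvent(kind="TE_insertion", position=pos, detail=labels))

    status = "pseudogene" if events else "intact"
    mutated = SequenceRecord(gene.id, seq, f"synthetic {status}")
    truth = TruthRecord(
        gene_id=gene.id, true_status=status, injected_events=events,
        true_polyQ=(0, 0), planted_epitopes=tuple(cfg.epitope_placement),
        true_abundance=cfg.intact_abundance * (
            cfg.pseudogene_delta if status == "pseudogene" else 1.0),
    )
    return mutated, truth


@dataclass
class Cohort:
    genes: list
    truths: list
    parents: list  # pre-mutation intact sequences (reference panel)


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """n_genes mutated genes plus their intact parents and ground truth."""
    rng = cfg.rng()
    genes, truths, parents = [], [], []
    for i in range(cfg.n_genes):
        parent, parent_truth = simulate_intact_gene(cfg, rng, gene_id=f"sim-g{i:03d}")
        mutated, truth = apply_mutations(parent, cfg, rng)
        truth.true_polyQ = parent_truth.true_polyQ  # designed runs of the parent
        genes.append(mutated)
        truths.append(truth)
        parents.append(SequenceRecord(f"ref-{parent.id}", parent.seq,
                                      "intact parent"))
    return Cohort(genes=genes, truths=truths, parents=parents)


def _spacer(cfg: SimulationConfig, rng: np.random.Generator,
            te_names: Sequence[str]) -> tuple[str, list[tuple[str, int, int]]]:
    """Intergenic spacer: random DNA with the requested TE copies inside."""
    by_name = {t.id: t for t in cfg.te_library}
    parts = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, size=int(rng.integers(200, 600)))])]
    tes = []
    offset = len(parts[0])
    for name in te_names:
        te = by_name[name]
        tes.append((name, offset, offset + len(te.seq)))
        parts.append(te.seq)
        offset += len(te.seq)
        filler = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=int(rng.integers(100, 400)))])
        parts.append(filler)
        offset += len(filler)
    return "".join(parts), tes


def simulate_locus(cfg: SimulationConfig, locus_id: str = "sim-locus",
                   te_plan: Optional[Sequence[Sequence[str]]] = None
                   ) -> tuple[SequenceRecord, list[FeatureInterval], list[TruthRecord]]:
    """Genes separated by TE-bearing intergenic spacers.

    ``te_plan`` optionally fixes the TE labels of each intergenic region
    (n_genes + 1 entries); by default 1–3 elements are drawn per region.
    """
    rng = cfg.rng()
    names = [t.id for t in cfg.te_library]
    if te_plan is None:
        te_plan = [
            [names[int(rng.integers(len(names)))]
             for _ in range(int(rng.integers(1, 4)))]
            for _ in range(cfg.n_genes + 1)
        ]
    chunks: list[str] = []
    features: list[FeatureInterval] = []
    truths: list[TruthRecord] = []
    pos = 0
    for i in range(cfg.n_genes):
        spacer, tes = _spacer(cfg, rng, te_plan[i])
        for name, s, e in tes:
            features.append(FeatureInterval(locus_id, pos + s, pos + e, "+", "TE", name))
        chunks.append(spacer)
        pos += len(spacer)
        gene, truth = simulate_intact_gene(cfg, rng, gene_id=f"{locus_id}-g{i:02d}")
        features.append(FeatureInterval(locus_id, pos, pos + len(gene.seq), "+",
                                        "gene", gene.id))
        truths.append(truth)
        chunks.append(gene.seq)
        pos += len(gene.seq)
    spacer, tes = _spacer(cfg, rng, te_plan[cfg.n_genes])
    for name, s, e in tes:
        features.append(FeatureInterval(locus_id, pos + s, pos + e, "+", "TE", name))
    chunks.append(spacer)
    locus = SequenceRecord(locus_id, "".join(chunks), "synthetic locus")
    return locus, features, truths


def simulate_homologous_loci(cfg: SimulationConfig, n_genes: int = 4
                             ) -> tuple[tuple, tuple, tuple[str, str]]:
    """Two loci where exactly one gene pair shares an intra-CDS TE insertion.

    Intergenic TE labels are disjoint between the loci, so the shared-TE
    orthology caller should recover exactly the designated pair. Returns
    ((locus_a, features_a), (locus_b, features_b), (gene_a_id, gene_b_id)).
    """
    sub = replace(cfg, n_genes=n_genes)
    rng = cfg.rng()
    names = [t.id for t in cfg.te_library]
    half = max(len(names) // 2, 1)
    plan_a = [[names[i % half]] for i in range(n_genes + 1)]
    plan_b = [[names[half + i % max(len(names) - half, 1)]]
              for i in range(n_genes + 1)]
    locus_a, feats_a, _ = simulate_locus(replace(sub, seed=cfg.seed + 1),
                                         "locus-A", plan_a)
    locus_b, feats_b, _ = simulate_locus(replace(sub, seed=cfg.seed + 2),
                                         "locus-B", plan_b)
    shared_te = cfg.te_library[int(rng.integers(len(cfg.te_library)))]
    target = int(rng.integers(n_genes))

    def insert_te(locus, feats, target_idx):
        gene_feats = [f for f in feats if f.kind == "gene"]
        g = gene_feats[target_idx]
        offset = 60  # same gene-relative insertion point in both loci
        at = g.start + offset
        new_seq = locus.seq[:at] + shared_te.seq + locus.seq[at:]
        new_feats = []
        for f in feats:
            if f.start >= at:
                new_feats.append(f.shift(len(shared_te.seq)))
            elif f.end > at:  # the disrupted gene grows
                new_feats.append(FeatureInterval(f.seq_id, f.start,
                                                 f.end + len(shared_te.seq),
                                                 f.strand, f.kind, f.label))
            else:
                new_feats.append(f)
        new_feats.append(FeatureInterval(g.seq_id, at, at + len(shared_te.seq),
                                         "+", "TE", shared_te.id))
        return SequenceRecord(locus.id, new_seq, locus.description), new_feats, g.label

    locus_a, feats_a, ga = insert_te(locus_a, feats_a, target)
    locus_b, feats_b, gb = insert_te(locus_b, feats_b, target)
    return (locus_a, feats_a), (locus_b, feats_b), (ga, gb)


def simulate_reads(genes: Sequence[SequenceRecord],
                   truths: Sequence[TruthRecord],
                   cfg: SimulationConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> list[SequenceRecord]:
    """Error-prone single-end reads, fragment counts ∝ abundance × positions.

    Each gene offers length − read_length + 1 uniform start positions;
    expected fragment counts are abundance-weighted (pseudogenes carry the
    δ multiplier via their truth records). Genes shorter than the read
    length are skipped with a warning.
    """
    import warnings as _warnings

    if cfg.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = rng if rng is not None else cfg.rng()
    abundance = {t.gene_id: t.true_abundance for t in truths}
    usable, weights = [], []
    for g in genes:
        eff = len(g.seq) - cfg.read_length + 1
        if eff <= 0:
            _warnings.warn(f"{g.id}: shorter than read length — skipped")
            continue
        usable.append((g, eff))
        weights.append(abundance[g.id] * eff)
    w = np.asarray(weights, dtype=float)
    w /= w.sum()
    counts = rng.multinomial(cfg.n_reads, w)
    bases = np.array(list("ACGT"))
    reads: list[SequenceRecord] = []
    ridx = 0
    for (gene, eff), n in zip(usable, counts):
        starts = rng.integers(0, eff, size=n)
        for s in starts:
            arr = np.frombuffer(gene.seq[s:s + cfg.read_length].encode(), dtype="S1").astype("U1")
            errs = np.nonzero(rng.random(cfg.read_length) < cfg.error_rate)[0]
            for e in errs:
                arr[e] = bases[(np.nonzero(bases == arr[e])[0][0] + int(rng.integers(1, 4))) % 4]
            reads.append(SequenceRecord(f"read{ridx:06d}", "".join(arr),
                                        f"src={gene.id}"))
            ridx += 1
    return reads


def simulate_clade_alignment(seed: int, n_per_clade: int = 5, length: int = 600,
                             between: float = 0.15, within: float = 0.01
                             ) -> list[SequenceRecord]:
    """Gap-free alignment of two deeply split clades (for bootstrap checks)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    anc = rng.integers(0, 4, size=length)

    def mutate(base: np.ndarray, rate: float) -> np.ndarray:
        out = base.copy()
        hit = rng.random(length) < rate
        out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        return out

    clade2 = mutate(anc, between)
    records = []
    for label, cons in (("cladeA", anc), ("cladeB", clade2)):
        for i in range(n_per_clade):
            seq = "".join(bases[mutate(cons, within)])
            records.append(SequenceRecord(f"{label}_{i}", seq))
    return records
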