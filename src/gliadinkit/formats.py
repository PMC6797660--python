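"""Readers/writers and shared record types used across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; GFF3 output
converts to the 1-based inclusive convention at the boundary and GFF3 input
converts back.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X")

FEATURE_KINDS = {"gene", "CDS", "TE", "polyQ_I", "polyQ_II", "epitope", "GLR"}

MUTATION_KINDS = {
    "stop_codon",
    "frameshift",
    "deletion_5prime",
    "deletion_3prime",
    "TE_insertion",
    "gap",
}


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence — the pipeline's currency."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    def validate_alphabet(self, mode: Literal["nucleotide", "protein"]) -> None:
        allowed = NUCLEOTIDE_ALPHABET if mode == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"not allowed in {mode} mode"
            )


@dataclass
class FeatureInterval:
    """Half-open interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "gene"
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, offset: int) -> "FeatureInterval":
        return FeatureInterval(
            self.seq_id, self.start + offset, self.end + offset,
            self.strand, self.kind, self.label,
        )


@dataclass
class GeneCatalogueRow:
    """One catalogue record: a gene, its lesions, and its status."""

    gene_id: str
    genome: str
    length_bp: int
    mutation_types: frozenset = frozenset()
    n_stop: int = 0
    n_stop_next_to_Q: int = 0

    def __post_init__(self) -> None:
        self.mutation_types = frozenset(self.mutation_types)
        unknown = self.mutation_types - MUTATION_KINDS
        if unknown:
            raise ValueError(f"unknown mutation kinds {sorted(unknown)}")
        if self.genome not in {"A", "B"}:
            raise ValueError(f"genome must be 'A' or 'B', got {self.genome!r}")
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if self.n_stop_next_to_Q > self.n_stop:
            raise ValueError(
                f"{self.gene_id}: n_stop_next_to_Q ({self.n_stop_next_to_Q}) "
                f"exceeds n_stop ({self.n_stop})"
            )

    @property
    def status(self) -> str:
        return "intact" if not self.mutation_types else "pseudogene"


def read_fasta(path, mode: Literal["nucleotide", "protein"] = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, order preserved)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        sr = SequenceRecord(rec.id, str(rec.seq), rec.description[len(rec.id):].strip())
        sr.validate_alphabet(mode)
        records.append(sr)
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_fastq(path) -> list[SequenceRecord]:
    """Read FASTQ reads (qualities are not used by the expression model)."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(SequenceRecord(rec.id, str(rec.seq)))
    return out


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    bio = []
    for r in records:
        b = _BioSeqRecord(Seq(r.seq), id=r.id, description="")
        b.letter_annotations["phred_quality"] = [40] * len(r.seq)
        bio.append(b)
    SeqIO.write(bio, str(path), "fastq")


# ---------------------------------------------------------------------------
# Catalogue TSV

_CATALOGUE_COLUMNS = [
    "gene_id", "genome", "length_bp", "mutation_types", "n_stop", "n_stop_next_to_Q",
]

# Printed-phrase vocabulary -> canonical mutation kinds. Matching is
# case-insensitive and tolerant of typographic prime variants.
_PHRASE_MAP = [
    ("both 5' and 3'", {"deletion_5prime", "deletion_3prime"}),
    ("5' end", {"deletion_5prime"}),
    ("3' end", {"deletion_3prime"}),
    ("te insertion", {"TE_insertion"}),
    ("stop codon", {"stop_codon"}),
    ("frameshift", {"frameshift"}),
    ("gap", {"gap"}),
]

_PRIME_VARIANTS = {"′": "'", "ʹ": "'", "´": "'", "`": "'"}


def parse_mutation_phrase(text: str) -> frozenset:
    """Normalize a printed-catalogue mutation phrase into canonical kinds.

    Accepts the printed phrases ("Frameshift and stop codon", "Deletion at
    5' end, frameshift, and gap", ...) as well as already-canonical
    keywords separated by ';' or ','. "Intact full-length" or an empty cell
    parses to the empty set. Unknown keywords raise ValueError.
    """
    t = text.strip()
    for variant, repl in _PRIME_VARIANTS.items():
        t = t.replace(variant, repl)
    if not t or t.lower().startswith("intact"):
        return frozenset()
    # Canonical keyword list?
    parts = [p.strip() for p in t.replace(";", ",").split(",") if p.strip()]
    if all(p in MUTATION_KINDS for p in parts):
        return frozenset(parts)
    low = t.lower()
    kinds: set[str] = set()
    consumed = False
    for phrase, mapped in _PHRASE_MAP:
        if phrase in low:
            kinds |= mapped
            consumed = True
            if phrase == "both 5' and 3'":
                low = low.replace(phrase, "")
    if not consumed:
        raise ValueError(f"unrecognized mutation description: {text!r}")
    # sanity: every word chunk must have been explicable
    leftovers = low
    for phrase, _ in _PHRASE_MAP:
        leftovers = leftovers.replace(phrase, "")
    for token in ("deletion at", "deletions at", "and", "ends", "end", ",", "s"):
        leftovers = leftovers.replace(token, " ")
    if leftovers.split():
        raise ValueError(
            f"unrecognized mutation keyword(s) {leftovers.split()} in {text!r}"
        )
    return frozenset(kinds)


def _format_mutation_types(kinds: frozenset) -> str:
    order = ["deletion_5prime", "deletion_3prime", "TE_insertion",
             "frameshift", "stop_codon", "gap"]
    return ";".join(k for k in order if k in kinds)


def read_catalogue_tsv(path) -> list[GeneCatalogueRow]:
    """Parse a gene catalogue TSV. Blank numeric cells read as 0."""
    rows: list[GeneCatalogueRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t", restval="")
        missing = set(_CATALOGUE_COLUMNS[:4]) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"catalogue is missing columns: {sorted(missing)}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                kinds = parse_mutation_phrase(rec.get("mutation_types") or "")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            rows.append(GeneCatalogueRow(
                gene_id=rec["gene_id"].strip(),
                genome=rec["genome"].strip(),
                length_bp=int(rec["length_bp"]),
                mutation_types=kinds,
                n_stop=int(rec.get("n_stop") or 0),
                n_stop_next_to_Q=int(rec.get("n_stop_next_to_Q") or 0),
            ))
    return rows


def write_catalogue_tsv(rows: Iterable[GeneCatalogueRow], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_CATALOGUE_COLUMNS + ["status"])
        for r in rows:
            w.writerow([
                r.gene_id, r.genome, r.length_bp,
                _format_mutation_types(r.mutation_types),
                r.n_stop, r.n_stop_next_to_Q, r.status,
            ])


def load_wild_emmer_catalogue() -> list[GeneCatalogueRow]:
    """The wild-emmer gene catalogue shipped with the package (40 genes)."""
    ref = resources.files("gliadinkit.data").joinpath("wild_emmer_catalogue.tsv")
    with resources.as_file(ref) as p:
        return read_catalogue_tsv(p)


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(features: Sequence[FeatureInterval], path,
               seq_lengths: dict[str, int] | None = None) -> None:
    """Write features as GFF3 (1-based inclusive on output)."""
    if seq_lengths is not None:
        for f in features:
            if f.seq_id not in seq_lengths or f.end > seq_lengths[f.seq_id]:
                raise ValueError(
                    f"feature {f.label or f.kind} [{f.start},{f.end}) out of "
                    f"bounds on {f.seq_id}"
                )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.label}" if f.label else "."
            fh.write("\t".join([
                f.seq_id, "gliadinkit", f.kind,
                str(f.start + 1), str(f.end), ".", f.strand, ".", attrs,
            ]) + "\n")


def read_gff3(path) -> list[FeatureInterval]:
    feats: list[FeatureInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            label = ""
            for kv in cols[8].split(";"):
                if kv.startswith("ID="):
                    label = kv[3:]
            feats.append(FeatureInterval(
                seq_id=cols[0], start=int(cols[3]) - 1, end=int(cols[4]),
                strand=cols[6] if cols[6] in "+-" else "+",
                kind=cols[2], label=label,
            ))
    return feats
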