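"""Celiac-disease T-cell epitope scanning of deduced prolamin proteins.

The scanner reports every 9-mer window within a configurable Hamming distance
of a known epitope, and flags 33-mer-like regions where six or more exact
hits from at least two distinct epitopes overlap — the hallmark of the highly
immunogenic α-gliadin 33-mer peptide.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .formats import FeatureInterval, SequenceRecord

EPITOPE_LEN = 9


@dataclass(frozen=True)
class EpitopeDefinition:
    name: str
    sequence: str
    hla_class: str = "DQ2.5"

    def __post_init__(self) -> None:
        if len(self.sequence) != EPITOPE_LEN:
            raise ValueError(f"{self.name}: epitope must be 9 residues")


# The four canonical DQ2.5 α-gliadin nine-mers. DQ8-class epitopes are taken
# from user configuration (load_epitope_config), not hard-coded.
DEFAULT_EPITOPES: tuple[EpitopeDefinition, ...] = (
    EpitopeDefinition("DQ2.5-Glia-alpha1a", "PFPQPQLPY"),
    EpitopeDefinition("DQ2.5-Glia-alpha1b", "PYPQPQLPY"),
    EpitopeDefinition("DQ2.5-Glia-alpha2", "PQPQLPYPQ"),
    EpitopeDefinition("DQ2.5-Glia-alpha3", "FRPQQPYPQ"),
)


@dataclass
class EpitopeHit:
    protein_id: str
    epitope_name: str
    start: int  # 0-based protein coordinate
    mismatches: int = 0
    mutated_residues: list = field(default_factory=list)  # (pos, ref_aa, obs_aa)


@dataclass
class ClusterCall:
    protein_id: str
    window: FeatureInterval
    n_overlapping_hits: int
    distinct_epitopes: frozenset


def load_epitope_config(path) -> list[EpitopeDefinition]:
    """Read epitope definitions from YAML/JSON: list of {name, sequence, class}."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [
        EpitopeDefinition(d["name"], d["sequence"].upper(), d.get("class", "DQ2.5"))
        for d in data
    ]


def scan_protein(protein: SequenceRecord,
                 epitopes: Sequence[EpitopeDefinition] = DEFAULT_EPITOPES,
                 max_mismatch: int = 0) -> list[EpitopeHit]:
    """All 9-mer windows within Hamming distance ≤ max_mismatch of an epitope.

    Overlapping occurrences (including of the same epitope) are each
    reported. Proteins shorter than 9 residues yield an empty list.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    seq = protein.seq
    hits: list[EpitopeHit] = []
    for start in range(len(seq) - EPITOPE_LEN + 1):
        window = seq[start:start + EPITOPE_LEN]
        for ep in epitopes:
            muts = [(i, r, o) for i, (r, o) in enumerate(zip(ep.sequence, window))
                    if r != o]
            if len(muts) <= max_mismatch:
                hits.append(EpitopeHit(
                    protein_id=protein.id, epitope_name=ep.name, start=start,
                    mismatches=len(muts), mutated_residues=muts,
                ))
    return hits


def detect_clusters(hits: Sequence[EpitopeHit], window_len: int = 33,
                    cluster_min_hits: int = 6, min_distinct: int = 2,
                    protein_len: int | None = None) -> list[ClusterCall]:
    """Maximal regions where ≥ cluster_min_hits exact hits overlap.

    A window of ≤ window_len residues qualifies when it fully contains
    ≥ cluster_min_hits exact hits from ≥ min_distinct distinct epitopes;
    overlapping qualifying windows are merged into one maximal call spanning
    the first to the last contained hit.
    """
    exact = sorted((h for h in hits if h.mismatches == 0), key=lambda h: h.start)
    if not exact:
        return []
    pid = exact[0].protein_id
    qualifying: list[tuple[int, int, int, frozenset]] = []
    for i in range(len(exact)):
        j = i
        while (j + 1 < len(exact)
               and exact[j + 1].start + EPITOPE_LEN - exact[i].start <= window_len):
            j += 1
        group = exact[i:j + 1]
        names = frozenset(h.epitope_name for h in group)
        if len(group) >= cluster_min_hits and len(names) >= min_distinct:
            qualifying.append((group[0].start, group[-1].start + EPITOPE_LEN,
                               len(group), names))
    calls: list[ClusterCall] = []
    for s, e, n, names in qualifying:
        if calls and s < calls[-1].window.end:
            prev = calls[-1]
            calls[-1] = ClusterCall(
                pid,
                FeatureInterval(pid, prev.window.start, max(prev.window.end, e),
                                "+", "epitope", "cluster"),
                max(prev.n_overlapping_hits, n),
                prev.distinct_epitopes | names,
            )
        else:
            calls.append(ClusterCall(
                pid, FeatureInterval(pid, s, e, "+", "epitope", "cluster"),
                n, names,
            ))
    return calls


def epitope_profile(proteins: Sequence[SequenceRecord],
                    epitopes: Sequence[EpitopeDefinition] = DEFAULT_EPITOPES,
                    cluster_kwargs: dict | None = None
                    ) -> tuple[pd.DataFrame, list[EpitopeHit]]:
    """Per-protein exact-hit counts per epitope plus a cluster flag.

    Returns (matrix, mismatch1_hits): the matrix holds exact counts; hits at
    Hamming distance 1 are returned separately as annotations.
    """
    cluster_kwargs = cluster_kwargs or {}
    rows = []
    near_hits: list[EpitopeHit] = []
    for prot in proteins:
        all_hits = scan_protein(prot, epitopes, max_mismatch=1)
        exact = [h for h in all_hits if h.mismatches == 0]
        near_hits.extend(h for h in all_hits if h.mismatches == 1)
        counts = {ep.name: 0 for ep in epitopes}
        for h in exact:
            counts[h.epitope_name] += 1
        counts["has_cluster"] = bool(detect_clusters(exact, **cluster_kwargs))
        rows.append(pd.Series(counts, name=prot.id))
    return pd.DataFrame(rows), near_hits


def hits_to_features(hits: Iterable[EpitopeHit]) -> list[FeatureInterval]:
    return [
        FeatureInterval(h.protein_id, h.start, h.start + EPITOPE_LEN, "+",
                        "epitope", h.epitope_name)
        for h in hits
    ]
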