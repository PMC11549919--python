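"""Majority-rule taxonomy transfer from per-protein reference hits.

Each vOTU protein inherits the lineage of its single top-scoring
reference hit (after coverage and E-value filtering); the vOTU is then
assigned to the deepest rank at which one taxon accounts for strictly
more than 70% of the annotated proteins.  Family- and genus-level
assignments additionally require AAI evidence against some reference
genome: at least two annotated proteins with mean AAI > 30% (family)
or at least three with mean AAI > 40% (genus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

RANKS = ("realm", "kingdom", "phylum", "class", "order", "family", "genus", "species")

MAJORITY = 0.70  # strict: a taxon must exceed this fraction

# rank -> (min annotated proteins, min mean AAI) for the evidence gate
_AAI_GATES = {"family": (2, 30.0), "genus": (3, 40.0)}


@dataclass(frozen=True)
class ProteinHit:
    protein_id: str
    reference_genome: str
    lineage: tuple[str, ...]  # aligned to RANKS; "" for unassigned ranks
    bitscore: float
    aai: float
    query_cover: float
    subject_cover: float
    evalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.query_cover <= 100 and 0 <= self.subject_cover <= 100):
            raise ValueError("covers must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if len(self.lineage) != len(RANKS):
            raise ValueError(f"lineage must have {len(RANKS)} ranks")


@dataclass(frozen=True)
class VotuTaxonomy:
    votu_id: str
    assigned_lineage: tuple[str, ...]  # empty when nothing qualifies
    rank: str | None
    support: float


def filter_hits(
    hits: Sequence[ProteinHit],
    min_query_cover: float = 50.0,
    min_subject_cover: float = 50.0,
    max_evalue: float = 1e-5,
) -> list[ProteinHit]:
    """Coverage/E-value filter, then the single top-bitscore hit per protein.

    Bitscore ties break toward the lexicographically smallest reference
    genome id, so the result is deterministic.
    """
    best: dict[str, ProteinHit] = {}
    for h in hits:
        if (
            h.query_cover < min_query_cover
            or h.subject_cover < min_subject_cover
            or h.evalue > max_evalue
        ):
            continue
        prev = best.get(h.protein_id)
        if (
            prev is None
            or h.bitscore > prev.bitscore
            or (h.bitscore == prev.bitscore and h.reference_genome < prev.reference_genome)
        ):
            best[h.protein_id] = h
    return [best[k] for k in sorted(best)]


def assign_votu_taxonomy(
    votu_id: str,
    per_protein_lineages: Sequence[tuple[str, ...]],
    aai_stats: Mapping[str, tuple[int, float]] | None = None,
) -> VotuTaxonomy:
    """Majority-rule rank walk with rank-specific AAI evidence gates.

    ``per_protein_lineages`` holds one lineage tuple per *annotated*
    protein (unannotated proteins are excluded from the denominator);
    ``aai_stats`` maps reference genome -> (n proteins aligned to it,
    mean AAI).  Walking from species toward realm, the first rank where
    one taxon exceeds 70% of annotated proteins — and, for family or
    genus, where the AAI gate is met — is assigned.
    """
    aai_stats = aai_stats or {}
    n = len(per_protein_lineages)
    if n == 0:
        return VotuTaxonomy(votu_id, (), None, 0.0)
    for depth in range(len(RANKS) - 1, -1, -1):
        rank = RANKS[depth]
        tally: dict[str, int] = {}
        for lin in per_protein_lineages:
            taxon = lin[depth]
            if taxon:
                tally[taxon] = tally.get(taxon, 0) + 1
        if not tally:
            continue
        taxon, count = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
        if count / n <= MAJORITY:
            continue
        if rank in _AAI_GATES:
            min_n, min_aai = _AAI_GATES[rank]
            if not any(
                np_ >= min_n and aai > min_aai for np_, aai in aai_stats.values()
            ):
                continue
        # assemble the consensus lineage down to the assigned rank from
        # the proteins that agree at that rank
        agreeing = [lin for lin in per_protein_lineages if lin[depth] == taxon]
        lineage = []
        for d in range(depth + 1):
            vals = {lin[d] for lin in agreeing if lin[d]}
            lineage.append(vals.pop() if len(vals) == 1 else "")
        return VotuTaxonomy(votu_id, tuple(lineage), rank, count / n)
    return VotuTaxonomy(votu_id, (), None, 0.0)
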