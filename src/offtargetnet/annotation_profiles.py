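"""Proteoform tallies and gene–disease association ranking.

A proteoform is any molecular form of a gene's protein product arising
from post-translational modification, allelic variation, or alternative
splicing; the per-protein proteoform count is the plain sum of the three
evidence sources.  PTM category breakdowns pool events over a protein set
and report per-category percentages rounded half-up to two decimals.
Disease rankings aggregate per-disease association scores across the
queried genes (max by default: one strong association should surface a
disease; mean available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from statistics import fmean
from typing import Iterable, Mapping

from .exceptions import UndefinedResultError, UsageError
from .io_core import PTM_CATEGORIES, DiseaseTable, ProteinID, ProteoformTable


@dataclass(frozen=True)
class PtmBreakdown:
    """Pooled PTM event counts and percentages per category.

    Counts sum to ``total_events``; percentages sum to 100 within the
    ±0.05-per-category tolerance introduced by two-decimal rounding.
    """

    counts: Mapping[str, int]
    percentages: Mapping[str, float]
    total_events: int


@dataclass(frozen=True)
class DiseaseAssociation:
    disease: str
    score: float
    genes: tuple[str, ...]


@dataclass(frozen=True)
class DiseaseRanking:
    """Diseases in descending aggregated-score order, ties broken by
    (score desc, disease label asc)."""

    entries: tuple[DiseaseAssociation, ...]

    def __post_init__(self) -> None:
        keys = [(-e.score, e.disease) for e in self.entries]
        if keys != sorted(keys):
            raise ValueError("disease ranking not in descending order")


def _round_half_up(value: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def proteoform_count(pf: ProteoformTable, protein: ProteinID) -> int:
    """PTM events + allelic variants + splice transcripts for one protein."""
    return pf.record(protein).total


def ptm_breakdown_from_counts(counts: Mapping[str, int]) -> PtmBreakdown:
    """Breakdown from an explicit category→count vector."""
    unknown = set(counts) - PTM_CATEGORIES
    if unknown:
        raise UsageError(f"unknown PTM categories: {sorted(unknown)}")
    clean = {c: int(v) for c, v in counts.items() if v}
    if any(v < 0 for v in clean.values()):
        raise UsageError("PTM counts must be non-negative")
    total = sum(clean.values())
    if total == 0:
        raise UndefinedResultError("no PTM events: breakdown undefined")
    percentages = {
        c: _round_half_up(100.0 * v / total) for c, v in sorted(clean.items())
    }
    return PtmBreakdown(counts=dict(sorted(clean.items())),
                        percentages=percentages, total_events=total)


def ptm_breakdown(pf: ProteoformTable, proteins: Iterable[ProteinID]) -> PtmBreakdown:
    """Pool PTM event categories over a protein set.

    Only PTM events enter the breakdown (allelic-variant and splice
    counts are separate evidence, not PTM categories).  Zero pooled
    events is undefined rather than an all-zero table.
    """
    protein_set = set(proteins)
    if not protein_set:
        raise UsageError("protein set is empty")
    counts: dict[str, int] = {}
    for p in sorted(protein_set):
        for cat, _ in pf.record(p).ptm_events:
            counts[cat] = counts.get(cat, 0) + 1
    return ptm_breakdown_from_counts(counts)


def top_diseases(
    dt: DiseaseTable,
    genes: Iterable[str],
    k: int = 10,
    aggregate: str = "max",
) -> DiseaseRanking:
    """Top-k diseases associated with a gene set.

    Per disease, the aggregated score is the max (default) or mean of the
    queried genes' scores.  Genes absent from the table contribute
    nothing; if none of the queried genes appear at all, an empty ranking
    is returned with a warning.
    """
    if k < 1:
        raise UsageError(f"k must be >= 1, got {k}")
    if aggregate not in ("max", "mean"):
        raise UsageError(f"unknown aggregation rule {aggregate!r}")
    gene_set = set(genes)
    rows = dt.rows_for(gene_set)
    if not rows:
        warnings.warn("none of the queried genes appear in the disease table",
                      stacklevel=2)
        return DiseaseRanking(entries=())
    per_disease: dict[str, list[tuple[str, float]]] = {}
    for r in rows:
        per_disease.setdefault(r.disease, []).append((r.gene, r.score))
    agg = max if aggregate == "max" else fmean
    entries = [
        DiseaseAssociation(
            disease=d,
            score=float(agg([s for _, s in pairs])),
            genes=tuple(sorted(g for g, _ in pairs)),
        )
        for d, pairs in per_disease.items()
    ]
    entries.sort(key=lambda e: (-e.score, e.disease))
    return DiseaseRanking(entries=tuple(entries[:k]))
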