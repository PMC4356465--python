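"""Host-read removal, threshold screening of homology hits, and read-to-gene
assignment.

All thresholds are strict inequalities: a hit survives the primary
translated-query screen only with E-value strictly below 1e-10, and the
sensitive protein-query re-screen additionally requires alignment length
strictly above 250 bp (amino-acid columns x 3) and identity strictly above
40%.  Boundary values are rejected.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formats import AlignmentHit, SearchType, SequenceRead, TaxonLineage

__all__ = [
    "SampleSummary",
    "GeneCount",
    "best_hit",
    "best_hits_per_query",
    "filter_host_reads",
    "screen_hits_blastx",
    "screen_hits_tblastn",
    "assign_read_genes",
    "assign_reads_to_genes",
    "sample_summary",
]

#: Default E-value cut-off applied to every homology screen.
EVALUE_CUTOFF = 1e-10
#: Minimum alignment span (bp) for the sensitive protein-query re-screen.
MIN_HIT_BP = 250
#: Minimum percent identity for the sensitive protein-query re-screen.
MIN_IDENTITY = 40.0
#: Clade whose best-nucleotide-hit reads are treated as host contamination.
HOST_LABEL = "Streptophyta"


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample sequencing summary: read count, total bases, floor-average
    read length, and the number of reads with at least one surviving
    protein-level hit."""

    sample_id: str
    total_reads: int
    total_bp: int
    avg_length_bp: int
    reads_with_similarity: int


@dataclass(frozen=True)
class GeneCount:
    sample_id: str
    gene_name: str
    read_count: int


def best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """The best hit for one query: maximum bitscore, ties broken by minimum
    E-value, then lexicographically smallest subject id.

    Raises if the hits do not all share one query id.
    """
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"best_hit called with mixed query ids: {sorted(queries)}")
    return min(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))


def best_hits_per_query(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Best hit for every query appearing in *hits*."""
    grouped: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        grouped[h.query_id].append(h)
    return {q: best_hit(hs) for q, hs in grouped.items()}  # type: ignore[misc]


def filter_host_reads(
    reads: Sequence[SequenceRead],
    nucl_hits: Iterable[AlignmentHit],
    taxon_map: Mapping[str, TaxonLineage],
    evalue_cutoff: float = EVALUE_CUTOFF,
    host_label: str = HOST_LABEL,
) -> tuple[list[SequenceRead], int]:
    """Remove reads whose best nucleotide-search hit maps to the host clade.

    A read is removed iff its best hit — among nucleotide hits with E-value
    strictly below *evalue_cutoff* — resolves to a lineage naming
    *host_label* at any rank.  Reads with no qualifying hit are retained.
    Returns (retained reads, removed count); counts always partition the
    input.
    """
    qualifying = [
        h
        for h in nucl_hits
        if h.search_type is SearchType.NUCL_NUCL and h.evalue < evalue_cutoff
    ]
    best = best_hits_per_query(qualifying)
    retained: list[SequenceRead] = []
    removed = 0
    for read in reads:
        hit = best.get(read.read_id)
        lineage = taxon_map.get(hit.subject_id) if hit is not None else None
        if lineage is not None and lineage.contains(host_label):
            removed += 1
        else:
            retained.append(read)
    return retained, removed


def screen_hits_blastx(
    hits: Iterable[AlignmentHit], evalue_cutoff: float = EVALUE_CUTOFF
) -> list[AlignmentHit]:
    """Primary screen of translated-query protein-database hits: keep hits
    with E-value strictly below the cut-off."""
    return [
        h
        for h in hits
        if h.search_type is SearchType.PROT_TRANSLATED and h.evalue < evalue_cutoff
    ]


def screen_hits_tblastn(
    hits: Iterable[AlignmentHit],
    evalue_cutoff: float = EVALUE_CUTOFF,
    min_hit_bp: int = MIN_HIT_BP,
    min_identity: float = MIN_IDENTITY,
) -> list[AlignmentHit]:
    """Sensitive protein-query re-screen: E-value strictly below the cut-off,
    alignment span strictly above *min_hit_bp* and identity strictly above
    *min_identity*.

    Alignment length for a protein query is in amino-acid columns; the bp
    threshold is applied to columns x 3, the only unit-consistent reading.
    """
    return [
        h
        for h in hits
        if h.search_type is SearchType.TRANSLATED_PROT
        and h.evalue < evalue_cutoff
        and h.alignment_length * 3 > min_hit_bp
        and h.percent_identity > min_identity
    ]


def assign_read_genes(
    screened_hits: Iterable[AlignmentHit],
    subject_to_gene: Mapping[str, str],
) -> dict[str, str]:
    """Map each hit-bearing read to the catalog gene of its best surviving
    hit.  Reads whose best hit resolves to no catalog gene are omitted."""
    best = best_hits_per_query(screened_hits)
    out: dict[str, str] = {}
    for query, hit in best.items():
        gene = subject_to_gene.get(hit.subject_id)
        if gene is not None:
            out[query] = gene
    return out


def assign_reads_to_genes(
    reads: Sequence[SequenceRead],
    screened_hits: Iterable[AlignmentHit],
    subject_to_gene: Mapping[str, str],
) -> list[GeneCount]:
    """Count reads per catalog gene per sample; each read counts once, toward
    the gene of its best surviving hit."""
    read_sample = {r.read_id: r.sample_id for r in reads}
    read_gene = assign_read_genes(screened_hits, subject_to_gene)
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for read_id, gene in read_gene.items():
        sample = read_sample.get(read_id)
        if sample is None:
            continue
        counts[(sample, gene)] += 1
    return [
        GeneCount(sample_id=s, gene_name=g, read_count=c)
        for (s, g), c in sorted(counts.items())
    ]


def sample_summary(
    reads: Sequence[SequenceRead], screened_hits: Iterable[AlignmentHit]
) -> SampleSummary:
    """Summarize one sample: totals, floor-average read length, and the count
    of reads with at least one surviving protein-level hit.

    Floor division for the average is the rule consistent with reporting
    whole base-pair-per-read values from exact totals.
    """
    sample_ids = {r.sample_id for r in reads}
    sample_id = sample_ids.pop() if len(sample_ids) == 1 else ",".join(sorted(sample_ids))
    total_reads = len(reads)
    total_bp = sum(r.length_bp for r in reads)
    avg = total_bp // total_reads if total_reads else 0
    read_ids = {r.read_id for r in reads}
    hit_bearing = {h.query_id for h in screened_hits} & read_ids
    return SampleSummary(
        sample_id=sample_id or "",
        total_reads=total_reads,
        total_bp=total_bp,
        avg_length_bp=avg,
        reads_with_similarity=len(hit_bearing),
    )
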