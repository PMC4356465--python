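"""Best-hit taxonomic assignment, rank-wise relative abundance with an
"Others" pool, Monte-Carlo rarefaction, and gene-by-genus cross-tabulation.

Percentages at a rank are computed over reads whose lineage names that rank
(unassigned reads and reads lacking the rank are excluded from the
denominator), so unrounded per-sample abundances always sum to exactly 100.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import RANKS, AlignmentHit, SequenceRead, TaxonLineage
from .frequency import aggregate_samples
from .screening import best_hits_per_query

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonAssignment",
    "AbundanceRow",
    "AbundanceTable",
    "assign_taxa",
    "relative_abundance",
    "rarefaction_curve",
    "pgpt_taxon_breakdown",
]


@dataclass(frozen=True)
class TaxonAssignment:
    read_id: str
    sample_id: str
    lineage: TaxonLineage | None  # None = unassigned


@dataclass(frozen=True)
class AbundanceRow:
    taxon_name: str
    per_sample_percent: dict[str, float]
    mean_percent: float
    sd_percent: float


@dataclass(frozen=True)
class AbundanceTable:
    rank: str
    rows: list[AbundanceRow]  # major taxa in rank order, then "Others"


def assign_taxa(
    reads: Sequence[SequenceRead],
    screened_hits: Iterable[AlignmentHit],
    taxon_map: Mapping[str, TaxonLineage],
) -> list[TaxonAssignment]:
    """Assign each hit-bearing read the lineage of its best surviving hit.

    Reads with no surviving hit, and reads whose best-hit subject is missing
    from the taxon map (warned), are left unassigned.
    """
    best = best_hits_per_query(screened_hits)
    unmapped = 0
    out: list[TaxonAssignment] = []
    for read in reads:
        hit = best.get(read.read_id)
        lineage: TaxonLineage | None = None
        if hit is not None:
            lineage = taxon_map.get(hit.subject_id)
            if lineage is None:
                unmapped += 1
        out.append(
            TaxonAssignment(read_id=read.read_id, sample_id=read.sample_id, lineage=lineage)
        )
    if unmapped:
        logger.warning(
            "%d hit-bearing reads had subjects missing from the taxon map; left unassigned",
            unmapped,
        )
    return out


def relative_abundance(
    assignments: Sequence[TaxonAssignment],
    rank: str,
    n_major: int = 3,
) -> AbundanceTable:
    """Rank-wise relative abundance (%) per sample, with the *n_major* taxa
    of highest mean abundance listed and the remainder pooled as "Others".

    Ties in the major-taxon ranking break lexicographically.
    """
    if rank not in RANKS:
        raise ValueError(f"unsupported rank {rank!r}")
    per_sample_counts: dict[str, Counter[str]] = defaultdict(Counter)
    for a in assignments:
        if a.lineage is None:
            continue
        name = a.lineage.name_at(rank)
        if name is None:
            continue
        per_sample_counts[a.sample_id][name] += 1
    if not per_sample_counts:
        raise ValueError(f"no assignment carries rank {rank!r}")
    samples = sorted(per_sample_counts)
    taxa = sorted({t for c in per_sample_counts.values() for t in c})
    percent: dict[str, dict[str, float]] = {}
    for t in taxa:
        percent[t] = {
            s: 100.0 * per_sample_counts[s][t] / sum(per_sample_counts[s].values())
            for s in samples
        }
    mean_of = {t: sum(percent[t].values()) / len(samples) for t in taxa}
    ranked = sorted(taxa, key=lambda t: (-mean_of[t], t))
    major = ranked[:n_major]
    rows: list[AbundanceRow] = []
    for t in major:
        mean, sd = aggregate_samples(percent[t])
        rows.append(
            AbundanceRow(taxon_name=t, per_sample_percent=percent[t], mean_percent=mean, sd_percent=sd)
        )
    others = {
        s: 100.0 - sum(percent[t][s] for t in major) for s in samples
    }
    o_mean, o_sd = aggregate_samples(others)
    rows.append(
        AbundanceRow(taxon_name="Others", per_sample_percent=others, mean_percent=o_mean, sd_percent=o_sd)
    )
    return AbundanceTable(rank=rank, rows=rows)


def rarefaction_curve(
    assignments: Sequence[TaxonAssignment],
    depths: Sequence[int],
    replicates: int = 50,
    seed: int = 0,
    rank: str = "genus",
) -> dict[int, tuple[float, float]]:
    """Expected taxon richness at each subsampling depth by Monte Carlo.

    Reads assigned at *rank* are subsampled without replacement *replicates*
    times per depth; the mean and population SD of the distinct-taxon count
    are returned.  Deterministic given *seed*.
    """
    labels = [
        a.lineage.name_at(rank)
        for a in assignments
        if a.lineage is not None and a.lineage.name_at(rank) is not None
    ]
    n = len(labels)
    label_arr = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    out: dict[int, tuple[float, float]] = {}
    for depth in depths:
        if depth > n:
            raise ValueError(f"depth {depth} exceeds assigned read count {n}")
        if depth == n:
            out[depth] = (float(len(set(labels))), 0.0)
            continue
        richness = np.empty(replicates)
        for i in range(replicates):
            idx = rng.choice(n, size=depth, replace=False)
            richness[i] = len(set(label_arr[idx]))
        out[depth] = (float(richness.mean()), float(richness.std()))
    return out


def pgpt_taxon_breakdown(
    read_genes: Mapping[str, str],
    assignments: Sequence[TaxonAssignment],
    rank: str = "genus",
) -> dict[str, Counter]:
    """Cross-tabulate catalog genes against taxa at *rank*.

    *read_genes* maps read id -> gene name (best surviving hit); reads
    without a lineage at the rank are tallied under "unassigned".  Row sums
    equal each gene's total counted reads.
    """
    lineage_of = {a.read_id: a.lineage for a in assignments}
    table: dict[str, Counter] = defaultdict(Counter)
    for read_id, gene in read_genes.items():
        lineage = lineage_of.get(read_id)
        name = lineage.name_at(rank) if lineage is not None else None
        table[gene][name or "unassigned"] += 1
    return dict(table)


def abundance_to_tsv(table: AbundanceTable) -> str:
    samples = sorted(table.rows[0].per_sample_percent) if table.rows else []
    header = ["rank", "taxon", *samples, "mean", "sd"]
    lines = ["\t".join(header)]
    for row in table.rows:
        cells = [table.rank, row.taxon_name]
        cells += [f"{row.per_sample_percent[s]:.4f}" for s in samples]
        cells += [f"{row.mean_percent:.4f}", f"{row.sd_percent:.4f}"]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
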