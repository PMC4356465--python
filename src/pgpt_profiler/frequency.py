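"""Gene-length-normalized detection frequency per 10^5 reads.

The central statistic: for one gene in one sample,

    frequency = (reads assigned to the gene / gene length in kbp)
                x (100,000 / total reads in the sample)

Frequencies are computed per sample from that sample's own read total and
then aggregated across samples as mean +/- sample standard deviation
(n-1 denominator).  Category totals are sums of *unrounded* member
frequencies; display rounding is applied only at rendering time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formats import GeneTarget
from .screening import GeneCount

__all__ = [
    "FrequencyRecord",
    "CategorySummary",
    "detection_frequency",
    "aggregate_samples",
    "compute_frequency_records",
    "category_totals",
    "format_value",
    "render_frequency_table",
]


@dataclass(frozen=True)
class FrequencyRecord:
    gene_name: str
    category: str
    per_sample_frequency: dict[str, float]
    mean: float
    sd: float


@dataclass(frozen=True)
class CategorySummary:
    category: str
    per_sample_total: dict[str, float]
    mean: float
    sd: float


def detection_frequency(
    read_count: int, gene_length_kbp: float, total_reads: int
) -> float:
    """Detection frequency of one gene in one sample, per 10^5 reads.

    Zero iff *read_count* is zero; linear in the read count and inversely
    proportional to both gene length and sequencing depth.
    """
    if gene_length_kbp <= 0:
        raise ValueError(f"gene_length_kbp must be positive, got {gene_length_kbp}")
    if total_reads <= 0:
        raise ValueError(f"total_reads must be positive, got {total_reads}")
    if read_count < 0:
        raise ValueError(f"read_count must be nonnegative, got {read_count}")
    return (read_count / gene_length_kbp) * (100_000 / total_reads)


def aggregate_samples(per_sample: Mapping[str, float] | Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) across samples."""
    values = list(per_sample.values()) if isinstance(per_sample, Mapping) else list(per_sample)
    n = len(values)
    if n < 2:
        raise ValueError(f"aggregate_samples needs >= 2 samples, got {n}")
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def compute_frequency_records(
    gene_counts: Iterable[GeneCount],
    catalog: Sequence[GeneTarget],
    total_reads_per_sample: Mapping[str, int],
) -> list[FrequencyRecord]:
    """Per-gene frequency records across samples, in catalog order.

    Genes with no counted reads in a sample get frequency 0 there; every
    catalog gene yields a record, so undetected genes appear explicitly.
    """
    count_lookup: dict[tuple[str, str], int] = {}
    for gc in gene_counts:
        count_lookup[(gc.sample_id, gc.gene_name)] = gc.read_count
    samples = sorted(total_reads_per_sample)
    records: list[FrequencyRecord] = []
    for gene in catalog:
        per_sample = {
            s: detection_frequency(
                count_lookup.get((s, gene.gene_name), 0),
                gene.length_kbp,
                total_reads_per_sample[s],
            )
            for s in samples
        }
        mean, sd = aggregate_samples(per_sample)
        records.append(
            FrequencyRecord(
                gene_name=gene.gene_name,
                category=gene.category,
                per_sample_frequency=per_sample,
                mean=mean,
                sd=sd,
            )
        )
    return records


def category_totals(records: Sequence[FrequencyRecord]) -> list[CategorySummary]:
    """Per-category totals over unrounded member frequencies.

    The category mean equals the sum of member means (additivity); standard
    deviations are recomputed from the per-sample totals, never summed.
    """
    by_cat: dict[str, list[FrequencyRecord]] = {}
    gene_seen: dict[str, str] = {}
    for rec in records:
        prev = gene_seen.get(rec.gene_name)
        if prev is not None and prev != rec.category:
            raise ValueError(
                f"gene {rec.gene_name!r} appears in categories {prev!r} and "
                f"{rec.category!r}"
            )
        gene_seen[rec.gene_name] = rec.category
        by_cat.setdefault(rec.category, []).append(rec)
    out: list[CategorySummary] = []
    for cat, members in by_cat.items():
        samples = sorted(members[0].per_sample_frequency)
        totals = {
            s: sum(m.per_sample_frequency[s] for m in members) for s in samples
        }
        mean, sd = aggregate_samples(totals)
        out.append(CategorySummary(category=cat, per_sample_total=totals, mean=mean, sd=sd))
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def format_value(v: float) -> str:
    """Display rounding: values >= 1 to the nearest integer (half away from
    zero), values below 1 to one decimal place."""
    if v >= 1:
        return str(_round_half_away(v))
    return f"{v:.1f}"


def format_mean_sd(mean: float, sd: float) -> str:
    return f"{format_value(mean)}±{format_value(sd)}"


def render_frequency_table(
    records: Sequence[FrequencyRecord],
    summaries: Sequence[CategorySummary],
) -> str:
    """Render a human-readable TSV: one bold-style category row (total) then
    member genes, with mean+/-SD display values and "ND" for genes never
    detected in any sample."""
    by_cat: dict[str, list[FrequencyRecord]] = {}
    for rec in records:
        by_cat.setdefault(rec.category, []).append(rec)
    sum_lookup = {s.category: s for s in summaries}
    lines = ["category\tgene_name\tfrequency_per_1e5_reads"]
    for cat in by_cat:
        members = by_cat[cat]
        summary = sum_lookup.get(cat)
        detected = [m for m in members if any(v > 0 for v in m.per_sample_frequency.values())]
        if summary is not None:
            cat_cell = (
                format_mean_sd(summary.mean, summary.sd) if detected else "ND"
            )
            lines.append(f"{cat}\t\t{cat_cell}")
        for m in members:
            if all(v == 0 for v in m.per_sample_frequency.values()):
                cell = "ND"
            else:
                cell = format_mean_sd(m.mean, m.sd)
            lines.append(f"{cat}\t{m.gene_name}\t{cell}")
    return "\n".join(lines) + "\n"


def records_to_tsv(records: Sequence[FrequencyRecord]) -> str:
    """Machine-readable companion table with unrounded values."""
    if not records:
        return "gene_name\tcategory\tmean\tsd\n"
    samples = sorted(records[0].per_sample_frequency)
    header = ["gene_name", "category", *samples, "mean", "sd"]
    lines = ["\t".join(header)]
    for r in records:
        row = [r.gene_name, r.category]
        row += [f"{r.per_sample_frequency[s]:.6f}" for s in samples]
        row += [f"{r.mean:.6f}", f"{r.sd:.6f}"]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
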