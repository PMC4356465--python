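"""Packaged reference tables.

Three small TSVs ship with the package: the curated trait-gene catalog
(KEGG orthology ids, UniRef representatives, approximate gene lengths in
kbp, trait categories), the per-sample sequencing statistics of the
emulated survey, and the delta-15N summary statistics of its 15N2 exposure
experiment.  They serve as worked-example inputs and as fixtures for the
arithmetic that is reproducible without the raw reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .formats import GeneTarget, read_gene_catalog
from .isotope_stats import IsotopeGroup

__all__ = [
    "load_gene_catalog",
    "load_sample_read_stats",
    "load_isotope_groups",
    "pool_read_stats",
    "SampleReadStats",
]


@dataclass(frozen=True)
class SampleReadStats:
    sample_id: str
    total_reads: int
    total_bp: int
    nr_similar_reads: int


def _data_path(name: str):
    return resources.files("pgpt_profiler.data").joinpath(name)


def load_gene_catalog() -> list[GeneTarget]:
    """The curated trait-gene catalog."""
    with resources.as_file(_data_path("pgpt_gene_catalog.tsv")) as path:
        return read_gene_catalog(path)


def load_sample_read_stats() -> list[SampleReadStats]:
    """Per-sample read counts, total bases and protein-similarity counts."""
    out: list[SampleReadStats] = []
    text = _data_path("sample_read_stats.tsv").read_text()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        sample, reads, bp, similar = line.split("\t")
        out.append(
            SampleReadStats(
                sample_id=sample,
                total_reads=int(reads),
                total_bp=int(bp),
                nr_similar_reads=int(similar),
            )
        )
    return out


def pool_read_stats(stats: list[SampleReadStats]) -> dict:
    """Pooled sequencing summary over samples.

    Floor division for the average length (whole bp/read from exact
    totals); the protein-similarity percentage is reported on the 0-100
    scale.
    """
    pooled_reads = sum(s.total_reads for s in stats)
    pooled_bp = sum(s.total_bp for s in stats)
    pooled_similar = sum(s.nr_similar_reads for s in stats)
    return {
        "total_reads": pooled_reads,
        "total_bp": pooled_bp,
        "avg_length_bp": pooled_bp // pooled_reads if pooled_reads else 0,
        "avg_length_per_sample": {
            s.sample_id: s.total_bp // s.total_reads for s in stats
        },
        "nr_similar_reads": pooled_similar,
        "percent_similar": 100.0 * pooled_similar / pooled_reads if pooled_reads else 0.0,
    }


def load_isotope_groups() -> dict[str, IsotopeGroup]:
    """Delta-15N summary statistics per treatment group (per mil)."""
    out: dict[str, IsotopeGroup] = {}
    text = _data_path("isotope_delta15n.tsv").read_text()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        label, mean, sd, n = line.split("\t")
        out[label] = IsotopeGroup(label=label, mean=float(mean), sd=float(sd), n=int(n))
    return out
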