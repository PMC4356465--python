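"""Synthetic metagenome generator with ground-truth labels.

Emulates the sampling frame of a small pyrosequencing survey of a
root-associated bacterial community: three composite samples, tens of
thousands of reads each, mean read length ~645 bp, ~2% host-plant
contamination, and a homology hit table in which roughly half of all reads
find a protein-level match.  Reads are drawn from mock gene families carried
by a handful of genera; every read carries a truth record, so downstream
screening, frequency and taxonomy stages can be checked against the
generative parameters.

Sequence content is random (alignment realism is out of scope — the
pipeline consumes hit tables, not alignments); what is faithful is the
*statistical* structure: best hits point to the true origin, decoy hits are
strictly worse, host reads are flagged only through their nucleotide-level
best hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats import (
    AlignmentHit,
    GeneTarget,
    SearchType,
    SequenceRead,
    TaxonLineage,
    write_fasta,
    write_gene_catalog,
    write_hit_table,
    write_taxon_map,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "ReferenceDB",
    "generate_reference_db",
    "simulate_reads",
    "simulate_hit_tables",
    "simulate_mdh_reference_set",
    "mutate_sequence",
    "random_protein",
    "write_simulation",
    "HOST_SUBJECT",
    "HOST_LINEAGE",
]

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_NT = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Subject id standing in for the host-plant genome in nucleotide searches.
HOST_SUBJECT = "host|BetaVulgaris"
HOST_LINEAGE = TaxonLineage((("phylum", "Streptophyta"),))

# Mock community defaults: genera dominant in root-associated communities,
# with plausible five-rank lineages.
_DEFAULT_LINEAGES: dict[str, TaxonLineage] = {
    "Mesorhizobium": TaxonLineage(
        (
            ("phylum", "Proteobacteria"),
            ("class", "Alphaproteobacteria"),
            ("order", "Rhizobiales"),
            ("family", "Phyllobacteriaceae"),
            ("genus", "Mesorhizobium"),
        )
    ),
    "Bradyrhizobium": TaxonLineage(
        (
            ("phylum", "Proteobacteria"),
            ("class", "Alphaproteobacteria"),
            ("order", "Rhizobiales"),
            ("family", "Bradyrhizobiaceae"),
            ("genus", "Bradyrhizobium"),
        )
    ),
    "Streptomyces": TaxonLineage(
        (
            ("phylum", "Actinobacteria"),
            ("class", "Actinobacteria"),
            ("order", "Actinomycetales"),
            ("family", "Streptomycetaceae"),
            ("genus", "Streptomyces"),
        )
    ),
    "Sphingomonas": TaxonLineage(
        (
            ("phylum", "Proteobacteria"),
            ("class", "Alphaproteobacteria"),
            ("order", "Sphingomonadales"),
            ("family", "Sphingomonadaceae"),
            ("genus", "Sphingomonas"),
        )
    ),
    "Rhizobium": TaxonLineage(
        (
            ("phylum", "Proteobacteria"),
            ("class", "Alphaproteobacteria"),
            ("order", "Rhizobiales"),
            ("family", "Rhizobiaceae"),
            ("genus", "Rhizobium"),
        )
    ),
    "Methylobacterium": TaxonLineage(
        (
            ("phylum", "Proteobacteria"),
            ("class", "Alphaproteobacteria"),
            ("order", "Rhizobiales"),
            ("family", "Methylobacteriaceae"),
            ("genus", "Methylobacterium"),
        )
    ),
}

# Free parameters of the mock community (true gene abundances are never
# reported for real data, only observed frequencies; these weights merely
# span two orders of magnitude so that recovery tests exercise both common
# and rare genes).
_DEFAULT_GENE_WEIGHTS: dict[str, float] = {
    "beta13_glucanase": 18.0,
    "gdh": 15.0,
    "pchB": 10.0,
    "acc_deaminase": 9.0,
    "chitinase": 6.0,
    "proX": 25.0,
    "iaaM": 0.7,
    "ipdC": 0.8,
}

_DEFAULT_GENE_CATEGORIES: dict[str, str] = {
    "beta13_glucanase": "Plant disease suppression",
    "chitinase": "Plant disease suppression",
    "gdh": "Phosphate solubilization",
    "pchB": "Siderophore",
    "acc_deaminase": "ACC deaminase",
    "proX": "Betaine utilization",
    "iaaM": "IAA",
    "ipdC": "IAA",
}

_DEFAULT_TAXON_WEIGHTS: dict[str, float] = {
    "Mesorhizobium": 14.0,
    "Bradyrhizobium": 11.0,
    "Streptomyces": 9.0,
    "Sphingomonas": 6.0,
    "Rhizobium": 5.0,
    "Methylobacterium": 3.0,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic survey.

    Defaults mirror the emulated study: 3 composite samples, mean read
    length 645 bp, ~2% host-origin reads, and a 54% protein-level hit rate.
    """

    n_samples: int = 3
    reads_per_sample: int = 60_000
    read_length_mean_bp: float = 645.0
    read_length_sd_bp: float = 130.0
    host_fraction: float = 0.02
    gene_abundance_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GENE_WEIGHTS)
    )
    gene_categories: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_GENE_CATEGORIES)
    )
    taxon_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TAXON_WEIGHTS)
    )
    taxon_lineages: dict[str, TaxonLineage] = field(
        default_factory=lambda: dict(_DEFAULT_LINEAGES)
    )
    hit_rate: float = 0.54
    decoy_hit_rate: float = 0.3
    identity_mean: float = 70.0
    identity_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("host_fraction", self.host_fraction),
            ("hit_rate", self.hit_rate),
            ("decoy_hit_rate", self.decoy_hit_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_samples < 1 or self.reads_per_sample < 0:
            raise ValueError("n_samples must be >= 1 and reads_per_sample >= 0")
        for label, weights in (
            ("gene_abundance_weights", self.gene_abundance_weights),
            ("taxon_weights", self.taxon_weights),
        ):
            if not weights:
                raise ValueError(f"{label} is empty")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{label} has negative weights")
            if not any(w > 0 for w in weights.values()):
                raise ValueError(f"{label} has no positive weight")
        for genus in self.taxon_weights:
            if genus not in self.taxon_lineages:
                raise ValueError(f"genus {genus!r} has no lineage")

    @property
    def sample_ids(self) -> list[str]:
        return [f"sample{i + 1}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    origin: str  # "gene" | "host" | "background"
    origin_gene: str = ""
    origin_taxon: TaxonLineage | None = None


@dataclass
class ReferenceDB:
    """Mock reference database: catalog, one protein per (gene, genus) pair,
    a subject->gene map and a subject->lineage map (including the host)."""

    catalog: list[GeneTarget]
    subject_seqs: dict[str, str]
    subject_to_gene: dict[str, str]
    taxon_map: dict[str, TaxonLineage]


def random_protein(rng: np.random.Generator, length: int) -> str:
    return bytes(_AA[rng.integers(0, len(_AA), size=length)]).decode()


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return bytes(_NT[rng.integers(0, 4, size=length)]).decode()


def generate_reference_db(cfg: SimulationConfig) -> ReferenceDB:
    """One mock protein per (gene, genus) pair.

    All subjects of a gene share one length drawn once per gene; the catalog
    length in kbp is 3 x amino acids / 1000 rounded to 3 decimals, so
    catalog lengths and emitted sequences are always consistent.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    genes = sorted(cfg.gene_abundance_weights)
    genera = sorted(cfg.taxon_weights)
    catalog: list[GeneTarget] = []
    subject_seqs: dict[str, str] = {}
    subject_to_gene: dict[str, str] = {}
    taxon_map: dict[str, TaxonLineage] = {HOST_SUBJECT: HOST_LINEAGE}
    for gene in genes:
        aa_len = int(rng.integers(250, 451))
        catalog.append(
            GeneTarget(
                gene_name=gene,
                ko_id=f"K{rng.integers(0, 100000):05d}",
                uniref_id=f"UniRef50_MOCK_{gene}",
                length_kbp=round(3 * aa_len / 1000, 3),
                category=cfg.gene_categories.get(gene, "Uncategorized"),
            )
        )
        for genus in genera:
            subject = f"{gene}|{genus}"
            subject_seqs[subject] = random_protein(rng, aa_len)
            subject_to_gene[subject] = gene
            taxon_map[subject] = cfg.taxon_lineages[genus]
    return ReferenceDB(
        catalog=catalog,
        subject_seqs=subject_seqs,
        subject_to_gene=subject_to_gene,
        taxon_map=taxon_map,
    )


def simulate_reads(
    refdb: ReferenceDB, cfg: SimulationConfig
) -> tuple[dict[str, list[SequenceRead]], list[TruthRecord]]:
    """Draw reads per sample with truth labels.

    Each read is host-derived with probability ``host_fraction``, otherwise
    gene-derived with gene and genus drawn from the configured weights.
    Lengths are Normal(mean, sd) truncated to [100, 1200] bp and rounded.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    genes = sorted(cfg.gene_abundance_weights)
    gene_p = np.array([cfg.gene_abundance_weights[g] for g in genes], dtype=float)
    gene_p /= gene_p.sum()
    genera = sorted(cfg.taxon_weights)
    taxon_p = np.array([cfg.taxon_weights[g] for g in genera], dtype=float)
    taxon_p /= taxon_p.sum()

    reads: dict[str, list[SequenceRead]] = {}
    truth: list[TruthRecord] = []
    for sample in cfg.sample_ids:
        n = cfg.reads_per_sample
        is_host = rng.random(n) < cfg.host_fraction
        gene_idx = rng.choice(len(genes), size=n, p=gene_p)
        taxon_idx = rng.choice(len(genera), size=n, p=taxon_p)
        lengths = rng.normal(cfg.read_length_mean_bp, cfg.read_length_sd_bp, size=n)
        lengths = np.clip(np.rint(lengths), 100, 1200).astype(int)
        sample_reads: list[SequenceRead] = []
        for i in range(n):
            read_id = f"{sample}_r{i:06d}"
            seq = _random_dna(rng, int(lengths[i]))
            sample_reads.append(
                SequenceRead(
                    read_id=read_id,
                    sample_id=sample,
                    sequence=seq,
                    length_bp=int(lengths[i]),
                )
            )
            if is_host[i]:
                truth.append(
                    TruthRecord(read_id=read_id, origin="host", origin_taxon=HOST_LINEAGE)
                )
            else:
                gene = genes[gene_idx[i]]
                genus = genera[taxon_idx[i]]
                truth.append(
                    TruthRecord(
                        read_id=read_id,
                        origin="gene",
                        origin_gene=gene,
                        origin_taxon=cfg.taxon_lineages[genus],
                    )
                )
        reads[sample] = sample_reads
    return reads, truth


def _bitscore(evalue: float) -> float:
    # any strictly decreasing map of the E-value works downstream
    return float(-2.0 * np.log10(evalue) + 40.0)


def simulate_hit_tables(
    reads: Mapping[str, Sequence[SequenceRead]],
    truth: Sequence[TruthRecord],
    refdb: ReferenceDB,
    cfg: SimulationConfig,
) -> dict[str, list[AlignmentHit]]:
    """Per-sample hit tables (nucleotide- and protein-level hits mixed;
    hits carry their search type).

    Gene-origin reads receive, with probability ``hit_rate``, a true-origin
    best hit (log-uniform E-value in [1e-60, 1e-12]) and possibly decoy
    hits to random other subjects with strictly larger E-values and strictly
    lower bitscores.  Host reads receive a nucleotide-search hit to the host
    subject.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    truth_by_read = {t.read_id: t for t in truth}
    subjects = sorted(refdb.subject_seqs)
    out: dict[str, list[AlignmentHit]] = {}
    for sample, sample_reads in reads.items():
        hits: list[AlignmentHit] = []
        for read in sample_reads:
            rec = truth_by_read[read.read_id]
            if rec.origin == "host":
                evalue = 10.0 ** rng.uniform(-80, -30)
                aln = max(50, int(read.length_bp * rng.uniform(0.8, 1.0)))
                hits.append(
                    AlignmentHit(
                        query_id=read.read_id,
                        subject_id=HOST_SUBJECT,
                        percent_identity=float(np.clip(rng.normal(97, 1.5), 80, 100)),
                        alignment_length=aln,
                        mismatches=int(aln * 0.02),
                        gap_opens=0,
                        qstart=1,
                        qend=aln,
                        sstart=1,
                        send=aln,
                        evalue=evalue,
                        bitscore=_bitscore(evalue),
                        search_type=SearchType.NUCL_NUCL,
                    )
                )
                continue
            if rec.origin != "gene" or rng.random() >= cfg.hit_rate:
                continue
            genus = rec.origin_taxon.name_at("genus") if rec.origin_taxon else None
            subject = f"{rec.origin_gene}|{genus}"
            evalue = 10.0 ** rng.uniform(-60, -12)
            identity = float(np.clip(rng.normal(cfg.identity_mean, cfg.identity_sd), 20, 100))
            aln = max(30, int(round(read.length_bp / 3)))
            mismatches = int(round(aln * (100 - identity) / 100))
            hits.append(
                AlignmentHit(
                    query_id=read.read_id,
                    subject_id=subject,
                    percent_identity=identity,
                    alignment_length=aln,
                    mismatches=mismatches,
                    gap_opens=0,
                    qstart=1,
                    qend=aln * 3,
                    sstart=1,
                    send=aln,
                    evalue=evalue,
                    bitscore=_bitscore(evalue),
                    search_type=SearchType.PROT_TRANSLATED,
                )
            )
            if rng.random() < cfg.decoy_hit_rate:
                for _ in range(int(rng.integers(1, 4))):
                    decoy_subject = subjects[int(rng.integers(0, len(subjects)))]
                    if decoy_subject == subject:
                        continue
                    decoy_evalue = min(evalue * 10.0 ** rng.uniform(2, 10), 1e-3)
                    decoy_evalue = max(decoy_evalue, evalue * 100)
                    hits.append(
                        AlignmentHit(
                            query_id=read.read_id,
                            subject_id=decoy_subject,
                            percent_identity=float(
                                np.clip(rng.normal(cfg.identity_mean - 20, cfg.identity_sd), 20, 100)
                            ),
                            alignment_length=aln,
                            mismatches=int(aln * 0.5),
                            gap_opens=0,
                            qstart=1,
                            qend=aln * 3,
                            sstart=1,
                            send=aln,
                            evalue=decoy_evalue,
                            bitscore=_bitscore(decoy_evalue),
                            search_type=SearchType.PROT_TRANSLATED,
                        )
                    )
        out[sample] = hits
    return out


# ---------------------------------------------------------------------------
# Mock methanol-dehydrogenase reference sets for the typing stage


def mutate_sequence(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability *divergence*
    (always to a different residue)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < divergence
    for i in np.nonzero(hit)[0]:
        choices = _AA[_AA != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_mdh_reference_set(
    seed: int = 0,
    n_refs_per_type: int = 4,
    n_outgroups: int = 2,
    aln_len: int = 150,
    within_type_divergence: float = 0.05,
    between_type_divergence: float = 0.4,
    outgroup_divergence: float = 0.65,
) -> tuple[dict[str, tuple[str, str]], dict[str, str]]:
    """Aligned mock reference families for the two MDH gene types.

    Returns ``(refs, outgroups)`` where refs maps label -> (sequence,
    type name "xoxF" or "mxaF").  The two type prototypes sit
    *between_type_divergence* apart; outgroup sequences are far from both.
    """
    rng = np.random.default_rng([seed, 3])
    xox_proto = random_protein(rng, aln_len)
    mxa_proto = mutate_sequence(xox_proto, between_type_divergence, rng)
    out_proto = mutate_sequence(xox_proto, outgroup_divergence, rng)
    refs: dict[str, tuple[str, str]] = {}
    for i in range(n_refs_per_type):
        refs[f"xoxF_ref{i + 1}"] = (
            mutate_sequence(xox_proto, within_type_divergence, rng),
            "xoxF",
        )
        refs[f"mxaF_ref{i + 1}"] = (
            mutate_sequence(mxa_proto, within_type_divergence, rng),
            "mxaF",
        )
    outgroups = {
        f"outgroup{i + 1}": mutate_sequence(out_proto, within_type_divergence, rng)
        for i in range(n_outgroups)
    }
    return refs, outgroups


# ---------------------------------------------------------------------------
# Serialization of a full simulation


def write_simulation(
    outdir: str | Path,
    refdb: ReferenceDB,
    reads: Mapping[str, Sequence[SequenceRead]],
    truth: Sequence[TruthRecord],
    hit_tables: Mapping[str, Sequence[AlignmentHit]],
) -> None:
    """Write reads (FASTA), hit tables (12-column TSV), truth, catalog and
    taxon map under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, sample_reads in reads.items():
        write_fasta(((r.read_id, r.sequence) for r in sample_reads), outdir / f"{sample}.fasta")
    for sample, hits in hit_tables.items():
        write_hit_table(
            [h for h in hits if h.search_type is SearchType.PROT_TRANSLATED],
            outdir / f"{sample}.prot_hits.tsv",
        )
        write_hit_table(
            [h for h in hits if h.search_type is SearchType.NUCL_NUCL],
            outdir / f"{sample}.nucl_hits.tsv",
        )
    write_gene_catalog(refdb.catalog, outdir / "catalog.tsv")
    write_taxon_map(refdb.taxon_map, outdir / "taxon_map.tsv")
    with open(outdir / "subject_to_gene.tsv", "w") as fh:
        for subject in sorted(refdb.subject_to_gene):
            fh.write(f"{subject}\t{refdb.subject_to_gene[subject]}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("read_id\torigin\torigin_gene\torigin_taxon\n")
        for t in truth:
            lineage = t.origin_taxon.to_string() if t.origin_taxon else ""
            fh.write(f"{t.read_id}\t{t.origin}\t{t.origin_gene}\t{lineage}\n")
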