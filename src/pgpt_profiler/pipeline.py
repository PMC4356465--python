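"""End-to-end orchestration: host filtering -> screening -> frequencies ->
taxonomy -> MDH typing -> isotope test, with a run manifest.

The pipeline runs either on real input files or entirely on synthetic data
(demo mode).  Every stage's thresholds default to the screening constants;
all randomness flows from one seed, so re-running a configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import frequency as freq
from . import screening, taxonomy
from .formats import (
    AlignmentHit,
    SearchType,
    SequenceRead,
    read_fasta,
    read_gene_catalog,
    read_hit_table,
    read_taxon_map,
    write_newick,
)
from .isotope_stats import IsotopeGroup, TTestVariant, significance_call, t_test
from .mdh_typing import Role, summarize_calls, type_all_with_trees
from .synthetic import (
    ReferenceDB,
    SimulationConfig,
    generate_reference_db,
    simulate_hit_tables,
    simulate_reads,
    write_simulation,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of synthetic mode (``simulation`` set) or file mode
    (explicit input paths) is active.
    """

    outdir: str | Path = "pgpt_out"
    seed: int = 0

    # synthetic mode
    simulation: SimulationConfig | None = None
    write_inputs: bool = False  # also serialize the simulated inputs

    # file mode
    reads_fasta: dict[str, str] = field(default_factory=dict)  # sample -> path
    prot_hits: dict[str, str] = field(default_factory=dict)
    nucl_hits: dict[str, str] = field(default_factory=dict)
    catalog_path: str | None = None
    subject_to_gene_path: str | None = None
    taxon_map_path: str | None = None

    # MDH typing inputs (aligned FASTA + label->role sidecar TSV)
    mdh_alignment: str | None = None
    mdh_roles: str | None = None

    # isotope inputs: TSV of group summaries (group, mean, sd, n); the two
    # named groups are compared
    isotope_path: str | None = None
    isotope_group1: str = "exposed_fertilized"
    isotope_group2: str = "unexposed_fertilized"

    # thresholds and flags
    evalue_cutoff: float = screening.EVALUE_CUTOFF
    min_hit_bp: int = screening.MIN_HIT_BP
    min_identity: float = screening.MIN_IDENTITY
    host_label: str = screening.HOST_LABEL
    raw_total_denominator: bool = True  # frequency denominator includes host reads
    t_test_variant: str = TTestVariant.WELCH.value
    n_major: int = 3
    rarefaction_depths: list[int] = field(default_factory=list)
    rarefaction_replicates: int = 20
    rarefaction_rank: str = "genus"

    def __post_init__(self) -> None:
        file_mode = bool(self.reads_fasta or self.prot_hits)
        if self.simulation is not None and file_mode:
            raise ValueError("config mixes synthetic mode and file inputs")
        if self.simulation is None and not file_mode:
            raise ValueError("config provides neither synthetic mode nor file inputs")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_subject_to_gene(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            subject, gene = line.split("\t")
            if subject in out and out[subject] != gene:
                raise ValueError(f"subject {subject!r} mapped to two genes")
            out[subject] = gene
    return out


def _load_inputs(
    cfg: PipelineConfig, manifest: dict
) -> tuple[
    dict[str, list[SequenceRead]],
    dict[str, list[AlignmentHit]],
    ReferenceDB,
]:
    if cfg.simulation is not None:
        sim = cfg.simulation
        refdb = generate_reference_db(sim)
        reads, truth = simulate_reads(refdb, sim)
        hits = simulate_hit_tables(reads, truth, refdb, sim)
        manifest["mode"] = "synthetic"
        manifest["simulation_seed"] = sim.seed
        if cfg.write_inputs:
            write_simulation(Path(cfg.outdir) / "inputs", refdb, reads, truth, hits)
        return reads, hits, refdb
    manifest["mode"] = "files"
    reads = {s: read_fasta(p, sample_id=s) for s, p in sorted(cfg.reads_fasta.items())}
    hits: dict[str, list[AlignmentHit]] = {s: [] for s in reads}
    for s, p in sorted(cfg.prot_hits.items()):
        hits.setdefault(s, []).extend(read_hit_table(p, SearchType.PROT_TRANSLATED))
    for s, p in sorted(cfg.nucl_hits.items()):
        hits.setdefault(s, []).extend(read_hit_table(p, SearchType.NUCL_NUCL))
    if not (cfg.catalog_path and cfg.subject_to_gene_path and cfg.taxon_map_path):
        raise ValueError("file mode requires catalog, subject_to_gene and taxon_map paths")
    refdb = ReferenceDB(
        catalog=read_gene_catalog(cfg.catalog_path),
        subject_seqs={},
        subject_to_gene=_load_subject_to_gene(cfg.subject_to_gene_path),
        taxon_map=read_taxon_map(cfg.taxon_map_path),
    )
    digests = {}
    for p in [
        *cfg.reads_fasta.values(),
        *cfg.prot_hits.values(),
        *cfg.nucl_hits.values(),
        cfg.catalog_path,
        cfg.subject_to_gene_path,
        cfg.taxon_map_path,
    ]:
        digests[str(p)] = _sha256(Path(p))
    manifest["input_digests"] = digests
    return reads, hits, refdb


def _run_mdh_stage(cfg: PipelineConfig, outdir: Path, manifest: dict) -> None:
    if not (cfg.mdh_alignment and cfg.mdh_roles):
        manifest["stages"]["mdh_typing"] = "skipped (no alignment provided)"
        return
    aligned = {r.read_id: r.sequence for r in read_fasta(cfg.mdh_alignment, sample_id="mdh")}
    roles: dict[str, str] = {}
    with open(cfg.mdh_roles) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            label, role = line.rstrip("\n").split("\t")
            roles[label] = role
    queries = {l: s for l, s in aligned.items() if roles.get(l) == Role.QUERY.value}
    refs = {
        l: (s, Role(roles[l]))
        for l, s in aligned.items()
        if roles.get(l) in (Role.REF_XOXF.value, Role.REF_MXAF.value)
    }
    outgroups = {l: s for l, s in aligned.items() if roles.get(l) == Role.OUTGROUP.value}
    calls, trees = type_all_with_trees(queries, refs, outgroups)
    tree_dir = outdir / "mdh_trees"
    tree_dir.mkdir(exist_ok=True)
    for qlabel, tree in sorted(trees.items()):
        write_newick(tree, tree_dir / f"{qlabel}.nwk")
    with open(outdir / "mdh_calls.tsv", "w") as fh:
        fh.write("query\tcall\n")
        for c in calls:
            fh.write(f"{c.query}\t{c.call.value}\n")
    manifest["stages"]["mdh_typing"] = "ok"
    manifest["mdh_call_counts"] = summarize_calls(calls)


def _run_isotope_stage(cfg: PipelineConfig, outdir: Path, manifest: dict) -> None:
    if cfg.isotope_path is None:
        manifest["stages"]["isotope"] = "skipped (no isotope data provided)"
        return
    groups: dict[str, IsotopeGroup] = {}
    with open(cfg.isotope_path) as fh:
        for line in fh.read().splitlines()[1:]:
            if not line.strip():
                continue
            label, mean, sd, n = line.split("\t")
            groups[label] = IsotopeGroup(label=label, mean=float(mean), sd=float(sd), n=int(n))
    g1, g2 = groups[cfg.isotope_group1], groups[cfg.isotope_group2]
    result = t_test(g1, g2, TTestVariant(cfg.t_test_variant))
    call = significance_call(result.p)
    with open(outdir / "isotope_test.json", "w") as fh:
        json.dump(
            {
                "group1": g1.label,
                "group2": g2.label,
                "variant": result.variant.value,
                "t": result.t,
                "df": result.df,
                "p": result.p,
                "call": call,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    manifest["stages"]["isotope"] = "ok"
    manifest["isotope_p"] = result.p
    manifest["isotope_call"] = call


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest (also written to
    ``<outdir>/manifest.json``)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": {
            "evalue_cutoff": cfg.evalue_cutoff,
            "min_hit_bp": cfg.min_hit_bp,
            "min_identity": cfg.min_identity,
            "host_label": cfg.host_label,
            "raw_total_denominator": cfg.raw_total_denominator,
            "n_major": cfg.n_major,
            "t_test_variant": cfg.t_test_variant,
        },
        "stages": {},
    }

    reads, hits, refdb = _load_inputs(cfg, manifest)
    manifest["stages"]["inputs"] = "ok"

    # --- host filtering -----------------------------------------------------
    raw_totals = {s: len(rs) for s, rs in reads.items()}
    retained: dict[str, list[SequenceRead]] = {}
    removed: dict[str, int] = {}
    for sample in sorted(reads):
        nucl = [h for h in hits[sample] if h.search_type is SearchType.NUCL_NUCL]
        kept, n_removed = screening.filter_host_reads(
            reads[sample], nucl, refdb.taxon_map, cfg.evalue_cutoff, cfg.host_label
        )
        retained[sample] = kept
        removed[sample] = n_removed
    total_raw = sum(raw_totals.values())
    manifest["host_filter"] = {
        "removed_per_sample": removed,
        "removed_total": sum(removed.values()),
        "removed_fraction": (sum(removed.values()) / total_raw) if total_raw else 0.0,
    }
    manifest["stages"]["host_filter"] = "ok"

    # --- protein-level screening and per-sample summaries -------------------
    screened: dict[str, list[AlignmentHit]] = {}
    summaries = []
    for sample in sorted(reads):
        prot = [h for h in hits[sample] if h.search_type is SearchType.PROT_TRANSLATED]
        screened[sample] = screening.screen_hits_blastx(prot, cfg.evalue_cutoff)
        summaries.append(screening.sample_summary(retained[sample], screened[sample]))
    with open(outdir / "sample_summary.tsv", "w") as fh:
        fh.write("sample_id\ttotal_reads\ttotal_bp\tavg_length_bp\treads_with_similarity\n")
        for s in summaries:
            fh.write(
                f"{s.sample_id}\t{s.total_reads}\t{s.total_bp}\t{s.avg_length_bp}\t"
                f"{s.reads_with_similarity}\n"
            )
    manifest["stages"]["screening"] = "ok"

    # --- detection frequencies ----------------------------------------------
    all_retained = [r for rs in retained.values() for r in rs]
    all_screened = [h for hs in screened.values() for h in hs]
    gene_counts = screening.assign_reads_to_genes(
        all_retained, all_screened, refdb.subject_to_gene
    )
    totals = (
        raw_totals
        if cfg.raw_total_denominator
        else {s: len(rs) for s, rs in retained.items()}
    )
    records = freq.compute_frequency_records(gene_counts, refdb.catalog, totals)
    summaries_cat = freq.category_totals(records)
    (outdir / "gene_frequencies.tsv").write_text(freq.records_to_tsv(records))
    (outdir / "frequency_table.tsv").write_text(
        freq.render_frequency_table(records, summaries_cat)
    )
    manifest["stages"]["frequency"] = "ok"

    # --- taxonomy -----------------------------------------------------------
    assignments = taxonomy.assign_taxa(all_retained, all_screened, refdb.taxon_map)
    abundance_text = []
    for rank in ("phylum", "class", "order", "family", "genus"):
        try:
            table = taxonomy.relative_abundance(assignments, rank, cfg.n_major)
        except ValueError:
            continue
        abundance_text.append(taxonomy.abundance_to_tsv(table))
    (outdir / "relative_abundance.tsv").write_text("".join(abundance_text))
    n_assigned = sum(
        1
        for a in assignments
        if a.lineage is not None and a.lineage.name_at(cfg.rarefaction_rank) is not None
    )
    depths = cfg.rarefaction_depths or _default_depths(n_assigned)
    if depths:
        curve = taxonomy.rarefaction_curve(
            assignments,
            depths,
            replicates=cfg.rarefaction_replicates,
            seed=cfg.seed,
            rank=cfg.rarefaction_rank,
        )
        with open(outdir / "rarefaction.tsv", "w") as fh:
            fh.write("depth\tmean_richness\tsd_richness\n")
            for depth in depths:
                mean, sd = curve[depth]
                fh.write(f"{depth}\t{mean:.4f}\t{sd:.4f}\n")
    manifest["stages"]["taxonomy"] = "ok"

    # --- MDH typing and isotope test ----------------------------------------
    _run_mdh_stage(cfg, outdir, manifest)
    _run_isotope_stage(cfg, outdir, manifest)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _default_depths(n_assigned: int) -> list[int]:
    if n_assigned < 10:
        return []
    depths = [int(n_assigned * f) for f in (0.1, 0.25, 0.5, 0.75)]
    depths.append(n_assigned)
    return sorted({d for d in depths if d >= 1})
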