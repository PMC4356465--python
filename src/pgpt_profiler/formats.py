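"""Readers and writers for the external representations the pipeline touches.

Everything downstream of this module consumes only the domain types defined
here: sequence reads, tabular homology hits (the standard 12-column dialect),
gene-catalog rows, taxon lineages and phylogenetic trees.  Coordinates in
hit tables are kept 1-based inclusive, exactly as in the source format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "SearchType",
    "SequenceRead",
    "AlignmentHit",
    "GeneTarget",
    "TaxonLineage",
    "TreeNode",
    "PhyloTree",
    "FormatError",
    "RANKS",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "write_hit_table",
    "read_gene_catalog",
    "write_gene_catalog",
    "read_taxon_map",
    "write_taxon_map",
    "write_newick",
]

#: Canonical lineage ranks, shallowest first.  Deeper ranks (species, strain)
#: are deliberately unsupported.
RANKS = ("phylum", "class", "order", "family", "genus")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


class SearchType(str, Enum):
    """Which flavour of homology search produced a hit.

    ``nucl_nucl`` is a nucleotide-vs-nucleotide search (used for host-plant
    contamination screening), ``prot_translated`` a translated-query search
    against a protein database, and ``translated_prot`` a protein query
    against a translated nucleotide database (used for the sensitive
    re-screen of genes the primary search missed).
    """

    NUCL_NUCL = "nucl_nucl"
    PROT_TRANSLATED = "prot_translated"
    TRANSLATED_PROT = "translated_prot"


@dataclass(frozen=True)
class SequenceRead:
    """One metagenomic read with sample membership."""

    read_id: str
    sample_id: str
    sequence: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: length_bp {self.length_bp} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.length_bp <= 0:
            raise ValueError(f"read {self.read_id!r}: empty sequence")


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a tabular homology search result.

    Fields mirror the standard 12-column tabular output: query, subject,
    percent identity, alignment length (in the search's native unit —
    amino-acid columns for protein-level searches), mismatches, gap opens,
    query/subject start/end (1-based inclusive), E-value and bit score.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    search_type: SearchType = SearchType.PROT_TRANSLATED

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative evalue")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if min(self.qstart, self.qend, self.sstart, self.send) < 1:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: coordinates must be >= 1"
            )
        if self.alignment_length <= 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: nonpositive alignment length"
            )


@dataclass(frozen=True)
class GeneTarget:
    """One gene-catalog entry: name, KEGG orthology id, UniRef representative,
    approximate gene length in kbp, and the trait category it belongs to."""

    gene_name: str
    ko_id: str
    uniref_id: str
    length_kbp: float
    category: str

    def __post_init__(self) -> None:
        if self.length_kbp <= 0:
            raise ValueError(f"gene {self.gene_name!r}: nonpositive length_kbp")


@dataclass(frozen=True)
class TaxonLineage:
    """Ordered rank->name assignment over the five canonical ranks.

    Any rank may be absent; present ranks must be drawn from :data:`RANKS`.
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen_idx = -1
        for rank, name in self.ranks:
            if rank not in RANKS:
                raise ValueError(f"unsupported rank {rank!r}")
            idx = RANKS.index(rank)
            if idx <= seen_idx:
                raise ValueError("ranks out of canonical order or duplicated")
            seen_idx = idx
            if not name:
                raise ValueError(f"empty name at rank {rank!r}")

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "TaxonLineage":
        pairs = tuple((r, mapping[r]) for r in RANKS if r in mapping)
        return cls(pairs)

    def name_at(self, rank: str) -> str | None:
        for r, name in self.ranks:
            if r == rank:
                return name
        return None

    def contains(self, label: str) -> bool:
        """True if *label* is the name at any rank of this lineage."""
        return any(name == label for _, name in self.ranks)

    def to_string(self) -> str:
        return ";".join(f"{r}:{n}" for r, n in self.ranks)


# ---------------------------------------------------------------------------
# Phylogenetic trees


@dataclass
class TreeNode:
    label: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """An unrooted tree stored with an arbitrary internal node as root.

    An unrooted binary tree over n leaves is represented with a trifurcating
    root; branch lengths are nonnegative.
    """

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [l.label or "" for l in self.leaves()]

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                if not node.label:
                    raise ValueError("unlabeled leaf cannot be serialized")
                return f"{node.label}:{node.length:.6f}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"

        if len(self.leaves()) < 2:
            raise ValueError("tree must have at least 2 leaves")
        inner = ",".join(
            render(c) if not c.is_leaf else f"{c.label}:{c.length:.6f}"
            for c in self.root.children
        )
        return f"({inner});"

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Sum of branch lengths between every unordered pair of leaves."""
        # depth of every leaf below each node via post-order accumulation
        out: dict[tuple[str, str], float] = {}

        def collect(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label or "", node.length)]
            below: list[list[tuple[str, float]]] = [collect(c) for c in node.children]
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for la, da in below[i]:
                        for lb, db in below[j]:
                            key = (min(la, lb), max(la, lb))
                            out[key] = da + db
            merged = [(l, d + node.length) for sub in below for l, d in sub]
            return merged

        collect(self.root)
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, sample_id: str | None = None) -> list[SequenceRead]:
    """Parse a FASTA file into :class:`SequenceRead` records.

    The read id is the first whitespace-delimited token of the header.
    ``sample_id`` defaults to the file's stem.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    # reject sequence data appearing before any header, with a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"{path}:{lineno}: sequence data before any FASTA header"
                )
            break
    reads: list[SequenceRead] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        rid = record.id
        if rid in seen:
            raise FormatError(f"{path}: duplicate read id {rid!r}")
        seen.add(rid)
        seq = str(record.seq)
        reads.append(
            SequenceRead(read_id=rid, sample_id=sample_id, sequence=seq, length_bp=len(seq))
        )
    return reads


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, 80 columns per line."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular hit tables

_HIT_COLUMNS = 12


def read_hit_table(
    path: str | Path, search_type: SearchType = SearchType.PROT_TRANSLATED
) -> list[AlignmentHit]:
    """Parse a 12-column tab-separated hit table.

    Lines starting with ``#`` are ignored.  Any deviation from exactly 12
    columns is an error — extra columns signal an upstream misconfiguration
    and are never silently dropped.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    search_type=search_type,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.alignment_length,
                        h.mismatches,
                        h.gap_opens,
                        h.qstart,
                        h.qend,
                        h.sstart,
                        h.send,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene catalog

_CATALOG_HEADER = ["gene_name", "ko_id", "uniref_id", "length_kbp", "category"]


def read_gene_catalog(path: str | Path) -> list[GeneTarget]:
    """Parse a TSV gene catalog (gene_name, ko_id, uniref_id, length_kbp,
    category).  A header row matching the column names is permitted."""
    genes: list[GeneTarget] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:1] == ["gene_name"]:
                continue
            if len(fields) != len(_CATALOG_HEADER):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_CATALOG_HEADER)} columns, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene {name!r}")
            seen.add(name)
            try:
                length = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad length_kbp {fields[3]!r}") from exc
            if length <= 0:
                raise FormatError(
                    f"{path}:{lineno}: gene {name!r} has nonpositive length_kbp {length}"
                )
            genes.append(
                GeneTarget(
                    gene_name=name,
                    ko_id=fields[1],
                    uniref_id=fields[2],
                    length_kbp=length,
                    category=fields[4],
                )
            )
    return genes


def write_gene_catalog(genes: Iterable[GeneTarget], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CATALOG_HEADER) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_name}\t{g.ko_id}\t{g.uniref_id}\t{g.length_kbp:.3f}\t{g.category}\n"
            )


# ---------------------------------------------------------------------------
# Taxon map


def read_taxon_map(path: str | Path) -> dict[str, TaxonLineage]:
    """Parse a TSV mapping subject ids to semicolon-delimited rank:name
    lineages, e.g. ``g7<TAB>phylum:Proteobacteria;genus:Bradyrhizobium``."""
    out: dict[str, TaxonLineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            subject, lineage_str = fields
            pairs = []
            for token in lineage_str.split(";"):
                if not token:
                    continue
                if ":" not in token:
                    raise FormatError(f"{path}:{lineno}: bad lineage token {token!r}")
                rank, name = token.split(":", 1)
                pairs.append((rank, name))
            try:
                lineage = TaxonLineage(tuple(pairs))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if subject in out and out[subject] != lineage:
                raise FormatError(
                    f"{path}:{lineno}: duplicate subject {subject!r} with "
                    f"conflicting lineage"
                )
            out[subject] = lineage
    return out


def write_taxon_map(taxon_map: Mapping[str, TaxonLineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for subject in sorted(taxon_map):
            fh.write(f"{subject}\t{taxon_map[subject].to_string()}\n")


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Serialize a tree to Newick with branch lengths at 6 decimal places."""
    for leaf in tree.leaves():
        if not leaf.label:
            raise ValueError("tree has an unlabeled leaf")
        if leaf.length < 0:
            raise ValueError(f"leaf {leaf.label!r} has a negative branch length")
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
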