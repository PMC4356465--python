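"""Taxonomy: best-hit assignment, relative abundance with Others pooling,
rarefaction against the hypergeometric oracle, gene-by-genus cross-tabs."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import hypergeom

from pgpt_profiler.formats import SearchType, SequenceRead, TaxonLineage
from pgpt_profiler.taxonomy import (
    TaxonAssignment,
    assign_taxa,
    pgpt_taxon_breakdown,
    rarefaction_curve,
    relative_abundance,
)
from .test_formats import make_hit


def read(read_id, sample="s1"):
    return SequenceRead(read_id=read_id, sample_id=sample, sequence="ACGT", length_bp=4)


def lineage(genus, phylum="Proteobacteria"):
    return TaxonLineage((("phylum", phylum), ("genus", genus)))


def assignment(read_id, sample, genus=None, phylum="Proteobacteria"):
    return TaxonAssignment(
        read_id=read_id,
        sample_id=sample,
        lineage=lineage(genus, phylum) if genus else None,
    )


class TestAssignTaxa:
    def test_single_hit_assigns_its_lineage(self):
        hits = [make_hit(query_id="r1", subject_id="g7")]
        out = assign_taxa([read("r1")], hits, {"g7": lineage("Bradyrhizobium")})
        assert out[0].lineage.name_at("genus") == "Bradyrhizobium"

    def test_no_hits_unassigned(self):
        out = assign_taxa([read("r1")], [], {})
        assert out[0].lineage is None

    def test_best_hit_decides(self):
        h1 = make_hit(query_id="r1", subject_id="x", bitscore=200)
        h2 = make_hit(query_id="r1", subject_id="y", bitscore=150)
        taxa = {"x": lineage("GenusX"), "y": lineage("GenusY")}
        out = assign_taxa([read("r1")], [h1, h2], taxa)
        assert out[0].lineage.name_at("genus") == "GenusX"

    def test_unmapped_subject_leaves_unassigned(self):
        out = assign_taxa([read("r1")], [make_hit(query_id="r1", subject_id="zz")], {})
        assert out[0].lineage is None


class TestRelativeAbundance:
    def test_single_genus_is_100_percent(self):
        assignments = [
            assignment(f"r{i}", s, "Bradyrhizobium")
            for s in ("s1", "s2")
            for i in range(5)
        ]
        table = relative_abundance(assignments, "genus")
        brady = table.rows[0]
        assert brady.taxon_name == "Bradyrhizobium"
        assert all(v == 100.0 for v in brady.per_sample_percent.values())
        assert all(v == 0.0 for v in table.rows[-1].per_sample_percent.values())

    def test_mean_sd_shape(self):
        # per-sample percentages 13, 14, 15 -> 14 +/- 1
        assignments = []
        for s, pct in (("s1", 13), ("s2", 14), ("s3", 15)):
            for i in range(pct):
                assignments.append(assignment(f"a{i}", s, "Mesorhizobium"))
            for i in range(100 - pct):
                assignments.append(assignment(f"b{i}", s, "OtherGenus"))
        table = relative_abundance(assignments, "genus", n_major=2)
        meso = next(r for r in table.rows if r.taxon_name == "Mesorhizobium")
        assert math.isclose(meso.mean_percent, 14.0)
        assert math.isclose(meso.sd_percent, 1.0)

    def test_others_is_complement_of_top_n(self):
        rng = np.random.default_rng(3)
        genera = [f"G{i}" for i in range(5)]
        assignments = []
        for s in ("s1", "s2"):
            for i in range(200):
                assignments.append(assignment(f"{s}_r{i}", s, genera[rng.integers(0, 5)]))
        table = relative_abundance(assignments, "genus", n_major=3)
        assert len(table.rows) == 4
        for s in ("s1", "s2"):
            top = sum(r.per_sample_percent[s] for r in table.rows[:3])
            assert math.isclose(table.rows[-1].per_sample_percent[s], 100 - top, abs_tol=1e-9)

    def test_unrounded_percentages_sum_to_100(self, small_sim):
        refdb, reads, _, hits = small_sim
        all_reads = [r for rs in reads.values() for r in rs]
        prot = [h for hs in hits.values() for h in hs if h.search_type is SearchType.PROT_TRANSLATED]
        assignments = assign_taxa(all_reads, prot, refdb.taxon_map)
        table = relative_abundance(assignments, "genus")
        for s in table.rows[0].per_sample_percent:
            assert math.isclose(sum(r.per_sample_percent[s] for r in table.rows), 100.0, abs_tol=1e-9)

    def test_pooling_invariance_between_ranks(self, small_sim):
        # abundance at phylum computed directly equals the sum over genera
        # sharing the phylum (lineages here always carry both ranks)
        refdb, reads, _, hits = small_sim
        all_reads = [r for rs in reads.values() for r in rs]
        prot = [h for hs in hits.values() for h in hs if h.search_type is SearchType.PROT_TRANSLATED]
        assignments = assign_taxa(all_reads, prot, refdb.taxon_map)
        phylum_table = relative_abundance(assignments, "genus", n_major=100)
        direct = relative_abundance(assignments, "phylum", n_major=100)
        # map genus -> phylum from the synthetic lineages
        genus_to_phylum = {}
        for lin in refdb.taxon_map.values():
            g, p = lin.name_at("genus"), lin.name_at("phylum")
            if g:
                genus_to_phylum[g] = p
        for row in direct.rows:
            if row.taxon_name == "Others":
                continue
            for s, pct in row.per_sample_percent.items():
                pooled = sum(
                    r.per_sample_percent[s]
                    for r in phylum_table.rows
                    if r.taxon_name != "Others"
                    and genus_to_phylum.get(r.taxon_name) == row.taxon_name
                )
                assert math.isclose(pct, pooled, abs_tol=1e-9)

    def test_missing_rank_rejected(self):
        assignments = [assignment("r1", "s1", "G1"), assignment("r2", "s2", "G2")]
        with pytest.raises(ValueError):
            relative_abundance(assignments, "family")


class TestRarefaction:
    @staticmethod
    def expected_richness(counts, depth):
        # E[S_d] = sum_i 1 - C(N - N_i, d) / C(N, d)
        N = sum(counts)
        return sum(1 - hypergeom(N, n_i, depth).pmf(0) for n_i in counts)

    def test_full_depth_equals_observed_richness(self):
        assignments = [assignment(f"r{i}", "s1", f"G{i % 7}") for i in range(50)]
        curve = rarefaction_curve(assignments, [50], replicates=5, seed=1)
        assert curve[50] == (7.0, 0.0)

    def test_depth_one_gives_richness_one(self):
        assignments = [assignment(f"r{i}", "s1", f"G{i % 3}") for i in range(30)]
        curve = rarefaction_curve(assignments, [1], replicates=20, seed=1)
        assert curve[1][0] == 1.0

    def test_monotone_nondecreasing_in_depth(self):
        assignments = [assignment(f"r{i}", "s1", f"G{i % 10}") for i in range(200)]
        depths = [10, 50, 100, 200]
        curve = rarefaction_curve(assignments, depths, replicates=30, seed=2)
        means = [curve[d][0] for d in depths]
        assert means == sorted(means)

    def test_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(9)
        labels = rng.choice(10, size=300)
        assignments = [assignment(f"r{i}", "s1", f"G{l}") for i, l in enumerate(labels)]
        counts = list(Counter(labels).values())
        replicates = 200
        curve = rarefaction_curve(assignments, [20, 100], replicates=replicates, seed=3)
        for depth in (20, 100):
            mean, sd = curve[depth]
            expected = self.expected_richness(counts, depth)
            se = max(sd, 1e-9) / math.sqrt(replicates)
            assert abs(mean - expected) <= max(3 * se, 0.2)

    def test_excess_depth_rejected(self):
        assignments = [assignment("r1", "s1", "G1")]
        with pytest.raises(ValueError, match="depth"):
            rarefaction_curve(assignments, [2], replicates=2, seed=0)

    def test_deterministic_under_seed(self):
        assignments = [assignment(f"r{i}", "s1", f"G{i % 5}") for i in range(40)]
        a = rarefaction_curve(assignments, [10, 20], replicates=10, seed=7)
        b = rarefaction_curve(assignments, [10, 20], replicates=10, seed=7)
        assert a == b


class TestBreakdown:
    def test_empty_gene_absent(self):
        assert pgpt_taxon_breakdown({}, []) == {}

    def test_single_genus_counts(self):
        read_genes = {"r1": "geneA", "r2": "geneA", "r3": "geneA"}
        assignments = [assignment(f"r{i}", "s1", "Bradyrhizobium") for i in (1, 2, 3)]
        table = pgpt_taxon_breakdown(read_genes, assignments)
        assert table == {"geneA": Counter({"Bradyrhizobium": 3})}

    def test_matches_brute_force_crosstab(self):
        rng = np.random.default_rng(4)
        genes = ["gA", "gB"]
        genera = ["X", "Y"]
        read_genes = {}
        assignments = []
        expected = Counter()
        for i in range(100):
            g = genes[rng.integers(0, 2)]
            t = genera[rng.integers(0, 2)]
            read_genes[f"r{i}"] = g
            assignments.append(assignment(f"r{i}", "s1", t))
            expected[(g, t)] += 1
        table = pgpt_taxon_breakdown(read_genes, assignments)
        for (g, t), n in expected.items():
            assert table[g][t] == n
        # row sums equal each gene's read total
        for g in genes:
            assert sum(table[g].values()) == sum(1 for v in read_genes.values() if v == g)
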