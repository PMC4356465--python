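# Methods

## Scope and model

The package analyses shotgun metagenome reads of a plant-associated
bacterial community through homology-search hit tables, not through the
alignments themselves. Its unit of evidence is one read assigned to one
catalog gene by its single best surviving hit; all statistics are built on
those per-read assignments. The gene catalog supplies the only quantities
the reads cannot: an approximate gene length per family (kbp, deduced from
UniRef representative sequences) and a trait category per gene.

### Detection frequency

For gene *g* in sample *s*: `F_gs = (n_gs / L_g) · (100000 / N_s)` with
`n_gs` the assigned read count, `L_g` the catalog length in kbp and `N_s`
the sample's total read count. The statistic is linear in `n_gs` and
inversely proportional to gene length and sequencing depth, so values are
comparable across genes of different lengths and samples of different
depths; at `L_g = 1` kbp and `N_s = 10⁵` it reduces to the raw count.
Frequencies are computed per sample from that sample's own total and then
aggregated as mean ± sample standard deviation (n−1 denominator — with
n = 3 samples, this is the conventional reading of a reported "± SD
(n = 3)"). Category totals sum *unrounded* member frequencies per sample
before aggregation; SDs are recomputed from the totals, never summed,
since member SDs are not additive.

`N_s` defaults to the *raw* per-sample total, including the ~2 % of reads
later removed as host contamination, because the published per-sample read
totals that the formula cites are the raw sequencer outputs. A flag
(`raw_total_denominator=False`) switches to post-filter totals; with 2 %
contamination the difference is a uniform ≈2 % inflation, immaterial to
ranking genes.

### Screening thresholds

All thresholds are strict inequalities, and boundary values are rejected:
E < 10⁻¹⁰ for both search flavours, plus alignment span > 250 bp and
identity > 40 % for the sensitive protein-query re-screen. For a protein
query the tabular alignment length is in amino-acid columns, so the bp
threshold is applied to columns × 3 — the only unit-consistent reading of
a bp cutoff on an amino-acid-level alignment. The two screens are separate
operations with independent thresholds, because the length/identity minima
are documented only for the re-screen.

The best hit of a query maximizes bitscore, with ties broken by minimum
E-value and then lexicographically smallest subject id. The tie-break makes
assignment deterministic under input reordering; in real hit tables
bitscore ties with E-value ties are rare enough that the lexicographic leg
is effectively a stability guarantee, not a biological claim.

Host filtering removes a read iff its best *nucleotide*-search hit (after
the E-value screen) resolves to a lineage containing the host label at any
rank. The label is a clade name, not a rank, so matching is rank-agnostic.
Reads without qualifying nucleotide hits are always retained; filtering
partitions the input exactly.

### Taxonomy

A read takes the lineage of its best surviving hit. Relative abundance at
a rank is a percentage of reads *assigned at that rank* (reads that are
unassigned, or whose lineage lacks the rank, are excluded from the
denominator), so unrounded per-sample percentages sum to exactly 100. The
`n_major` (default 3) taxa of highest mean abundance are listed; the rest
pool into "Others"; ranking ties break lexicographically. Rarefaction is
explicit Monte-Carlo subsampling without replacement, seeded; tests compare
it to the closed-form hypergeometric expectation
`E[S_d] = Σ_i (1 − C(N−N_i, d)/C(N, d))`.

### Methanol-dehydrogenase typing

Distances are uncorrected p-distances with pairwise deletion of gapped
columns (the simplest defensible metric for short, highly divergent
fragments; a Poisson correction `−ln(1−p)` is available behind a flag but
changes no call on monotone-transformed distances in practice). Trees are
built by Saitou–Nei neighbor joining: join the pair minimizing
`Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`, standard branch-length
formulas, negative estimates clamped to zero, ties on Q broken by the
lexicographically smallest pair of subtree leaf labels so that input order
never matters.

Typing is one tree per query — short environmental fragments are too
divergent from each other for a stable joint tree, so each query is placed
alone among the references. The tree is rooted on the edge separating the
outgroup leaves from everything else (falling back to the pendant edge of
the first outgroup leaf if the outgroup is not monophyletic in the
estimate). Walking rootward from the query, the first clade containing a
typed reference decides: all-xoxF → xoxF, all-mxaF → mxaF, mixed →
undetermined; a query on the outgroup side of the root is undetermined.
This operationalizes "clusters with the references" / "clusters with the
outgroup" as rooted clade membership — the natural reading, but one of
several possible formalizations, which is why the rule is documented here.

### Isotope test

Welch's unequal-variance t-test is the default (with n = 3 per group and
visibly unequal SDs, pooling is the stronger assumption); Student's pooled
test is selectable. p-values are two-sided. The degenerate all-constant
case (both SDs zero, equal means) is defined as p = 1; zero SDs with
unequal means raise instead of fabricating an infinite t.

## Synthetic data

The generator emulates the emulated survey's *statistical frame*, not its
sequences: 3 composite samples (default), reads of mean length 645 bp
(truncated Normal on [100, 1200]; the SD, 130 bp, is a free choice of
plausible pyrosequencer spread — only the mean is anchored), 2 % host
contamination, and a 54 % protein-level hit rate. Gene and genus weights
are free parameters: true abundances are never reported for real surveys,
so the defaults merely span common-to-rare (weights 0.7–25 across eight
trait genes, six genera weighted like a root community's dominant genera)
to exercise recovery tests at both ends. The default `reads_per_sample`
(60 000) sits near the middle of the emulated survey's 46k–80k per-sample
range; heavier tests scale it down (tests use 2 000–20 000) purely as a
problem-size choice.

Hit tables are constructed so that downstream screening provably recovers
truth: every gene-origin read's true-origin hit has the minimum E-value for
that read, decoy hits are strictly worse (E-value ≥ 100× larger, bitscore
strictly lower via a shared monotone map), and host reads are visible only
through nucleotide-level hits to the host subject. E-values are log-uniform
in [10⁻⁶⁰, 10⁻¹²] for true hits — only ordering and threshold behaviour
matter downstream, not realism. Read sequence content is random nucleotide;
no sequencing-error or chimera model is included. Passing recovery tests
therefore demonstrates the *pipeline arithmetic* is correct under the
assumed hit structure; it says nothing about BLAST's actual sensitivity on
real reads.

All randomness flows from `numpy.random.default_rng` seeded from one config
seed (distinct fixed streams per stage), so identical configs give
byte-identical outputs; the pipeline manifest records the seed and every
threshold.

The mock MDH reference set places two type prototypes 0.4 p-distance apart
with 0.05 within-type diversity and an outgroup at 0.65 — proportions
chosen to mimic a gene family whose types are distinguishable by phylogeny
but not by simple similarity screens.

## Numerical choices and edge cases

- Average read length per sample is floor(total bp / total reads): the only
  rule that reproduces whole-bp/read values exactly from exact totals.
- Display rounding of frequency tables: values ≥ 1 to the nearest integer
  (half away from zero), values < 1 to one decimal; genes never detected in
  any sample render "ND". Unrounded values are always written alongside, and
  all aggregation happens before rounding.
- Newick output carries branch lengths at 6 decimals; round-trips through
  an independent parser are tested to 10⁻⁶.
- An empty sample yields an all-zero summary; fewer than two samples make
  SD (and hence aggregation) an error rather than a silent 0.

## Known limitations

- The pipeline consumes hit tables; it neither runs nor models the
  homology search itself, and cannot correct for database composition.
- One-read-one-gene assignment ignores genuinely ambiguous reads (e.g.
  conserved domains shared across families); a lowest-common-ancestor
  scheme is out of scope.
- Lineages are restricted to phylum–genus; species-level calls from short
  reads are not attempted.
- The typing clade rule is an operationalization of an informal criterion;
  bootstrap support is not computed, so single-tree calls carry no
  uncertainty estimate.
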