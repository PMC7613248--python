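# Methods

`scartree` reconstructs developmental lineage relationships between cell
types from CRISPR genetic scars — Cas9-induced indels at a transgene locus
created during early embryogenesis and read out by single-cell sequencing
in the adult organ. Cells sharing a scar descend from the cell in which it
was created, so scars act as heritable clonal barcodes. The package covers
the full desk-side analysis: read filtering, tree reconstruction, lineage
statistics, secretome scoring, and a simulator that generates data with
known ground truth.

## Filtering model

Input is a table of scar amplicon reads (cell barcode, UMI, scar sequence),
assumed already aligned and barcode-validated upstream. The cascade:

1. **Truncation.** Scar sequences are truncated to 75 nt; shorter reads are
   dropped. All downstream sequence comparisons assume this fixed length.
2. **Read support.** A molecule is a unique (barcode, UMI, sequence)
   combination; molecules sequenced fewer than twice are discarded as
   likely sequencing errors.
3. **Chimera resolution.** PCR chimeras produce conflicting assignments.
   Sequentially, only the most prevalent (by read count) scar per
   (barcode, UMI), UMI per (barcode, scar), and barcode per (UMI, scar) is
   kept. Ties go to the lexicographically smallest sequence/identifier so
   the cascade is deterministic and order-independent. Each pass only
   removes rows, so earlier uniqueness is preserved and the operation is
   idempotent. A consequence of the literal second pass is that each
   (cell, scar) pair retains a single molecule; per-cell scar counts are
   therefore presence-weighted rather than UMI-weighted downstream.
4. **Near-identical scars.** Within a cell, alleles within Hamming
   distance 2 are merged (minor absorbed into major, counts summed) unless
   both are independently credible: each with ≥ 2 molecules in the cell
   and each observed without the other in ≥ 2 other cells. The exact
   published criteria live in earlier scar-tracing work; this cross-cell
   evidence rule is this package's operationalization of "verifiably
   correct" and is deliberately conservative.
5. **Doublets.** A droplet containing two cells shows the union of two
   scar sets. Cells whose distinct-scar count exceeds
   median + max(3·MAD, 2) of their cell type's distribution are flagged
   (raw median absolute deviation; the +2 floor prevents zero-MAD types
   from flagging everything). Types with fewer than 5 cells fall back to
   the global distribution. Because scar counts are clade-correlated,
   types concentrated in lightly scarred clades can have low medians and
   flag a few true singlets from heavily scarred clades; the rule trades
   this small false-positive rate for robust doublet removal.

## Tree reconstruction

Scars that co-occur in a cell were on the same lineage branch; a scar
created early co-occurs with many later scars. The algorithm builds a
graph over alleles (edge weight = number of cells containing both), then
iteratively extracts the most-connected allele as the next ancestor,
appending it below the current position; when removal disconnects the
graph, the components become sibling branches. "Most connected" is
highest degree, with ties broken by total edge weight, then by cell
support (cells carrying the allele), then lexicographically — degree alone
cannot order a two-scar chain, but cell support can, since the ancestral
allele is carried by a superset of cells. A virtual unlabelled root sits
above all components so scar-free cells have a home and disconnected
clades coexist.

Cells are placed at the lowest node whose root-path scar set is contained
in the cell's scars and covers every cell scar present in the tree. Cells
whose scars span disjoint branches (dropout, recurrent alleles) are placed
at the node explaining the largest number of scar molecules (ties to the
shallower node) and flagged as conflicts. This is the ideal-data scheme;
production corrections for variable detection rates are out of scope, and
on noiseless simulations the inferred tree equals the true scar-event tree
exactly (verified per seed in the tests).

Trees are built per replicate heart; replicates are integrated at the
statistics layer, never by merging trees.

## Lineage statistics

**Contraction.** Nodes with exactly one child are merged downward (cells
pooled), leaving only lineage splits; the root survives if it carries
cells.

**Composition and weighted correlation.** For each node, cell-type ratios
are counts divided by node size. Node membership is subtree-inclusive by
default (a node's cells include its whole subtree, since descendants share
the node's ancestor); a flag switches to node-local counting. The lineage
similarity of types *a*, *b* is the node-size-weighted Pearson correlation
of their ratio vectors: with weights *wᵢ* (node sizes), weighted means
*mₐ = Σwᵢrₐᵢ/Σwᵢ* and covariances *C(a,b) = Σwᵢ(rₐᵢ−mₐ)(r_bᵢ−m_b)/Σwᵢ*,
the entry is *C(a,b)/√(C(a,a)C(b,b))*. Ratios emphasize deep, pure nodes;
size weighting emphasizes reproducible large nodes. Entries are reported
missing (never zeroed) for types present in fewer than two nodes or with
zero weighted variance.

**Clustering.** Agglomerative clustering on distance 1 − correlation,
average linkage by default (configurable), cut either at a cluster count
or a distance threshold. The analysis scripts cut at distance 0.6, i.e.
types join a cluster at average correlation ≥ 0.4. Types absent from a
matrix are excluded from that clustering; remaining missing pairwise
entries are imputed as zero correlation, with a log message.

**Downsampling stability.** The data are repeatedly downsampled to a
fraction (default half) of the cells — robustness to low cell numbers — or
of the pooled nodes — robustness to low clonality and clone-specific
transition rates. Correlations and clusters are recomputed per repetition
and each present type pair scored as co-clustered or not; pairs with an
absent member are recorded as missing for that repetition, not imputed.
The report gives the pairwise co-clustering frequency matrix and, since
"recovering the same clusters" admits several readings, also an
exact-partition match rate against the reference clustering.

**Conditional probabilities.** For a target type, P(source | target) is
the fraction of leaf nodes (of the contracted trees, pooled over
replicates) containing the target that also contain the source. The table
is deliberately asymmetric: if a transient type arises only from a subset
of source clones, P(source | derived) stays near 1 while
P(derived | source) is small — the signature that survives clone-dependent
transition rates, which destabilize correlation-based clustering.

## Secretome scoring

Cells are depth-normalized to 10,000 transcripts. The secretome fraction
is the mean percentage of a cell's transcripts falling in a user-supplied
secreted-gene list, per (cell type, time point); neuronal and myelin cells
are excluded. For the clustered summary, per-type mean expression is
filtered to genes reaching a mean of ≥ 10 (boundary inclusive) in at least
one type, log(1+x)-transformed, then z-scored per gene across cell types
(population standard deviation), capped at 5 from above, keeping genes
with max z > 2; both axes are ordered by Ward clustering on Euclidean
distance. Note that the maximum attainable z over *n* cell types is
√(n−1), so the z > 2 filter is only meaningful with six or more cell
types — it presumes an atlas-scale annotation. Zero-variance genes are
dropped with a warning. Ortholog conversion of a secretome database is out
of scope; the module takes a plain gene list.

## Simulator

The generator emulates the experiment: a binary division tree of
`n_generations`; each lineage segment independently acquires at most one
new scar allele with probability `scar_rate` (alleles are unique random
75-mers drawn from a finite alphabet; exhaustion is an error unless a
skewed-reuse stress mode is enabled); cells sample leaves uniformly and
inherit all root-path scars. Clones are clades at `clone_depth` divisions
(default 2, i.e. four clones) — the natural operational unit, since
"clone" has no other observable definition here. Base cell types are drawn
per clone from configurable propensities; an injury converts source-type
cells to a transient derived state with a global or per-clone rate. The
readout detects each scar with `detection_prob`, draws molecules per scar
and reads per molecule from small count distributions (constant, or
1 + Poisson), samples UMIs uniformly from the 10-base space (collisions
allowed), applies per-base substitution errors, and fuses pairs of cells
into doublet barcodes with probability `doublet_rate`. All randomness
derives from one seed through fixed substreams; output is bit-identical
across runs.

What the simulator does **not** emulate: transcriptomes and
annotation errors, Cas9 cutting biochemistry and indel spectra, scar-allele
frequency skew of a real locus (no published distribution is available;
the unique-allele default is a free parameter), ambient RNA, or
amplification chimeras. Passing tests therefore demonstrate correctness of
the algorithms under the stated statistical assumptions, not performance
on any real library.

## Canonical scenarios (study conditions)

`scartree.scenarios` fixes the conditions used by the analysis scripts,
tests and acceptance script.

*Noiseless recovery*: 4 generations (30 segments) at scar rate 2/3 — an
expected 20 scar events — 500 cells, full detection, constant 2 reads per
molecule. Dense sampling makes every ancestral cell-set relation strict,
so exact topology recovery is the correct expectation.

*Injury cohorts*: 6 generations, scar rate 0.6, four clones, two replicate
hearts of 4,000 cells. An endocardium-like source type is abundant (60%)
in two clones and scarcer (30%) in the other two, with clone-specific
fibroblast markers as the remaining types. This spread makes node
compositions vary across clones much more than the binomial conversion
noise within nodes — the regime the correlation statistic assumes. The
clone-independent cohort converts source → derived at 50% everywhere; the
clone-dependent cohort uses 30% in the source-rich clones and 80% in the
source-poor ones, so derived abundance decouples from the overall clone
composition axis (the injury hits a region, not the clones where the
source is abundant). Cell numbers were chosen so that leaves retain
roughly 18+ source cells even in source-poor clades: the chance that a
responding leaf converts *all* of its source cells (which would break the
leaf-level conditional-probability signature) is then ≈ 0.8¹⁸ ≈ 0.02.
Readout is noiseless in both cohorts — they probe the statistics, not the
error model. Stability uses 200 node-downsampling repetitions at fraction
0.5; the full thousand-fold repetition changes the frequencies by less
than the seed-to-seed spread and is available by raising `reps`.

## Numerical choices

- Tie-breaks everywhere are (support desc, lexicographic asc); no
  randomness outside the configured seeds.
- Weighted correlations use frequency weights normalized per call;
  agreement with a direct-summation oracle is tested to 1e−10.
- Distance matrices passed to linkage are symmetrized, clipped at 0, and
  converted to condensed form without redundancy checks.
- z-scores use ddof = 0; the cap applies from above only (strong depletion
  is preserved as-is).
- Degenerate inputs (no scars at all, < 2 nodes, < 2 cell types, empty
  gene sets, zero-count cells) raise or warn explicitly rather than
  returning silently empty results.

## Known limitations

- The tree builder implements the ideal-data scheme; heavy dropout or
  recurrent alleles produce placement conflicts that are flagged but not
  probabilistically resolved.
- The doublet rule's MAD threshold can misfire for cell types whose scar
  counts are clade-skewed (see above).
- Conditional probabilities use contracted-tree leaves; with node-local
  membership the leaf sets coincide with raw placement, but internal-node
  co-occurrence is not considered.
- Replicate integration by node pooling assumes replicates share the
  cell-type vocabulary; no batch correction is attempted.
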