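# Methods and design notes

This note records the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and
the decisions taken where the procedure left genuine freedom.

## Cell typing (`celltyping`)

Normalization is library-size scaling to 10,000 counts per cell followed
by log(1 + x) — the common single-cell convention. All-zero cells are
dropped with a warning. The two marker criteria use *strict*
inequalities (">10% of cells", ">50% of the maximum cluster mean"),
and criterion 2 is evaluated on mean log-normalized expression; whether
the original analysis used normalized, raw or scaled means is not
documented, so the normalized mean is adopted as the convention and the
thresholds (`frac_min`, `rel_level_min`) are exposed.

Cluster labeling is a strict-argmax vote; ties and zero votes yield
`UNASSIGNED` rather than an arbitrary winner — deliberately, because the
same procedure applied to the real data left one cluster undefined (the
small-spermatid cluster, typed later on other evidence).

Pruning iterates to a fixed point. Within an iteration every surviving
gene is judged against one fixed cluster→type assignment; after each
round of removals the assignment is recomputed from the survivors. The
two rules: a gene marking exactly one (assigned) cell type must be
supported for it; a gene marking two or more may have at most two
unsupported correspondences. A gene whose marked clusters are all
`UNASSIGNED` marks no cell type and is treated as uninformative
(pruned). Iteration is bounded by the number of genes; order of inputs
never matters (verified by test).

The DEG surrogate is a two-sided Wilcoxon rank-sum of one cluster
against all other cells with BH adjustment: exact enumeration of all
rank splits (midranks for ties) when the pooled sample has ≤ 20
observations, the tie-corrected normal approximation with continuity
correction above that. The log2 fold-change uses mean log-normalized
expression with a 1e-9 pseudocount. This is a plumbing surrogate for a
full DE framework, not a reimplementation of one.

Hypergeometric set enrichment is upper-tail: P(X ≥ k) for the overlap k
of a hit set with a category inside a declared background.

## Gene ages and enrichment (`agestats`)

Age classes are assigned deepest-first from three presence flags
(ortholog beyond Hymenoptera → pre-Hymenoptera; in non-Apidae
Hymenoptera → post-Hymenoptera; in other bees → post-Apidae; otherwise
Novel). `is_hrg` is definitionally "not pre-Hymenoptera".

Fisher's exact test is implemented with exact integer arithmetic: the
hypergeometric weights C(r1, x)·C(n−r1, c1−x) are compared as integers
and the two-sided p sums all tables no more likely than the observed
one (the minimum-likelihood rule, the dominant convention). This avoids
the float tie-guards that library implementations need and makes the
test exactly reproducible against exhaustive enumeration; a library
cross-check is kept in the tests. The odds ratio is the sample
cross-product ratio with a Haldane 0.5 correction only when a cell is
zero (flagged). BH runs across the four classes of one group (or all
classes × groups when called per group by the CLI).

tau is computed on the scale supplied (FPKM/RPKM/CPM) without a log
transform; tau is scale-invariant, so any per-sample scaling cancels,
and the original analysis did not state a transform. All-zero vectors
have no defined specificity and return NaN; callers exclude them from
ECDFs.

## Regulatory networks (`regnet`)

**Promoter windows** cover −3000..+1000 around each TSS, strand-
oriented (minus-strand windows reverse-complemented so index 0 is the
most upstream base); contig-edge truncation is flagged, coordinates are
1-based inclusive in memory and BED 0-based half-open on disk.

**Motif-cluster scanner.** The published pipeline scored promoters with
an HMM-based motif-cluster tool; reproducing its HMM internals is a
non-goal. The scanner here keeps the same interface (one maximal
cluster score per TF–gene pair) with a transparent surrogate: log₂-odds
site scores against the window's own mononucleotide background
(complement-symmetrized so scores are strand-invariant, floored at
0.01), sites = positions on either strand scoring ≥ 6 bits, and the
cluster score = the best sum of non-overlapping site scores within any
sliding 200 bp span (greedy by descending score; exact whenever sites in
a span do not overlap, deterministic always). PWM probabilities are
floored at 1e-4 before taking logs; positions containing N never form
sites. Absolute scores are not comparable to the original tool's — only
the ordering properties are claimed, and those are what the regulon
filter consumes.

**Network inference** follows the tree-ensemble importance paradigm:
each gene is regressed on the TFs (excluding itself) with a
1,000-tree random forest, square-root feature subsampling, and the edge
weight is the TF's impurity importance normalized to sum to one per
target. Raw UMI counts are the default input, per the original choice;
normalized input is accepted. Per-target seeds are spawned from the
master seed, so results do not depend on gene order. Constant targets
yield all-zero weights.

**Regulons**: weight floor 0.02 (inclusive ≥), then per TF the
ceil(0.05 × candidates) top targets by motif score, ties broken by
higher edge weight then gene id. "5% of the target genes" is read as 5%
of the post-weight-filter candidates (the pre-filter reading is the
other defensible option).

**HRG flagging.** The "95% confidence interval" of the published figure
is not defined there; the implementation flags TFs whose HRG/pre-HRG
target ratio strictly exceeds the 97.5th percentile of the across-TF
ratio distribution — a symmetric, assumption-free reading, recorded as
interpretive rather than as the authors' construction. Zero pre-HRG
denominators use max(n, 1) with a flag.

**Connectivity** C(g) = Σ_{h≠g} r(g,h)⁶; zero-variance partners
contribute 0, a zero-variance focal gene is an error. Verified against
a double loop to 1e-12.

## Mutation load (`mutload`)

The cascade is a pure conjunction (clause order irrelevant, order of
candidates preserved). Depth bounds are inclusive-retain [10, 50],
reading "depth < 10 or > 50" literally. "Within 10 bp in the same
cells" is realized as single-linkage chaining: two surviving candidates
link when they share a contig, lie ≤ 10 bp apart and their supporting
barcode sets intersect within the same cell type; connected components
become events (the most conservative event count). The DNA-seq panel
and the A-to-I site list arrive as boolean flags on candidates — their
discovery requires external alignments and is out of scope. Coverage
(bases with ≥ 10 reads) is a per-cell-type scalar supplied alongside.
The DNA-repair contrast is a two-sided Welch t-test on per-cell means
over the repair-gene set.

## Dynamics (`dynamics`)

Pseudotime and branch labels are inputs; any monotone pseudotime works.
"Scaled expression" for binned profiles is whatever the caller supplies
(the convention used here in examples: per-gene z-scored log-normalized
values), with the across-bin z-score (ddof 1) applied after binning;
constant genes are flagged and reported as zero profiles. The branch
point is the intersection of per-branch [min t, max t] ranges; an empty
intersection is reported explicitly, not raised.

Change rates: per bootstrap replicate, each day's replicate values are
resampled with replacement, day means taken, and an OLS slope fitted
over the 5-day window (two days each side). 20 bootstrap replicates is
the default, matching the published procedure. All bootstrap draws come
from one seeded generator.

Expression phylogeny: distance 1 − Pearson r on log(1 + expression),
neighbor joining, and gene-resampling bootstrap supports per internal
bipartition of the main tree. The original figure names neither its
distance nor its tree method; this pair is the common convention for
expression phylogenies and is documented as a choice, not an assertion.
Degenerate bootstrap resamples (a taxon constant) count as
non-supporting.

## Synthetic data (`synthdata`)

Generators emulate the *structure* the analyses assume, not the real
data's parameters (which the study does not report):

* **Counts**: negative binomial with variance μ + φμ² (φ = 0.1), a
  shared lognormal baseline abundance profile, markers as fold-8 mean
  elevation in disjoint blocks of 10 genes per cluster, 3 clusters ×
  200 cells of 500 genes by default, cell library sizes lognormal
  (CV ≈ 0.2) around a 5,000-UMI plan. A low-library cluster is made by
  shrinking its library-size plan only — mirroring the observation that
  small spermatids have low total UMI but high *relative* marker
  expression — never by changing folds.
* **Networks**: TF expression Gamma(2, 2); targets are
  effect × Σ(true TFs) + N(0, 1), clipped at 0; each true TF–target
  promoter carries at least one planted consensus site. Defaults: 5 TFs,
  100 targets, density 0.1, effect 2.0, 200 cells.
* **Variants**: classes planted at kilobase-spaced anchors so only the
  intended proximal pairs are proximal; A-to-I sites are A→G on the
  plus strand (the canonical editing signature); quality scores are
  integer-valued, as pileup callers emit and as VCF's single-precision
  QUAL serializes losslessly. The implied per-type rates are recorded
  in the truth object, so rate recovery is checked against the actual
  plant rather than an asymptotic target.
* **Daily counts**: piecewise-linear plan plus Gaussian noise, 20
  replicates per day (the published sampling depth), clipped at zero.
* **Species bulk**: Brownian motion of log-expression along a 5-taxon
  tree (fly outgroup, wasp, ant, two sister bees), 2,000 genes by
  default — a desk-scale stand-in for the ~5,000-ortholog table used in
  the original figure.

What passing these tests shows: the procedures recover what they are
defined to recover under their own assumptions. What it does not show:
robustness to ambient RNA, doublets, batch effects, UMI saturation,
mapping artefacts, or non-NB dispersion — none of which the generators
model (and several of which the out-of-scope upstream tools handle).

## Numerical conventions

* Exact tests (Fisher, small-sample rank-sum) use exact integer /
  enumerative arithmetic; asymptotic paths switch on at pooled n > 20
  with tie correction and continuity correction.
* PWM validation: rows sum to 1 ± 1e-6, length ≥ 4; probabilities
  floored at 1e-4 in log space.
* Degenerate inputs fail loudly (zero-variance correlation profiles,
  all-zero tau vectors → NaN, empty regulons, missing coverage) rather
  than returning silently wrong numbers; warnings are used where
  dropping is the documented behaviour (all-zero cells, zero-cell
  types, clipped negative counts).
* Determinism: every stochastic routine takes a seed; per-target /
  per-replicate streams are spawned from it, so outputs are independent
  of iteration order and reproducible across platforms.

## Problem sizes

Default test-suite problem sizes (600 cells × 500 genes; 105-gene
network with 1,000 trees; 635,376 Fisher tables; 1,000 tree bootstraps
over 2,000 genes) were chosen so the full validation runs in a few
minutes on one CPU while keeping every recovery check comfortably
powered.

## Known limitations

* The motif scanner is a surrogate: scores are not comparable to
  HMM-based cluster scores, only rank-consistent for planted signals.
* The regulon "top 5%" and the HRG-flag percentile are documented
  interpretations of under-specified published choices (see above).
* The rank-sum exact path enumerates C(n, n1) splits and is intended
  for n ≤ 20 only.
* VCF QUAL is serialized at single precision by htslib; non-integer
  quality values round-trip only approximately through the VCF dialect
  (the TSV dialect is exact).
* `collapse_proximal` treats each cell type independently; a variant
  supported by several germline cell types contributes one event to
  each, matching the per-type rate definition.
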