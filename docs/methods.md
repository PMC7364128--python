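# Methods

This note documents the models implemented in `qtlconverge`, their
assumptions, the defaults that matter, and the design choices made
where the methodology left room.

## QTL mapping by marker regression

The panel is assumed fully inbred: every strain carries one founder
allele at every locus, coded 0 (B-type) or 1 (D-type), with no
heterozygotes and no residual segregation.  Strain means are assumed
pre-computed — one trait value per strain; within-strain replicates are
out of scope.

Scans use **marker regression**: the trait is regressed on the observed
marker code itself, with no interval mapping or imputation of
pseudomarker genotypes between markers.  At marker $j$ over the $n_j$
pairwise-complete strains,

    LOD_j = (n_j/2) * log10(RSS0 / RSS1) = -(n_j/2) * log10(1 - R_j^2),

with the allele-effect sign taken from the regression slope (+1 when
the 1-coded allele increases the trait).  Markers with fewer than 3
complete observations are skipped and flagged; monomorphic markers get
LOD 0 with sign 0.  The LOD is capped at 300 when the fit is
numerically perfect, so downstream arithmetic stays finite.  Missing
data are handled pairwise-complete per marker in scans but listwise in
model fits and pair scans; the asymmetry matches common practice (a
scan should not discard a strain for a single bad call, a fixed model
matrix must be complete).

**Permutation thresholds.**  Each permutation shuffles trait values
across strains, breaking genotype–phenotype association while keeping
both marginal distributions and the marker correlation structure; the
genome-wide maximum LOD is recorded.  The significant threshold is the
95th percentile of the maxima and the suggestive threshold the 63rd
(the long-standing genome-scan convention in which roughly one
suggestive false positive is expected per scan); both percentiles are
configurable.  The default is 1000 permutations; fewer than 100 earns
a warning but still returns.

**Support intervals.**  The 1.5-LOD support interval extends from the
peak marker outward to the first markers whose LOD is at least 1.5
below the peak (bounds inclusive), clamped to the terminal scanned
markers.  The rule is an approximate 95% confidence region; the
simulation studies below measure its actual coverage rather than assume
it.

**Multi-locus models.**  `fit_multi_qtl` fits OLS with one column per
locus plus optional product columns per interaction pair.  Total
percent variance is `100 * (1 - RSS_model/RSS_null)`.  Per-term
percents use the **drop-one** decomposition (R² of the full model minus
R² without that one column), which charges shared variance to no term;
a sequential (Type-I) decomposition is available behind
`decomposition="sequential"`.  Monomorphic or collinear columns are
excluded and reported rather than silently absorbed.  Peak-marker ties
break toward the lowest genomic coordinate.

**Pair scans.**  For every eligible marker pair (different chromosomes,
or at least a configurable base-pair separation), the interaction LOD
is the LOD of the full model (two loci + product) minus the LOD of the
additive model — zero when the product term adds nothing, by nesting.
The binary coding makes all cross-moments of the product term available
from marker-by-marker matrix products, so the scan is vectorized over
all pairs; the permutation p-value for the genome-wide maximum
interaction LOD uses the same machinery per shuffle.  Whether main
effects accompany a selected interaction in a combined model is a model
hierarchy question; `fit_multi_qtl` always includes them.

## Positional candidates

Internal coordinates are 1-based inclusive (GFF3 convention); the BED
reader converts from 0-based half-open at the parser boundary and the
writer converts back, so BED round-trips are exact.  A gene is a
positional candidate when its span overlaps the support interval by at
least 1 bp — any-overlap rather than containment, matching typical QTL
candidate retrieval; containment is available behind a flag.  The
default biotype filter keeps protein-coding genes.  Candidates from
multiple intervals are pooled into one ranking with per-gene interval
provenance, since the prioritization question is "which gene anywhere
under a detected QTL converges most".

## Convergent prioritization

The gene-set corpus is a bipartite membership graph.  **Maximal
bicliques** are enumerated by a depth-first search over the set side:
each recursion extends the current set collection by one set,
intersects the gene side, and closes the collection (adds every set
containing the reduced gene side); a closure that pulls in a set below
the extension point has been visited before and is pruned.  This
enumerates each closed set-side exactly once, which is exactly the
maximal bicliques; the published enumeration algorithm for bipartite
graphs is the reference behaviour, not the internal structure.
Memberships are integer bitmasks, so extensions and closures are
word-wide ANDs; on the reference corpus (113 sets, ~7500 memberships)
enumeration takes ~25 ms.  Internal nodes require a set side of at
least 2 — single-set "bicliques" are represented by the terminals
themselves.

**HiSim graph.**  Terminals (one per input set) and internal nodes (one
per biclique) are connected by immediate-cover edges: parent → child
exactly when the child's set side is strictly contained in the parent's
with no enumerated node strictly between.  Covers are found through an
inverted index keyed by each node's rarest member set, keeping
construction near-linear in local overlap.  The graph is acyclic by
construction, parents carry strictly larger set sides and weakly
smaller gene sides.

**Bootstrap pruning.**  Each iteration draws `round(0.75 * K)` sets
*with replacement*, deduplicates, and rebuilds the hierarchy; an edge's
support is the fraction of all iterations in which the same
parent–child relation (keyed by the frozen pair of set-id collections,
not gene contents) reappears.  Edges with support ≤ 0.5 are removed,
and internal nodes left without any retained edge are dropped —
terminals always remain.  Two read-the-procedure ambiguities are
resolved as follows and kept configurable: "sampled with replacement at
75%" is taken as draw-0.75K-then-deduplicate (the draw-K-keep-75%
variant sits behind `resample_mode="keep_fraction"`), and supports are
counted against **all** iterations rather than only those in which both
endpoint collections were sampled, which makes retention a statement
about the corpus as a whole.  High-order intersections are therefore
pruned aggressively when their member sets rarely co-occur in a 75%
resample; this is the intended conservatism of the procedure.

**Ranking.**  A candidate's **degree of connectivity** is the number of
distinct corpus sets containing it — the membership count, which is the
only reading consistent with a gene node's degree in the bipartite
graph.  Ties break on the deepest retained biclique (largest set side
over retained internal nodes whose gene side holds the candidate; 0
when none), then on gene id.  Candidates absent from the corpus rank
last with degree 0.  Candidate highlighting on the graph is an
annotation, never a filter: the corpus topology is preserved.

## Synthetic data: what it emulates, what it does not

`simulate_ri_genotypes` draws, per strain and chromosome, a fair-coin
allele at the first marker and flips with probability `recomb_fraction`
at each subsequent marker.  The fraction is the *observed strain-level*
recombination rate between adjacent markers; RI map expansion (the
4r/(1+6r) relation for sib-mated lines) is deliberately not modelled —
downstream stages need realistic marker correlation, not meiotic
realism.  Real RI panels additionally show shared strain-distribution
patterns, segregation distortion and residual heterozygosity, none of
which are emulated; passing tests therefore certify the statistics, not
robustness to those artefacts.

`simulate_phenotype` builds
`y = sum_i a_i g_i + b * (g1 - mean)(g2 - mean) + eps` with
coefficients solved from the realized genotype variances so each term's
expected variance fraction equals its target, positive `a_i` (the
1-coded, D-type allele is the increaser), the epistatic term coded as a
product of mean-centered codes (orthogonal to the main effects in
expectation), and Gaussian noise filling the remainder to unit
variance.

`generate_geneset_corpus` plants each named candidate in exactly its
specified number of sets and fills the background with independent
per-gene inclusion at probability `mean_set_size / universe`, optionally
capped per gene.  Real corpora have correlated, publication-clustered
sets with heavy-tailed sizes; the independence assumption makes planted
convergence unambiguous but understates real-world biclique depth.
Empty sets are an error at generation and at GMT ingestion — they are
meaningless in a membership graph.

## Reference study conditions

The simulation studies in `qtlconverge.studies` (used by the test suite
and `scripts/acceptance.py`) fix one set of conditions:

- genome of 10 chromosomes × 120 Mb with 15 evenly spaced markers per
  chromosome (~7.5 Mb spacing) and adjacent-marker recombination
  fraction 0.25, a legacy backbone-map density at which neighbouring
  markers correlate ≈ 0.5 and a QTL peak identifies a marker rather
  than a linked block — the regime the peak-recovery statistics are
  defined in;
- 200 strains for mapping studies (100 for the threshold-calibration
  and interval-coverage studies, where the weaker setting is the point);
- two planted additive loci at 11.38% and 15.60% of trait variance on
  chromosomes 1 and 2;
- a corpus of 113 sets averaging 66.5 genes drawn from the ~16,000-gene
  annotation (mouse protein-coding scale), the planted candidate in 7
  sets, background memberships capped at 4;
- scaled study sizes chosen for a laptop-class single CPU: 100
  replicates for recovery, 200 null datasets × 200 permutations for
  type-I error, 200 replicates for coverage, and 50 pipeline runs at
  200 permutations / 25 bootstrap iterations for end-to-end recovery
  (degree ranking does not depend on bootstrap depth; the full 1000 is
  the analysis default).

Measured at these conditions (seed 1): drop-one estimates 11.6% and
15.7% for the planted 11.38%/15.60%, top-2 peak recovery 0.98,
genome-wide type-I error 0.025 at nominal 0.05, interval coverage
0.875, and the planted candidate ranked first with degree 7 in 50/50
runs.  The drop-one estimates sit slightly above their targets because
coefficients are solved against realized in-sample genotype variance.

## Numerical and degenerate-input choices

- LOD cap 300 on perfect fits; interaction LODs clipped to [0, 300].
- Percentiles via linear interpolation (`numpy.quantile` default).
- Pair-scan normal equations solved with a pseudoinverse
  (`rcond=1e-10`), so collinear or monomorphic pairs degrade to
  interaction LOD 0 instead of erroring mid-scan.
- All generators and resamplers take explicit integer seeds and are
  bit-reproducible; the pipeline derives per-stage sub-seeds from one
  seed sequence, so a fixed seed yields byte-identical artifacts.
- Heterozygote tokens in genotype files are a hard error by default
  (soft-skip to missing behind a dialect flag); duplicate genes within
  a GMT line are deduplicated with a warning; empty sets are rejected.

## Known limitations

- No covariate-adjusted or mixed-model scans: stratified analyses
  (e.g. one sex) are realized by subsetting rows before mapping.
- Marker regression only; QTL localized between markers are attributed
  to flanking markers.
- One shared gene namespace; no cross-species homology mapping.
- Bootstrap support is computed over all iterations, so relations among
  rarely co-sampled sets are penalized by design; see above.
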