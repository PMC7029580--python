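# Methods

This note records the models, conventions and design choices behind
snanno, in the order the pipeline applies them.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic cohorts

The generator emulates the structure of a droplet snRNA-seq study of
cortex in a disease/control design.  Counts are negative binomial with
mean μ and inverse-dispersion φ (variance μ + μ²/φ), sampled as a
gamma–Poisson mixture so the mean is exact for array-valued μ; φ = ∞ gives
the Poisson limit.  Defaults, chosen once as the simulated study
conditions:

| parameter | default | meaning |
|---|---|---|
| `n_nuclei_per_class` | 100 | per (class, condition); 6 × 2 × 100 ≈ 1200 nuclei |
| `n_genes` | 2000 | gene universe |
| `baseline_mean` | 0.3 counts | background gene mean; realistic snRNA-seq sparsity |
| `marker_effect` | 8 | fold elevation of a class's 40-gene marker program |
| `dispersion` | 2 | moderate droplet overdispersion |
| `doublet_rate` | 0.05 | fraction of barcodes that are summed pairs |
| `exonic_beta` | Beta(20, 20) | exonic fraction; mass inside the 25–75% window |
| `mito_beta` | Beta(2, 38) | mito fraction; mean 5%, a tail beyond the 14% cut |
| `depth_sigma` | 0.15 | lognormal spread of per-nucleus depth (mean 1) |

Class marker programs occupy consecutive 40-gene blocks overlapping by 5
(marker lists of adjacent lineages share genes, as curated lists do); the
astrocyte list additionally contains its canonical markers SLC1A2 and
GFAP.  Astrocytes carry a planted reactivity state drawn from a
per-condition mixture; the default mixture is the published composition of
the four states renormalized to sum to one (control
0.664/0.283/0.019/0.034, disease 0.026/0.614/0.230/0.130 for
Quiescent/1Q/2R/3R), because a generator that plants only rule-consistent
states cannot produce the unknown/ambiguous remainder seen in tissue.
Each state has (a) target log₂ triplet values for the three sentinel
genes, placed with ≥ 1 log unit of margin inside its rule region so that
Poisson count noise keeps the post-normalization triplet in-region with
probability ≥ 0.95, and (b) a disjoint 25-gene elevated program
(`state_marker_effect` 6) mirroring the broad MT/GFAP expression programs
that distinguish reactive sub-clusters in tissue — three sentinel genes
alone cannot dominate a 2000-gene distance, so the programs are what makes
sub-cluster recovery a fair test.  Configurations whose target triplet
falls outside its own rule region are rejected at validation.

Doublets are sums of two uniformly drawn distinct singlets, appended as
extra barcodes so they make up `doublet_rate` of the cohort; they inherit
the first member's metadata and truth class, and carry `is_doublet = True`
in the truth table, which is what tests use.

What the generator does **not** model: ambient RNA, batch structure
beyond a recorded label, gene–gene correlation within programs beyond
shared means, UMI saturation, and empirically shaped marker lists.
Passing tests therefore demonstrate the pipeline's correctness and
calibration on data satisfying its own assumptions, not performance on
tissue.

## QC

Nucleus filters: exonic fraction within [0.25, 0.75] (inclusive), mito
fraction ≤ 0.14.  Gene filter: the published phrase "> 10 counts per row
in at least in 31 cells" is ambiguous; the default reading is row total
> 10 AND detected (count > 0) in ≥ 31 nuclei.  The literal reading
(count > 10 in each of ≥ 31 nuclei) removes nearly all genes at realistic
depth and is available behind `strict_gene_filter`.  Filters run in fixed
order (nuclei → genes → doublets), each exclusion is logged exactly once
with stage and reason.

Doublet scores are a density ratio in 10-dimensional PCA space of log1p
raw counts: artificial doublets (sums of random pairs) are projected into
the same space, local densities of simulated doublets and observed nuclei
are estimated with a tricube kernel (bandwidth 3× the median 10-NN
distance), and the score is their ratio; nuclei scoring ≥ 1.5 are dropped.
Library size is deliberately not normalized away: a doublet's roughly
doubled depth is informative, and removing it would make same-class
doublets undetectable by construction.  This is a contract-level
reimplementation of the cited density method, used only as a hard
threshold.

## Normalization

Coarse pre-grouping uses average-linkage hierarchical clustering on
Spearman correlation distance, cut at the largest group count for which
every group has ≥ `min_size` nuclei (default 50); fewer than 2·min_size
nuclei yields one group with a warning.  Size factors are then estimated
per group by pooled deconvolution: nuclei are arranged on a ring ordered
by library size (ends interleaved), sliding windows of sizes
(5, 11, 21, 31, 41, 61) capped at the group size form pools, each pool
contributes the equation Σ factors = median per-gene ratio of the pooled
profile to the group mean profile, and low-weight (0.1) library-size
anchor equations pin scale and sign before a sparse least-squares solve.
The finer size grid (vs starting at 21) keeps the system well conditioned
at desk-scale group sizes; the 5% scale-equivariance contract (doubling
one nucleus's counts doubles its factor within 5%) is tested.  Non-positive
solutions fall back to the nucleus's library-size factor and are logged.
Groups are rescaled against the global mean profile by median ratio and
the factors finally scaled so their geometric mean is exactly 1.
Expression used downstream is log₂(count/factor + 1) — base 2 with
pseudo-count 1, matching the scale the state thresholds assume.  Batch is
carried as a label but not regressed out: no removal formula is specified
for the original design, so none is guessed.

## Classification

Identity scores count detection (raw count > 0; no threshold is published
for "expressed"), making them invariant to any monotone zero-preserving
transform.  Argmax ties break by the fixed class order (Neuron, Astrocyte,
Oligodendrocyte, OPC, Microglia, Endothelial).  All-zero score vectors
give Unknown + ambiguous.  Nuclei whose *maximum* score is below 20% are
dropped as low quality — the published filter does not say which score;
failing on the best class is the defensible reading.  The ambiguity
default ρ = 1 replaces the printed but arithmetically inert ρ = 2 (kept as
`literal_mode`); the tests prove both behaviours.

Pre-clusters come from a shared-nearest-neighbour graph on the tSNE
embedding (the original design's choice; PCA is available) partitioned by
walktrap.  The k-NN list of a nucleus includes the nucleus itself plus its
k−1 nearest neighbours; edges join any two nuclei appearing in a common
list, weighted by shared-neighbour count.  Walktrap fragments geometric
kNN graphs at small k — many small pre-clusters, as in the original
analysis — and the fragments are agglomerated into master classes by
majority argmax class.  Mixed pre-clusters (two or more classes scoring
within δ = 0.1 of the score range of the cluster maximum in the
cluster-level enrichment matrix) are split by each nucleus's argmax class
into `<Class>_r<orig>` clusters, with provenance recorded.

## Consensus sub-clustering

Within one master class, for each of three distance matrices (Euclidean,
Pearson, Spearman) × two spectral transforms (PCA of the distance matrix;
eigenvectors of the symmetric normalized Laplacian of a Gaussian
similarity) × dimensionalities d spanning 4–7% of n, k-means (10 inits,
seeded per run) produces a labelling; the consensus matrix is the mean of
the binary co-clustering indicators, cut by complete-linkage hierarchical
clustering at k.  Cluster quality is the average silhouette width on
consensus distances (1 − consensus).  Note the known stability/validity
conflation of consensus silhouettes: a stable ensemble saturates the
consensus towards {0,1} for *any* data, so even an arbitrary split of a
single blob can score moderately high; the tests therefore compare
spurious against planted structure rather than asserting a low absolute
null value.  Sub-clustering sees only its master class's nuclei by
construction.  A gene-exclusion option (drop named genes before
clustering, e.g. astrocytic GFAP/AQP4 from neuronal sub-clustering)
supports the exclude-then-renormalize workflow.

Default k for astrocyte sub-clustering is 4 — the number of planted
reactivity states in the default simulation; the original tissue analysis
chose 6 by silhouette examination of its own data.  k is config-exposed
per class, and the SNN k model-selection loop (count mixed pre-clusters
across k) is reported, not auto-optimized.

## Markers

The AUROC route uses the tie-aware rank formulation (Mann–Whitney U
rescaled), a normal-approximation rank-sum test with tie correction, and
Holm adjustment across genes within a cluster; records are kept at
AUROC > 0.65 and adjusted p < 0.05 (0.01 is the stricter published preset,
available via `p_max`).  The pairwise route tests each gene in each
cluster pair with a Welch t-statistic against a log-fold-change threshold
of 0.5 in "any" direction (two shifted one-sided tests, doubled minimum),
combines evidence across comparisons with Simes, and BH-adjusts across
genes.  Zero-variance gene/cluster combinations are floored at 1e-8 and
counted in a warning.  The ranked marker list sorts survivors by
descending sum of per-comparison LFCs, excluding any gene with a negative
per-comparison LFC or FDR > 0.05 regardless of its sum; ties break by gene
name under a stable sort.  The two routes deliberately use different
multiplicity corrections (Holm vs BH), each following its own published
convention.

## Gene-set scoring

Cluster-mean profiles are scored per set by: a Gaussian-kernel CDF
estimate per gene across clusters (bandwidth sd/n^{1/5}; constant rows
fall back to tied mid-ranks), per-cluster gene ranking by that statistic,
and a KS-like random walk down the ranked list with up-steps on set genes
weighted by the symmetric rank magnitude |p/2 − r + ½| and constant
down-steps elsewhere.  The score is the walk's maximum deviation from
zero (signed), the printed `mx.diff = FALSE` convention.  Scores depend on
the input only through within-gene orderings and kernel CDF values, so
they are invariant to positive rescaling or shifting of any single gene's
row (tested).  Scores are used comparatively (z-scaled by row for
display); bit parity with the cited implementation is a non-goal.
Over-representation of discrete gene lists uses the upper-tail
hypergeometric test with BH adjustment — a generic stand-in for
web-service GO enrichment, which is out of scope.

## Astrocyte states

The rule table is stored as threshold-side patterns over the three
sentinel genes; distinctness of patterns guarantees pairwise mutual
exclusivity, checked at load.  Boundary conventions follow the printed
inequalities exactly (≥ on 2/4/3, strict < elsewhere).  Under these
thresholds the Ambiguous category is provably empty and the Unknown region
non-empty (e.g. high SLC1A2 with high GFAP) — both verified by grid
enumeration in the tests; the Ambiguous label is retained for generality
of user-supplied rule sets.  Input is log₂(normalized + 1); thresholds are
config-exposed so other bases can be matched.  Trajectory interpretation
of the states is out of scope.

## Differential correlation

Genes above the 95th percentile of mean expression are kept (ties: the
top ⌈5%⌉ in stable order, with a warning).  Up to 1000 gene pairs are
sampled; per condition Pearson r, Fisher-z difference scaled by
√(1/(n₁−3) + 1/(n₂−3)), and a permutation null of 100 condition-label
shuffles.  The default null pools |z| across all sampled pairs (100
permutations of 1000 pairs give a pooled null fine enough for p < 0.01,
which 100 per-pair permutations alone cannot resolve); per-pair mode is
available.  Empirical p uses the add-one rule (1 + #{|z*| ≥ |z|})/(1 + N);
BH adjustment follows.  Pairs are classed by per-condition sign and
significance (two-sided t on r at 0.05), e.g. "+/−".  Zero-variance genes
in either condition skip their pairs, logged in `attrs["skipped"]`.
Planar-network module construction is out of scope; module gene lists are
accepted as plain gene sets by the enrichment functions.

## Pipeline and determinism

Stage order is fixed: input → nucleus QC → gene filter → doublet
exclusion → identity scoring and low-quality exclusion → normalization →
embedding → SNN pre-clustering → cluster-level enrichment and mixed
resolution → master classes → per-class consensus sub-clustering →
markers → states → differential correlation.  Per-stage nucleus/gene
tallies go to the run log; all outputs are flat TSV/JSON plus the resolved
config.  All randomness derives from one seed via `SeedSequence` spawning,
and identical config + seed gives byte-identical outputs (tested).
Default problem sizes (600-nucleus smoke cohort, 1200-nucleus study-scale
cohort) keep a full run under half a minute on one core while leaving
every per-condition astrocyte state populated.

## Known limitations

- The identity classifier is only as good as its marker lists; the
  synthetic defaults are idealized block programs.
- Consensus silhouettes measure ensemble stability, not cluster validity
  (see above).
- The doublet score is a simplified density ratio; exact parity with the
  cited library is not claimed, and only the thresholded decision is used.
- Batch is recorded, never removed.
- Gene-set scores are comparative; absolute values are not calibrated
  across universes of different size.
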