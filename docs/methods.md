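# Methods

## Count model and differential expression

Counts are modelled per gene as negative binomial,
Var(K) = μ + αμ², with a log link and the sample's log size factor as
offset. Size factors are median-of-ratios: the per-sample median of
count / gene-wise-geometric-mean over the reference set of genes with
positive counts in every sample (the plain median of ratios, not the
exponentiated median of log ratios; the two differ when the reference set
has even size). Factors are not rescaled afterwards, so normalized counts
live on the scale of the "typical" sample.

The factorial design (genotype × age × environment) is fitted with a
cell-means parameterization: one coefficient per design cell, which makes
every group contrast a simple coefficient difference. The known sequencing
batch can be added as an additive covariate (dummy-coded against the first
batch); latent-factor correction is deliberately out of scope because its
fitted surrogates are not reproducible across reruns of the data.

Dispersion is estimated in two steps. A method-of-moments estimate pools
within-cell variances of normalized counts,
α̂ = (s² − μ̄·E[1/s]) / μ̄², floored at 1e−8 and capped at 50. A log-log
linear trend log α = c₀ + c₁ log μ is then fitted across genes, and each
gene's estimate is shrunk toward the trend in log space with weight
d/(d + w₀), where d is the residual degrees of freedom of the pooled
variance and w₀ = 10 a constant prior weight. This mimics the borrow-
strength behaviour of the standard RNA-seq engines with far less machinery;
it does not reproduce their exact MAP shrinkage, and the test suite
cross-checks the resulting fold-changes against an independent
implementation of the full procedure rather than asserting equality of
p-values.

Each gene's GLM is fitted by IRLS, vectorized across genes (all genes share
the model matrix; each keeps its own dispersion). Linear predictors are
clipped to ±30 so that design cells with all-zero counts stay finite; a
ridge of 1e−10 stabilises the weighted normal equations; convergence is
max|Δβ| < 1e−8 with a 60-iteration cap. Wald statistics use the observed
information at convergence and a standard-normal reference; at n = 6 per
cell this is mildly liberal in theory, and the measured type-I error is
reported by the acceptance script rather than assumed. Genes with zero
counts in both contrasted cells are reported with log₂FC = 0 and p = 1.
Benjamini–Hochberg adjustment is applied per contrast across all tested
genes.

Thresholds (all configurable, defaults in `DEConfig`): genes with fewer
than 50 raw reads summed over all samples are removed before analysis (the
total-count reading; a per-sample-mean variant would scale the cutoff with
cohort size, which the total does not); a DEG satisfies |log₂FC| ≥ 0.3 and
adjusted p ≤ 0.1, both inclusive.

## Technical-bias filter

A sample is flagged for a gene when its log₂ normalized expression deviates
from the mean of the remaining samples of its design cell by more than 4
times their standard deviation (leave-one-out, ddof = 1; cells with < 3
samples are skipped with a warning). A gene is excluded only when some
sequencing batch accumulates at least `min_flagged = 3` flagged samples.
The recurrence requirement is what ties the exclusion to a sequencing day:
a single flagged sample is an outlier, not a day effect. The choice of 3 is
a power calculation, not a tuning constant: the leave-one-out statistic at
cell size 6 is ≈ 1.1·t₄, so a clean gene flags each sample with probability
≈ 2%; over 60 samples roughly every second clean gene would show ≥ 1 flag,
and ≥ 2 flags land in one batch for several percent of clean genes, while
≥ 3 same-batch flags are rare under noise yet certain for a genuine day
shift that touches one sample per cell.

## Trajectory classes

The environment-invariance filter takes each gene's WT 12-vs-6-month
fold-change in SE (x) and EE (y) and keeps genes with |y − x| ≤ 0.5·|x|,
i.e. the band between the lines y = 0.5x and y = 1.5x around the identity
diagonal; genes with x = 0 are inside only if y = 0. A symmetric variant
(bound 0.5·max(|x|, |y|)) is available as a config option.

Classes are boolean logic on three DEG indicators — A: window-restricted WT
temporal, B: TG temporal, C: genotype at 12 months:

* class 1 ⇐ A ∧ B with equal temporal sign,
* class 2 ⇐ ¬A ∧ (B ∨ C),
* class 3 ⇐ A ∧ ¬B,
* A ∧ B with opposing signs → explicitly unclassified (never forced into
  class 1).

Clusters split each class by direction (WT sign for classes 1/3; TG
temporal sign, falling back to the genotype sign, for class 2). Cluster
trajectories are summarised by the medoid — the member minimising the
summed Euclidean distance to all other members over the four
standard-environment cell-mean z-score points — with per-point SD over
members. z-scores use the sample (n−1) standard deviation; constant genes
map to zero. Heatmap ordering is average-linkage agglomeration on
Pearson-correlation distance 1 − r; constant genes get the maximal distance
2, and rows are pre-sorted lexicographically so ties resolve
deterministically.

## Signatures and networks

Ortholog mapping keeps only one-to-one pairs; many-to-many relations are
quarantined and reported, never silently dropped. Directional concordance
compares the sign of the midlife change (WT 12 vs 6) with the sign of the
genotype-driven change (TG vs WT at 12); a configurable dead-zone (default
0) sends near-zero fold-changes to "indeterminate". Overrepresentation of
GMT sets uses the one-sided hypergeometric upper tail with BH adjustment
across sets — a transparent replacement for proprietary pathway tools,
whose knowledgebase-specific scores are explicitly not reproduced.

The interaction network is undirected and deduplicated; self-loops are kept
in the echoed graph but excluded from every metric. Topological relevance
defaults to degree (betweenness available behind a flag). The neighbourhood
ratio n₂/(n₂+n₃) is undefined (NaN) without class-2/3 neighbours. The
compensation score clip(1 − |fc_res|/|fc_dist|, 0, 1) is computed on the
log₂ scale, consistent with all other fold-change handling; it is 1 only at
exactly zero residual and undefined at zero disturbance. Candidates are
ranked by (EE-responsive, degree, compensation) descending with
lexicographic tie-break; non-responsive genes are retained but flagged.

## Cell-type composition

Deconvolution is non-negative least squares of each sample's marker vector
on the signature matrix, normalized to the simplex — minimal, scale-
invariant, and closed to interpretation drift; the signature is an input
file so real single-cell references can be plugged in. The bundled 4-type
signature (neuron, astrocyte, microglia, oligodendrocyte) is synthetic.
Group shifts are tested by permuting group labels (difference of mean
proportions, two-sided, +1-corrected p, BH across types) — assumption-light
at small n.

## Synthetic generator

The generator is the package's study-condition definition, not a demo. Base
means are log-uniform on [5, 5000]; dispersions follow α(μ) = 3/μ + 0.05
times log-normal noise (σ = 0.2), the classic decreasing mean–dispersion
shape of bulk data. Planted offsets are exactly ±`lfc_magnitude`
(randomness enters through direction only): class 1 adds the offset to
WT-12 and TG-12, class 2 to TG-12 only, class 3 to WT-12 only, identically
in SE and EE (midlife changes are environment-invariant by construction);
stress cells carry no archetype offsets. EE compensation zeroes the
TG-12-EE offset for a configurable fraction of class-2 genes. The default
design has ten cells — both genotypes at 6 months in SE/EE and at 12 months
in SE/EE/ST — with batches assigned round-robin so each cell spreads over
sequencing days; a batch bias adds a log₂ shift to a gene subset in one
batch. Counts are gamma-Poisson draws, numerically stable down to the
Poisson limit. Library sizes default to log-normal (σ = 0.2).

What the generator does **not** emulate: correlated genes, GC/length bias,
isoform switching, outlier samples beyond the planted day shift, and
compositional (non-NB) distortions. Passing recovery benchmarks therefore
demonstrates correctness of the machinery under the stated model, not
robustness to everything real data can do.

## Known limitations

* The diagonal-window filter acts on *estimated* fold-changes. At n = 6 per
  cell the SE-vs-EE fold-change difference for a truly invariant gene has a
  standard deviation of ≈ 0.3–0.4 even for well-expressed genes (the
  dispersion floor keeps it ≈ 0.27 as μ → ∞), which is of the same order as
  the window half-width 0.5·|fc|. A substantial minority of genuinely
  environment-invariant midlife genes therefore falls outside the window,
  and — because such genes still carry the genotype-at-12 signal — class-3
  genes pushed outside are misassigned to class 2. This caps attainable
  class-3 recovery well below 100% at these sample sizes; the acceptance
  script reports the measured values.
* Because every union gene descends from per-contrast BH calls at FDR 0.1,
  the class universe necessarily contains false-positive null genes at
  roughly the FDR level united over contrasts.
* The dispersion shrinkage is deliberately simpler than the MAP estimators
  of the standard engines; p-values at very low counts are correspondingly
  rougher.
* The NNLS deconvolution reports point estimates only; no uncertainty
  propagation.
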