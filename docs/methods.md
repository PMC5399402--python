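# Methods

## Study structure and data model

The pipeline targets paired omics time courses from cold-storage
experiments on fruit peel: an expression block (genes × samples, RPKM-like
non-negative values) and a metabolite block (relative abundances), with
samples indexed by treatment ∈ {control, DPA, MCP}, storage day, and
replicate, plus an ordinal scald-severity score (1 = no symptoms …
4 = >50% surface coverage). Blocks are held samples × variables in memory
(`OmicsBlock`), written variables-as-rows on disk.

## Preprocessing

**Gene filter.** A gene is kept iff (a) at least one (treatment, day)
cell has a replicate sum strictly greater than the RPKM threshold
(default 5), and (b) it is detected — replicate sum > 0 — in at least two
cells. "Detected" is defined as a non-zero sum because zero RPKM is the
only unambiguous non-detection. The filter is idempotent and invariant to
sample order; genes failing (a) are reported under that rule even when
they also fail (b). Metabolites are never filtered.

**Autoscaling.** Each variable is mean-centred and divided by its sample
standard deviation (n−1 denominator, the chemometrics convention).
Means/sds are stored so the transform is invertible to 1e−10; constant
variables are dropped and reported rather than raising. The Y matrix
(treatment dummies, day, scald) is autoscaled with the same convention so
both sides of the model share a scale. An optional log2(x+1) pre-transform
for the metabolite block is exposed but off by default: whether raw
abundances should be logged is data-dependent, and correlations and PLS
directions on the synthetic data are insensitive to it at the noise levels
used.

## Multi-block PLS

Consensus NIPALS with a super-score layer. Per component: block weights
w_b ∝ X_bᵀu (unit norm within block), block scores t_b = X_b w_b; super
weights ∝ Tᵀu over the matrix of block scores (unit norm); super score
T = Σ_b ws_b t_b; Y-weights q = YᵀT/TᵀT; u = Yq/qᵀq until convergence
(relative tolerance 1e−12). Blocks *and* Y are deflated by the super
score, which makes successive super scores exactly orthogonal and reduces
the model to ordinary NIPALS PLS2 when only one block is supplied (the
test suite checks this against an independently written PLS2 at 1e−6).
Each autoscaled block is additionally divided by √p_b before fitting so
block size does not dominate the super level; weight normalization makes
VIPs invariant to this factor. Component signs are fixed by making the
largest-magnitude Y-weight positive. SSY_ar, the explained sum of squares
of response r by component a, is ‖T_a‖²q_ar². The default A = 3
components reflects the number of interpretable score planes in this kind
of storage time course; it is configurable.

## VIP normalization

Raw (Wold) VIP per response uses block-normalized weights, so
Σ_{j∈b} VIP_j² = p_b identically. Printed summaries in this field assert
two facts simultaneously: the average VIP equals one, and the block-mean
VIP ratio between blocks equals the inverse ratio of their sizes (≈60×
for 610 vs 36,253 variables). The only per-block affine rescaling
consistent with both is *equal block sums*: each block's VIPs are
multiplied by a constant so Σ_{j∈b} VIP_j = P_total/B. The grand mean is
then exactly 1 and mean ratios equal p_b'/p_b. The alternative convention
(equal Σ VIP² per block) would preserve neither printed fact and is not
used; raw VIPs are reported alongside for transparency.

**Selection.** Per block, variables with VIP > μ + z_p·σ are flagged,
with z_p the upper-p standard-normal quantile (a t with ∞ df; p = 0.33 →
z ≈ 0.4399) and σ the within-block sd (n−1). Single-variable blocks have
undefined σ: nothing is selected and a warning is emitted. Selected
variables are signed by their Pearson correlation with the chosen
response over all observations; exact zero correlation falls to "+" by
convention and is logged.

## Cluster summarization

Expression profiles (genes as points, samples as dimensions, autoscaled)
are smoothed by reconstructing the matrix from its first 10 principal
components, then partitioned by a single run of Lloyd's k-means started
from k_init = 100 gene profiles drawn uniformly without replacement.
Empty clusters persist during iteration (keeping their centroid) and are
deleted only after convergence (assignments stable, or 300 iterations);
within-cluster SSE is asserted non-increasing at every step. Cluster
means are computed on the scaled but *unsmoothed* expression — smoothing
exists only to stabilize centroid estimation. Deliberate over-clustering
followed by correlation-based grouping is the intended regime, so the
recovery tests measure majority-mapping agreement (splits of a planted
cluster are acceptable; merges of distinct planted clusters are errors).

## Correlation networks

Profiles are the cluster means plus individual metabolites, restricted to
a storage-day window: days {0, 7, 14, 28, 61} for the pre-symptomatic
"2-month" network, all days for the "6-month" network. Correlation uses
replicate-level observations (more observations stabilize r; results at
the tested noise levels are insensitive to averaging replicates first).
An undirected edge requires r² ≥ 0.700 — magnitude only, the sign is
stored on the edge — and carries weight 1 − r². Constant-in-window
profiles are excluded and logged. Anchor analysis takes the induced
first-neighbor subgraph of a configured anchor metabolite (defaults CTOL
for the early window, methanol for the late one); genes of adjacent
clusters are then re-screened individually and kept only at r² ≥ 0.700
with the anchor trace over the window. Node metrics (degree, neighborhood
connectivity = mean neighbor degree, clustering coefficient; both 0 by
convention for degree ≤ 1 nodes) are validated against brute-force
adjacency enumeration. Graph layout is delegated to downstream viewers
via GraphML export.

## Over-representation analysis

For each annotation bin with at least one background gene, k (list genes
in bin) follows Hypergeom(N, K, n) under the null; p_over = P(X ≥ k) and
p_under = P(X ≤ k) are reported as two one-sided tests because over- and
under-representation are interpreted separately. Bonferroni multiplies by
the number of bins actually tested. Direction is the smaller adjusted
tail when it clears α = 0.05, else "none". Bins are tested at the full
bin-path level only; testing ancestor prefixes as well would, with
single-bin gene annotations, duplicate leaf counts and create ties.
Legacy "ORA cutoff" display thresholds from bin-visualization tools are
not reproduced; exact p values are reported instead.

## Synthetic data generator

The generator defines the conditions every stochastic test runs under:
3 treatments × 8 days (0, 7, 14, 28, 61, 92, 123, 183) × 3 replicates
= 72 observation columns, with day-0 values generated once and shared
across treatments (treatments are applied at harvest, so the
pre-treatment state is common). Defaults: 2,000 genes, 120 metabolites.

Planted signals, each with a unit-height curve c(day), an amplitude
(log2 fold change at full height, default 3) and per-treatment
multipliers in [0, 1]:

* *biphasic_early* (CTOL-like): 0 until onset (day 14), linear rise to a
  mid-storage peak (day 61), linear decline to 0 at the final day;
  strongly suppressed under DPA/1-MCP (multipliers 0.15/0.10).
* *sigmoidal_late* (methanol-like): exactly 0 through its onset (day 61,
  i.e. a rise beginning between 8 and 12 weeks), then a logistic ramp
  (τ = 45 d); present essentially only in control fruit (multipliers
  1/0.05/0).
* *monotone_ripening*: proportional to day; attenuated by 1-MCP (0.35).

log2 abundance = baseline (log-uniform over [3, 9], i.e. 8–512 on the
raw scale) + amplitude·c(day)·multiplier + N(0, noise_sd), default
noise_sd 0.25 — additive Gaussian on the log scale is the standard
log-normal noise assumption for relative-abundance platforms. All
entities linked to one signal share the amplitude, so at vanishing noise
every linked gene is exactly proportional to its signal's metabolite
trace (r² = 1), which makes the planted-correlation invariants exact.
One gene cluster is planted per signal (60/90/80 genes): clusters sharing
a curve would be statistically unidentifiable after per-gene scaling, so
multiple same-shape clusters would test nothing; the `PlantedSignal` type
nevertheless supports several clusters per signal. The scald trajectory
is deterministic: control 1 until day 61, then 2/3/4 at days 92/123/183;
DPA 1 until a minor 2 at day 183; MCP 1 throughout. Each planted cluster
receives its own annotation bin; background genes cycle through 12
generic bins.

**What the generator does not emulate:** count noise and
library-size effects of sequencing, missing or censored metabolite peaks,
batch/run-order drift, unequal replicate numbers between platforms, and
biological correlation among "noise" genes. Passing recovery tests
therefore demonstrate that the pipeline's inference is correct when its
assumptions hold, not that those assumptions hold for any particular
instrument's output.

## Problem sizes and numerical choices

The test suite exercises the full default generator scale (2,000 genes ×
72 samples, five seeds) and a 63 × (610 + 36,253) fit for the block-ratio
figure; both complete in seconds, so no down-scaling was needed. Fixed
conventions: PCA/PCA-smoothing sign fixed by the largest-magnitude
loading; k-means ties in assignment resolve to the lowest cluster index
(numpy argmin); VIP tables break ORA sorting ties lexicographically;
all randomness flows from explicit integer seeds and identical configs
reproduce output bytes.

## Known limitations

No cross-validated choice of the number of components, no permutation
validation of the MB-PLS model, no sparse/orthogonal PLS variants, no
community detection beyond first neighbors, and no imputation — inputs
must be complete. The VIP block-rescaling convention is an inference from
the two printed normalization facts it must satisfy (see above); other
conventions exist but are inconsistent with those facts.
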