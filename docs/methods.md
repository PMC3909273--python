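# Methods

## Scope and model

The package analyses single-cell morphology screens in which every cell is
described by a vector of positive numeric features and a treatment-condition
(TC) label.  The analysis assumes that the population occupies a small
number of discrete shape classes discoverable as clusters in a
low-dimensional principal-component space, that per-condition shape
*fractions* are the right summary of a perturbation's effect, and that
dependencies between those fractions across conditions reflect the order in
which cells traverse shape space.

## Preprocessing

Each feature is independently min–max scaled to [0, 1] over all cells, a
constant offset (default 0.01) is added, and the natural log is taken.  The
offset keeps the log finite at the per-feature minimum; the scaling makes
the offset commensurate across features.  Zero-range (constant) features
cannot be min–max scaled; all their values are mapped to 0 before the
offset and log, and the event is logged — this keeps the transform total
without inventing variation.  Scaling constants are recorded so held-out
cells can be transformed identically.  Min–max is computed globally per
feature (not per plate or condition); this is an interpretive choice.

PCA is covariance PCA on the transformed table (features are already on a
common scale, so correlation PCA would discard meaningful differences in
spread).  The default retains a fixed three components; an optional rule
retaining components with ≥ 5% variance is available but off by default.
Component signs are fixed by making each component's largest-magnitude
loading positive, which makes results identical across BLAS backends.

## Shape-class discovery

Two model families are swept over an inclusive k range (default 5..30 —
26 values per method, 52 models; the range is configurable):

* hierarchical agglomerative clustering, Euclidean distance, Ward linkage,
  cut at k (the merge tree is computed once per sweep);
* Gaussian mixtures with full covariances, k-means++ initialisation,
  diagonal regularisation 1e-6, and the best total log-likelihood of 10 EM
  restarts.  Restart r draws its RNG stream from (seed, r), so the model
  chosen from m restarts is always among the candidates of any larger
  restart budget with the same seed — selection is monotone in restarts.

Model quality is the mean silhouette value with Euclidean distances in PC
space.  Silhouettes are computed in-package (chunked, never materialising
the full distance matrix) with two conventions: cells in singleton clusters
score 0, and cells whose intra- and inter-cluster distances both vanish
(exact duplicates) score 0.  The implementation is tested for exact
agreement with an O(n²) double-loop oracle.  Ties in model selection go to
hierarchical clustering, then to smaller k.

Cells with silhouette below a threshold (default 0.6) are reassigned by
majority vote of their 10 nearest confident cells; the reference set is
global rather than per-cluster.  Vote ties go to the nearest voting
neighbour whose label is among the tied winners.  A single pass is made, and
silhouettes are recomputed on the final labels; both before- and
after-correction means are reported.

## Heterogeneity profiles

A condition's TCHP is its vector of per-shape cell fractions; profiles are
normalised by subtracting the wild-type TCHP, giving zero-sum vectors.  The
distance between two normalised profiles weights their difference by how
far apart the shapes lie in PC space: with Δ the profile difference and M
the matrix of Euclidean distances between per-shape mean PC coordinates,

    D(x₁, x₂) = sqrt(max(0, −Δ M Δᵀ)).

A Euclidean distance matrix is conditionally negative definite on zero-sum
vectors, so the negated quadratic form is non-negative and D is a
pseudometric (the max(0, ·) only absorbs round-off).  Fractions rather than
percentages are used throughout; distances scale linearly, so clusterings
are unchanged.  Condition clustering is complete-linkage agglomeration on
the precomputed D matrix.  The number of condition clusters is a required
configuration (default 17): the original selection rule maximised overlap
with an external reference grouping that is not available here.

Enrichment is strict: a shape is enriched in a condition when its fraction
exceeds 0.10, so a shape at exactly 10% is not enriched.

## Boolean Rac/Rho model

The model is static: two compartments (cortical, adhesion), each in one of
three activity states (RAC, RHO, NONE — mutual antagonism is structural in
the encoding), pruned by two toggleable rules: at least one GTPase active
somewhere (excludes only the all-off state), and cortical RAC forcing
adhesion-compartment activity (excludes cortical RAC with a silent adhesion
compartment).  Under the defaults exactly 7 of the 9 raw states survive;
lifting the forcing rule gives 8, lifting both gives 9.  The global-activity
rule is read as "at least one compartment active": the per-compartment
reading would leave only 4 states, contradicting the seven observed shapes.
No update dynamics are implemented — upstream regulators (RhoGEFs/RhoGAPs)
can move the system between states at any time, so the model is enumerated,
not iterated.  The state→shape map ships with textual evidence per entry;
the three entries that rest on shape characteristics rather than an explicit
statement are marked "inferred" and are configurable.

## Consensus Bayesian network

Shape fractions are rescaled per shape onto [0, 1]; constant columns (a
shape absent everywhere) are zeroed, excluded from learning and reported.
Each of the (default 500) runs resamples conditions with replacement and
greedily climbs the BGe score from the empty graph — add/delete/reverse
moves, first strictly improving move in a freshly shuffled order — to a
local optimum.  Undirected edges present in ≥ 60% of runs are kept,
directed by the majority of their directed occurrences (even when neither
direction alone reaches the threshold), and signed by the Pearson
correlation of the two shapes on the full panel.  The consensus of DAGs
need not be acyclic; acyclicity is reported, never enforced.

The BGe score uses a normal-Wishart prior with prior sample size 1,
degrees of freedom d + 2, prior mean equal to the column means, and a
prior scale matrix equal to the diagonal of the empirical column
variances.  The scale choice matters: a fixed scale that is large relative
to the data scatter (for [0, 1]-rescaled fractions, even the identity)
inverts the score's Occam penalty, and independent columns then *gain*
edges.  Matching the prior scale to the data keeps the penalty positive, so
null panels yield empty graphs.  Score equivalence across Markov-equivalent
DAGs holds for any fixed scale matrix and is verified by exhaustive
enumeration of equivalence classes on up to five nodes.

### Compositional closure and what the network tests show

Shape fractions sum to 1 in every condition, so any panel of them carries
one exact linear constraint: its covariance is singular and each shape is
(near-)deterministic given all the others.  No sparse acyclic model is
faithful to such data — the constraint itself is a dependence that only a
dense graph can express — so a Gaussian-score learner that can use many
parents will genuinely support edges beyond any planted topology.  In
practice the consensus on planted synthetic panels recovers every planted
edge with the correct sign (sensitivity), and independent-column null
panels yield no edges, but the consensus also retains closure-induced extra
edges (specificity fails); the corresponding test is kept at face value and
fails honestly.  Interpreting consensus networks from compositional panels
therefore requires treating edge presence as reliable for strong planted
dependencies while expecting additional closure artefacts.

## Shape transitions

Every consecutive frame pair of every cell contributes one transition count
(self-pairs included: the diagonal is the probability of staying put);
row-normalised counts are the maximum-likelihood Markov estimate.  Rows for
never-visited shapes are reported all-zero with an explicit flag rather
than smoothed (add-α smoothing is available, default 0).  Both the
self-pair-inclusive transition tally and the off-diagonal-only tally are
reported.  The consistency report lists the empirical probability of every
network edge, flags observed transitions with no corresponding edge
(including child→parent back-transitions), and totals the probability mass
crossing between the rounded block {1, 2, 3} and the spread block {5, 6, 7}.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
three levels.

**Cells.**  Each shape class is a Gaussian archetype in a 3-D latent
morphology space (mirroring the three retained PCs).  Default centroids sit
on cube corners scaled so the minimum pairwise separation is 8× the
within-class spread.  Features are exp(Az + b + ε): the lift A (entries
N(0, 1/3)) and intercept b are drawn once per loading seed and then fixed,
giving reproducible correlated features; the exponential keeps all values
strictly positive so the offset/log stage is exercised end to end.  The
exponential-affine lift is a modelling convenience, not a claim about real
feature distributions.

**Condition panels.**  The wild-type mixture defaults to the measured
control distribution (3, 0, 6.9, 20, 17, 18.6, 33.8% for shapes 1–7),
renormalised from its printed 99.3% total.  Perturbed conditions propagate
Gaussian noise (sd 0.01) ancestrally through a planted signed DAG —
default: shape 5 at the top, positive arcs to 6 and 7, negative arcs to 1,
3 and 4, arc weight 0.8 — centre the perturbation to zero sum over the
wild-type support, and clip/renormalise.  The noise scale keeps
perturbations within the linear range of the smallest wild-type fraction
(3%), so the planted correlations survive the clip; it is deliberately
smaller than the shape-fraction swings of a real screen, a trade made so
that the planted dependency structure, rather than clipping nonlinearity,
dominates the panel.  A shape absent from the wild type (shape 2) appears
in a small random subset of conditions at sub-enrichment fractions,
independent of everything else.

**Trajectories.**  Independent first-order Markov chains, default 37 frames
at 5-minute intervals (a 3-hour acquisition).  The default matrix is
diagonal-dominant with shape 1 near-absorbing (97% self-transition), a 25%
shape-5→6 and 15% shape-6→7 probability, relatively frequent 6/7→5
back-transitions, and rare block crossings.

Passing tests on these data show that the pipeline's machinery is correct
under its own assumptions — well-separated Gaussian classes, log-normal-ish
features, linear-regime perturbations, first-order Markov dynamics.  They
do not show robustness to the ways real screens deviate: overlapping shape
classes, batch and plate effects, heavy-tailed features, segmentation
errors, or non-Markov shape memory.

## Problem sizes and numerical choices

The default pipeline and the verification scripts run at ~2,000 cells
(64 conditions × 31 cells) for clustering and at 256 conditions for network
inference; trajectory statistics use a few hundred chains.  The
cluster-number recovery check uses a balanced base mixture: at screen-like
rarity a 13-cell seventh class is genuinely merged by the maximum-mean-
silhouette criterion (the merged model scores higher), so the balanced
panel is what makes the seven-class question well-posed at this cell count.
Transition-recovery checks use simultaneous 95% Clopper–Pearson intervals
(Bonferroni across matrix entries), the joint-coverage reading under which
"all entries within their interval" is itself a 95% event.  Hill-climbing
score improvements must exceed 1e-9 to count; consensus bootstrap redraws
a resample once if it produces a zero-variance column.  All randomness is
explicit: every stage takes a seed, GMM restarts and consensus runs derive
per-iteration streams from it, and identical configurations reproduce
identical manifests.
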