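# Methods

## Model

A detected LC-MS feature is a finite set of intensity-weighted peaks in the
(RT, m/z) plane. After RT scaling (below), each feature is normalised to a
unit-mass discrete measure: weights are intensities divided by the feature's
total intensity. Normalisation makes the trash penalty comparable across
features of very different abundance; relative total intensity between
features is deliberately discarded, since correspondence should not depend on
abundance differences between runs.

The dissimilarity between two measures μ and ν is the unbalanced
(generalized) Wasserstein distance with total-variation mass penalty:

    GWD(μ, ν) = min_{T ≥ 0, T_μ ≤ μ, T_ν ≤ ν}
                Σ T(x,y) d(x,y) + λ (|μ| − |T|) + λ (|ν| − |T|),

with d the ℓ1 distance in scaled coordinates. Equivalent formulation: add a
virtual trash point to each measure (absorbing mass at λ per unit, free
trash-to-trash transport) and solve a *balanced* problem. Properties used
throughout: GWD is symmetric, saturates at λ(|μ|+|ν|) = 2λ for unit masses,
and for two Dirac masses equals min(d, 2λ) exactly.

One consequence worth stating: with an ℓ1 ground metric, when two features'
supports are disjoint along an axis every feasible plan costs exactly the
centroid displacement along that axis — the shape of the envelope only
discriminates when features (partially) overlap. Shape information therefore
resolves ambiguous matches between nearby/overlapping candidates (the swap
case) but cannot help for candidates far apart; this mirrors the method's
known failure mode on very distant correspondences.

## RT scaling

RT spans thousands of seconds, m/z envelopes a few Da. RT is divided by
`k · mean(feature RT span) / mean(feature m/z span)` with `k = 1` by default
(`rt_scale_k`). Features with zero span on an axis are excluded from that
axis's mean (single-peak features would otherwise bias the ratio) but are
still scaled and alignable. The factor is logged for every run.

## Solvers

**Exact reference.** The LP is solved with HiGHS over the n·m plan variables
after absorbing the constant penalty: minimise Σ T(d − 2λ) subject to the
marginal inequalities. Intended for supports up to ~50 points; it serves as
the oracle in the test suite, never in the pipeline.

**Sinkhorn–Knopp.** The trash-augmented balanced problem is regularized with
an entropic term of strength ε (default λ/100) and solved by log-domain
diagonal scaling. An ε-annealing ladder (geometric, factor 4, 25 sweeps per
level) warm-starts the potentials; at the target ε, iteration stops when the
worst marginal violation falls below `tol` (default 1e-6), when the
potentials become stationary (the entropic fixed point is reached but sits
above `tol` — the value is still accurate, flagged `converged=False`), or at
`max_iter` (default 5000, with a warning). The reported cost is the linear
transport objective of the resulting plan, excluding the entropy term; no
further debiasing is applied. On 200 random pairs of ≤10-point measures the
worst deviation from the exact LP is ~0.3% at the default ε.

Supports larger than `max_support` (default 500 points) are coarsened by
intensity-weighted binning on a grid before transport (memory and time are
quadratic in support size).

## Candidate pruning

Pairwise GWDs are computed only for feature pairs whose centroid ℓ1 distance
is at most `window` (default 2λ): beyond that the distance has saturated and
can never beat the trash option, so absent cache entries are exact, not
approximate, prunings.

## Matching

With >2 runs, centroids of all features are clustered: mini-batch k-means
with k = ceil(total/n_runs) × `overcluster` (default 2, seed 42), followed by
average-linkage agglomerative merging of the k-means centers with Manhattan
distance threshold `cluster_cut`. The cut defaults to λ/4 and approximates
the intra-analyte centroid scatter across runs; it must stay well below the
spacing between distinct analytes, because every cluster admits at most one
matched feature per iteration — overmerged clusters directly cap how many
features can be matched at all (we measured a three-run alignment collapse
from F=1.00 to F=0.21 when the cut was set an order of magnitude too wide).

Each chromatogram serves once as the target (L side) against the pooled
features of all others (R side). The flow network is: source→L_i (capacity 1),
L_i→R_j (capacity 1, cost = GWD, only for cached candidate pairs), R_j→its
cluster C_k (capacity 1), C_k→sink (capacity 1), plus L_i→Tr (capacity 1,
cost c) and Tr→sink (capacity n) so that any feature may stay unmatched at
cost `c` (default 1.9λ, just under saturation). Costs are scaled by 10^4 and
rounded to integers for the network simplex; ties after rounding are broken
by node construction order, which is deterministic. The solved flow always
has value n, and decoding follows unit flows L→R→C. Consensus features are
the per-cluster unions of matched features over all iterations; clusters
matched by fewer than two runs are dropped unless `keep_singletons` is set.

For exactly two runs the cluster layer is omitted (L→R→sink directly),
which is a plain optimal assignment with a trash option.

λ should be chosen so that the trash cost 1.9λ comfortably exceeds the
largest expected drift distance in scaled units: if true correspondences
cost nearly as much as trashing, chains of one wrong-but-near match plus one
trashed feature become globally cheaper than the truth. The default λ=15
covers uniform drifts of ±150 s / ±0.3 Da under the generator's default
geometry with about 2× margin.

## Synthetic data

The generator emulates what upstream feature detection delivers for a
nanoflow LC-MS/MS run, at reduced scale: `n_features` = 200 analytes with
uniform random monoisotopic m/z in 300–1100 Da, elution apex uniform in
0–2000 s, charge 1–3, 4 isotopologues spaced 1/z Da with a geometric
envelope (ratio 0.7), Gaussian elution profile (σ = 10 s, i.e. ~40 s base
width, typical of long-gradient peptide peaks) sampled every 3 s (a typical
MS1 survey cycle), and a per-feature abundance factor uniform in 0.5–2.
Drift simulation shifts every feature rigidly and independently by uniform
draws within ±`rt_range` (default 150 s) and ±`mz_range` (default 0.3 Da).

What this does *not* emulate: chemically accurate isotope abundances,
peak-shape tailing, co-eluting interferences, missing or split detections,
and intensity variation of individual peaks between runs. Passing tests on
these data therefore demonstrate the geometry of the matching problem
(drift, density, swaps, envelope shapes), not robustness to detection
artifacts in real chromatograms.

The dedicated swap scenario builds two same-m/z features with *symmetric but
different* isotope envelopes (peaked vs. broad over 5 isotopologues) whose
elution order reverses between runs. Symmetry makes their centroids
coincide, so any centroid-based cost is exactly ambiguous between the
correct and the crossed pairing, while the transport distance sees the
envelope shapes and resolves the swap.

## Evaluation metrics

For each ground-truth consensus set G the best-intersecting tool consensus
t* is selected (ties: larger intersection, then smaller |t*|); recall(G) =
|t*∩G|/|G|, precision(G) = |t*∩G|/|t*|, both averaged arithmetically over
all G, F their harmonic mean (reported to 2 dp). Note that averaging P and R
over dataset fractions does not commute with the harmonic mean, so
fraction-averaged published tables need not satisfy F = 2PR/(P+R) exactly.
Identification recall is the fraction of identifications repeating in ≥2
chromatograms of a subset whose annotated features all lie in one tool
consensus. A correspondence pair counts as swapped when the RT order of its
two features differs between runs (exact ties are non-swaps), and as
resolved when both correspondences are recovered by the matcher.

## Problem sizes and defaults used in the shipped experiments

The acceptance script uses 200 features for the two-run drift experiment,
100 features × 3 runs (±60 s / ±0.1 Da inter-replicate drift, a moderate
replicate-level drift) for the clustered multi-run path, and 200 random
measure pairs for the solver-accuracy sweep. These sizes exercise every code
path at chromatogram densities comparable to the emulated experiments while
keeping a full run to about two minutes on a single CPU.

## Known limitations

- Distant correspondences (drift ≫ feature extent) are matched on centroid
  geometry only; a nearer wrong candidate can camouflage the true partner.
  Mitigation is parametric (λ, window) and partial by design.
- The featureXML reader uses convex-hull points with uniformly apportioned
  intensity; subordinate mass-trace peaks would be a richer alternative
  where present.
- featureXML files storing RT in minutes are not auto-detected; pass
  `--rt-minutes` to convert (silent unit guessing would corrupt the scaled
  distances).
- Clustering quality gates the multi-run path: `cluster_cut` must lie
  between the intra-analyte drift scatter and the inter-analyte spacing; no
  default can satisfy that for every dataset, so the knob is exposed.
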