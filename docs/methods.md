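# Methods

## Generative model

A parcellation world consists of P voxels with coordinates, hemisphere
labels and a left/right mirror pairing (`VoxelSpace`). Each subject's latent
parcel assignment vector U is drawn independently per voxel from the group
probabilities `p(U_{k,i}) = softmax_k(η_{k,i})`; the K×P log-potentials η
are the arrangement model's parameters. Conditional on U, every dataset's
emission model generates the subject's functional profiles: within session
n, the voxel's unit-normalized condition profile is von Mises–Fisher (vMF)
with mean direction v_k^n (one per parcel) and concentration κ^n (one per
session, shared across parcels). Profiles are unit vectors because task
activation estimates are normalized per voxel and session before modeling;
the discarded vector length is retained and reused as a signal-strength
weight in the prediction-error metric.

Assumptions worth stating explicitly: voxels are conditionally independent
given U (no spatial coupling in the prior — spatial coherence of fitted maps
comes entirely from the data); sessions are independent given U; one κ per
session means every parcel in a session is equally concentrated; and missing
voxel/session blocks are missing completely at random (they are simply
dropped from both E- and M-step sums).

## Fitting

All parameters are estimated by EM on the marginal likelihood
`Σ_i log Σ_k softmax(η)_{k,i} p(y_i | U_i=k)` summed over subjects of all
datasets. The E-step yields per-subject K×P posteriors; the M-step updates

- v_k^n as the normalized posterior-weighted resultant of the session
  profiles;
- κ^n from the mean resultant length r̄ via the Banerjee approximation
  `κ ≈ r̄(d − r̄²)/(1 − r̄²)` followed by up to 10 Newton steps on the exact
  score `A_d(κ) = r̄` (Bessel ratio), clipped to [1e-3, 1e5];
- η as the log of the across-subject mean posterior (floored at 1e-10
  before the log). In the symmetric model the mean posterior is first
  averaged over the two hemispheres through the (voxel-mirror, parcel-shift
  K/2) pairing and tiled back, which keeps the group map exactly
  mirror-symmetric; hemisphere confinement is enforced by −1e6 potentials,
  whose softmax contribution underflows to exactly zero. Self-paired
  midline voxels (possible in user-supplied spaces, absent from the default
  synthetic grids) split their mass equally between parcel k and k+K/2 — a
  documented convention.

All vMF normalizers are evaluated in the log domain with exponentially
scaled Bessel functions (`scipy.special.ive`), finite for κ up to 1e5 and
dimensions of several hundred conditions.

**Initialization.** Each start draws η as iid noise of scale 1.0 around
uniform, and then initializes *every* dataset's emission model with one
M-step from that same prior. This consensus initialization is deliberate:
initializing each dataset's mean directions independently at random lets
each emission model lock onto its own arbitrary parcel permutation within
the first hard E-step, after which the shared arrangement cannot realign
them — the fit converges to a state whose partition is fine but whose
parcel identities disagree across datasets, at a large likelihood cost.
Seeding all emissions from one shared prior makes parcels crystallize with
matching labels. Multi-start selection (default 20 starts in tests;
production fits of real atlases use thousands) keeps the best final
marginal log-likelihood; convergence is a relative log-likelihood change
below 1e-6 (default) or 200 iterations.

**Coarse-to-fine refits** transfer η to a finer voxel grid by
nearest-neighbor correspondence and continue EM from that single start —
the standard way to fit at low resolution first and refine.

**Desymmetrization.** The asymmetric companion atlas freezes the fitted
emission models and re-runs EM over the arrangement only, dropping the
mirror tie but keeping each parcel confined to its hemisphere. Because this
relaxes a constraint from an EM stationary point, the marginal likelihood
can only rise; the per-voxel correlation between symmetric and asymmetric
probability vectors is the boundary-symmetry index.

## Individual precision mapping

Given a fitted atlas and a subject's localizer data, three maps are
defined: `group` (prior only), `data_only` (emission likelihood only), and
`integrated` (their normalized product — Bayes rule). For localizer tasks
outside the training task sets, a new emission model is trained with the
arrangement frozen, pooling all available subjects; it is initialized from
the constant-direction emission so its first posterior equals the group
prior exactly, anchoring the new model to the atlas labels
deterministically. Winner-take-all maps break ties toward the lowest parcel
index. "Amount of data" is manipulated by the number of localizer runs
used; runs are i.i.d. condition replicates, and run-averaging before
normalization is what makes more runs more concentrated.

## Evaluation metrics

- **ARI** between winner-take-all maps (chance-corrected pair counting;
  label-permutation invariant, which is also how the mixture's label
  degeneracy is handled throughout).
- **Reliability-adjusted ARI** across a granularity ladder: the mean
  between-set ARI over different-granularity pairs divided by the geometric
  mean of the two within-set mean ARIs (within = ARI between different
  granularities of the same set). Same-granularity pairs are excluded from
  the between mean as well as from the within means, keeping numerator and
  denominator commensurate; a set compared with an identical copy scores
  exactly 1.
- **DCBC**: within-parcel minus between-parcel mean Pearson correlation of
  session-concatenated normalized profiles, per spatial-distance bin, then
  averaged across bins with the variance-minimizing weights
  n_w·n_b/(n_w+n_b). Defaults: bin width 1 template unit, maximum distance
  35 units; both configurable. Individual DCBC follows a two-fold localizer
  protocol: half the held-out dataset trains a localizer emission, each
  subject's integrated map is derived from their own localizer half and
  scored on the other half, folds are swapped and averaged, and the group
  map is scored on the same halves for comparability.
- **Prediction error**: each test voxel is predicted by its assigned
  region's mean profile estimated from the remaining subjects; the error is
  1 − cosine(prediction, data), averaged with the data vector's length as
  weight.
- **Inter-subject variability**: all-pairs between-subject correlation of
  concatenated split-half profiles, each pair normalized by
  √(rel_s·rel_t) of the subjects' split-half reliabilities
  (non-positive-reliability pairs dropped), averaged and divided by the
  mean reliability for the per-voxel map.
- **Classical (Torgerson) MDS** of 1 − similarity for embedding
  parcellation similarities; also the basis of the colormap.

## Atlas hierarchy and characterization

Parcel functional similarity is the κ·N-weighted mean (over sessions and
datasets; N = subject count) of cosine similarities between
hemisphere-averaged mean directions. Parcels that win no voxels are merged
iteratively — smallest first, into the functionally most similar parcel, by
summing probability columns (hemisphere pairs merge jointly in symmetric
atlases), refitting the emissions with the arrangement fixed after each
merge. Domains come from average-linkage agglomerative clustering on cosine
distance; the number of domains is a parameter (the dendrogram gives no
canonical cut). Names follow Domain letter + region number (medial→lateral
by mean winner-voxel |x|) + hemisphere. The colormap embeds the similarity
in 3-D by classical MDS and aligns it to ≥3 anchor colors by orthogonal
Procrustes with uniform scaling, clipped to the RGB cube. The
lateralization index is the κ·N-weighted session cosine between each
left/right voxel pair's probability-weighted mean profiles. Covariate
adjustment of region profiles (e.g. movement counts) is closed-form ridge
regression on z-normalized design and profiles.

## Connectivity

Per subject, cortical parcel activity X (conditions × Q) predicts
cerebellar voxel activity Y by ridge regression, `W = (XᵀX + λI)⁻¹XᵀY`.
λ is tuned per dataset on cross-dataset prediction (grid default
10⁻²…10⁴, ties to the smallest λ). Evaluation averages W over training
subjects — always excluding the evaluated subject — and scores the cosine
similarity of the concatenated predicted and observed patterns (a
per-voxel variant is exposed as well). Fusion is the plain mean of weight
matrices across datasets, with the same leave-one-subject-out discipline.
The noise-ceiling adjustment divides a score by √(rel_cereb·rel_pred) of
split-half reliabilities; this formula is one explicit interpretation of a
reliability-based ceiling and is flagged as such.

## Synthetic worlds

The generator emulates the structure of a multi-dataset parcellation study:
a mirror-symmetric 2-D voxel grid; a ground-truth group map built as a
softened Voronoi partition (probability ∝ exp(−smoothness·distance to a
parcel seed); smoothness→∞ gives hard labels); per-dataset session mean
directions drawn uniformly on the sphere; subjects drawn label-wise from
the group map and profile-wise from the vMF emissions. Default study
conditions: two datasets of 5 subjects, two 10-condition sessions each,
κ = 20, two runs. Specific experiments set the parameters their question
needs, chosen a priori:

- *recovery*: smoothness 8 (a near-deterministic truth — recovery is only
  well-posed when the truth itself is identifiable);
- *fusion gain*: smoothness 4 and two datasets whose session means are tied
  within complementary parcel pairings, so each alone resolves only half
  the boundaries;
- *precision mapping*: smoothness 2 (mean maximal group probability ≈ 0.8,
  so individuals genuinely deviate from the group map) and a 6-subject
  localizer dataset with κ = 10 and 32 runs;
- *DCBC null*: spatially smooth but parcel-free data, generated by
  convolving white condition noise (60 conditions, the scale of a broad
  task battery) on a source lattice that extends three kernel lengthscales
  beyond the grid, so the field is stationary up to the edge —
  edge-truncated smoothing would correlate peripheral pairs extra and bias
  boundary metrics;
- *connectivity*: three datasets sharing a ground-truth W (unit-scale
  normal entries) plus a small dataset-level perturbation (sd 0.1) and
  subject-level noise (sd 1.0), the "similar but not identical" regime in
  which both diagonal dominance of cross-dataset prediction and fusion
  gain hold.

What the synthetic worlds do **not** emulate: hemodynamics, temporally or
spatially autocorrelated noise, realistic anatomy or lobular geometry,
inter-subject misalignment, and session-level nonstationarities. Passing
tests therefore demonstrate the correctness and calibration of the
algorithms under the stated generative assumptions, not performance on real
fMRI.

## Numerical choices and degenerate inputs

κ clipped to [1e-3, 1e5]; posterior floor 1e-10 before logs; winner ties to
the lowest index; zero or all-missing voxel-session blocks are flagged and
skipped, never fatal; a parcel with zero posterior weight keeps its
previous mean and is flagged; constant probability vectors make the
boundary-symmetry correlation undefined (NaN) at that voxel; a
rank-deficient design with zero penalty is an error rather than a silent
pseudo-inverse. Run splits with odd run counts use the floor for the first
half. All randomness flows through `numpy.random.default_rng` seeds; the
pipeline manifest records content hashes so reruns are bit-checkable.

## Known limitations

- The independent-voxel prior cannot encode spatial smoothness; with weak
  data the individual maps inherit the group map rather than a spatially
  regularized compromise.
- When true parcel sizes are very unbalanced, multi-start EM may split a
  large parcel and absorb a small one; the partition ARI stays high but a
  few mean directions then match the truth poorly. More starts mitigate
  but do not eliminate this.
- DCBC on regular grids retains a small positive bias (~0.002 under the
  null at default binning) from the discreteness of lattice distances
  within bins.
- The hierarchy's domain count and the anchor colors are user choices; the
  naming scheme, not specific anatomical labels, is implemented.
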