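# parcelfuse

Probabilistic functional brain parcellation by multi-dataset fusion.

Functional atlases of structures like the cerebellum are usually built from a
single task-fMRI dataset, so they inherit that dataset's task battery and its
noise. `parcelfuse` implements a hierarchical Bayesian framework that fuses
many functional datasets — differing in subjects, task conditions, sessions
and reliability — into one probabilistic group parcellation, and then tailors
that group atlas to a new individual from a small amount of localizer data.

The package is aimed at researchers who want to (a) build or re-fit fused
probabilistic parcellations, (b) derive individual precision maps from a
group atlas, (c) evaluate parcellations with boundary- and prediction-based
metrics, or (d) study cortico-cerebellar connectivity — and at method
developers, who can exercise every stage on fully synthetic worlds with
known ground truth.

## The model

Each voxel `i` of subject `s` carries a latent parcel assignment
`U_i^s ∈ {1..K}`. Two components define the generative model:

- **Arrangement model (group prior).** Voxels are independent with
  `p(U_{k,i}) = softmax_k(η_{k,i})` for a K×P matrix of log-potentials θ_A =
  {η}. A *symmetric* variant confines parcels 1..K/2 to the left hemisphere
  and K/2+1..K to the right and ties every left voxel's probabilities to its
  mirrored right voxel's, yielding exactly mirror-symmetric group maps while
  functional profiles remain hemisphere-specific.
- **Emission models (one per dataset).** Within dataset `n`, a voxel's
  unit-normalized session profile y is von Mises–Fisher distributed around
  its parcel's session mean direction, `p(y | U=k) ∝ exp(κⁿ vₖⁿ·y)`, with
  one concentration κⁿ per session shared across parcels. κ measures a
  session's reliability and is also the weight with which the dataset pulls
  on the fused group map.

All parameters are estimated jointly by multi-start EM. From a fitted model
one derives the probabilistic group map `p_group = softmax(η)`, a data-only
individual map `p_data ∝ p(Y|U)`, and the Bayes-integrated individual map
`p_indiv ∝ p(Y|U) p(U)`. Evaluation uses the Distance-Controlled Boundary
Coefficient (within- minus between-parcel profile correlation, averaged
inside spatial-distance bins), signal-weighted cosine prediction error, and
reliability-adjusted ARI across a granularity ladder. Further modules build
a functional hierarchy over parcels (merging, domains, naming, a
similarity-derived RGB colormap, lateralization and boundary-symmetry
indices) and fused cortico-cerebellar ridge-regression connectivity.

## Worked example

```python
import numpy as np
import parcelfuse as pf

# simulate a two-dataset world with a known symmetric 10-parcel organization
space, truth, datasets = pf.make_world(width=20, height=20, K=10,
                                       smoothness=8.0, symmetric=True, seed=0)

# fuse both datasets into one probabilistic group atlas
model = pf.fit_fusion(datasets, K=10, symmetric=True, space=space,
                      n_starts=20, max_iter=200, seed=1)
print(f"marginal log-likelihood: {model.fit_info['loglik']:.1f}")
ari = pf.adjusted_rand_index(model.hard_labels(),
                             np.argmax(truth.group_prob, axis=0))
print(f"group-map recovery ARI vs ground truth: {ari:.3f}")
print(f"estimated session kappas (dsA): {np.round(model.emissions['dsA'].kappa, 1)}")

# tailor the atlas to one subject from a single localizer run
from parcelfuse.emission import prepare_dataset
subject = prepare_dataset(datasets[0].select_runs([0]))[0]
indiv = pf.individual_map(model, model.emissions["dsA"], subject, "integrated")
group_ari = pf.adjusted_rand_index(model.hard_labels(), truth.subject_labels["dsA"][0])
indiv_ari = pf.adjusted_rand_index(indiv.hard_labels, truth.subject_labels["dsA"][0])
print(f"subject's true labels vs group map:      ARI {group_ari:.3f}")
print(f"subject's true labels vs integrated map: ARI {indiv_ari:.3f}")
```

Output:

```
marginal log-likelihood: 30296.8
group-map recovery ARI vs ground truth: 0.961
estimated session kappas (dsA): [36.4 36. ]
subject's true labels vs group map:      ARI 0.948
subject's true labels vs integrated map: ARI 1.000
```

The fused group map recovers the generating parcellation almost perfectly
(ARI 0.961; the residual reflects genuinely ambiguous boundary voxels of the
probabilistic truth). The estimated κ ≈ 36 refers to the run-averaged
profiles, which are more concentrated than the per-run draws. For the single
subject, one run of localizer data combined with the group prior by Bayes
rule pinpoints that subject's individual parcel layout exactly (ARI 1.000),
where the group map alone leaves idiosyncratic voxels wrong (ARI 0.948) —
the core of functional precision mapping.

A `parcelfuse` command-line tool exposes the same functionality
(`simulate`, `fit`, `individual`, `evaluate`, `hierarchy`, `connect`, and an
end-to-end `run` driven by a YAML config that writes a deterministic
manifest).

As estimators, `parcelfuse.FusedParcellation` (fit / predict /
predict_proba) and `parcelfuse.RidgeConnectivity` (fit / predict / score)
follow scikit-learn conventions and compose with its model-selection tools.

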