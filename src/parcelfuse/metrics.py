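"""Parcellation evaluation: ARI, reliability-adjusted ARI, DCBC, weighted
cosine prediction error, inter-subject variability and classical MDS.

The Distance-Controlled Boundary Coefficient (DCBC) asks whether a
parcellation's boundaries separate function: within each spatial-distance
bin it takes the mean Pearson correlation of functional profiles for
voxel pairs inside a parcel minus that for pairs straddling a boundary,
then averages the bin differences with variance-minimizing weights. The
distance binning removes the trivial advantage that near pairs are both
more correlated and more often within-parcel.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .data import FunctionalDataset
from .emission import PreparedSubject, prepare_dataset
from .fusion import FusedModel
from .spaces import VoxelSpace


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model ARI from the contingency table (label-invariant)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.size == 0 or labels_b.size == 0:
        raise ValueError("empty labelings")
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings differ in length")
    return float(adjusted_rand_score(labels_a, labels_b))


def reliability_adjusted_ari(parcellations_a, parcellations_b) -> float:
    """Between-set ARI corrected for each set's internal consistency.

    Both arguments are ladders of labelings at several granularities. The
    mean ARI over between-set granularity pairs is divided by the geometric
    mean of the two within-set mean ARIs (within = ARI between different
    granularities of the same set), so unreliable parcellations are not
    penalized twice. Same-granularity pairs are excluded from the between
    mean as well, keeping numerator and denominator commensurate — this
    makes a set's similarity to an identical copy exactly 1 instead of
    inflating it through the trivial same-granularity agreements.
    """
    a = [np.asarray(x) for x in parcellations_a]
    b = [np.asarray(x) for x in parcellations_b]
    if len(a) != len(b):
        raise ValueError("ladders must cover the same granularities")
    between = np.mean(
        [
            adjusted_rand_index(x, y)
            for i, x in enumerate(a)
            for j, y in enumerate(b)
            if i != j
        ]
    )
    within_a = np.mean(
        [adjusted_rand_index(x, y) for x, y in itertools.combinations(a, 2)]
    )
    within_b = np.mean(
        [adjusted_rand_index(x, y) for x, y in itertools.combinations(b, 2)]
    )
    if within_a <= 0 or within_b <= 0:
        raise ValueError("unreliable parcellation: non-positive within-set ARI")
    return float(between / np.sqrt(within_a * within_b))


class DistanceBinning:
    """Precomputed voxel-pair distance bins for a voxel space.

    Bins are half-open ``[b, b + width)`` in template units; pairs beyond
    ``max_dist`` are excluded. Only unordered pairs (i < j) are stored.
    """

    def __init__(self, space: VoxelSpace, bin_width: float = 1.0, max_dist: float = 35.0):
        self.bin_width = float(bin_width)
        self.max_dist = float(max_dist)
        d = space.pairwise_distances()
        i, j = np.triu_indices(space.n_voxels, k=1)
        dij = d[i, j]
        keep = dij < self.max_dist
        self.pair_i = i[keep]
        self.pair_j = j[keep]
        self.bin_id = np.floor(dij[keep] / self.bin_width).astype(int)
        self.n_bins = int(self.bin_id.max()) + 1 if self.bin_id.size else 0


def profile_matrix(subject: PreparedSubject) -> np.ndarray:
    """Session-concatenated normalized profiles, the input DCBC correlates."""
    return np.concatenate(subject.Y, axis=1)


def dcbc(
    hard_labels: np.ndarray,
    data: np.ndarray,
    space: VoxelSpace,
    binning: DistanceBinning | None = None,
) -> float:
    """Distance-Controlled Boundary Coefficient of a hard parcellation.

    ``data`` is a P x N matrix of functional profiles (one row per voxel).
    Per distance bin the mean profile correlation of within-parcel pairs
    minus that of between-parcel pairs is formed; bins lacking either kind
    of pair are skipped, and the remaining differences are averaged with
    weights ``n_w n_b / (n_w + n_b)``. Positive values mean boundaries
    separate function better than distance alone predicts.
    """
    hard_labels = np.asarray(hard_labels)
    if len(np.unique(hard_labels)) < 2:
        raise ValueError("no boundaries to evaluate: single-parcel labeling")
    if binning is None:
        binning = DistanceBinning(space)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(np.asarray(data, dtype=float))
    r = corr[binning.pair_i, binning.pair_j]
    same = hard_labels[binning.pair_i] == hard_labels[binning.pair_j]
    ok = np.isfinite(r)

    num = 0.0
    den = 0.0
    for b in range(binning.n_bins):
        sel = (binning.bin_id == b) & ok
        w_mask = sel & same
        b_mask = sel & ~same
        n_w, n_b = int(w_mask.sum()), int(b_mask.sum())
        if n_w == 0 or n_b == 0:
            continue
        diff = r[w_mask].mean() - r[b_mask].mean()
        weight = n_w * n_b / (n_w + n_b)
        num += weight * diff
        den += weight
    if den == 0:
        raise ValueError("no distance bin contains both within- and between-pairs")
    return float(num / den)


def dcbc_individual(
    model: FusedModel,
    test_dataset: FunctionalDataset,
    space: VoxelSpace,
    binning: DistanceBinning | None = None,
) -> pd.DataFrame:
    """Group- vs individual-boundary DCBC on a held-out dataset.

    One half of the test dataset (by runs) serves as localizer: a
    dataset-specific emission model is trained on it across subjects
    (arrangement frozen), each subject's integrated winner-take-all map is
    derived from their own localizer half, and boundaries are scored on the
    other half. Roles are then reversed and the two folds averaged. The
    group map is scored on the same held-out halves so the comparison is
    like-for-like. The caller is responsible for having left
    ``test_dataset`` out of the model's training.
    """
    from .precision import individual_map, train_localizer_emission

    if binning is None:
        binning = DistanceBinning(space)
    half_a, half_b = test_dataset.split_half_by_runs()
    group_labels = model.hard_labels()
    scores = np.zeros((test_dataset.n_subjects, 2, 2))  # subject x fold x (group, indiv)
    for fold, (loc, ev) in enumerate([(half_a, half_b), (half_b, half_a)]):
        emission = train_localizer_emission(model, loc)
        prep_loc = prepare_dataset(loc)
        prep_ev = prepare_dataset(ev)
        for s in range(test_dataset.n_subjects):
            eval_profiles = profile_matrix(prep_ev[s])
            indiv = individual_map(model, emission, prep_loc[s], "integrated")
            scores[s, fold, 0] = dcbc(group_labels, eval_profiles, space, binning)
            scores[s, fold, 1] = dcbc(indiv.hard_labels, eval_profiles, space, binning)
    mean = scores.mean(axis=1)
    return pd.DataFrame(
        {
            "subject": test_dataset.subjects,
            "dcbc_group": mean[:, 0],
            "dcbc_individual": mean[:, 1],
        }
    )


def prediction_error(
    hard_labels: np.ndarray,
    train_subjects_data: list[np.ndarray],
    test_subject_data: np.ndarray,
    train_labels: list[np.ndarray] | None = None,
) -> float:
    """Signal-weighted cosine error of region-mean predictions.

    Region means are estimated from the training subjects' data (each
    averaged over the voxels its labeling — ``train_labels``, defaulting to
    ``hard_labels`` — assigns to the region). Each test voxel is predicted
    by its assigned region's mean; the error is one minus the cosine of
    prediction and data vector, averaged with the data vector's length as
    weight so strong-signal voxels count more. Voxels whose region has no
    training voxels (or zero-length data) are excluded.
    """
    hard_labels = np.asarray(hard_labels)
    Y = np.asarray(test_subject_data, dtype=float)
    if train_labels is None:
        train_labels = [hard_labels] * len(train_subjects_data)
    K = int(hard_labels.max()) + 1
    means = np.zeros((K, Y.shape[1]))
    counts = np.zeros(K)
    for X, lab in zip(train_subjects_data, train_labels):
        X = np.asarray(X, dtype=float)
        for k in range(K):
            vox = np.flatnonzero(np.asarray(lab) == k)
            if vox.size:
                means[k] += np.nansum(X[vox], axis=0)
                counts[k] += vox.size
    defined = counts > 0

    lengths = np.linalg.norm(Y, axis=1)
    num = 0.0
    den = 0.0
    for i in range(Y.shape[0]):
        k = hard_labels[i]
        if not defined[k] or lengths[i] == 0:
            continue
        v = means[k]
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        err = 1.0 - float(v @ Y[i]) / (nv * lengths[i])
        num += lengths[i] * err
        den += lengths[i]
    if den == 0:
        raise ValueError("no voxel had a defined region prediction")
    return float(num / den)


def inter_subject_variability(dataset: FunctionalDataset) -> np.ndarray:
    """Per-voxel reliability-normalized inter-subject correlation map.

    Each subject contributes two independent half-data profile estimates
    (first/second half of the runs). Between-subject Pearson correlations of
    the concatenated half-profiles are normalized per pair by the square
    root of the product of the two subjects' split-half reliabilities
    (non-positive-reliability pairs are dropped), averaged over pairs, and
    finally divided by the mean reliability — one value per voxel, as used
    for visualization. NaN where nothing valid remains.
    """
    half1, half2 = dataset.split_half_by_runs()
    a = half1.average_runs().data  # (S, P, N)
    b = half2.average_runs().data
    S, P, _ = a.shape
    rel = np.array([_rowwise_corr(a[s], b[s]) for s in range(S)])  # (S, P)
    conc = np.concatenate([a, b], axis=2)

    num = np.zeros(P)
    n_pairs = np.zeros(P)
    for s, t in itertools.combinations(range(S), 2):
        r = _rowwise_corr(conc[s], conc[t])
        denom = rel[s] * rel[t]
        ok = denom > 0
        num[ok] += r[ok] / np.sqrt(denom[ok])
        n_pairs[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_mean = num / n_pairs
        out = pair_mean / rel.mean(axis=0)
    return out


def _rowwise_corr(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching rows of two (P, N) matrices."""
    Xc = X - np.nanmean(X, axis=1, keepdims=True)
    Yc = Y - np.nanmean(Y, axis=1, keepdims=True)
    num = np.nansum(Xc * Yc, axis=1)
    den = np.sqrt(np.nansum(Xc**2, axis=1) * np.nansum(Yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def mds_embed(similarity: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a similarity matrix.

    Dissimilarity is ``1 - similarity``; squared dissimilarities are double
    centered and the top ``dims`` eigenvectors, scaled by the square roots
    of their (positive) eigenvalues, give the coordinates.
    """
    S = np.asarray(similarity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("similarity must be symmetric")
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int(np.sum(vals > 1e-10))
    if dims > n_pos:
        raise ValueError(f"only {n_pos} positive eigenvalues; cannot embed in {dims}-D")
    return vecs[:, :dims] * np.sqrt(vals[:dims])
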