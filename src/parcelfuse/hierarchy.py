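"""Functional characterization of a fitted atlas.

From a fused model this module derives: a kappa-and-sample-size weighted
functional similarity between parcels; an iterative merge of parcels that
win no voxels into their functionally closest neighbor; an agglomerative
grouping of parcels into functional domains with systematic names
(Domain letter + medial-to-lateral region number + hemisphere + subregion
letter); a similarity-preserving RGB colormap via 3-D classical MDS
anchored to user-chosen colors; lateralization and boundary-symmetry
indices; region-size asymmetries; and covariate-adjusted functional
profiles by ridge regression.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import squareform

from .arrangement import Arrangement
from .fusion import FusedModel, prepare_all
from .spaces import VoxelSpace


@dataclass
class ParcelHierarchy:
    """Merge history, nested granularity levels, names and colors."""

    merge_tree: list = field(default_factory=list)  # (children tuple, parent) steps
    levels: dict = field(default_factory=dict)  # name -> per-parcel label vector
    names: list = field(default_factory=list)
    colors: np.ndarray | None = None

    def to_lookup_table(self) -> pd.DataFrame:
        colors = self.colors if self.colors is not None else np.zeros((len(self.names), 3))
        return pd.DataFrame(
            {
                "index": np.arange(len(self.names)),
                "name": self.names,
                "R": colors[:, 0],
                "G": colors[:, 1],
                "B": colors[:, 2],
            }
        )


def _session_weights(model: FusedModel) -> dict:
    """Per dataset: session weight kappa^n * N^n (N^n = subject count)."""
    n_subjects = model.fit_info.get("n_subjects", {})
    out = {}
    for ds_id, emi in model.emissions.items():
        N = float(n_subjects.get(ds_id, 1))
        out[ds_id] = emi.kappa * N
    return out


def parcel_similarity(model: FusedModel, hemisphere_average: bool = True) -> np.ndarray:
    """Weighted-mean cosine similarity of parcel functional profiles.

    Mean directions are first averaged across left/right parcel pairs
    (``hemisphere_average``, requires the symmetric parcel layout), cosine
    similarity is taken per session, and sessions are combined with weights
    ``kappa^n * N^n`` across all datasets.
    """
    weights = _session_weights(model)
    K = model.K
    if hemisphere_average:
        if K % 2 != 0:
            raise ValueError("hemisphere averaging requires even K")
        m = K // 2
    else:
        m = K
    num = np.zeros((m, m))
    den = 0.0
    for ds_id, emi in model.emissions.items():
        for n, v in enumerate(emi.V):
            if hemisphere_average:
                v = 0.5 * (v[: K // 2] + v[K // 2 :])
            norms = np.linalg.norm(v, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            u = v / norms
            w = float(weights[ds_id][n])
            num += w * (u @ u.T)
            den += w
    return num / den


def refit_emissions(
    model: FusedModel, datasets, max_iter: int = 50, tol: float = 1e-6
) -> None:
    """EM over the emissions only, arrangement probabilities held fixed."""
    from .fusion import e_step

    prepared = prepare_all(datasets)
    prev = -np.inf
    for _ in range(max_iter):
        posteriors, ll = e_step(model.arrangement, model.emissions, prepared)
        for ds_id, subjects in prepared.items():
            model.emissions[ds_id].m_step(posteriors[ds_id], subjects)
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            break
        prev = ll


def merge_until_winners(
    model: FusedModel, datasets, max_merges: int | None = None
) -> tuple[FusedModel, ParcelHierarchy]:
    """Iteratively absorb parcels that win no voxels.

    While some parcel wins fewer voxels than every other (zero allowed), the
    smallest parcel is merged into its functionally most similar parcel by
    summing their probability columns; the emissions are then refit with the
    arrangement fixed. On symmetric models the merge is applied to the
    left/right parcel pair jointly so symmetry is preserved. Stops when
    every parcel wins at least one voxel (or one parcel remains).
    """
    model = model.copy()
    tree: list = []
    symmetric = model.arrangement.symmetric
    n_done = 0
    while True:
        labels = model.hard_labels()
        K = model.K
        counts = np.bincount(labels, minlength=K)
        if symmetric:
            m = K // 2
            pair_counts = counts[:m] + counts[m:]
            if pair_counts.min() > 0 or m <= 1:
                break
            small = int(np.argmin(pair_counts))
            sim = parcel_similarity(model, hemisphere_average=True)
        else:
            if counts.min() > 0 or K <= 1:
                break
            small = int(np.argmin(counts))
            sim = parcel_similarity(model, hemisphere_average=False)
        np.fill_diagonal(sim, -np.inf)
        target = int(np.argmax(sim[small]))
        model = _merge_pair(model, small, target, symmetric)
        refit_emissions(model, datasets)
        tree.append(((small, target), min(small, target)))
        n_done += 1
        if max_merges is not None and n_done >= max_merges:
            break
    hier = ParcelHierarchy(merge_tree=tree)
    return model, hier


def _merge_pair(model: FusedModel, a: int, b: int, symmetric: bool) -> FusedModel:
    """Merge parcel a into b by summing probability columns; drop parcel a.

    For symmetric models a and b index hemisphere pairs: (a, a+K/2) merges
    into (b, b+K/2).
    """
    prob = model.group_prob()
    K = model.K
    keep: np.ndarray
    if symmetric:
        m = K // 2
        prob[b] += prob[a]
        prob[b + m] += prob[a + m]
        keep = np.array([k for k in range(K) if k not in (a, a + m)])
    else:
        prob[b] += prob[a]
        keep = np.array([k for k in range(K) if k != a])
    new_prob = prob[keep]
    arr = model.arrangement
    new_arr = Arrangement.__new__(Arrangement)
    new_arr.symmetric = arr.symmetric
    new_arr.hemisphere_locked = arr.hemisphere_locked
    new_arr.space = arr.space
    new_arr.eta = np.log(np.maximum(new_prob, 1e-300))
    mask = new_arr.allowed_mask()
    new_arr.eta = np.where(mask, new_arr.eta, -1e6)

    new_emis = {}
    for ds_id, emi in model.emissions.items():
        e = emi.copy()
        e.K = len(keep)
        e.V = [v[keep] for v in e.V]
        new_emis[ds_id] = e
    return FusedModel(arrangement=new_arr, emissions=new_emis, fit_info=dict(model.fit_info))


def build_domains(
    similarity: np.ndarray,
    n_domains: int,
    model: FusedModel | None = None,
    space: VoxelSpace | None = None,
) -> ParcelHierarchy:
    """Group parcels into functional domains by agglomerative clustering.

    Average linkage on cosine distance (1 - similarity); the tree is cut at
    ``n_domains`` (and at ``min(K, 2 n_domains)`` for a medium level, nested
    by construction). Names follow Domain letter + region number +
    hemisphere: regions are numbered within each domain from medial to
    lateral when winner-voxel coordinates are available, by index otherwise.
    """
    S = np.asarray(similarity, dtype=float)
    m = S.shape[0]
    if n_domains > m:
        raise ValueError("more domains than parcels")
    if n_domains == m:
        domains = np.arange(m)
        Z = None
    else:
        D = 1.0 - S
        np.fill_diagonal(D, 0.0)
        D = 0.5 * (D + D.T)
        Z = linkage(squareform(D, checks=False), method="average")
        domains = fcluster(Z, t=n_domains, criterion="maxclust") - 1
    n_medium = min(m, 2 * n_domains)
    medium = (
        np.arange(m)
        if Z is None or n_medium == m
        else fcluster(Z, t=n_medium, criterion="maxclust") - 1
    )
    # force exact nesting: relabel medium clusters within their domain
    medium = _nest_levels(domains, medium)

    lateral_pos = _lateral_position(model, space, m)
    names = _assign_names(domains, lateral_pos)
    hier = ParcelHierarchy(
        levels={"fine": np.arange(m), "medium": medium, "domain": domains},
        names=names,
    )
    hier.merge_tree = [] if Z is None else [((int(a), int(b)), m + i) for i, (a, b, *_ ) in enumerate(Z)]
    return hier


def _nest_levels(coarse: np.ndarray, fine: np.ndarray) -> np.ndarray:
    """Relabel ``fine`` so its clusters never straddle a coarse cluster."""
    out = np.zeros_like(fine)
    next_id = 0
    for c in np.unique(coarse):
        idx = np.flatnonzero(coarse == c)
        for f in np.unique(fine[idx]):
            sel = idx[fine[idx] == f]
            out[sel] = next_id
            next_id += 1
    return out


def _lateral_position(model, space, m) -> np.ndarray:
    if model is None or space is None:
        return np.arange(m, dtype=float)
    labels = model.hard_labels()
    pos = np.full(m, np.inf)
    for k in range(m):
        vox = np.flatnonzero((labels == k) | (labels == k + m) if model.K == 2 * m else labels == k)
        if vox.size:
            pos[k] = float(np.abs(space.coords[vox, 0]).mean())
    return pos


def _assign_names(domains: np.ndarray, lateral_pos: np.ndarray) -> list[str]:
    letters = string.ascii_uppercase
    names = [""] * len(domains)
    for d in np.unique(domains):
        members = np.flatnonzero(domains == d)
        order = members[np.argsort(lateral_pos[members], kind="stable")]
        for rank, k in enumerate(order):
            names[k] = f"{letters[d % 26]}{rank + 1}"
    return names


def expand_names_to_hemispheres(names: list[str]) -> list[str]:
    """Left/right name pairs share Domain+number: ['A1', ...] -> A1L...A1R."""
    return [n + "L" for n in names] + [n + "R" for n in names]


def colormap_from_similarity(similarity: np.ndarray, anchors: dict) -> np.ndarray:
    """Similarity-preserving RGB colors for parcels.

    3-D classical MDS of the similarity structure, orthogonally aligned
    (rotation/reflection + uniform scale via Procrustes on the anchor
    subset) to the anchor parcels' RGB targets, translated to the anchor
    color centroid, and clipped into the unit RGB cube. Needs at least 3
    anchors for a determined alignment; rank-deficient similarities are
    zero-padded with a warning.
    """
    import warnings

    if len(anchors) < 3:
        raise ValueError("need at least 3 color anchors")
    S = np.asarray(similarity, dtype=float)
    m = S.shape[0]
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int(np.sum(vals > 1e-10))
    if n_pos < 3:
        warnings.warn("similarity has rank < 3; padding MDS coordinates with zeros")
    dims = min(3, max(n_pos, 1))
    X = np.zeros((m, 3))
    X[:, :dims] = vecs[:, :dims] * np.sqrt(np.maximum(vals[:dims], 0.0))

    idx = np.array(sorted(anchors.keys()))
    C = np.array([anchors[k] for k in idx], dtype=float)
    Xa = X[idx] - X[idx].mean(axis=0)
    Ca = C - C.mean(axis=0)
    R, scale_num = orthogonal_procrustes(Xa, Ca)
    denom = (Xa**2).sum()
    scale = scale_num / denom if denom > 0 else 1.0
    Y = scale * (X - X[idx].mean(axis=0)) @ R + C.mean(axis=0)
    return np.clip(Y, 0.0, 1.0)


def lateralization_index(model: FusedModel, space: VoxelSpace) -> np.ndarray:
    """Per-voxel weighted cosine similarity of mirrored functional profiles.

    Each voxel's session profile is the group-probability-weighted mix of
    the parcel means; for every left/right voxel pair the session cosines
    are averaged with weights ``kappa^n * N^n``. Both partners receive the
    pair's value; self-paired (midline) voxels are excluded (NaN).
    """
    prob = model.group_prob()  # (K, P)
    weights = _session_weights(model)
    P = space.n_voxels
    num = np.zeros(P)
    den = 0.0
    mirror = space.mirror
    for ds_id, emi in model.emissions.items():
        for n, v in enumerate(emi.V):
            profiles = prob.T @ v  # (P, N_n)
            a = profiles
            b = profiles[mirror]
            na = np.linalg.norm(a, axis=1)
            nb = np.linalg.norm(b, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cos = np.sum(a * b, axis=1) / (na * nb)
            w = float(weights[ds_id][n])
            num += w * cos
            den += w
    out = num / den
    out[mirror == np.arange(P)] = np.nan
    return out


def boundary_symmetry(
    sym_model: FusedModel,
    asym_model: FusedModel,
    level: str = "group",
    datasets=None,
) -> np.ndarray:
    """Per-voxel correlation between symmetric and asymmetric parcel
    probability vectors; 1 where the boundary geometry is unchanged.

    ``level='individual'`` averages the correlation over all subjects'
    integrated individual maps (requires ``datasets``). Voxels with a
    constant probability vector in either model are NaN.
    """
    if sym_model.K != asym_model.K:
        raise ValueError("models must share K")
    if level == "group":
        return _colwise_corr(sym_model.group_prob(), asym_model.group_prob())
    if level != "individual":
        raise ValueError("level must be 'group' or 'individual'")
    if not datasets:
        raise ValueError("individual level requires datasets")
    from .emission import prepare_dataset
    from .precision import individual_map

    maps = []
    for ds in datasets:
        for subj in prepare_dataset(ds):
            p_sym = individual_map(sym_model, sym_model.emissions[ds.dataset_id], subj)
            p_asym = individual_map(asym_model, asym_model.emissions[ds.dataset_id], subj)
            maps.append(_colwise_corr(p_sym.posterior, p_asym.posterior))
    return np.nanmean(maps, axis=0)


def _colwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=0, keepdims=True)
    Bc = B - B.mean(axis=0, keepdims=True)
    num = np.sum(Ac * Bc, axis=0)
    den = np.sqrt(np.sum(Ac**2, axis=0) * np.sum(Bc**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def profile_regression(
    region_profiles: np.ndarray, design: np.ndarray, l2: float = 1.0
) -> np.ndarray:
    """Covariate-adjusted functional profiles via ridge regression.

    Columns of the design (condition x feature, e.g. presses/saccades per
    second alongside condition indicators) and of the region profiles
    (condition x region) are z-normalized across conditions, then the ridge
    solution ``(X'X + l2 I)^-1 X'Y`` separates motor-feature loadings from
    condition activations.
    """
    X = _zscore_columns(np.asarray(design, dtype=float))
    Y = _zscore_columns(np.asarray(region_profiles, dtype=float))
    G = X.T @ X
    if l2 == 0.0 and np.linalg.matrix_rank(G) < G.shape[0]:
        raise ValueError("rank-deficient design requires l2 > 0")
    return np.linalg.solve(G + l2 * np.eye(G.shape[0]), X.T @ Y)


def _zscore_columns(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0, keepdims=True)
    sd = M.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


def region_size_asymmetry(asym_model: FusedModel) -> pd.DataFrame:
    """Winner-voxel counts per hemisphere-paired region of an asymmetric atlas."""
    labels = asym_model.hard_labels()
    K = asym_model.K
    m = K // 2
    counts = np.bincount(labels, minlength=K)
    return pd.DataFrame(
        {
            "pair": np.arange(m),
            "left_count": counts[:m],
            "right_count": counts[m:],
        }
    )
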