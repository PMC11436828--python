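"""Synthetic worlds: ground-truth parcellations and sampled functional data.

A world is a small voxel grid, a (optionally mirror-symmetric) ground-truth
group parcellation, and per-dataset vMF emission parameters. Datasets sampled
from a world differ in number of subjects, sessions, runs and concentration
(reliability), so every downstream stage — EM fusion, precision mapping,
evaluation metrics, connectivity — can be exercised and scored against a
known truth without any external data.

The spatial structure of the group maps is a softened Voronoi partition:
parcel probability at a voxel decays exponentially with distance to the
parcel's seed, with ``smoothness`` acting as the inverse temperature. The
group prior of the fitted model is spatially independent, but a spatially
coherent truth is needed so that boundary-based evaluation (DCBC) has
boundaries to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FunctionalDataset
from .spaces import VoxelSpace, make_symmetric_grid  # noqa: F401  (re-export)
from .vmf import sample_vmf

import pandas as pd


@dataclass
class GroundTruth:
    """Ground-truth counterparts of the fitted model parameters.

    ``group_prob`` plays the role of the group arrangement probabilities,
    ``true_V``/``true_kappa`` of the per-dataset emission parameters, and
    ``subject_labels`` records each sampled subject's hard assignments for
    scoring recovery.
    """

    group_prob: np.ndarray  # (K, P), columns sum to 1
    true_V: dict = field(default_factory=dict)  # dataset -> [ (K, N_n) per session ]
    true_kappa: dict = field(default_factory=dict)  # dataset -> [ kappa_n per session ]
    subject_labels: dict = field(default_factory=dict)  # dataset -> (S, P) int

    @property
    def K(self) -> int:
        return self.group_prob.shape[0]


def sample_group_arrangement(
    space: VoxelSpace,
    K: int,
    smoothness: float = 1.0,
    symmetric: bool = False,
    seed=None,
) -> np.ndarray:
    """Sample a spatially contiguous K x P group probability matrix.

    Seeds are drawn without replacement among voxels and each voxel's parcel
    probabilities are ``softmax_k(-smoothness * d(i, seed_k))`` — a Voronoi
    partition softened by the temperature ``1/smoothness`` (``smoothness ->
    inf`` gives hard nearest-seed labels). With ``symmetric=True`` parcels
    ``1..K/2`` live in the left hemisphere, ``K/2+1..K`` in the right, seeds
    are mirrored, and ``p[k, i] == p[k + K/2, mirror(i)]`` holds exactly.
    """
    rng = np.random.default_rng(seed)
    P = space.n_voxels
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > P:
        raise ValueError("more parcels than voxels")
    if K == 1:
        return np.ones((1, P))
    if not symmetric:
        seeds = rng.choice(P, size=K, replace=False)
        d = np.linalg.norm(space.coords[None, :, :] - space.coords[seeds, None, :], axis=2)
        return _softmax_rows(-smoothness * d)

    if K % 2 != 0:
        raise ValueError("symmetric arrangement requires even K")
    left = space.left
    if K // 2 > left.size:
        raise ValueError("more left-hemisphere parcels than left voxels")
    seeds_l = rng.choice(left, size=K // 2, replace=False)
    d_l = np.linalg.norm(
        space.coords[None, left, :] - space.coords[seeds_l, None, :], axis=2
    )
    p_left = _softmax_rows(-smoothness * d_l)  # (K/2, n_left)
    prob = np.zeros((K, P))
    prob[: K // 2, left] = p_left
    prob[K // 2:, space.mirror[left]] = p_left
    mid = space.midline
    if mid.size:
        # self-paired voxels: mass split equally between the parcel pair
        d_m = np.linalg.norm(
            space.coords[None, mid, :] - space.coords[seeds_l, None, :], axis=2
        )
        p_m = _softmax_rows(-smoothness * d_m)
        prob[: K // 2, mid] = 0.5 * p_m
        prob[K // 2:, mid] = 0.5 * p_m
    return prob


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    """Column-wise softmax over axis 0 of a (K, P) logit matrix."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def make_true_emission(K: int, session_sizes: list[int], seed=None) -> list[np.ndarray]:
    """Uniform-random unit mean directions per session (kappa supplied elsewhere)."""
    rng = np.random.default_rng(seed)
    V = []
    for n_cond in session_sizes:
        x = rng.standard_normal((K, n_cond))
        V.append(x / np.linalg.norm(x, axis=1, keepdims=True))
    return V


def sample_dataset(
    truth: GroundTruth,
    space: VoxelSpace,
    dataset_id: str,
    n_subjects: int,
    n_runs: int = 2,
    seed=None,
) -> FunctionalDataset:
    """Sample one dataset's subjects from the ground-truth world.

    Per subject: hard labels are drawn from ``group_prob`` independently per
    voxel, then for every session and run each voxel's profile is a vMF draw
    around the assigned parcel's session mean with the session's
    concentration. Runs are i.i.d. replicates of the same condition set.
    Ground-truth labels are recorded in ``truth.subject_labels[dataset_id]``.
    """
    rng = np.random.default_rng(seed)
    V = truth.true_V[dataset_id]
    kappas = truth.true_kappa[dataset_id]
    if len(V) != len(kappas):
        raise ValueError("session mean and concentration lists differ in length")
    K, P = truth.group_prob.shape
    session_sizes = [v.shape[1] for v in V]
    n_cols = sum(session_sizes) * n_runs

    rows = []
    for n, size in enumerate(session_sizes):
        for r in range(n_runs):
            for c in range(size):
                rows.append((n, r, c))
    cond_info = pd.DataFrame(rows, columns=["session", "run", "condition"])

    data = np.empty((n_subjects, P, n_cols))
    labels = np.empty((n_subjects, P), dtype=int)
    cum = np.cumsum(truth.group_prob, axis=0)
    for s in range(n_subjects):
        u = rng.random(P)
        labels[s] = (u[None, :] > cum).sum(axis=0)
        for n, size in enumerate(session_sizes):
            cols_by_run = [
                np.flatnonzero(
                    ((cond_info["session"] == n) & (cond_info["run"] == r)).to_numpy()
                )
                for r in range(n_runs)
            ]
            for k in range(K):
                vox = np.flatnonzero(labels[s] == k)
                if vox.size == 0:
                    continue
                draws = sample_vmf(V[n][k], kappas[n], vox.size * n_runs, seed=rng)
                draws = draws.reshape(n_runs, vox.size, size)
                for r in range(n_runs):
                    data[s, vox[:, None], cols_by_run[r][None, :]] = draws[r]
    subjects = [f"{dataset_id}-s{s:02d}" for s in range(n_subjects)]
    truth.subject_labels[dataset_id] = labels
    return FunctionalDataset(dataset_id, subjects, data, cond_info)


def sample_smooth_noise(
    space: VoxelSpace, n_conditions: int = 20, lengthscale: float = 2.0, seed=None
) -> np.ndarray:
    """Spatially smooth but parcel-free functional data (P x N).

    White condition noise on a source lattice convolved with a Gaussian
    spatial kernel of the given lengthscale: nearby voxels correlate, yet no
    boundary structure exists anywhere — the null world for
    boundary-detection metrics. The source lattice extends 3 lengthscales
    beyond the voxel bounding box so the field is stationary right up to the
    grid edge (edge-truncated smoothing would make peripheral pairs
    systematically more correlated and bias boundary metrics).
    """
    rng = np.random.default_rng(seed)
    coords = space.coords
    d_pair = space.pairwise_distances()
    spacing = float(d_pair[d_pair > 0].min())
    pad = spacing * np.ceil(3.0 * lengthscale / spacing)
    axes = [
        np.arange(coords[:, a].min() - pad, coords[:, a].max() + pad + spacing / 2, spacing)
        for a in range(coords.shape[1])
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    sources = np.column_stack([m.ravel() for m in mesh])
    d = np.linalg.norm(coords[:, None, :] - sources[None, :, :], axis=2)
    G = np.exp(-(d**2) / (2.0 * lengthscale**2))
    return G @ rng.standard_normal((sources.shape[0], n_conditions))


def random_voronoi_labels(space: VoxelSpace, K: int, seed=None) -> np.ndarray:
    """Hard nearest-seed parcellation with random seeds (a random competitor
    parcellation of matched granularity and compactness)."""
    rng = np.random.default_rng(seed)
    seeds = rng.choice(space.n_voxels, size=K, replace=False)
    d = np.linalg.norm(space.coords[:, None, :] - space.coords[seeds][None, :, :], axis=2)
    return np.argmin(d, axis=1)


def make_complementary_world(
    width: int = 16,
    height: int = 16,
    K: int = 8,
    smoothness: float = 4.0,
    n_subjects: int = 5,
    session_sizes: list[int] | None = None,
    kappa: float = 20.0,
    n_runs: int = 2,
    seed=None,
) -> tuple[VoxelSpace, GroundTruth, list[FunctionalDataset]]:
    """Two datasets informative about complementary parcel distinctions.

    The symmetric ground truth has K parcels (K/2 per hemisphere, K a
    multiple of 4). Dataset ``dsA`` assigns identical session means to the
    consecutive parcel pairs (2j, 2j+1) within each hemisphere, so it cannot
    tell those apart; dataset ``dsB`` shares means within the complementary
    cyclic pairing (2j+1, 2j+2). Each
    dataset alone therefore only resolves half the boundaries; only their
    fusion identifies all K parcels.
    """
    if K % 4 != 0:
        raise ValueError("complementary world needs K divisible by 4")
    if session_sizes is None:
        session_sizes = [10, 10]
    rng = np.random.default_rng(seed)
    space = make_symmetric_grid(width, height)
    group_prob = sample_group_arrangement(space, K, smoothness=smoothness, symmetric=True, seed=rng)
    truth = GroundTruth(group_prob=group_prob)
    m = K // 2  # parcels per hemisphere

    def tie(pairing: list[tuple[int, int]]) -> list[np.ndarray]:
        V = make_true_emission(K, session_sizes, seed=rng)
        for v in V:
            for a, b in pairing:
                v[b] = v[a]  # left-hemisphere tie
                v[b + m] = v[a + m]  # mirrored right-hemisphere tie
        return V

    pairs_a = [(2 * j, 2 * j + 1) for j in range(m // 2)]
    pairs_b = [((2 * j + 1) % m, (2 * j + 2) % m) for j in range(m // 2)]
    for ds_id, pairing in (("dsA", pairs_a), ("dsB", pairs_b)):
        truth.true_V[ds_id] = tie(pairing)
        truth.true_kappa[ds_id] = [float(kappa)] * len(session_sizes)
    datasets = [
        sample_dataset(truth, space, ds_id, n_subjects=n_subjects, n_runs=n_runs, seed=rng)
        for ds_id in ("dsA", "dsB")
    ]
    return space, truth, datasets


def make_world(
    width: int = 20,
    height: int = 20,
    K: int = 10,
    smoothness: float = 2.0,
    symmetric: bool = True,
    dataset_specs: dict | None = None,
    seed=None,
) -> tuple[VoxelSpace, GroundTruth, list[FunctionalDataset]]:
    """Convenience constructor for a full synthetic study.

    ``dataset_specs`` maps dataset id -> dict with keys ``n_subjects``,
    ``session_sizes``, ``kappa`` (scalar or per-session list) and optional
    ``n_runs``. Defaults emulate a two-dataset study of moderate reliability.
    """
    if dataset_specs is None:
        dataset_specs = {
            "dsA": {"n_subjects": 5, "session_sizes": [10, 10], "kappa": 20.0},
            "dsB": {"n_subjects": 5, "session_sizes": [10, 10], "kappa": 20.0},
        }
    rng = np.random.default_rng(seed)
    space = make_symmetric_grid(width, height)
    group_prob = sample_group_arrangement(
        space, K, smoothness=smoothness, symmetric=symmetric, seed=rng
    )
    truth = GroundTruth(group_prob=group_prob)
    datasets = []
    for ds_id, spec in dataset_specs.items():
        sizes = list(spec["session_sizes"])
        kappa = spec["kappa"]
        kappas = [float(kappa)] * len(sizes) if np.isscalar(kappa) else [float(k) for k in kappa]
        truth.true_V[ds_id] = make_true_emission(truth.K, sizes, seed=rng)
        truth.true_kappa[ds_id] = kappas
        datasets.append(
            sample_dataset(
                truth,
                space,
                ds_id,
                n_subjects=int(spec["n_subjects"]),
                n_runs=int(spec.get("n_runs", 2)),
                seed=rng,
            )
        )
    return space, truth, datasets
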