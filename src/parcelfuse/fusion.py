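"""Joint EM fitting of one arrangement model with per-dataset emission models.

The fused model's marginal likelihood treats voxels independently: for each
subject, ``p(y_i) = sum_k softmax(eta)_{k,i} p(y_i | U_i = k)`` with the
emission term supplied by the subject's dataset-specific vMF mixture. The
E-step yields per-subject parcel posteriors; the M-step updates each
dataset's emission parameters from its own subjects and the arrangement
from the average posterior across *all* subjects — which is where a
reliable (high-kappa) dataset earns a larger pull on the group map.

Fitting restarts from many random initializations and keeps the start with
the highest final marginal log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .arrangement import Arrangement, desymmetrize
from .data import FunctionalDataset
from .emission import PreparedSubject, VmfEmission, prepare_dataset
from .spaces import VoxelSpace


def prepare_all(datasets: list[FunctionalDataset]) -> dict[str, list[PreparedSubject]]:
    return {ds.dataset_id: prepare_dataset(ds) for ds in datasets}


def e_step(
    arrangement: Arrangement,
    emissions: dict[str, VmfEmission],
    prepared: dict[str, list[PreparedSubject]],
) -> tuple[dict[str, list[np.ndarray]], float]:
    """Per-subject posteriors and the total marginal log-likelihood.

    Posterior at voxel i: ``softmax_k(emission loglik + log softmax(eta))``;
    the marginal log-likelihood sums ``logsumexp_k`` over voxels and
    subjects of every dataset.
    """
    log_prior = arrangement.log_prob()
    posteriors: dict[str, list[np.ndarray]] = {}
    total_ll = 0.0
    for ds_id, subjects in prepared.items():
        emi = emissions[ds_id]
        posteriors[ds_id] = []
        for subj in subjects:
            logp = emi.log_prob(subj) + log_prior
            ll = logsumexp(logp, axis=0)
            post = np.exp(logp - ll[None, :])
            posteriors[ds_id].append(post)
            total_ll += float(ll.sum())
        if not np.isfinite(total_ll):
            raise FloatingPointError(f"non-finite likelihood in dataset {ds_id!r}")
    return posteriors, total_ll


@dataclass
class FusedModel:
    """A fitted atlas: arrangement + one emission model per dataset."""

    arrangement: Arrangement
    emissions: dict[str, VmfEmission]
    fit_info: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.arrangement.K

    def group_prob(self) -> np.ndarray:
        return self.arrangement.group_prob()

    def hard_labels(self) -> np.ndarray:
        """Winner-take-all group map (ties break to the lowest parcel index)."""
        return np.argmax(self.group_prob(), axis=0)

    def log_likelihood(self, datasets: list[FunctionalDataset]) -> float:
        _, ll = e_step(self.arrangement, self.emissions, prepare_all(datasets))
        return ll

    def desymmetrized(self, datasets: list[FunctionalDataset], **kwargs) -> "FusedModel":
        """Asymmetric counterpart: emissions frozen, arrangement refit
        without the mirror tie (hemisphere confinement retained)."""
        prepared = prepare_all(datasets)
        arr, trace = desymmetrize(self.arrangement, self.emissions, prepared, **kwargs)
        return FusedModel(
            arrangement=arr,
            emissions={k: v.copy() for k, v in self.emissions.items()},
            fit_info={"desymmetrized_from": self.fit_info.get("seed"), "loglik_trace": trace},
        )

    def copy(self) -> "FusedModel":
        return FusedModel(
            arrangement=self.arrangement.copy(),
            emissions={k: v.copy() for k, v in self.emissions.items()},
            fit_info=dict(self.fit_info),
        )


def _em_loop(
    arrangement: Arrangement,
    emissions: dict[str, VmfEmission],
    prepared: dict[str, list[PreparedSubject]],
    max_iter: int,
    tol: float,
    update_emissions: bool = True,
) -> list[float]:
    trace: list[float] = []
    for _ in range(max_iter):
        posteriors, ll = e_step(arrangement, emissions, prepared)
        trace.append(ll)
        all_posts = [p for ps in posteriors.values() for p in ps]
        if update_emissions:
            for ds_id, subjects in prepared.items():
                emissions[ds_id].m_step(posteriors[ds_id], subjects)
        arrangement.m_step(np.mean(all_posts, axis=0))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
            break
    return trace


def fit_fusion(
    datasets: list[FunctionalDataset],
    K: int,
    symmetric: bool = False,
    space: VoxelSpace | None = None,
    n_starts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed=None,
    init_scale: float = 1.0,
) -> FusedModel:
    """Fit the fused parcellation model by multi-start EM.

    Each start draws a fresh random arrangement (iid noise of scale
    ``init_scale`` on the log-potentials) and initializes every dataset's
    emission model with one M-step from that shared prior; the start with
    the highest final marginal log-likelihood wins. ``n_starts`` defaults to
    a test-friendly 20; production atlas fits use thousands of starts.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if symmetric and space is None:
        raise ValueError("symmetric fit requires a VoxelSpace")
    rng = np.random.default_rng(seed)
    prepared = prepare_all(datasets)
    P = datasets[0].n_voxels
    session_sizes = {
        ds.dataset_id: [len(c) for c in ds.average_runs().session_partition()]
        for ds in datasets
    }

    best: FusedModel | None = None
    finals: list[float] = []
    initial_lls: list[float] = []
    for _ in range(n_starts):
        arr = Arrangement.random_init(
            K, P, scale=init_scale, symmetric=symmetric, space=space, seed=rng
        )
        # consensus initialization: every dataset's emission takes one M-step
        # from the same random prior, so parcels crystallize with matching
        # labels across datasets instead of each dataset locking onto its
        # own arbitrary permutation
        q0 = arr.group_prob()
        emis = {}
        for ds_id, sizes in session_sizes.items():
            e = VmfEmission(K, sizes)
            e.m_step([q0] * len(prepared[ds_id]), prepared[ds_id])
            emis[ds_id] = e
        trace = _em_loop(arr, emis, prepared, max_iter=max_iter, tol=tol)
        finals.append(trace[-1])
        initial_lls.append(trace[0])
        if best is None or trace[-1] > best.fit_info["loglik"]:
            best = FusedModel(
                arrangement=arr,
                emissions=emis,
                fit_info={
                    "loglik": trace[-1],
                    "loglik_trace": trace,
                    "n_iter": len(trace),
                    "converged": len(trace) < max_iter,
                    "K": K,
                    "symmetric": symmetric,
                },
            )
    best.fit_info["per_start_loglik"] = finals
    best.fit_info["seed"] = seed
    best.fit_info["n_subjects"] = {ds.dataset_id: ds.n_subjects for ds in datasets}
    best.fit_info["improved_over_init"] = bool(
        max(f - i for f, i in zip(finals, initial_lls)) > 0
    )
    return best


def refit_at_resolution(
    model: FusedModel,
    coarse_space: VoxelSpace,
    fine_space: VoxelSpace,
    datasets_fine: list[FunctionalDataset],
    correspondence: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> FusedModel:
    """Coarse-to-fine refit: transfer eta to the fine grid, then run EM once.

    ``correspondence[i]`` gives the coarse voxel backing fine voxel ``i``
    (nearest neighbor by coordinates when omitted). The transferred model is
    the single EM start; by the EM ascent property the fine log-likelihood
    ends at or above that of the transferred initialization.
    """
    if correspondence is None:
        d = np.linalg.norm(
            fine_space.coords[:, None, :] - coarse_space.coords[None, :, :], axis=2
        )
        correspondence = np.argmin(d, axis=1)
    correspondence = np.asarray(correspondence, dtype=int)
    if correspondence.shape[0] != fine_space.n_voxels:
        raise ValueError("missing correspondence for some fine voxels")
    eta_fine = model.arrangement.eta[:, correspondence]
    arr = Arrangement(
        eta_fine,
        symmetric=model.arrangement.symmetric,
        hemisphere_locked=model.arrangement.hemisphere_locked,
        space=fine_space if (model.arrangement.symmetric or model.arrangement.hemisphere_locked) else None,
    )
    emis = {k: v.copy() for k, v in model.emissions.items()}
    prepared = prepare_all(datasets_fine)
    trace = _em_loop(arr, emis, prepared, max_iter=max_iter, tol=tol)
    return FusedModel(
        arrangement=arr,
        emissions=emis,
        fit_info={"loglik": trace[-1], "loglik_trace": trace, "refit_from_coarse": True},
    )


def match_parcels(V_est: list[np.ndarray], V_true: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Match estimated to true parcels by mean-direction cosine similarity.

    Mixture labels are arbitrary, so recovery scoring needs an explicit
    correspondence: sessions are concatenated along the condition axis and a
    maximum-weight bipartite matching on the K x K cosine matrix is solved.
    Returns ``perm`` with ``perm[true_k] = est_k`` and the mean matched
    cosine.
    """
    A = np.concatenate(V_est, axis=1)
    B = np.concatenate(V_true, axis=1)
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    B = B / np.linalg.norm(B, axis=1, keepdims=True)
    C = B @ A.T  # (K_true, K_est)
    rows, cols = linear_sum_assignment(-C)
    return cols, float(C[rows, cols].mean())


class FusedParcellation(BaseEstimator):
    """Probabilistic group parcellation fused across datasets (estimator API).

    Parameters mirror :func:`fit_fusion`. ``fit`` takes a list of
    :class:`FunctionalDataset` (and a ``space`` when ``symmetric``); fitted
    state lands in ``model_``, ``arrangement_``, ``emissions_`` and
    ``log_likelihood_``. ``predict`` returns the winner-take-all group
    labels for the fitted voxels.
    """

    def __init__(
        self,
        K: int = 10,
        symmetric: bool = False,
        n_starts: int = 20,
        max_iter: int = 200,
        tol: float = 1e-6,
        random_state=None,
    ):
        self.K = K
        self.symmetric = symmetric
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X: list[FunctionalDataset], y=None, space: VoxelSpace | None = None):
        self.model_ = fit_fusion(
            X,
            K=self.K,
            symmetric=self.symmetric,
            space=space,
            n_starts=self.n_starts,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )
        self.arrangement_ = self.model_.arrangement
        self.emissions_ = self.model_.emissions
        self.log_likelihood_ = self.model_.fit_info["loglik"]
        return self

    def predict(self, X=None) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        return self.model_.hard_labels()

    def predict_proba(self, X=None) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        return self.model_.group_prob()
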