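"""Dataset-specific von Mises-Fisher mixture emission models.

Each dataset gets its own emission model: per session ``n`` a ``K x N_n``
matrix of unit mean directions ``v_k^n`` (one per parcel) and a single
concentration ``kappa^n`` shared across parcels. Conditional on a voxel's
parcel assignment, its normalized session profile is vMF-distributed around
the parcel's session mean. The concentration measures a session's
reliability and — through the E-step — acts as the weight with which the
dataset pulls on the fused group map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FunctionalDataset, normalize_profiles
from .vmf import estimate_kappa, vmf_log_norm_const


@dataclass
class PreparedSubject:
    """One subject's data readied for the emission model: per-session
    unit-normalized profiles plus validity flags and signal lengths."""

    Y: list  # per session: (P, N_n) with unit rows (invalid rows zeroed)
    valid: np.ndarray  # (P, n_sessions) bool
    lengths: np.ndarray  # (P, n_sessions)


def prepare_dataset(ds: FunctionalDataset, average_runs: bool = True) -> list[PreparedSubject]:
    """Run-average (optionally) and session-normalize every subject."""
    if average_runs:
        ds = ds.average_runs()
    partition = ds.session_partition()
    out = []
    for s in range(ds.n_subjects):
        normalized, lengths, valid = normalize_profiles(ds.data[s], partition)
        Y = [normalized[:, cols] for cols in partition]
        out.append(PreparedSubject(Y=Y, valid=valid, lengths=lengths))
    return out


class VmfEmission:
    """vMF mixture emission parameters for one dataset.

    Attributes
    ----------
    V : list of (K, N_n) arrays
        Unit mean directions per session.
    kappa : (n_sessions,) array
        Positive concentration, one per session shared across parcels.
    stale_parcels : list of (session, parcel) pairs
        Parcels that received zero posterior weight at the last M-step and
        therefore kept their previous mean.
    """

    def __init__(self, K: int, session_sizes: list[int], V=None, kappa=None):
        self.K = int(K)
        self.session_sizes = [int(n) for n in session_sizes]
        if any(n < 2 for n in self.session_sizes):
            raise ValueError("each session needs at least 2 conditions")
        if V is None:
            V = [np.full((K, n), 1.0 / np.sqrt(n)) for n in self.session_sizes]
        self.V = [np.asarray(v, dtype=float) for v in V]
        for v, n in zip(self.V, self.session_sizes):
            if v.shape != (K, n):
                raise ValueError("V shape does not match (K, session size)")
        if kappa is None:
            kappa = np.full(len(self.session_sizes), 5.0)
        self.kappa = np.asarray(kappa, dtype=float)
        if np.any(self.kappa <= 0):
            raise ValueError("kappa must be positive")
        self.stale_parcels: list = []

    @classmethod
    def random_init(cls, K, session_sizes, seed=None, kappa0: float = 5.0) -> "VmfEmission":
        """Mean directions uniform on the sphere, kappa at a moderate start."""
        rng = np.random.default_rng(seed)
        V = []
        for n in session_sizes:
            x = rng.standard_normal((K, n))
            V.append(x / np.linalg.norm(x, axis=1, keepdims=True))
        return cls(K, session_sizes, V=V, kappa=np.full(len(session_sizes), kappa0))

    @property
    def n_sessions(self) -> int:
        return len(self.session_sizes)

    def copy(self) -> "VmfEmission":
        return VmfEmission(
            self.K,
            list(self.session_sizes),
            V=[v.copy() for v in self.V],
            kappa=self.kappa.copy(),
        )

    def log_prob(self, subject: PreparedSubject) -> np.ndarray:
        """K x P log-likelihood ``log p(y_i | U_i = k)``.

        Entry (k, i) sums ``log C(kappa^n) + kappa^n v_k^n . y_i^n`` over the
        subject's valid sessions; missing/degenerate voxel-sessions are
        skipped (contribute zero).
        """
        P = subject.Y[0].shape[0]
        out = np.zeros((self.K, P))
        for n in range(self.n_sessions):
            if subject.Y[n].shape[1] != self.session_sizes[n]:
                raise ValueError("session condition count mismatch")
            log_c = vmf_log_norm_const(self.session_sizes[n], float(self.kappa[n]))
            dots = self.V[n] @ subject.Y[n].T  # (K, P); invalid rows are zero
            ok = subject.valid[:, n]
            out[:, ok] += log_c + self.kappa[n] * dots[:, ok]
        return out

    def m_step(self, posteriors: list[np.ndarray], subjects: list[PreparedSubject]) -> None:
        """Update means and concentrations from posterior parcel weights.

        ``v_k^n`` is the normalized posterior-weighted resultant of the
        subjects' session profiles; ``kappa^n`` is estimated from the mean
        resultant length via the high-dimensional approximation plus Newton
        refinement (see :func:`parcelfuse.vmf.estimate_kappa`). A parcel with
        zero total weight keeps its previous mean and is flagged in
        ``stale_parcels``.
        """
        self.stale_parcels = []
        for n in range(self.n_sessions):
            dim = self.session_sizes[n]
            R = np.zeros((self.K, dim))
            W = np.zeros(self.K)
            for post, subj in zip(posteriors, subjects):
                ok = subj.valid[:, n]
                R += post[:, ok] @ subj.Y[n][ok]
                W += post[:, ok].sum(axis=1)
            norms = np.linalg.norm(R, axis=1)
            for k in range(self.K):
                if W[k] <= 0 or norms[k] == 0:
                    self.stale_parcels.append((n, k))
                else:
                    self.V[n][k] = R[k] / norms[k]
            total = W.sum()
            if total > 0:
                rbar = norms.sum() / total
                self.kappa[n] = estimate_kappa(rbar, dim)

    # -- serialization ----------------------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Tabular form: long V table and per-session kappa table."""
        rows = []
        for n, v in enumerate(self.V):
            for k in range(self.K):
                for c in range(v.shape[1]):
                    rows.append((n, k, c, v[k, c]))
        v_df = pd.DataFrame(rows, columns=["session", "parcel", "condition", "value"])
        k_df = pd.DataFrame(
            {"session": np.arange(self.n_sessions), "kappa": self.kappa}
        )
        return v_df, k_df

    @classmethod
    def from_frames(cls, v_df: pd.DataFrame, k_df: pd.DataFrame) -> "VmfEmission":
        sessions = sorted(v_df["session"].unique())
        K = int(v_df["parcel"].max()) + 1
        V = []
        for n in sessions:
            sub = v_df[v_df["session"] == n]
            n_cond = int(sub["condition"].max()) + 1
            v = np.zeros((K, n_cond))
            v[sub["parcel"], sub["condition"]] = sub["value"]
            V.append(v)
        kappa = k_df.sort_values("session")["kappa"].to_numpy()
        return cls(K, [v.shape[1] for v in V], V=V, kappa=kappa)
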