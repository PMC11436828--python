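"""Group spatial prior over parcel assignments.

The arrangement model treats voxels independently: parcel probabilities at
voxel ``i`` are ``softmax_k(eta[k, i])`` for a ``K x P`` matrix of
log-potentials. Its M-step is simply the log of the average individual
posterior. The symmetric variant confines parcels ``1..K/2`` to the left
hemisphere and ``K/2+1..K`` to the right and ties each left voxel's
probabilities to its mirrored right voxel's, producing exactly
mirror-symmetric group maps while the emission means stay free to differ
between hemispheres.
"""

from __future__ import annotations

import numpy as np

from .spaces import VoxelSpace

# potentials for disallowed parcel/voxel pairs: exp() underflows to exactly 0
NEG_POTENTIAL = -1e6
POSTERIOR_FLOOR = 1e-10


def softmax_columns(eta: np.ndarray) -> np.ndarray:
    z = eta - eta.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


class Arrangement:
    """Independent-voxel softmax prior, optionally symmetric.

    Parameters
    ----------
    eta : (K, P) log-potential matrix
    symmetric : tie mirrored voxels to paired parcels (requires ``space``)
    hemisphere_locked : keep parcels confined to their hemisphere even
        without the mirror tie (the asymmetric-atlas constraint); implied by
        ``symmetric``
    space : VoxelSpace with the mirror pairing, required when symmetric or
        hemisphere-locked
    """

    def __init__(
        self,
        eta: np.ndarray,
        symmetric: bool = False,
        hemisphere_locked: bool = False,
        space: VoxelSpace | None = None,
    ):
        self.eta = np.asarray(eta, dtype=float)
        if self.eta.ndim != 2:
            raise ValueError("eta must be K x P")
        self.symmetric = bool(symmetric)
        self.hemisphere_locked = bool(hemisphere_locked or symmetric)
        self.space = space
        if self.hemisphere_locked:
            if space is None:
                raise ValueError("symmetric/hemisphere-locked arrangement needs a VoxelSpace")
            if self.K % 2 != 0:
                raise ValueError("hemisphere-locked arrangement requires even K")

    @property
    def K(self) -> int:
        return self.eta.shape[0]

    @property
    def P(self) -> int:
        return self.eta.shape[1]

    def allowed_mask(self) -> np.ndarray:
        """(K, P) bool: parcel k may occupy voxel i."""
        mask = np.ones((self.K, self.P), dtype=bool)
        if self.hemisphere_locked:
            Kh = self.K // 2
            mask[:Kh, self.space.right] = False
            mask[Kh:, self.space.left] = False
        return mask

    @classmethod
    def random_init(
        cls,
        K: int,
        P: int,
        scale: float = 0.1,
        symmetric: bool = False,
        space: VoxelSpace | None = None,
        seed=None,
    ) -> "Arrangement":
        """Small-variance noise around the uniform prior; symmetric variants
        draw the left-hemisphere block and tile it to the mirror."""
        rng = np.random.default_rng(seed)
        if not symmetric:
            return cls(scale * rng.standard_normal((K, P)))
        if space is None:
            raise ValueError("symmetric init needs a VoxelSpace")
        Kh = K // 2
        eta = np.full((K, P), NEG_POTENTIAL)
        left = space.left
        block = scale * rng.standard_normal((Kh, left.size))
        eta[:Kh, left] = block
        eta[Kh:, space.mirror[left]] = block
        mid = space.midline
        if mid.size:
            b = scale * rng.standard_normal((Kh, mid.size))
            eta[:Kh, mid] = b
            eta[Kh:, mid] = b
        return cls(eta, symmetric=True, space=space)

    def group_prob(self) -> np.ndarray:
        """K x P group probabilities: column-wise softmax of eta."""
        return softmax_columns(self.eta)

    def log_prob(self) -> np.ndarray:
        """Column-wise log-softmax (disallowed entries stay very negative)."""
        z = self.eta - self.eta.max(axis=0, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=0, keepdims=True))
        return z - lse

    def m_step(self, mean_posterior: np.ndarray) -> None:
        """Refit eta from the across-subject average posterior.

        Plain model: ``eta = log(q + floor)`` renormalized. Symmetric model:
        the posterior is first averaged over the two hemispheres through the
        (voxel-mirror, parcel-shift) pairing and then tiled back, so the
        resulting group map is exactly mirror-symmetric. Self-paired midline
        voxels split their mass equally between parcel k and k + K/2.
        """
        q = np.asarray(mean_posterior, dtype=float)
        if q.shape != self.eta.shape:
            raise ValueError("posterior shape mismatch")
        if self.symmetric:
            q = self._symmetrize(q)
        mask = self.allowed_mask()
        q = np.where(mask, q + POSTERIOR_FLOOR, 0.0)
        q = q / q.sum(axis=0, keepdims=True)
        self.eta = np.where(mask, np.log(np.maximum(q, POSTERIOR_FLOOR**2)), NEG_POTENTIAL)

    def _symmetrize(self, q: np.ndarray) -> np.ndarray:
        Kh = self.K // 2
        left = self.space.left
        mirrored = self.space.mirror[left]
        out = np.zeros_like(q)
        avg = 0.5 * (q[:Kh, left] + q[Kh:, mirrored])
        out[:Kh, left] = avg
        out[Kh:, mirrored] = avg
        mid = self.space.midline
        if mid.size:
            # equal-split convention: parcel k and k+K/2 share the mass
            m = 0.5 * (q[:Kh, mid] + q[Kh:, mid])
            out[:Kh, mid] = m
            out[Kh:, mid] = m
        return out

    def copy(self) -> "Arrangement":
        return Arrangement(
            self.eta.copy(),
            symmetric=self.symmetric,
            hemisphere_locked=self.hemisphere_locked,
            space=self.space,
        )


def desymmetrize(
    arr: Arrangement,
    emissions: dict,
    datasets: list,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[Arrangement, list[float]]:
    """Refit a symmetric model's arrangement without the mirror tie.

    The fitted emission models are frozen; only eta is re-estimated by EM,
    keeping the constraint that each parcel stays within its designated
    hemisphere. Relaxing the mirror tie can only raise the marginal
    log-likelihood at convergence. Returns the asymmetric arrangement and
    the log-likelihood trace.
    """
    if not arr.symmetric:
        raise ValueError("expected a symmetric arrangement")
    from .fusion import e_step  # local import: fusion builds on this module

    out = Arrangement(
        arr.eta.copy(), symmetric=False, hemisphere_locked=True, space=arr.space
    )
    trace: list[float] = []
    for _ in range(max_iter):
        posteriors, ll = e_step(out, emissions, datasets)
        trace.append(ll)
        mean_post = np.mean([p for ps in posteriors.values() for p in ps], axis=0)
        out.m_step(mean_post)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
            break
    return out, trace
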