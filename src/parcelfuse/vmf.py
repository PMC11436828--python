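"""von Mises-Fisher building blocks.

The vMF distribution over unit vectors y in R^dim has density
``C_dim(kappa) * exp(kappa * mu . y)`` on the unit sphere; ``mu`` is the mean
direction and ``kappa >= 0`` the concentration. Everything here is written
for the log domain so that the large concentrations (kappa up to 1e5) and
dimensions (several hundred task conditions) that arise when fitting real
functional profiles stay finite.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

KAPPA_MIN = 1e-3
KAPPA_MAX = 1e5


def vmf_log_norm_const(dim: int, kappa: float) -> float:
    """Log normalizing constant ``log C_dim(kappa)`` of the vMF density.

    ``C_dim(kappa) = kappa^(dim/2-1) / ((2 pi)^(dim/2) I_{dim/2-1}(kappa))``,
    evaluated with exponentially scaled Bessel functions so it is finite for
    kappa up to ~1e5 and dim up to several hundred. ``kappa = 0`` reduces to
    the reciprocal surface area of the (dim-1)-sphere.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    nu = dim / 2.0 - 1.0
    if kappa < 1e-9:
        # uniform limit: 1 / surface area of S^{dim-1}
        return float(special.gammaln(dim / 2.0) - np.log(2.0) - (dim / 2.0) * np.log(np.pi))
    # log I_nu(kappa) = log ive(nu, kappa) + kappa
    log_iv = np.log(special.ive(nu, kappa)) + kappa
    out = nu * np.log(kappa) - (dim / 2.0) * np.log(2.0 * np.pi) - log_iv
    if not np.isfinite(out):
        raise FloatingPointError("numeric overflow in normalizer")
    return float(out)


def mean_resultant_length(dim: int, kappa: float) -> float:
    """Expected mean resultant length ``A_dim(kappa) = I_{dim/2} / I_{dim/2-1}``.

    This Bessel ratio is the expectation of ``mu . y`` under the vMF law, and
    the quantity the concentration estimator inverts.
    """
    if kappa < 1e-12:
        return 0.0
    nu = dim / 2.0 - 1.0
    return float(special.ive(nu + 1.0, kappa) / special.ive(nu, kappa))


def estimate_kappa(rbar: float, dim: int, newton_steps: int = 10) -> float:
    """Concentration from a mean resultant length.

    Starts from the Banerjee approximation
    ``kappa ~= rbar (dim - rbar^2) / (1 - rbar^2)`` and refines with Newton
    steps on ``A_dim(kappa) = rbar`` using
    ``A' = 1 - A^2 - (dim-1)/kappa * A``. The result is clipped to
    [1e-3, 1e5]; the clip bounds double as floors/caps for degenerate data
    (antipodal cancellation, single observations).
    """
    rbar = float(np.clip(rbar, 0.0, 1.0 - 1e-12))
    if rbar <= 0.0:
        return KAPPA_MIN
    kappa = rbar * (dim - rbar**2) / (1.0 - rbar**2)
    kappa = float(np.clip(kappa, KAPPA_MIN, KAPPA_MAX))
    for _ in range(newton_steps):
        a = mean_resultant_length(dim, kappa)
        da = 1.0 - a * a - (dim - 1.0) / kappa * a
        if da == 0.0:
            break
        step = (a - rbar) / da
        kappa = float(np.clip(kappa - step, KAPPA_MIN, KAPPA_MAX))
    return kappa


def sample_vmf(mean: np.ndarray, kappa: float, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` unit vectors from vMF(mean, kappa).

    ``kappa = 0`` gives the uniform law on the sphere. ``seed`` is anything
    ``numpy.random.default_rng`` accepts (including a Generator).
    """
    rng = np.random.default_rng(seed)
    mean = np.asarray(mean, dtype=float)
    dim = mean.shape[0]
    if dim < 2:
        raise ValueError("dimension must be >= 2")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    norm = np.linalg.norm(mean)
    if kappa == 0.0:
        x = rng.standard_normal((n, dim))
        return x / np.linalg.norm(x, axis=1, keepdims=True)
    if norm == 0.0:
        raise ValueError("zero-norm mean direction with kappa > 0")
    out = stats.vonmises_fisher(mean / norm, kappa).rvs(n, random_state=rng)
    return np.atleast_2d(out)
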