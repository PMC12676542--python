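"""von Mises-Fisher machinery: density, sampling, concentration estimation,
and mixture-model EM for group-level network discovery.

Connectivity profiles are unit vectors on the (R-1)-sphere, so the natural
clustering model is a mixture of von Mises-Fisher (vMF) distributions

    f(x | mu, kappa) = C_d(kappa) * exp(kappa * mu . x),   |mu| = |x| = 1,

with log normalizer
    log C_d(k) = (d/2 - 1) log k - (d/2) log(2 pi) - log I_{d/2-1}(k).

Pooling every training subject's per-session profiles and fitting a K-class
vMF mixture yields the group-average networks; per-vertex labels come from
the summed responsibilities of that vertex's pooled rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

KAPPA_MAX = 1e6
_RBAR_CLIP = 1.0 - 1e-9


# --------------------------------------------------------------------------
# density pieces

def log_vmf_normalizer(kappa: float, d: int) -> float:
    """log C_d(kappa); continuous at kappa=0 (uniform on the sphere)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa < 1e-12:
        # uniform density = 1 / surface area of S^{d-1}
        return float(special.gammaln(d / 2.0) - np.log(2.0) - (d / 2.0) * np.log(np.pi))
    nu = d / 2.0 - 1.0
    # log I_nu(k) = k + log ive(nu, k), stable for large k
    log_bessel = kappa + np.log(special.ive(nu, kappa))
    return float(nu * np.log(kappa) - (d / 2.0) * np.log(2.0 * np.pi) - log_bessel)


def bessel_ratio(kappa: float | np.ndarray, d: int):
    """A_d(kappa) = I_{d/2}(kappa) / I_{d/2-1}(kappa), the mean resultant
    length of a vMF(mu, kappa) in d dimensions."""
    kappa = np.asarray(kappa, dtype=float)
    out = np.zeros_like(kappa)
    pos = kappa > 0
    out[pos] = special.ive(d / 2.0, kappa[pos]) / special.ive(d / 2.0 - 1.0, kappa[pos])
    return out if out.ndim else float(out)


def estimate_kappa(rbar: float, d: int, kappa_max: float = KAPPA_MAX) -> float:
    """Closed-form concentration estimate kappa = rbar (d - rbar^2) / (1 - rbar^2).

    Standard high-dimensional approximation to the MLE A_d(kappa) = rbar,
    clipped at ``kappa_max`` to keep degenerate resultants finite.
    """
    if not 0.0 <= rbar < 1.0:
        raise ValueError("rbar must lie in [0, 1)")
    if d < 2:
        raise ValueError("dimension must be >= 2")
    kappa = rbar * (d - rbar**2) / (1.0 - rbar**2)
    return float(min(kappa, kappa_max))


def solve_kappa(rbar: float, d: int, kappa_max: float = KAPPA_MAX) -> float:
    """Solve A_d(kappa) = rbar by Newton iteration from the closed-form start.

    Used inside EM so concentration updates are exact conditional maximizers
    (the closed form alone is accurate to a few percent, which is enough for
    estimation but not for strict objective monotonicity).
    """
    rbar = float(np.clip(rbar, 0.0, _RBAR_CLIP))
    if rbar == 0.0:
        return 0.0
    kappa = estimate_kappa(rbar, d, kappa_max=kappa_max)
    if kappa >= kappa_max:
        return float(kappa_max)
    for _ in range(50):
        a = bessel_ratio(kappa, d)
        # dA/dk = 1 - A^2 - (d-1)/k * A
        da = 1.0 - a * a - (d - 1.0) / kappa * a
        if da <= 0:
            break
        step = (a - rbar) / da
        new = kappa - step
        if not np.isfinite(new) or new <= 0:
            new = kappa / 2.0
        if new > kappa_max:
            return float(kappa_max)
        if abs(new - kappa) < 1e-10 * max(1.0, kappa):
            kappa = new
            break
        kappa = new
    return float(min(kappa, kappa_max))


# --------------------------------------------------------------------------
# sampling

def sample_vmf(mu: np.ndarray, kappa: float, n: int, seed) -> np.ndarray:
    """Draw n unit vectors from vMF(mu, kappa).

    kappa = 0 is the uniform distribution on the sphere (normalized
    Gaussians); kappa > 0 delegates to scipy's exact sampler.
    """
    mu = np.asarray(mu, dtype=float)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if abs(np.linalg.norm(mu) - 1.0) > 1e-8:
        raise ValueError("mu must be unit-norm")
    rng = np.random.default_rng(seed)
    if kappa == 0:
        x = rng.standard_normal((n, mu.size))
        return x / np.linalg.norm(x, axis=1, keepdims=True)
    return stats.vonmises_fisher(mu, kappa).rvs(n, random_state=rng)


# --------------------------------------------------------------------------
# mixture model

@dataclass
class VMFMixtureParams:
    mu: np.ndarray          # (K, R) unit rows
    kappa: np.ndarray       # (K,) concentrations
    weights: np.ndarray     # (K,) simplex
    loglik: float
    n_iter: int
    seed: int
    loglik_path: np.ndarray = field(default=None)  # per-iteration trace

    @property
    def K(self) -> int:
        return self.mu.shape[0]


@dataclass
class GroupParcellation:
    labels: np.ndarray              # (V,) int in 0..K, 0 = masked
    K: int
    network_names: list[str] = None
    source: str = "synthetic"

    def __post_init__(self):
        if self.network_names is None:
            self.network_names = [f"Network{k}" for k in range(1, self.K + 1)]


def _log_density_matrix(X: np.ndarray, mu: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log vMF densities."""
    d = X.shape[1]
    logC = np.array([log_vmf_normalizer(k, d) for k in kappa])
    return X @ (mu * kappa[:, None]).T + logC[None, :]


def _em_once(X, K, max_iter, tol, rng, shared_kappa):
    n, d = X.shape
    # k-means++-style seeding on the sphere: pick spread-out rows
    idx = [int(rng.integers(n))]
    for _ in range(K - 1):
        sim = X @ X[idx].T            # (n, len(idx))
        dist = 1.0 - sim.max(axis=1)
        dist = np.clip(dist, 0, None)
        if dist.sum() <= 0:
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=dist / dist.sum())))
    mu = X[idx].copy()
    kappa = np.full(K, float(d))      # mild initial concentration
    weights = np.full(K, 1.0 / K)

    prev_ll = -np.inf
    path = []
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        logp = _log_density_matrix(X, mu, kappa) + np.log(weights)[None, :]
        lse = special.logsumexp(logp, axis=1)
        ll = float(lse.sum())
        gamma = np.exp(logp - lse[:, None])
        path.append(ll)
        # M-step
        nk = gamma.sum(axis=0)
        # empty-cluster rescue: reseed at worst-fit row
        for k in np.flatnonzero(nk < 1e-8):
            worst = int(np.argmin(lse))
            mu[k] = X[worst]
            kappa[k] = float(d)
            nk[k] = 1e-8
        resultant = gamma.T @ X                      # (K, R)
        rnorm = np.linalg.norm(resultant, axis=1)
        nz = rnorm > 0
        mu[nz] = resultant[nz] / rnorm[nz][:, None]
        if shared_kappa:
            rbar = float(rnorm.sum() / n)
            kappa[:] = solve_kappa(rbar, d)
        else:
            for k in range(K):
                rbar = rnorm[k] / max(nk[k], 1e-300)
                kappa[k] = solve_kappa(rbar, d)
        weights = nk / n
        weights = np.clip(weights, 1e-12, None)
        weights /= weights.sum()
        if ll - prev_ll < tol * abs(ll) and it > 1:
            prev_ll = ll
            break
        prev_ll = ll
    return mu, kappa, weights, prev_ll, it, np.array(path), gamma


def fit_vmf_mixture(
    profiles: np.ndarray,
    K: int,
    vertex_index: np.ndarray | None = None,
    n_vertices: int | None = None,
    mask: np.ndarray | None = None,
    n_init: int = 10,
    max_iter: int = 100,
    tol: float = 1e-5,
    seed: int = 0,
    shared_kappa: bool = False,
    source: str = "synthetic",
) -> tuple[VMFMixtureParams, GroupParcellation]:
    """Fit a K-class vMF mixture to pooled unit-norm profile rows by EM.

    Parameters
    ----------
    profiles : (n, R) array
        Stacked unit-norm rows from all training subjects/sessions.
    vertex_index : (n,) int array, optional
        Which vertex each row belongs to; required to produce group labels
        (per-vertex argmax of summed responsibilities).
    n_vertices, mask : parcellation geometry; ``mask`` False rows get label 0.

    Returns the best of ``n_init`` seeded restarts by log-likelihood,
    together with the group parcellation.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < K or K < 1:
        raise ValueError("need at least K unit-norm rows")
    norms = np.linalg.norm(X, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("profile rows must be unit-norm")

    root = np.random.SeedSequence(seed)
    best = None
    for child in root.spawn(n_init):
        rng = np.random.default_rng(child)
        fit = _em_once(X, K, max_iter, tol, rng, shared_kappa)
        if best is None or fit[3] > best[3]:
            best = fit
    mu, kappa, weights, ll, n_iter, path, gamma = best
    params = VMFMixtureParams(mu=mu, kappa=kappa, weights=weights, loglik=ll,
                              n_iter=n_iter, seed=seed, loglik_path=path)

    if vertex_index is None:
        labels = np.argmax(gamma, axis=1) + 1
        parc = GroupParcellation(labels=labels, K=K, source=source)
        return params, parc

    vertex_index = np.asarray(vertex_index, dtype=int)
    V = int(n_vertices if n_vertices is not None else vertex_index.max() + 1)
    resp_sum = np.zeros((V, K))
    np.add.at(resp_sum, vertex_index, gamma)
    labels = np.where(resp_sum.sum(axis=1) > 0, np.argmax(resp_sum, axis=1) + 1, 0)
    if mask is not None:
        labels = np.where(np.asarray(mask, bool), labels, 0)
    parc = GroupParcellation(labels=labels.astype(np.int64), K=K, source=source)
    return params, parc
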