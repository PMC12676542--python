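"""Multi-session hierarchical Bayesian model (MS-HBM) for
individual-specific parcellation.

Generative model (point-estimate form).  For K networks over R ROIs:

    group mean directions      mu_k                 (unit vectors)
    subject means              mu_k^s     ~ vMF(mu_k,   epsilon_k)
    session means              mu_k^{s,t} ~ vMF(mu_k^s,  sigma_k)
    observed profiles          x_v^{s,t}  ~ vMF(mu_{l_v^s}^{s,t}, kappa)

epsilon_k captures inter-subject functional-connectivity variability of
network k, sigma_k intra-subject (between-session) variability, and kappa
the observation concentration (shared across networks).  The label field
l^s of subject s has a spatial prior

    P(l^s)  propto  exp( sum_v log theta_v(l_v)  +  c * sum_{(u,v) in E} 1[l_u = l_v] )

where theta (rows on the simplex) is the inter-subject spatial-variability
prior and c >= 0 the smoothness weight on the vertex graph's MRF.

Fitting is blocked coordinate ascent on a mean-field variational objective
(ELBO): the subject and session mean directions carry vMF posteriors whose
expectations are resultant-attenuated vectors (norm < 1), labels are updated
by ICM sweeps, group means by closed-form resultants, concentrations by
Newton-refined solutions of A_d(kappa) = rbar, and theta by a
Dirichlet-smoothed empirical update.  The posterior treatment of the means
matters: with pure point estimates the between-subject concentration
epsilon is degenerate (subject means collapse onto the group mean and
epsilon diverges), whereas the attenuated posterior means keep the
resultant honest.  Every block is an exact conditional maximizer, so the
tracked ELBO is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .graph import CorticalGraph
from .profiles import ConnectivityProfile
from .vmf import (GroupParcellation, VMFMixtureParams, bessel_ratio,
                  log_vmf_normalizer, solve_kappa)


@dataclass
class MSHBMParams:
    mu: np.ndarray          # (K, R) group mean directions
    epsilon: np.ndarray     # (K,) inter-subject concentration
    sigma: np.ndarray       # (K,) intra-subject concentration
    kappa: float            # observation concentration (shared)
    theta: np.ndarray       # (V, K) spatial prior, rows on the simplex
    c: float                # MRF smoothness weight
    K: int
    R: int
    V: int
    trained_on: str = "synthetic"
    objective_path: np.ndarray = field(default=None)


@dataclass
class IndividualParcellation:
    subject_id: int
    labels: np.ndarray              # (V,) 0..K
    subject_mu: np.ndarray          # (K, R)
    session_mu: np.ndarray          # (n_sessions, K, R)
    converged: bool
    n_iter: int


# --------------------------------------------------------------------------
# helpers

def _stack_sessions(profiles: list[ConnectivityProfile]) -> np.ndarray:
    """(n_sessions, V, R) array from one subject's session profiles."""
    return np.stack([p.matrix for p in profiles])


def _active_mask(X: np.ndarray) -> np.ndarray:
    """Vertices with a nonzero profile in every session."""
    return (np.linalg.norm(X, axis=2) > 0).all(axis=0)


def _icm_sweeps(data_term: np.ndarray, labels: np.ndarray, active: np.ndarray,
                graph: CorticalGraph, c: float, theta: np.ndarray, K: int,
                max_sweeps: int = 50) -> np.ndarray:
    """Iterated conditional modes on the label field, raster order ascending.

    data_term is (V, K): log-likelihood + log-prior terms per label; the MRF
    bonus c * (#same-label neighbors) is added locally.  Ties broken by
    larger theta, then lower label index.
    """
    labels = labels.copy()
    if c == 0:
        # decoupled: vectorized per-vertex argmax with the stated tie-break
        best = data_term.max(axis=1, keepdims=True)
        is_best = data_term >= best - 1e-12 * np.abs(best)
        score = np.where(is_best, theta, -np.inf)
        new = np.argmax(score, axis=1) + 1
        labels[active] = new[active]
        labels[~active] = 0
        return labels
    order = np.flatnonzero(active)
    for _ in range(max_sweeps):
        changed = 0
        for v in order:
            neigh = graph.neighbors(v)
            nl = labels[neigh]
            counts = np.bincount(nl[nl > 0], minlength=K + 1)[1:]
            score = data_term[v] + c * counts
            best = score.max()
            cand = np.flatnonzero(score >= best - 1e-12 * abs(best) - 1e-300)
            k = cand[int(np.argmax(theta[v, cand]))]
            k += 1
            if k != labels[v]:
                labels[v] = k
                changed += 1
        if changed == 0:
            break
    labels[~active] = 0
    return labels


def _label_edge_agreement(labels: np.ndarray, graph: CorticalGraph) -> int:
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    ok = (labels[u] > 0) & (labels[u] == labels[v])
    return int(ok.sum())


# --------------------------------------------------------------------------
# variational pieces

def _posterior_mean(a: np.ndarray) -> np.ndarray:
    """Row-wise posterior expectation of a vMF mean with natural parameter a.

    The optimal mean-field factor for a vMF-hierarchy mean with natural
    parameter a is vMF(a/|a|, |a|); its expectation is A_d(|a|) * a/|a| — a
    shrunk (norm < 1) vector. Zero rows stay zero (uniform posterior).
    """
    a = np.atleast_2d(a)
    d = a.shape[1]
    norm = np.linalg.norm(a, axis=1)
    out = np.zeros_like(a)
    pos = norm > 0
    if np.any(pos):
        att = np.atleast_1d(bessel_ratio(norm[pos], d))
        out[pos] = (att / norm[pos])[:, None] * a[pos]
    return out


def _vmf_entropy(c: float, d: int) -> float:
    """Entropy of vMF with concentration c in d dimensions."""
    if c <= 0:
        return -log_vmf_normalizer(0.0, d)
    return float(-log_vmf_normalizer(c, d) - c * bessel_ratio(c, d))


def _entropy_rows(a: np.ndarray) -> float:
    """Sum of posterior entropies for rows of natural parameters a."""
    d = a.shape[-1]
    norms = np.linalg.norm(a.reshape(-1, d), axis=1)
    return float(sum(_vmf_entropy(c, d) for c in norms))


# --------------------------------------------------------------------------
# training

def train_mshbm(profile_sets: list[list[ConnectivityProfile]],
                graph: CorticalGraph,
                init_parcellation: GroupParcellation,
                init_mixture: VMFMixtureParams,
                c: float = 1.0,
                max_iter: int = 30,
                tol: float = 1e-6,
                alpha: float = 1.0,
                trained_on: str = "synthetic",
                seed: int = 0) -> MSHBMParams:
    """Estimate MS-HBM parameters from multi-session training profiles.

    ``profile_sets`` holds one list of session profiles per subject; every
    training subject needs >= 2 sessions (the epsilon/sigma split is not
    identifiable from single-session subjects).
    """
    S = len(profile_sets)
    for s, plist in enumerate(profile_sets):
        if len(plist) < 2:
            raise ValueError(f"subject {s} has {len(plist)} session(s); "
                             "training requires at least 2 per subject")
    K = init_parcellation.K
    X = [_stack_sessions(p) for p in profile_sets]          # per subject (T_s, V, R)
    V, R = X[0].shape[1], X[0].shape[2]
    active = np.logical_and.reduce([_active_mask(x) for x in X])
    active &= graph.cortex_mask

    mu = init_mixture.mu.copy()
    kappa = float(np.mean(init_mixture.kappa))
    epsilon = np.full(K, float(R))
    sigma = np.full(K, float(R))
    labels = [np.where(active, init_parcellation.labels, 0).copy() for _ in range(S)]
    theta = _theta_update(labels, active, K, alpha)
    # variational posteriors over subject/session means: natural parameters
    # a_* and their (shrunk) expectations m_*
    a_subj = [epsilon[:, None] * mu for _ in range(S)]
    m_subj = [_posterior_mean(a) for a in a_subj]
    a_sess = [np.stack([sigma[:, None] * m_subj[s]] * X[s].shape[0]) for s in range(S)]
    m_sess = [np.stack([_posterior_mean(a) for a in a_sess[s]]) for s in range(S)]

    def elbo():
        J = 0.0
        logC_eps = np.array([log_vmf_normalizer(e, R) for e in epsilon])
        logC_sig = np.array([log_vmf_normalizer(sg, R) for sg in sigma])
        logC_kap = log_vmf_normalizer(kappa, R)
        n_obs = 0
        for s in range(S):
            J += float(np.sum(logC_eps + epsilon * np.sum(m_subj[s] * mu, axis=1)))
            J += _entropy_rows(a_subj[s])
            for t in range(X[s].shape[0]):
                J += float(np.sum(logC_sig + sigma *
                                  np.sum(m_sess[s][t] * m_subj[s], axis=1)))
                J += _entropy_rows(a_sess[s][t])
                lab = labels[s]
                av = active & (lab > 0)
                cos = np.sum(X[s][t][av] * m_sess[s][t][lab[av] - 1], axis=1)
                J += kappa * float(cos.sum())
                n_obs += int(av.sum())
            lab = labels[s]
            av = active & (lab > 0)
            J += float(np.sum(np.log(theta[av, lab[av] - 1])))
            J += c * _label_edge_agreement(lab, graph)
        J += n_obs * logC_kap
        J += alpha * float(np.sum(np.log(theta[active])))
        return J

    path = [elbo()]
    for it in range(1, max_iter + 1):
        # (b) posterior mean updates, bottom-up
        for s in range(S):
            lab = labels[s]
            onehot = np.zeros((V, K))
            av = active & (lab > 0)
            onehot[av, lab[av] - 1] = 1.0
            for t in range(X[s].shape[0]):
                a_sess[s][t] = kappa * (onehot.T @ X[s][t]) + sigma[:, None] * m_subj[s]
                m_sess[s][t] = _posterior_mean(a_sess[s][t])
            a_subj[s] = sigma[:, None] * m_sess[s].sum(axis=0) + epsilon[:, None] * mu
            m_subj[s] = _posterior_mean(a_subj[s])
        mu = _normalize_rows(np.sum(m_subj, axis=0), mu)

        # (c) concentration updates (exact conditional maximizers, A_d(k)=rbar)
        rb = np.clip(np.mean([np.sum(m_subj[s] * mu, axis=1) for s in range(S)],
                             axis=0), 0.0, 1.0)
        epsilon = np.array([solve_kappa(r, R) for r in rb])
        cos_sum = np.zeros(K)
        n_sess = 0
        for s in range(S):
            cos_sum += np.sum(m_sess[s] * m_subj[s][None], axis=(0, 2))
            n_sess += X[s].shape[0]
        sigma = np.array([solve_kappa(max(r, 0.0), R) for r in cos_sum / n_sess])
        num, den = 0.0, 0
        for s in range(S):
            lab = labels[s]
            av = active & (lab > 0)
            for t in range(X[s].shape[0]):
                num += float(np.sum(X[s][t][av] * m_sess[s][t][lab[av] - 1]))
                den += int(av.sum())
        kappa = solve_kappa(max(num / max(den, 1), 0.0), R)

        # (d) spatial prior
        theta = _theta_update(labels, active, K, alpha)

        # (a) label updates by ICM
        for s in range(S):
            data = np.full((V, K), -np.inf)
            dt = np.zeros((V, K))
            for t in range(X[s].shape[0]):
                dt += kappa * (X[s][t] @ m_sess[s][t].T)
            data[active] = dt[active] + np.log(theta[active])
            labels[s] = _icm_sweeps(data, labels[s], active, graph, c, theta, K)

        path.append(elbo())
        if path[-1] - path[-2] < tol * abs(path[-1]):
            break

    return MSHBMParams(mu=mu, epsilon=epsilon, sigma=sigma, kappa=kappa,
                       theta=theta, c=c, K=K, R=R, V=V, trained_on=trained_on,
                       objective_path=np.array(path))


def _normalize_rows(a: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(a, axis=1, keepdims=True)
    out = np.where(norm > 1e-300, a / np.where(norm > 1e-300, norm, 1.0), fallback)
    return out


def _theta_update(labels: list[np.ndarray], active: np.ndarray, K: int,
                  alpha: float) -> np.ndarray:
    V = labels[0].shape[0]
    counts = np.zeros((V, K))
    for lab in labels:
        av = active & (lab > 0)
        counts[av, lab[av] - 1] += 1.0
    theta = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + K * alpha)
    theta[~active] = 1.0 / K
    return theta


# --------------------------------------------------------------------------
# individual inference

def infer_individual(params: MSHBMParams,
                     profiles: list[ConnectivityProfile],
                     graph: CorticalGraph,
                     subject_id: int | None = None,
                     max_iter: int = 50) -> IndividualParcellation:
    """Infer an individual-specific parcellation with group parameters frozen.

    Alternates closed-form session/subject mean updates with ICM label
    sweeps until the labels stop changing (or ``max_iter``).  Works from a
    single session upward.
    """
    if not profiles:
        raise ValueError("at least one session profile is required")
    X = _stack_sessions(profiles)
    Tn, V, R = X.shape
    if V != params.V or R != params.R:
        raise ValueError(f"profile dims ({V}, {R}) do not match model "
                         f"({params.V}, {params.R})")
    K = params.K
    active = _active_mask(X) & graph.cortex_mask
    sid = subject_id if subject_id is not None else profiles[0].subject_id

    m_subj = _posterior_mean(params.epsilon[:, None] * params.mu)
    m_sess = np.stack([m_subj] * Tn)
    log_theta = np.log(params.theta)

    # initial labels: decoupled argmax given group means
    data = np.full((V, K), -np.inf)
    dt = params.kappa * np.einsum("tvr,kr->vk", X, params.mu)
    data[active] = dt[active] + log_theta[active]
    labels = _icm_sweeps(data, np.zeros(V, dtype=np.int64), active, graph,
                         0.0, params.theta, K)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        onehot = np.zeros((V, K))
        av = active & (labels > 0)
        onehot[av, labels[av] - 1] = 1.0
        for t in range(Tn):
            a = params.kappa * (onehot.T @ X[t]) + params.sigma[:, None] * m_subj
            m_sess[t] = _posterior_mean(a)
        a = (params.sigma[:, None] * m_sess.sum(axis=0)
             + params.epsilon[:, None] * params.mu)
        m_subj = _posterior_mean(a)

        dt = np.zeros((V, K))
        for t in range(Tn):
            dt += params.kappa * (X[t] @ m_sess[t].T)
        data = np.full((V, K), -np.inf)
        data[active] = dt[active] + log_theta[active]
        new = _icm_sweeps(data, labels, active, graph, params.c, params.theta, K)
        if np.array_equal(new, labels):
            converged = True
            labels = new
            break
        labels = new

    subject_mu = _normalize_rows(m_subj, params.mu)
    session_mu = np.stack([_normalize_rows(m_sess[t], params.mu)
                           for t in range(Tn)])
    return IndividualParcellation(subject_id=sid, labels=labels,
                                  subject_mu=subject_mu, session_mu=session_mu,
                                  converged=converged, n_iter=it)


# --------------------------------------------------------------------------
# label alignment

def match_networks(a: np.ndarray, b: np.ndarray, K: int) -> np.ndarray:
    """Hungarian matching of label sets: returns perm with perm[k-1] = the
    b-label assigned to a-label k, maximizing total overlap counts."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label arrays must share the vertex set")
    if a.max(initial=0) > K or b.max(initial=0) > K:
        raise ValueError("labels exceed K")
    overlap = np.zeros((K, K), dtype=np.int64)
    valid = (a > 0) & (b > 0)
    np.add.at(overlap, (a[valid] - 1, b[valid] - 1), 1)
    rows, cols = linear_sum_assignment(-overlap)
    perm = np.zeros(K, dtype=np.int64)
    perm[rows] = cols + 1
    return perm


def relabel(labels: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Apply a 1-based permutation (as returned by match_networks) to labels."""
    out = labels.copy()
    pos = labels > 0
    out[pos] = perm[labels[pos] - 1]
    return out
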