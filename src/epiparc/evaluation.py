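"""Parcellation quality metrics and the statistics around them.

Two complementary metrics:

* resting-state **homogeneity** — size-weighted mean, over networks, of the
  average Pearson correlation between each member vertex's time course and
  its network's mean time course (higher = vertices grouped together really
  do covary);
* stimulation **inhomogeneity** — size-weighted mean within-network sample
  standard deviation of stimulation-evoked z-scores (lower = network
  boundaries align with evoked activity).

Plus leave-one-run-out cross-validation, a block-design OLS GLM with a
canonical HRF, pairwise paired t-tests with Benjamini-Hochberg FDR control,
and the DVARS data-quality index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import RunTimeSeries, StimulationDesign
from .hrf import stim_regressor


@dataclass
class EvaluationResult:
    subject_id: int
    approach: str
    metric: str                 # "homogeneity" or "inhomogeneity"
    value: float                # size-weighted mean of per_network
    per_network: np.ndarray     # (K,) NaN where the network is empty
    network_sizes: np.ndarray   # (K,)
    n_folds: int = 1


@dataclass
class ActivationZMap:
    subject_id: int
    z: np.ndarray               # (V,)
    design_ref: StimulationDesign | None = None


@dataclass
class PairwiseStats:
    approaches: list
    t: np.ndarray               # (A, A), antisymmetric
    p: np.ndarray               # symmetric; NaN where undefined
    q: np.ndarray               # BH-adjusted, symmetric
    direction: np.ndarray       # sign(t)
    dof: int
    significant: np.ndarray     # q < q_level
    q_level: float = 0.05


def _weighted(per_network: np.ndarray, sizes: np.ndarray) -> float:
    """Network-size-weighted mean over non-empty networks."""
    ok = sizes > 0
    if not np.any(ok):
        return float("nan")
    w = sizes[ok] / sizes[ok].sum()
    return float(np.sum(w * per_network[ok]))


def resting_homogeneity(labels: np.ndarray, run: RunTimeSeries, K: int,
                        subject_id: int | None = None,
                        approach: str = "") -> EvaluationResult:
    """Size-weighted resting-state connectional homogeneity of a labeling.

    Per network: the mean correlation of member time courses with the
    network-mean time course; singleton networks score 1 by convention
    (a vertex correlates perfectly with itself).
    """
    if run.n_frames < 3:
        raise ValueError("need at least 3 frames")
    labels = np.asarray(labels)
    if labels.shape[0] != run.vertex_ts.shape[1]:
        raise ValueError("parcellation does not cover the run's vertices")
    per = np.full(K, np.nan)
    sizes = np.zeros(K)
    ts = run.vertex_ts
    for k in range(1, K + 1):
        members = np.flatnonzero(labels == k)
        sizes[k - 1] = len(members)
        if len(members) == 0:
            warnings.warn(f"network {k} is empty; excluded from weighting")
            continue
        if len(members) == 1:
            per[k - 1] = 1.0
            continue
        block = ts[:, members]
        meants = block.mean(axis=1)
        mc = meants - meants.mean()
        bc = block - block.mean(axis=0)
        denom = np.linalg.norm(bc, axis=0) * np.linalg.norm(mc)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (bc.T @ mc) / denom
        per[k - 1] = float(np.nanmean(corr))
    return EvaluationResult(subject_id=subject_id if subject_id is not None
                            else run.subject_id,
                            approach=approach, metric="homogeneity",
                            value=_weighted(per, sizes),
                            per_network=per, network_sizes=sizes)


def stim_glm(run: RunTimeSeries, design: StimulationDesign) -> ActivationZMap:
    """Per-vertex OLS of the time course on [intercept, HRF-convolved stim
    boxcar]; z is the t-statistic of the stimulation beta."""
    if design.n_frames > run.n_frames:
        raise ValueError("run shorter than the design")
    T = run.n_frames
    reg = stim_regressor(T, design.block_onsets, design.block_durations,
                         design.block_kinds, run.tr_seconds)
    Xd = np.column_stack([np.ones(T), reg])
    if np.linalg.matrix_rank(Xd) < 2:
        raise ValueError("collinear design (stimulation regressor is constant)")
    Y = run.vertex_ts
    beta, _, _, _ = np.linalg.lstsq(Xd, Y, rcond=None)
    resid = Y - Xd @ beta
    dof = T - 2
    mse = np.sum(resid**2, axis=0) / dof
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(mse * xtx_inv[1, 1])
        z = beta[1] / se
    z = np.where(se == 0, np.sign(beta[1]) * np.inf, z)
    return ActivationZMap(subject_id=run.subject_id, z=z, design_ref=design)


def task_inhomogeneity(labels: np.ndarray, zmap: ActivationZMap, K: int,
                       subject_id: int | None = None,
                       approach: str = "") -> EvaluationResult:
    """Size-weighted within-network sample SD (ddof=1) of activation
    z-scores; singleton networks score 0 by convention."""
    labels = np.asarray(labels)
    z = np.asarray(zmap.z, dtype=float)
    per = np.full(K, np.nan)
    sizes = np.zeros(K)
    for k in range(1, K + 1):
        members = labels == k
        sizes[k - 1] = int(members.sum())
        if sizes[k - 1] == 0:
            warnings.warn(f"network {k} is empty; excluded from weighting")
            continue
        if sizes[k - 1] == 1:
            warnings.warn(f"network {k} is a singleton; SD set to 0")
            per[k - 1] = 0.0
            continue
        per[k - 1] = float(np.std(z[members], ddof=1))
    return EvaluationResult(subject_id=subject_id if subject_id is not None
                            else zmap.subject_id,
                            approach=approach, metric="inhomogeneity",
                            value=_weighted(per, sizes),
                            per_network=per, network_sizes=sizes)


def loro_evaluate(runs: Sequence[RunTimeSeries],
                  parcellation_source: Callable[[Sequence[RunTimeSeries]], np.ndarray],
                  metric: Callable[[np.ndarray, RunTimeSeries], float]) -> tuple[float, list]:
    """Leave-one-run-out cross-validation.

    For each of the n >= 2 runs, labels are estimated from the other n-1
    runs (``parcellation_source``) and ``metric(labels, held_out_run)`` is
    scored on the held-out run; returns (mean over folds, per-fold values).
    """
    n = len(runs)
    if n < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs; subject excluded")
    fold_values = []
    for i in range(n):
        train = [r for j, r in enumerate(runs) if j != i]
        labels = parcellation_source(train)
        fold_values.append(float(metric(labels, runs[i])))
    return float(np.mean(fold_values)), fold_values


def bh_fdr(p: Sequence[float], q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (rejected mask, adjusted q-values); empty input gives empty
    outputs, NaN p-values pass through as NaN/unrejected.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    ok = np.isfinite(p)
    rejected = np.zeros(p.shape, dtype=bool)
    q = np.full(p.shape, np.nan)
    if ok.any():
        rej, adj, _, _ = multipletests(p[ok], alpha=q_level, method="fdr_bh")
        rejected[ok] = rej
        q[ok] = adj
    return rejected, q


def compare_approaches(values: np.ndarray, approaches: list | None = None,
                       q_level: float = 0.05) -> PairwiseStats:
    """All pairwise two-tailed paired t-tests across approaches
    (dof = n_subjects - 1), BH-FDR corrected over the pair set.

    ``values`` is subjects x approaches with no missing cells; pairs with a
    zero-variance difference vector get an undefined (NaN) p.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 approaches")
    if np.any(~np.isfinite(values)):
        raise ValueError("missing cells in the subject x approach matrix")
    n, A = values.shape
    if approaches is None:
        approaches = [f"approach{j}" for j in range(A)]
    t = np.zeros((A, A))
    p = np.full((A, A), np.nan)
    pairs = list(combinations(range(A), 2))
    pvec = []
    for i, j in pairs:
        diff = values[:, i] - values[:, j]
        if np.allclose(diff, diff[0]):
            warnings.warn(f"zero-variance differences for pair ({i},{j}); "
                          "p undefined")
            tij, pij = np.nan, np.nan
        else:
            res = stats.ttest_rel(values[:, i], values[:, j])
            tij, pij = float(res.statistic), float(res.pvalue)
        t[i, j], t[j, i] = tij, -tij if np.isfinite(tij) else np.nan
        p[i, j] = p[j, i] = pij
        pvec.append(pij)
    _, qvec = bh_fdr(pvec, q_level)
    q = np.full((A, A), np.nan)
    for (i, j), qv in zip(pairs, qvec):
        q[i, j] = q[j, i] = qv
    with np.errstate(invalid="ignore"):
        sig = q < q_level
    return PairwiseStats(approaches=list(approaches), t=t, p=p, q=q,
                         direction=np.sign(t), dof=n - 1, significant=sig,
                         q_level=q_level)


def dvars(run: RunTimeSeries) -> float:
    """Root-mean-square, over frames, of the spatial RMS of the temporal
    backward difference of the vertex series."""
    if run.n_frames < 2:
        raise ValueError("DVARS needs at least 2 frames")
    d = np.diff(run.vertex_ts, axis=0)
    return float(np.sqrt(np.mean(d**2)))
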