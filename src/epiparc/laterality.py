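"""Language laterality from network topography, dominance-group statistics,
and inter-subject topographic similarity.

The resting-state laterality index of a subject is

    LI = (LH - RH) / (LH + RH)

where LH and RH count the vertices in the left and right hemispheres
assigned to the two language-related networks (Language A and
Language/Default B).  Positive LI = left-lateralized language topography.
LI is compared across task-based dominance groups (left / bilateral /
right) by one-way ANOVA and its predictive power per group quantified by
one-vs-rest ROC/AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .graph import HEMI_L, HEMI_R, CorticalGraph

#: default one-vs-rest score orientation per dominance group: +1 means a
#: higher LI votes for the group. Right and bilateral groups sit below the
#: left-dominant majority's LI, hence -1.
DEFAULT_ORIENTATION = {"left": +1, "bilateral": -1, "right": -1}


@dataclass
class LateralityRecord:
    subject_id: int
    lh_count: int
    rh_count: int
    li: float | None            # None when LH + RH = 0 (undefined)
    dominance: str | None = None

    @property
    def defined(self) -> bool:
        return self.li is not None


@dataclass
class DominanceComparison:
    groups: list
    group_means: np.ndarray
    group_sds: np.ndarray
    n_per_group: np.ndarray
    F: float
    p: float


@dataclass
class ROCResult:
    positive_group: str
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    orientation: int


def compute_li(labels: np.ndarray, graph: CorticalGraph, language_ids,
               subject_id: int = 0, dominance: str | None = None) -> LateralityRecord:
    """Laterality record from a labeling: exact rational LI from hemisphere
    vertex counts over the language networks."""
    language_ids = list(language_ids)
    if not language_ids:
        raise ValueError("language_ids must be non-empty")
    labels = np.asarray(labels)
    if labels.shape[0] != graph.n_vertices:
        raise ValueError("hemisphere map does not cover the labeling")
    lang = np.isin(labels, language_ids)
    lh = int(np.sum(lang & (graph.hemisphere == HEMI_L)))
    rh = int(np.sum(lang & (graph.hemisphere == HEMI_R)))
    if lh + rh == 0:
        warnings.warn(f"subject {subject_id}: no language-network vertices; "
                      "LI undefined, excluded downstream")
        return LateralityRecord(subject_id, lh, rh, None, dominance)
    li = float(Fraction(lh - rh, lh + rh))
    return LateralityRecord(subject_id, lh, rh, li, dominance)


def anova_li(records: list[LateralityRecord]) -> DominanceComparison:
    """One-way fixed-effects ANOVA of LI across dominance groups; subjects
    with undefined LI are dropped with a warning."""
    records = _defined(records)
    groups = sorted({r.dominance for r in records if r.dominance is not None})
    samples = [np.array([r.li for r in records if r.dominance == g]) for g in groups]
    if len(groups) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 members each")
    means = np.array([s.mean() for s in samples])
    sds = np.array([s.std(ddof=1) for s in samples])
    ns = np.array([len(s) for s in samples])
    pooled = np.concatenate(samples)
    if np.allclose(pooled, pooled[0]):
        warnings.warn("all LI values identical; F undefined")
        F, p = np.nan, np.nan
    else:
        res = stats.f_oneway(*samples)
        F, p = float(res.statistic), float(res.pvalue)
        if np.isnan(F):       # zero within-group variance everywhere
            F = np.inf
            p = 0.0
    return DominanceComparison(groups=groups, group_means=means, group_sds=sds,
                               n_per_group=ns, F=F, p=p)


def roc_auc(records: list[LateralityRecord], positive_group: str,
            orientation: int | None = None) -> ROCResult:
    """One-vs-rest ROC of LI for a dominance group.

    AUC is the Mann-Whitney concordance (ties get half credit) of the
    oriented score ``orientation * LI``; defaults per group come from
    ``DEFAULT_ORIENTATION``.
    """
    records = _defined(records)
    if orientation is None:
        orientation = DEFAULT_ORIENTATION.get(positive_group, +1)
    y = np.array([1 if r.dominance == positive_group else 0 for r in records])
    scores = orientation * np.array([r.li for r in records])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be non-empty")
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thr = roc_curve(y, scores)
    return ROCResult(positive_group=positive_group, thresholds=thr,
                     tpr=tpr, fpr=fpr, auc=auc, orientation=int(orientation))


def _defined(records):
    out = [r for r in records if r.defined]
    if len(out) < len(records):
        warnings.warn(f"{len(records) - len(out)} subject(s) with undefined LI excluded")
    return out


# --------------------------------------------------------------------------
# topographic similarity

def dice_per_network(a: np.ndarray, b: np.ndarray, K: int) -> np.ndarray:
    """Dice coefficient 2|A∩B|/(|A|+|B|) per network; NaN when both empty."""
    a = np.asarray(a)
    b = np.asarray(b)
    out = np.full(K, np.nan)
    for k in range(1, K + 1):
        A, B = a == k, b == k
        denom = int(A.sum()) + int(B.sum())
        if denom == 0:
            continue
        out[k - 1] = 2.0 * int((A & B).sum()) / denom
    return out


@dataclass
class DiceMatrix:
    pairs: list                    # list of (i, j) subject index pairs
    values: np.ndarray             # (n_pairs, K)
    per_network_mean: np.ndarray   # (K,) mean over pairs, NaN-aware


def inter_subject_dice(label_list: list[np.ndarray], K: int) -> DiceMatrix:
    """Per-network Dice over all subject pairs (topographic similarity)."""
    V = label_list[0].shape[0]
    for lab in label_list:
        if lab.shape[0] != V:
            raise ValueError("parcellations must share the vertex set")
    pairs = list(combinations(range(len(label_list)), 2))
    values = np.array([dice_per_network(label_list[i], label_list[j], K)
                       for i, j in pairs]).reshape(len(pairs), K)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_mean = np.nanmean(values, axis=0) if pairs else np.full(K, np.nan)
    return DiceMatrix(pairs=pairs, values=values, per_network_mean=per_mean)
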