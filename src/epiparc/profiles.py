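"""Functional-connectivity profiles: per-vertex correlations to a set of
ROIs, binarized to the top fraction and unit-normalized; plus rest-block
censoring of stimulation runs.

A vertex's profile is its vector of Pearson correlations with the R ROI
time courses, with only the top 10% (by default) of correlations kept (as
ones) and the row L2-normalized — the representation clustered on the unit
sphere downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import RunTimeSeries, StimulationDesign


@dataclass
class ConnectivityProfile:
    subject_id: int
    session_id: int
    matrix: np.ndarray       # (V, R) nonnegative; unmasked rows unit-norm
    top_fraction: float
    n_kept: int

    @property
    def V(self) -> int:
        return self.matrix.shape[0]

    @property
    def R(self) -> int:
        return self.matrix.shape[1]

    def unmasked_rows(self) -> np.ndarray:
        return np.flatnonzero(np.linalg.norm(self.matrix, axis=1) > 0)


def _standardize(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columns to zero mean / unit norm; returns (standardized, zero-variance mask)."""
    c = ts - ts.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(c, axis=0)
    zero = norm < 1e-12
    norm = np.where(zero, 1.0, norm)
    return c / norm, zero


def compute_profile(run: RunTimeSeries, mask: np.ndarray | None = None,
                    top_fraction: float = 0.10) -> ConnectivityProfile:
    """Binarized, unit-normalized connectivity profile of one run.

    Per vertex: Pearson correlation to every ROI; the ceil(top_fraction*R)
    largest correlations are kept as ones (ties at the cutoff broken by the
    larger correlation, then the lower ROI index), the rest zeroed; the row
    is then L2-normalized. Masked-out and zero-variance vertices yield
    all-zero rows.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    V = run.vertex_ts.shape[1]
    R = run.roi_ts.shape[1]
    if mask is None:
        mask = np.ones(V, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    vstd, vzero = _standardize(run.vertex_ts)
    rstd, rzero = _standardize(run.roi_ts)
    if np.any(rzero):
        raise ValueError(f"zero-variance ROI(s): {np.flatnonzero(rzero).tolist()}")
    if np.any(vzero & mask):
        warnings.warn(
            f"{int(np.sum(vzero & mask))} zero-variance vertex(es) inside the "
            "mask excluded (all-zero profile rows)")
    corr = vstd.T @ rstd                    # (V, R) Pearson correlations

    n_kept = math.ceil(top_fraction * R)
    # rank ROIs per vertex: larger correlation first, lower index on ties
    order = np.lexsort((np.broadcast_to(np.arange(R), corr.shape), -corr), axis=1)
    top = order[:, :n_kept]
    out = np.zeros((V, R))
    np.put_along_axis(out, top, 1.0 / np.sqrt(n_kept), axis=1)
    out[~mask | vzero] = 0.0
    return ConnectivityProfile(run.subject_id, run.session_id, out,
                               float(top_fraction), n_kept)


def censor_stim_blocks(run: RunTimeSeries, design: StimulationDesign) -> RunTimeSeries:
    """Keep only rest blocks, discarding the first ``design.discard_frames``
    frames of each to shed residual hemodynamic response; frames are
    concatenated in order."""
    if design.n_frames > run.n_frames:
        raise ValueError("design extends beyond the run")
    keep = []
    for i, (onset, dur, kind) in enumerate(zip(design.block_onsets,
                                               design.block_durations,
                                               design.block_kinds)):
        if kind != "rest":
            continue
        if dur <= design.discard_frames:
            raise ValueError(
                f"rest block {i} ({dur} frames) is not longer than the "
                f"{design.discard_frames}-frame discard window")
        keep.append(np.arange(onset + design.discard_frames, onset + dur))
    if not keep:
        raise ValueError("no rest frames survive censoring")
    idx = np.concatenate(keep)
    if len(idx) < 20:
        raise ValueError(f"only {len(idx)} rest frames survive censoring (< 20)")
    return RunTimeSeries(run.subject_id, run.session_id,
                         run.vertex_ts[idx], run.roi_ts[idx], run.tr_seconds)
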