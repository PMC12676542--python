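"""Canonical double-gamma hemodynamic response function.

Shared by the stimulation-run simulator and the block-design GLM so the two
sides of the forward/inverse problem use the same response shape.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def double_gamma_hrf(tr_seconds: float, duration: float = 32.0,
                     peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF at the repetition time.

    Peak at ~6 s, undershoot at ~16 s, undershoot/peak ratio 1/6; peak
    normalized to 1.
    """
    t = np.arange(0, duration + tr_seconds, tr_seconds)
    h = stats.gamma.pdf(t, peak) - ratio * stats.gamma.pdf(t, undershoot)
    return h / h.max()


def stim_regressor(n_frames: int, onsets: np.ndarray, durations: np.ndarray,
                   kinds: list[str], tr_seconds: float) -> np.ndarray:
    """Boxcar over stimulation blocks convolved with the canonical HRF,
    truncated to the run length."""
    box = np.zeros(n_frames)
    for onset, dur, kind in zip(onsets, durations, kinds):
        if kind == "stim":
            box[onset:onset + dur] = 1.0
    return np.convolve(box, double_gamma_hrf(tr_seconds))[:n_frames]
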