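"""Canonical hemodynamic response and event-regressor convolution.

One code path builds every HRF-convolved regressor in the package — both
the synthetic BOLD generator and the GLM design matrices — so that noiseless
simulation followed by estimation is exact by construction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["double_gamma_hrf", "convolve_events", "cosine_drift_basis"]


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (seconds).

    Positive gamma peaking near 6 s minus a scaled undershoot gamma peaking
    near 16 s; normalized to unit peak so regressor amplitudes are
    interpretable as response amplitudes.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    h = h - ratio * stats.gamma.pdf(t, undershoot_delay / undershoot_disp,
                                    scale=undershoot_disp)
    h[t < 0] = 0.0
    peak = h.max()
    return h / peak if peak > 0 else h


def convolve_events(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_scans: int,
    tr: float,
    oversample: int = 20,
    hrf_length: float = 32.0,
) -> np.ndarray:
    """HRF-convolved regressor for a set of events, sampled at scan times.

    Events are boxcars (``duration`` 0 gives a single-sample impulse) on an
    oversampled grid of step ``tr / oversample``, convolved with the
    canonical double-gamma HRF and read out at acquisition times
    ``0, tr, 2 tr, ...``.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    dt = tr / oversample
    n_hi = n_scans * oversample + int(np.ceil(hrf_length / dt))
    stim = np.zeros(n_hi)
    for on, du in zip(onsets, durations):
        i0 = int(np.round(on / dt))
        i1 = max(i0 + 1, int(np.round((on + du) / dt)))
        if i0 >= n_hi:
            continue
        stim[i0:min(i1, n_hi)] = 1.0
    hrf = double_gamma_hrf(np.arange(0, hrf_length, dt))
    conv = np.convolve(stim, hrf)[:n_hi] * dt
    return conv[:: oversample][:n_scans].copy()


def cosine_drift_basis(n_scans: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass drift basis (periods longer than ``cutoff_s``).

    Returns an (n_scans × k) matrix of unit-norm cosines, excluding the
    constant term (the design's intercept covers it). k may be 0 for short
    runs.
    """
    duration = n_scans * tr
    k = int(np.floor(2.0 * duration / cutoff_s))
    t = np.arange(n_scans)
    cols = []
    for j in range(1, k + 1):
        c = np.cos(np.pi * j * (2 * t + 1) / (2 * n_scans))
        cols.append(c / np.linalg.norm(c))
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))
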