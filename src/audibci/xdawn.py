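"""xDAWN spatial filters for overlapping evoked responses.

The evoked response is estimated by least squares with a stimulus-onset
Toeplitz design matrix, which remains unbiased when consecutive responses
overlap (SOA shorter than the response window).  Spatial filters then
maximize the generalized Rayleigh quotient

    rho(w) = ||S w||^2 / ||X w||^2,

where ``X`` is the continuous (filtered) recording and ``S`` the modelled
evoked signal — here either the estimated attended-minus-ignored
difference response replicated at its onsets (contrast
``attended_vs_ignored``, the online configuration: the filters separate
ATTENDED from IGNORED responses), or the full estimated evoked signal
(contrast ``evoked_vs_noise``, classic single-class xDAWN).  The solve
uses the numerically stable whitening route: Cholesky of the total
covariance, then SVD of the whitened signal matrix.  The bank contains as
many mutually X-orthogonal filters as channels, ranked by score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .synthdata import Recording

logger = logging.getLogger("audibci")

__all__ = ["SpatialFilterBank", "fit_xdawn", "apply_filters", "select_n_filters"]


@dataclass
class SpatialFilterBank:
    """Ranked xDAWN filter bank (one column per filter)."""

    filters: np.ndarray  # (n_channels, n_filters)
    patterns: np.ndarray  # (n_channels, n_filters) forward models
    scores: np.ndarray  # (n_filters,) generalized Rayleigh quotients
    channels: list[str]
    window_s: float
    contrast: str
    n_selected: int = field(default=0)

    def __post_init__(self):
        norms = np.linalg.norm(self.filters, axis=0)
        if np.any(norms == 0):
            raise ValueError("all-zero spatial filter in bank")
        if np.any(np.diff(self.scores) > 1e-10):
            raise ValueError("scores must be non-increasing")
        if self.n_selected == 0:
            self.n_selected = self.filters.shape[1]

    @property
    def n_filters(self) -> int:
        return self.filters.shape[1]

    def to_dict(self) -> dict:
        return {
            "filters": self.filters.tolist(),
            "patterns": self.patterns.tolist(),
            "scores": self.scores.tolist(),
            "channels": self.channels,
            "window_s": self.window_s,
            "contrast": self.contrast,
            "n_selected": self.n_selected,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpatialFilterBank":
        return cls(
            filters=np.asarray(d["filters"], float),
            patterns=np.asarray(d["patterns"], float),
            scores=np.asarray(d["scores"], float),
            channels=list(d["channels"]),
            window_s=float(d["window_s"]),
            contrast=str(d["contrast"]),
            n_selected=int(d["n_selected"]),
        )


def _toeplitz_design(
    samples: np.ndarray, n_samples: int, window: int
) -> np.ndarray:
    """Sparse-in-spirit 0/1 design: column j is 1 at (onset + j)."""
    design = np.zeros((n_samples, window))
    for s in samples:
        hi = min(s + window, n_samples)
        idx = np.arange(s, hi)
        design[idx, idx - s] += 1.0
    return design


def fit_xdawn(
    data: Recording | np.ndarray,
    events: list[tuple[int, int]],
    window_s: float,
    contrast: str = "attended_vs_ignored",
    fs: float | None = None,
    channels: list[str] | None = None,
) -> SpatialFilterBank:
    """Estimate the full ranked filter bank.

    Parameters
    ----------
    data
        A Recording, or a (n_channels, n_samples) array with ``fs`` given.
    events
        (sample, class) pairs; class 1 = attended/target, 0 = ignored.
        For ``evoked_vs_noise`` all events form a single class.
    window_s
        Evoked-response window length in seconds.
    """
    if isinstance(data, Recording):
        fs = data.fs
        channels = list(data.channels)
        X = data.signal.T  # samples x channels
    else:
        if fs is None:
            raise ValueError("fs required when passing a bare array")
        X = np.asarray(data, float).T
        if channels is None:
            channels = [f"ch{i}" for i in range(X.shape[1])]
    n_samples, n_ch = X.shape
    window = int(round(window_s * fs))
    if window <= 0 or window > n_samples:
        raise ValueError("window does not fit the data")
    ev = np.asarray(events, int)
    if ev.ndim != 2 or ev.shape[1] != 2:
        raise ValueError("events must be (sample, class) pairs")

    if contrast == "attended_vs_ignored":
        groups = [ev[ev[:, 1] == c, 0] for c in (1, 0)]
        if any(len(g) < 2 for g in groups):
            raise ValueError("need >= 2 events of each contrasted class")
        D = np.hstack(
            [_toeplitz_design(g, n_samples, window) for g in groups]
        )
    elif contrast == "evoked_vs_noise":
        if len(ev) < 2:
            raise ValueError("need >= 2 events")
        groups = [ev[:, 0]]
        D = _toeplitz_design(ev[:, 0], n_samples, window)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    # least-squares evoked estimate, QR route
    Q, R = np.linalg.qr(D)
    rcond = np.abs(np.diag(R))
    if rcond.min() < 1e-10 * rcond.max():
        logger.warning("xDAWN design rank-deficient; using regularized solve")
        A = np.linalg.lstsq(D, X, rcond=1e-8)[0]
    else:
        A = scipy.linalg.solve_triangular(R, Q.T @ X)

    if contrast == "attended_vs_ignored":
        signal = A[:window] - A[window:]  # difference evoked response
    else:
        signal = A

    Cx = X.T @ X
    try:
        L = np.linalg.cholesky(Cx)
    except np.linalg.LinAlgError:
        logger.warning("singular total covariance; adding ridge")
        Cx = Cx + 1e-8 * np.trace(Cx) / n_ch * np.eye(n_ch)
        L = np.linalg.cholesky(Cx)
    # whiten: w = L^{-T} v  =>  ||X w||^2 = ||v||^2
    M = scipy.linalg.solve_triangular(L, signal.T, lower=True).T  # signal @ L^{-T}
    _, svals, Vt = np.linalg.svd(M, full_matrices=False)
    k = Vt.shape[0]
    V = np.zeros((n_ch, n_ch))
    V[:, :k] = Vt.T
    if k < n_ch:  # complete the basis with zero-score directions
        q, _ = np.linalg.qr(np.eye(n_ch) - Vt.T @ Vt)
        V[:, k:] = q[:, : n_ch - k]
    scores = np.zeros(n_ch)
    scores[: len(svals)] = svals**2
    W = scipy.linalg.solve_triangular(L, V, lower=True, trans="T")
    # unit-variance virtual channels: ||X w||^2 = n_samples
    W = W * np.sqrt(n_samples)
    patterns = Cx @ W / np.einsum("ij,ij->j", W, Cx @ W)
    return SpatialFilterBank(
        filters=W,
        patterns=patterns,
        scores=scores,
        channels=channels,
        window_s=window_s,
        contrast=contrast,
    )


def apply_filters(epochs: np.ndarray, bank: SpatialFilterBank, n: int) -> np.ndarray:
    """Project epochs (n_epochs, n_channels, n_samples) onto the first n filters."""
    if not (1 <= n <= bank.n_filters):
        raise ValueError(f"n must be in 1..{bank.n_filters}")
    epochs = np.asarray(epochs, float)
    if epochs.shape[-2] != bank.filters.shape[0]:
        raise ValueError("channel count does not match bank")
    return np.einsum("cf,...ct->...ft", bank.filters[:, :n], epochs)


def select_n_filters(
    calibration: Recording,
    targets,
    config,
    candidates=range(1, 6),
) -> int:
    """Per-subject filter count by block leave-one-out cross-validation.

    Evaluates the decoder's block-LOO accuracy for each candidate count
    and returns the maximizer; ties go to the smallest count.
    """
    from .decoder import loo_accuracy_by_candidate

    acc = loo_accuracy_by_candidate(calibration, targets, config, list(candidates))
    best = max(acc, key=lambda n: (acc[n], -n))
    return best
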