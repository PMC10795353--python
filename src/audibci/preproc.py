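"""Filtering, epoching, artifact-epoch rejection and ICA cleanup.

Two processing paths share this module: the *online* path (causal
band-pass, no artifact correction — exactly what ran during the
experiment) and the *offline ERP* path (zero-phase band-pass, ICA-based
removal of blinks / saccades / common-offset components, −200..+1000 ms
epochs, no baseline correction, 15% peak-to-peak rejection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal
from scipy.stats import kurtosis
from sklearn.decomposition import FastICA

from .stimgen import CODE_TO_CONDITION, BLOCK_START_MARKER, Kind, Stream
from .synthdata import Recording
from .io_formats import montage_positions

logger = logging.getLogger("audibci")

__all__ = [
    "EpochSet",
    "IcaDecomposition",
    "bandpass",
    "decimate_recording",
    "epoch",
    "reject_peak_to_peak",
    "fit_ica",
    "remove_components",
    "score_components",
    "component_erp_contrast",
]


# ---------------------------------------------------------------------------
# filtering


def _design_bandpass(low: float, high: float, fs: float) -> np.ndarray:
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"invalid band edges ({low}, {high}) for fs={fs}: need 0 < low < high < fs/2"
        )
    return scipy.signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    recording: Recording, low: float = 0.5, high: float = 20.0, mode: str = "causal"
) -> Recording:
    """4th-order Butterworth band-pass.

    ``mode='causal'`` applies a direct-form filter (online replay: only
    causal delay); ``mode='zero_phase'`` applies it forward-backward
    (ERP analysis: zero group delay).
    """
    sos = _design_bandpass(low, high, recording.fs)
    out = recording.copy()
    if mode == "causal":
        out.signal = scipy.signal.sosfilt(sos, out.signal, axis=1)
    elif mode == "zero_phase":
        out.signal = scipy.signal.sosfiltfilt(sos, out.signal, axis=1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return out


def decimate_recording(recording: Recording, q: int) -> Recording:
    """Anti-aliased FIR decimation by ``q``; event samples are rescaled."""
    if q == 1:
        return recording.copy()
    sig = scipy.signal.decimate(recording.signal, q, ftype="fir", axis=1)
    n = sig.shape[1]
    events = [(min(s // q, n - 1), c) for s, c in recording.events]
    return Recording(
        signal=sig,
        fs=recording.fs / q,
        channels=list(recording.channels),
        events=events,
        annotations=list(recording.annotations),
    )


# ---------------------------------------------------------------------------
# epoching


@dataclass
class EpochSet:
    """Stimulus-locked epochs with condition labels.

    ``data`` maps stimulus kind to an (n_epochs, n_channels, n_samples)
    array; windows may differ between kinds, so the arrays are stored per
    kind.  ``info`` has one row per epoch (across kinds, in temporal
    order) with columns: kind, stream, attended, block, kind_row, kept.
    """

    data: dict[Kind, np.ndarray]
    fs: float
    channels: list[str]
    windows: dict[Kind, tuple[float, float]]
    info: pd.DataFrame

    @property
    def n_epochs(self) -> int:
        return len(self.info)

    def select(
        self,
        kind: Kind | None = None,
        stream: Stream | None = None,
        attended: bool | None = None,
        block: int | None = None,
        kept_only: bool = True,
    ) -> tuple[np.ndarray, pd.DataFrame]:
        """Epoch array + label rows matching the given condition."""
        mask = pd.Series(True, index=self.info.index)
        if kind is not None:
            mask &= self.info["kind"] == Kind(kind).value
        if stream is not None:
            mask &= self.info["stream"] == Stream(stream).value
        if attended is not None:
            mask &= self.info["attended"] == attended
        if block is not None:
            mask &= self.info["block"] == block
        if kept_only:
            mask &= self.info["kept"]
        sub = self.info[mask]
        if kind is None:
            kinds = set(sub["kind"])
            if len(kinds) > 1:
                raise ValueError("selection spans kinds with different windows")
            kind = Kind(next(iter(kinds))) if kinds else Kind.STANDARD
        arr = self.data[Kind(kind)][sub["kind_row"].to_numpy(int)]
        return arr, sub


def _normalize_windows(window_by_kind) -> dict[Kind, tuple[float, float]]:
    out = {}
    for key, win in window_by_kind.items():
        if np.isscalar(win):
            win = (0.0, float(win))
        out[Kind(key)] = (float(win[0]), float(win[1]))
    return out


def epoch(
    recording: Recording,
    window_by_kind: dict,
    targets: list[Stream] | None = None,
) -> EpochSet:
    """Cut stimulus-locked epochs with per-kind half-open windows [tmin, tmax).

    Overlapping neighbour responses are intentionally kept (overlap is
    intrinsic when the SOA is shorter than the window).  No baseline
    correction.  Epochs exceeding the recording bounds are dropped with a
    warning.  ``targets`` (per block, from block-start markers) assign the
    ``attended`` label: a stimulus is attended iff its stream equals its
    block's target.
    """
    windows = _normalize_windows(window_by_kind)
    fs = recording.fs
    arrays: dict[Kind, list[np.ndarray]] = {k: [] for k in windows}
    rows = []
    block_idx = -1
    for sample, code in recording.events:
        if code == BLOCK_START_MARKER:
            block_idx += 1
            continue
        cond = CODE_TO_CONDITION.get(code)
        if cond is None:
            continue
        stream, kind = cond
        if kind not in windows:
            continue
        tmin, tmax = windows[kind]
        lo = sample + int(round(tmin * fs))
        hi = sample + int(round(tmax * fs))
        if lo < 0 or hi > recording.n_samples:
            logger.warning(
                "dropping epoch at sample %d (window [%d, %d) outside recording)",
                sample, lo, hi,
            )
            continue
        attended = None
        if targets is not None and 0 <= block_idx < len(targets):
            attended = stream is Stream(targets[block_idx])
        rows.append(
            {
                "kind": kind.value,
                "stream": stream.value,
                "attended": attended,
                "block": block_idx,
                "kind_row": len(arrays[kind]),
                "kept": True,
            }
        )
        arrays[kind].append(recording.signal[:, lo:hi])
    data = {
        k: (np.stack(v) if v else np.empty((0, recording.n_channels, 0)))
        for k, v in arrays.items()
    }
    return EpochSet(
        data=data,
        fs=fs,
        channels=list(recording.channels),
        windows=windows,
        info=pd.DataFrame(
            rows,
            columns=["kind", "stream", "attended", "block", "kind_row", "kept"],
        ),
    )


def reject_peak_to_peak(epochs: EpochSet, fraction: float = 0.15) -> EpochSet:
    """Flag the ``floor(fraction * n)`` highest peak-to-peak epochs as rejected.

    Amplitude is the max-over-channels peak-to-peak value; ranking is
    pooled over all epochs of the set, ties broken by epoch index
    (earlier epochs kept).  Exactly ``ceil((1 - fraction) * n)`` epochs
    remain kept.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    n = epochs.n_epochs
    n_remove = int(np.floor(fraction * n))
    info = epochs.info.copy()
    info["kept"] = True
    if n_remove > 0:
        p2p = np.empty(n)
        for i, row in enumerate(epochs.info.itertuples()):
            ep = epochs.data[Kind(row.kind)][row.kind_row]
            p2p[i] = (ep.max(axis=1) - ep.min(axis=1)).max()
        # descending amplitude; ties -> later epoch removed first
        order = np.lexsort((-np.arange(n), -p2p))
        info.iloc[order[:n_remove], info.columns.get_loc("kept")] = False
    return EpochSet(
        data=epochs.data,
        fs=epochs.fs,
        channels=epochs.channels,
        windows=epochs.windows,
        info=info,
    )


# ---------------------------------------------------------------------------
# ICA


@dataclass
class IcaDecomposition:
    """FastICA decomposition with artifact-likeness scores per component."""

    unmixing: np.ndarray  # (n_components, n_channels)
    mixing: np.ndarray  # (n_channels, n_components)
    mean: np.ndarray  # (n_channels,)
    channels: list[str]
    scores: pd.DataFrame | None = None
    excluded: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def sources(self, recording: Recording) -> np.ndarray:
        return self.unmixing @ (recording.signal - self.mean[:, None])


def fit_ica(
    recording: Recording, n_components: int | None = None, seed: int = 0
) -> IcaDecomposition:
    """FastICA (tanh/logcosh nonlinearity) on the continuous recording.

    The recording should be high-pass filtered first.  Deterministic for
    a fixed seed.
    """
    n_ch = recording.n_channels
    if n_components is None:
        n_components = n_ch
    if n_components > n_ch:
        raise ValueError("n_components cannot exceed channel count")
    if np.linalg.matrix_rank(np.cov(recording.signal)) < n_components:
        raise ValueError("rank-deficient input for requested component count")
    ica = FastICA(
        n_components=n_components,
        fun="logcosh",
        whiten="unit-variance",
        random_state=seed,
        max_iter=500,
    )
    ica.fit(recording.signal.T)
    dec = IcaDecomposition(
        unmixing=ica.components_,
        mixing=ica.mixing_,
        mean=ica.mean_,
        channels=list(recording.channels),
    )
    dec.scores = score_components(recording, dec)
    return dec


def remove_components(
    recording: Recording, ica: IcaDecomposition, which: list[int]
) -> Recording:
    """Reconstruct the recording without the listed components."""
    bad = [w for w in which if not (0 <= w < ica.n_components)]
    if bad:
        raise ValueError(f"component indices out of range: {bad}")
    out = recording.copy()
    if which:
        src = ica.sources(recording)
        out.signal = recording.signal - ica.mixing[:, which] @ src[which]
    return out


def _blob_weights(channels: list[str], center_xy, sigma: float) -> np.ndarray:
    pos = montage_positions(channels)
    d2 = np.sum((pos - np.asarray(center_xy)) ** 2, axis=1)
    return np.exp(-d2 / (2 * sigma**2))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))


def score_components(recording: Recording, ica: IcaDecomposition) -> pd.DataFrame:
    """Blink / saccade / common-offset likeness scores in [0, 1].

    Each score combines a spatial-pattern prior with a temporal
    signature, so broadband neural components score low on clean data:

    * blink: frontal-pole pattern x peakedness (excess kurtosis) of the
      source;
    * saccade: left/right-antisymmetric frontal pattern x peakedness of
      the source derivative (step-likeness);
    * offset: near-uniform pattern x fraction of power below 1 Hz.
    """
    src = ica.sources(recording)
    patterns = ica.mixing / np.linalg.norm(ica.mixing, axis=0, keepdims=True)
    blink_topo = _blob_weights(ica.channels, (0.0, 1.05), 0.55)
    blink_topo /= np.linalg.norm(blink_topo)
    pos = montage_positions(ica.channels)
    sacc_topo = pos[:, 0] * _blob_weights(ica.channels, (0.0, 0.75), 0.8)
    sacc_topo /= np.linalg.norm(sacc_topo)
    uniform = np.ones(len(ica.channels)) / np.sqrt(len(ica.channels))
    fs = recording.fs

    rows = []
    for i in range(ica.n_components):
        p = patterns[:, i]
        s = src[i]
        kurt = max(0.0, float(kurtosis(s)))
        dkurt = max(0.0, float(kurtosis(np.diff(s))))
        f, pxx = scipy.signal.welch(s, fs=fs, nperseg=min(len(s), 4096))
        low = float(pxx[f < 1.0].sum() / max(pxx.sum(), 1e-30))
        rows.append(
            {
                "blink": abs(float(np.dot(p, blink_topo))) * min(1.0, kurt / 10.0),
                "saccade": abs(float(np.dot(p, sacc_topo))) * min(1.0, dkurt / 10.0),
                "offset": abs(float(np.dot(p, uniform))) * low,
            }
        )
    return pd.DataFrame(rows)


def suggest_artifact_components(
    ica: IcaDecomposition,
    blink_threshold: float = 0.5,
    saccade_threshold: float = 0.5,
    offset_threshold: float = 0.5,
) -> list[int]:
    """Component indices whose scores exceed the default thresholds."""
    if ica.scores is None:
        raise ValueError("decomposition has no scores")
    s = ica.scores
    flagged = (
        (s["blink"] > blink_threshold)
        | (s["saccade"] > saccade_threshold)
        | (s["offset"] > offset_threshold)
    )
    return list(np.flatnonzero(flagged.to_numpy()))


def component_erp_contrast(
    epochs: EpochSet,
    ica: IcaDecomposition,
    component: int,
    kind: Kind = Kind.STANDARD,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Attended-vs-ignored temporal cluster test on one ICA component.

    Projects the epochs on the component's unmixing vector and runs the
    1-D TFCE permutation test (the component-level analogue of the
    sensor-space contrast), at the component-test alpha of 0.05.
    """
    from .erpstats import cluster_permutation_test

    if not (0 <= component < ica.n_components):
        raise ValueError(f"component {component} out of range")
    w = ica.unmixing[component]
    att, _ = epochs.select(kind=kind, attended=True)
    ign, _ = epochs.select(kind=kind, attended=False)
    if len(att) < 2 or len(ign) < 2:
        raise ValueError("need >= 2 epochs per condition")
    a = np.einsum("c,ect->et", w, att)[:, None, :]
    b = np.einsum("c,ect->et", w, ign)[:, None, :]
    if a.std() == 0 and b.std() == 0:
        raise ValueError("degenerate input: zero-variance component")
    adjacency = np.zeros((1, 1), bool)
    return cluster_permutation_test(
        a, b, adjacency, n_perm=n_permutations, alpha=alpha, seed=seed
    )
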