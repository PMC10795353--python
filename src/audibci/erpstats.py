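"""ERP averaging and TFCE spatio-temporal cluster permutation tests.

The attended-vs-ignored and standard-vs-deviant contrasts are assessed
with a non-parametric max-statistic permutation test over the
channels x time statistic map, enhanced by threshold-free cluster
enhancement (TFCE):

    TFCE(v) = sum_h extent_h(v)^E * h^H * dh,   h = dh, 2 dh, ... stat(v)

where ``extent_h(v)`` is the size of the spatio-temporal connected
component containing v after thresholding the map at h.  Components
connect neighbouring time samples within a channel and simultaneous
samples of spatially adjacent channels (Delaunay neighbourhood of the 2-D
montage).  Negative deflections are enhanced by applying the transform to
the negated map.  Defaults E = 0.5, H = 2 (the reference parametrisation),
dh = max|stat| / 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import Delaunay, distance_matrix

from .preproc import EpochSet
from .stimgen import Kind

__all__ = [
    "ErpAverage",
    "ClusterResult",
    "average_erp",
    "channel_adjacency",
    "tfce_enhance",
    "cluster_permutation_test",
    "erp_contrast",
    "plot_erp_clusters",
]


# ---------------------------------------------------------------------------
# averaging


@dataclass
class ErpAverage:
    mean: np.ndarray  # (n_channels, n_samples), µV
    n_epochs: int
    fs: float
    window: tuple[float, float]
    channels: list[str]
    label: str = ""


def average_erp(
    epochs: EpochSet,
    kind: Kind | str,
    stream=None,
    attended: bool | None = None,
    block: int | None = None,
    label: str = "",
) -> ErpAverage:
    """Arithmetic mean over the kept epochs of one condition."""
    data, _ = epochs.select(kind=kind, stream=stream, attended=attended, block=block)
    if len(data) == 0:
        raise ValueError("empty selection")
    kind = Kind(kind)
    return ErpAverage(
        mean=data.mean(axis=0),
        n_epochs=len(data),
        fs=epochs.fs,
        window=epochs.windows[kind],
        channels=list(epochs.channels),
        label=label,
    )


# ---------------------------------------------------------------------------
# adjacency


def channel_adjacency(positions: np.ndarray, prune_factor: float = 1.5) -> np.ndarray:
    """Symmetric channel neighbour matrix from 2-D positions.

    Delaunay triangulation with edges longer than ``prune_factor`` x the
    median edge length removed; with fewer than 4 channels all pairs are
    neighbours.
    """
    n = len(positions)
    adj = np.zeros((n, n), bool)
    if n < 4:
        adj[:] = True
    else:
        tri = Delaunay(positions)
        for simplex in tri.simplices:
            for i in range(3):
                a, b = simplex[i], simplex[(i + 1) % 3]
                adj[a, b] = adj[b, a] = True
        d = distance_matrix(positions, positions)
        lengths = d[adj]
        if lengths.size:
            adj &= d <= prune_factor * np.median(lengths)
    np.fill_diagonal(adj, False)
    return adj


# ---------------------------------------------------------------------------
# TFCE


@njit(cache=False)
def _tfce_kernel(stat, nbr_idx, nbr_ptr, heights, E, H, dh):  # pragma: no cover
    n = stat.shape[0]
    out = np.zeros(n)
    labels = np.empty(n, np.int64)
    stack = np.empty(n, np.int64)
    sizes = np.empty(n, np.int64)
    for h in heights:
        labels[:] = -1
        n_comp = 0
        for start in range(n):
            if stat[start] < h or labels[start] >= 0:
                continue
            # flood fill one component
            top = 0
            stack[0] = start
            labels[start] = n_comp
            size = 0
            while top >= 0:
                v = stack[top]
                top -= 1
                size += 1
                for k in range(nbr_ptr[v], nbr_ptr[v + 1]):
                    u = nbr_idx[k]
                    if stat[u] >= h and labels[u] < 0:
                        labels[u] = n_comp
                        top += 1
                        stack[top] = u
            sizes[n_comp] = size
            n_comp += 1
        inc_h = h**H * dh
        for v in range(n):
            if labels[v] >= 0:
                out[v] += sizes[labels[v]] ** E * inc_h
    return out


def _grid_neighbors(n_ch: int, n_t: int, adjacency: np.ndarray):
    """CSR neighbour lists of the channels x time grid graph."""
    nbrs = [[] for _ in range(n_ch * n_t)]
    for c in range(n_ch):
        base = c * n_t
        for t in range(n_t):
            v = base + t
            if t > 0:
                nbrs[v].append(v - 1)
            if t < n_t - 1:
                nbrs[v].append(v + 1)
        for c2 in np.flatnonzero(adjacency[c]):
            for t in range(n_t):
                nbrs[c * n_t + t].append(int(c2) * n_t + t)
    ptr = np.zeros(n_ch * n_t + 1, np.int64)
    for v, lst in enumerate(nbrs):
        ptr[v + 1] = ptr[v] + len(lst)
    idx = np.empty(ptr[-1], np.int64)
    for v, lst in enumerate(nbrs):
        idx[ptr[v] : ptr[v + 1]] = lst
    return idx, ptr


def tfce_enhance(
    stat: np.ndarray,
    adjacency: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    _graph=None,
) -> np.ndarray:
    """Signed TFCE transform of a channels x time statistic map.

    Positive and negative parts are enhanced separately; the output
    carries the sign of the input.  ``dh`` defaults to max|stat| / 100.
    """
    stat = np.asarray(stat, float)
    if stat.ndim != 2:
        raise ValueError("stat map must be 2-D (channels x time)")
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic map must be finite")
    vmax = np.abs(stat).max()
    if vmax == 0:
        return np.zeros_like(stat)
    if dh is None:
        dh = vmax / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    n_ch, n_t = stat.shape
    if _graph is None:
        _graph = _grid_neighbors(n_ch, n_t, np.asarray(adjacency, bool))
    idx, ptr = _graph
    out = np.zeros(n_ch * n_t)
    for sign in (1.0, -1.0):
        part = sign * stat.ravel()
        top = part.max()
        if top < dh:
            continue
        heights = np.arange(dh, top + dh / 2, dh)
        out += sign * _tfce_kernel(part, idx, ptr, heights, E, H, dh)
    return out.reshape(n_ch, n_t)


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class ClusterResult:
    stat: np.ndarray  # observed statistic map (channels x time)
    tfce: np.ndarray  # signed TFCE-enhanced map
    p_values: np.ndarray  # per-sample FWE-corrected p-values
    mask: np.ndarray  # p <= alpha
    alpha: float
    n_permutations: int

    @property
    def polarity(self) -> np.ndarray:
        """+1 / -1 / 0 per sample (positive / negative / null statistic)."""
        return np.sign(self.stat).astype(int)

    def significant_clusters(self) -> bool:
        return bool(self.mask.any())


def _t_map(a: np.ndarray, b: np.ndarray, var_floor: float) -> np.ndarray:
    """Independent-samples t statistic per (channel, time) cell."""
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1) if na > 1 else np.zeros_like(ma)
    vb = b.var(axis=0, ddof=1) if nb > 1 else np.zeros_like(mb)
    sp = ((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1)
    denom = np.sqrt(sp * (1 / na + 1 / nb) + var_floor)
    return (ma - mb) / denom


def _t_one_sample(d: np.ndarray, var_floor: float) -> np.ndarray:
    n = len(d)
    return d.mean(axis=0) / np.sqrt(d.var(axis=0, ddof=1) / n + var_floor)


def cluster_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.01,
    seed: int = 0,
    design: str = "independent",
    E: float = 0.5,
    H: float = 2.0,
) -> ClusterResult:
    """Max-TFCE permutation test between two epoch sets.

    ``a`` and ``b`` are (n_epochs, n_channels, n_samples) arrays.  The
    observed per-sample statistic is an independent-samples t (labels
    permuted under the null) or, with ``design='paired'``, a one-sample t
    on a - b (signs flipped under the null).  Family-wise correction uses
    the null distribution of the maximum |TFCE| over the map; p-values
    are permutation ranks in [1/(n_perm+1), 1].  Degenerate (zero)
    variances are handled by a small variance floor.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("conditions must be (epochs, channels, samples) alike")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per condition")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    scale = max(np.var(a), np.var(b))
    var_floor = 1e-12 * max(scale, 1e-30)
    rng = np.random.default_rng(seed)
    n_ch, n_t = a.shape[1:]
    graph = _grid_neighbors(n_ch, n_t, np.asarray(adjacency, bool))

    if design == "independent":
        obs = _t_map(a, b, var_floor)
    elif design == "paired":
        if len(a) != len(b):
            raise ValueError("paired design needs equal epoch counts")
        obs = _t_one_sample(a - b, var_floor)
    else:
        raise ValueError(f"unknown design {design!r}")

    vmax = np.abs(obs).max()
    dh = vmax / 100.0 if vmax > 0 else 1.0
    tfce_obs = tfce_enhance(obs, adjacency, E=E, H=H, dh=dh, _graph=graph)

    null_max = np.empty(n_perm)
    if design == "independent":
        pooled = np.concatenate([a, b], axis=0)
        na = len(a)
        for i in range(n_perm):
            perm = rng.permutation(len(pooled))
            t = _t_map(pooled[perm[:na]], pooled[perm[na:]], var_floor)
            null_max[i] = np.abs(
                tfce_enhance(t, adjacency, E=E, H=H, dh=dh, _graph=graph)
            ).max()
    else:
        d = a - b
        for i in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=len(d))[:, None, None]
            t = _t_one_sample(d * signs, var_floor)
            null_max[i] = np.abs(
                tfce_enhance(t, adjacency, E=E, H=H, dh=dh, _graph=graph)
            ).max()

    null_sorted = np.sort(null_max)
    exceed = len(null_sorted) - np.searchsorted(
        null_sorted, np.abs(tfce_obs).ravel(), side="left"
    )
    p = (1.0 + exceed) / (n_perm + 1.0)
    p = p.reshape(n_ch, n_t)
    return ClusterResult(
        stat=obs,
        tfce=tfce_obs,
        p_values=p,
        mask=p <= alpha,
        alpha=alpha,
        n_permutations=n_perm,
    )


def erp_contrast(
    epochs: EpochSet,
    kind: Kind | str,
    adjacency: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.01,
    seed: int = 0,
) -> ClusterResult:
    """Attended-vs-ignored TFCE cluster test for one stimulus kind."""
    att, _ = epochs.select(kind=kind, attended=True)
    ign, _ = epochs.select(kind=kind, attended=False)
    return cluster_permutation_test(
        att, ign, adjacency, n_perm=n_perm, alpha=alpha, seed=seed
    )


def plot_erp_clusters(
    averages: list[ErpAverage],
    result: ClusterResult,
    channel: str,
    path=None,
):
    """Waveforms of one channel with significant samples shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ci = averages[0].channels.index(channel)
    t = (
        np.arange(averages[0].mean.shape[1]) / averages[0].fs
        + averages[0].window[0]
    )
    for avg in averages:
        ax.plot(t, avg.mean[ci], label=avg.label or f"n={avg.n_epochs}")
    sig = result.mask[ci]
    if sig.any():
        ylim = ax.get_ylim()
        ax.fill_between(t, *ylim, where=sig, color="0.8", zorder=0)
        ax.set_ylim(ylim)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("amplitude (µV)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
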