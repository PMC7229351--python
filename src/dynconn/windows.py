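"""Sliding-window construction of multilayer functional-connectivity networks.

A subject's ROI time series (volumes x regions) is cut into overlapping
rectangular windows; within each window the pairwise Pearson correlation
matrix forms one layer of a weighted dynamic network.  Layers can then be
thresholded at a target sparsity (fraction of strongest connections kept)
to obtain binary dynamic networks on which the temporal graph metrics are
defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROITimeSeries",
    "WindowScheme",
    "WeightedDynamicNetwork",
    "BinaryDynamicNetwork",
    "make_windows",
    "window_fc",
    "binarize_by_sparsity",
    "binarize_grid",
]


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"roi{i:03d}" for i in range(n))


@dataclass(frozen=True, eq=False)
class ROITimeSeries:
    """One subject's ROI time series: BOLD-like values, volumes x regions.

    Parameters
    ----------
    data : ndarray, shape (volumes, regions)
        Region-averaged signal per volume; dimensionless.
    tr_s : float
        Repetition time in seconds (time between consecutive volumes).
    node_labels : sequence of str, optional
        Region identifiers, one per column; generated if omitted.
    """

    data: np.ndarray
    tr_s: float
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("time-series data must be 2-D (volumes x regions)")
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError("need at least 2 volumes and 2 regions")
        if not np.isfinite(data).all():
            raise ValueError("time-series data contains missing/non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        object.__setattr__(self, "data", data)
        labels = tuple(self.node_labels) or _default_labels(data.shape[1])
        if len(labels) != data.shape[1]:
            raise ValueError("node_labels length must equal number of regions")
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowScheme:
    """Placement of rectangular sliding windows on a scan."""

    window_s: float
    step_s: float
    window_vols: int
    step_vols: int
    n_windows: int
    starts: tuple[int, ...]


def _seconds_to_vols(seconds: float, tr_s: float, name: str) -> int:
    vols = seconds / tr_s
    rounded = round(vols)
    if abs(vols - rounded) > 1e-9 or rounded < 1:
        raise ValueError(
            f"{name}={seconds} s is not a positive whole multiple of TR={tr_s} s"
        )
    return int(rounded)


def make_windows(
    n_volumes: int, tr_s: float, window_s: float, step_s: float
) -> WindowScheme:
    """Compute the sliding-window scheme for a scan of ``n_volumes`` volumes.

    The window and step lengths are given in seconds and must be exact
    multiples of the repetition time; fractional conversions are rejected
    rather than rounded.  Windows start at 0 and advance by the step until
    the next window would overrun the scan.
    """
    window_vols = _seconds_to_vols(window_s, tr_s, "window_s")
    step_vols = _seconds_to_vols(step_s, tr_s, "step_s")
    if window_vols < 2:
        raise ValueError("window must span at least 2 volumes")
    if window_vols > n_volumes:
        raise ValueError(
            f"window of {window_vols} volumes exceeds series of {n_volumes} volumes"
        )
    n_windows = (n_volumes - window_vols) // step_vols + 1
    starts = tuple(range(0, n_windows * step_vols, step_vols))
    return WindowScheme(
        window_s=float(window_s),
        step_s=float(step_s),
        window_vols=window_vols,
        step_vols=step_vols,
        n_windows=n_windows,
        starts=starts,
    )


@dataclass(frozen=True, eq=False)
class WeightedDynamicNetwork:
    """T layers of symmetric window-wise Pearson correlation matrices.

    ``layers`` has shape (T, N, N); diagonals are fixed at 0 (self
    connections are not edges).
    """

    layers: np.ndarray
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        layers = np.asarray(self.layers, dtype=float)
        if layers.ndim != 3 or layers.shape[1] != layers.shape[2]:
            raise ValueError("layers must have shape (T, N, N)")
        if np.abs(layers - layers.transpose(0, 2, 1)).max() > 1e-8:
            raise ValueError("layers must be symmetric")
        if np.abs(np.diagonal(layers, axis1=1, axis2=2)).max() > 0:
            raise ValueError("layer diagonals must be zero")
        if layers.min() < -1 - 1e-9 or layers.max() > 1 + 1e-9:
            raise ValueError("correlation weights must lie in [-1, 1]")
        object.__setattr__(self, "layers", layers)
        labels = tuple(self.node_labels) or _default_labels(layers.shape[1])
        if len(labels) != layers.shape[1]:
            raise ValueError("node_labels length must equal number of regions")
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_regions(self) -> int:
        return self.layers.shape[1]


@dataclass(frozen=True, eq=False)
class BinaryDynamicNetwork:
    """T symmetric 0/1 adjacency layers at one sparsity level."""

    layers: np.ndarray
    sparsity: float
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        layers = np.asarray(self.layers)
        if layers.ndim != 3 or layers.shape[1] != layers.shape[2]:
            raise ValueError("layers must have shape (T, N, N)")
        layers = layers.astype(bool)
        if (layers != layers.transpose(0, 2, 1)).any():
            raise ValueError("layers must be symmetric")
        if np.diagonal(layers, axis1=1, axis2=2).any():
            raise ValueError("layer diagonals must be zero")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must lie in (0, 1]")
        object.__setattr__(self, "layers", layers)
        labels = tuple(self.node_labels) or _default_labels(layers.shape[1])
        if len(labels) != layers.shape[1]:
            raise ValueError("node_labels length must equal number of regions")
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_regions(self) -> int:
        return self.layers.shape[1]


def window_fc(ts: ROITimeSeries, scheme: WindowScheme) -> WeightedDynamicNetwork:
    """Window-wise pairwise Pearson correlation layers for one subject.

    Raises
    ------
    ValueError
        If any node's series has zero variance inside any window (a
        correlation would be undefined; silently imputed values would
        corrupt every downstream metric, so this is a hard error naming
        the node and window).
    """
    if scheme.starts[-1] + scheme.window_vols > ts.n_volumes:
        raise ValueError("window scheme overruns the time series")
    T = scheme.n_windows
    N = ts.n_regions
    layers = np.empty((T, N, N))
    for t, start in enumerate(scheme.starts):
        seg = ts.data[start : start + scheme.window_vols]
        sd = seg.std(axis=0)
        # numerically constant counts as zero variance
        tol = 1e-12 * np.maximum(1.0, np.abs(seg).max(axis=0))
        flat = sd <= tol
        if flat.any():
            j = int(np.flatnonzero(flat)[0])
            raise ValueError(
                f"zero-variance series for node '{ts.node_labels[j]}' "
                f"(index {j}) in window {t}"
            )
        corr = np.corrcoef(seg, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        layers[t] = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return WeightedDynamicNetwork(layers=layers, node_labels=ts.node_labels)


def _edge_count(sparsity: float, n_regions: int) -> int:
    # round-half-away-from-zero, deterministic across platforms
    E = n_regions * (n_regions - 1) // 2
    k = int(math.floor(sparsity * E + 0.5))
    if k == 0:
        raise ValueError(
            f"sparsity {sparsity} keeps zero of {E} edges after rounding"
        )
    return min(k, E)


def _edge_rank_matrices(layers: np.ndarray, ranking: str) -> np.ndarray:
    """Per-layer rank of every undirected edge in the retention order.

    Rank 0 is the strongest edge.  Ties are broken by ascending (i, j)
    linear index so binarization is deterministic and edge sets are nested
    across sparsities.
    """
    if ranking not in ("signed", "absolute"):
        raise ValueError("ranking must be 'signed' or 'absolute'")
    T, N, _ = layers.shape
    iu = np.triu_indices(N, 1)
    E = iu[0].size
    ranks = np.full((T, N, N), E, dtype=np.int64)
    idx = np.arange(E)
    for t in range(T):
        w = layers[t][iu]
        if ranking == "absolute":
            w = np.abs(w)
        order = np.lexsort((idx, -w))  # primary: weight desc; ties: index asc
        r = np.empty(E, dtype=np.int64)
        r[order] = idx
        ranks[t][iu] = r
        ranks[t].T[iu] = r
    return ranks


def binarize_by_sparsity(
    net: WeightedDynamicNetwork, sparsity: float, ranking: str = "signed"
) -> BinaryDynamicNetwork:
    """Keep the ``round(sparsity * E)`` strongest undirected edges per layer.

    ``ranking='signed'`` (default) ranks raw correlations, strongest
    positive first; ``'absolute'`` ranks by magnitude.  Ties at the cutoff
    are broken by ascending (i, j) index order.
    """
    return binarize_grid(net, [sparsity], ranking=ranking)[0]


def binarize_grid(
    net: WeightedDynamicNetwork, sparsities, ranking: str = "signed"
) -> list[BinaryDynamicNetwork]:
    """Binarize at several sparsity levels, ranking each layer only once.

    Because ties are broken identically at every level, the edge set at a
    lower sparsity is always a subset of the edge set at a higher one.
    """
    sparsities = [float(s) for s in sparsities]
    for s in sparsities:
        if not 0 < s <= 1:
            raise ValueError("sparsity must lie in (0, 1]")
    ranks = _edge_rank_matrices(net.layers, ranking)
    out = []
    for s in sparsities:
        k = _edge_count(s, net.n_regions)
        out.append(
            BinaryDynamicNetwork(
                layers=ranks < k, sparsity=s, node_labels=net.node_labels
            )
        )
    return out
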