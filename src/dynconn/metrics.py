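"""Spatio-temporal metrics of multilayer dynamic networks.

Three metric families, each at global and nodal level:

* **Temporal variability** (weighted layers): one minus the mean Pearson
  correlation of a node's connectivity profile between all window pairs.
  Ranges 0 (frozen connectivity) to 2 (perfectly anticorrelated profiles).
* **Temporal correlation coefficient** (binary layers): mean normalized
  overlap of a node's neighbor set between consecutive windows; 0 to 1,
  higher = stronger temporal clustering.
* **Temporal path length** (binary layers): mean arrival layer of the
  fastest time-respecting paths between nodes; >= 1, lower = higher
  temporal efficiency.

A time-respecting path uses at most one edge per layer with strictly
increasing layer indices; waiting at a node costs nothing.  The arrival
layer of the fastest such path is the temporal distance d(i, j); it is
direction-dependent even though each layer is undirected, because a path
cannot be reversed without decreasing layer indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .windows import BinaryDynamicNetwork, ROITimeSeries, WeightedDynamicNetwork, WindowScheme, binarize_grid, window_fc

__all__ = [
    "NodalMetricVector",
    "GlobalMetrics",
    "LatencyMatrix",
    "SubjectMetricsRecord",
    "default_sparsity_grid",
    "nodal_temporal_variability",
    "global_temporal_variability",
    "nodal_temporal_correlation",
    "global_temporal_correlation",
    "latency_matrix",
    "nodal_temporal_path_length",
    "characteristic_temporal_path_length",
    "subject_metrics",
]


def default_sparsity_grid() -> np.ndarray:
    """Sparsity levels 0.10, 0.11, ..., 0.50 (41 levels)."""
    return np.round(np.arange(10, 51) / 100.0, 2)


@dataclass(frozen=True, eq=False)
class NodalMetricVector:
    """One value per region for a single metric (and sparsity, if binary)."""

    values: np.ndarray
    metric_name: str
    sparsity: float | None = None
    unreachable: np.ndarray | None = None  # per-node flag: some target unreachable


@dataclass(frozen=True, eq=False)
class LatencyMatrix:
    """Temporal distances d(i, j) in layers; inf where j is never reached.

    Not necessarily symmetric: time-respecting reachability is
    direction-dependent.  Diagonal is 0.
    """

    d: np.ndarray


@dataclass(frozen=True)
class GlobalMetrics:
    temporal_variability: float
    temporal_correlation_by_sparsity: dict
    characteristic_temporal_path_length_by_sparsity: dict
    unreachable_pair_fraction_by_sparsity: dict
    temporal_correlation_mean: float
    characteristic_temporal_path_length_mean: float
    unreachable_pair_fraction_mean: float


@dataclass(frozen=True, eq=False)
class SubjectMetricsRecord:
    """All global and nodal metrics for one subject."""

    global_metrics: GlobalMetrics
    nodal_variability: NodalMetricVector
    nodal_correlation_by_sparsity: dict
    nodal_path_by_sparsity: dict
    nodal_correlation_mean: np.ndarray
    nodal_path_mean: np.ndarray
    node_labels: tuple


# ---------------------------------------------------------------------------
# temporal variability (weighted layers)
# ---------------------------------------------------------------------------

def _node_profiles(net: WeightedDynamicNetwork, k: int) -> np.ndarray:
    # connectivity profile of node k per layer, self entry removed: (T, N-1)
    return np.delete(net.layers[:, k, :], k, axis=1)


def nodal_temporal_variability(net: WeightedDynamicNetwork) -> NodalMetricVector:
    """V_k = 1 - mean over window pairs of corr(profile_k(t), profile_k(t')).

    Profiles are the node's correlation row with the self entry removed.
    A constant profile in any layer makes the correlation undefined and is
    reported as an error naming the node and layer.
    """
    T, N = net.n_layers, net.n_regions
    if T < 2:
        raise ValueError("temporal variability needs at least 2 layers")
    values = np.empty(N)
    for k in range(N):
        prof = _node_profiles(net, k)
        sd = prof.std(axis=1)
        flat = sd <= 1e-12  # weights are bounded by 1, absolute tol suffices
        if flat.any():
            t = int(np.flatnonzero(flat)[0])
            raise ValueError(
                f"constant connectivity profile for node "
                f"'{net.node_labels[k]}' (index {k}) in layer {t}"
            )
        C = np.corrcoef(prof)
        iu = np.triu_indices(T, 1)
        values[k] = 1.0 - C[iu].mean()
    return NodalMetricVector(
        values=np.clip(values, 0.0, 2.0), metric_name="temporal_variability"
    )


def global_temporal_variability(
    net: WeightedDynamicNetwork, method: str = "nodal_mean"
) -> float:
    """Whole-brain temporal variability.

    ``method='nodal_mean'`` (default) averages the nodal values;
    ``'matrix'`` computes 1 minus the mean pairwise correlation of the
    vectorized upper triangles of the layers.
    """
    if method == "nodal_mean":
        return float(nodal_temporal_variability(net).values.mean())
    if method == "matrix":
        T = net.n_layers
        iu = np.triu_indices(net.n_regions, 1)
        vecs = np.stack([net.layers[t][iu] for t in range(T)])
        if (vecs.std(axis=1) == 0).any():
            raise ValueError("constant layer: whole-matrix correlation undefined")
        C = np.corrcoef(vecs)
        pu = np.triu_indices(T, 1)
        return float(np.clip(1.0 - C[pu].mean(), 0.0, 2.0))
    raise ValueError("method must be 'nodal_mean' or 'matrix'")


# ---------------------------------------------------------------------------
# temporal correlation coefficient (binary layers)
# ---------------------------------------------------------------------------

def _tcc_from_adjacency(A: np.ndarray) -> np.ndarray:
    """Nodal temporal correlation from adjacency stack(s).

    ``A`` has shape (..., T, N, N); returns (..., N).  Terms with an
    isolated node at either end of a step contribute 0, keeping values in
    [0, 1] and the global mean's denominator fixed at N.
    """
    Af = A.astype(float)
    deg = Af.sum(axis=-1)  # (..., T, N)
    num = (Af[..., :-1, :, :] * Af[..., 1:, :, :]).sum(axis=-1)  # (..., T-1, N)
    den = np.sqrt(deg[..., :-1, :] * deg[..., 1:, :])
    terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return terms.mean(axis=-2)


def nodal_temporal_correlation(net: BinaryDynamicNetwork) -> NodalMetricVector:
    """C_i: mean degree-normalized neighbor overlap between consecutive layers."""
    if net.n_layers < 2:
        raise ValueError("temporal correlation needs at least 2 layers")
    values = _tcc_from_adjacency(net.layers)
    return NodalMetricVector(
        values=np.clip(values, 0.0, 1.0),
        metric_name="temporal_correlation",
        sparsity=net.sparsity,
    )


def global_temporal_correlation(net: BinaryDynamicNetwork) -> float:
    """Mean of the nodal temporal correlation over all nodes."""
    return float(nodal_temporal_correlation(net).values.mean())


# ---------------------------------------------------------------------------
# temporal efficiency (binary layers)
# ---------------------------------------------------------------------------

def _latency_batch(A: np.ndarray) -> np.ndarray:
    """Temporal distances for a batch of adjacency stacks.

    ``A`` has shape (B, T, N, N) boolean; returns (B, N, N) float with inf
    for unreachable pairs.  Layer-sequential frontier expansion: the
    reached set persists across layers (waiting is free); at layer t every
    in-layer neighbor of the reached set is absorbed with arrival layer t.
    """
    B, T, N, _ = A.shape
    Af = A.astype(np.float32)
    eye = np.eye(N, dtype=bool)
    R = np.broadcast_to(eye, (B, N, N)).copy()
    D = np.full((B, N, N), np.inf)
    D[:, eye] = 0.0
    for t in range(T):
        new = (R.astype(np.float32) @ Af[:, t]) > 0.5
        new &= ~R
        if new.any():
            D[new] = t + 1
            R |= new
        if R.all():
            break
    return D


def latency_matrix(net: BinaryDynamicNetwork) -> LatencyMatrix:
    """Fastest-arrival temporal distance for every ordered node pair.

    d(i, j) is the smallest layer index t such that a time-respecting path
    from i reaches j with its last edge in layer t (a direct edge in layer
    1 gives d = 1); inf if j is never reached by layer T.
    """
    return LatencyMatrix(d=_latency_batch(net.layers[None])[0])


def nodal_temporal_path_length(lat: LatencyMatrix) -> NodalMetricVector:
    """L_i: mean finite outgoing temporal distance d(i, j), j != i.

    Nodes with unreachable targets are flagged; a node reaching nothing
    gets inf.
    """
    d = lat.d
    N = d.shape[0]
    off = ~np.eye(N, dtype=bool)
    finite = np.isfinite(d) & off
    counts = finite.sum(axis=1)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    values = np.divide(sums, counts, out=np.full(N, np.inf), where=counts > 0)
    unreachable = counts < N - 1
    return NodalMetricVector(
        values=values, metric_name="temporal_path_length", unreachable=unreachable
    )


def characteristic_temporal_path_length(lat: LatencyMatrix) -> tuple[float, float]:
    """Mean finite temporal distance over ordered pairs, plus the fraction
    of ordered pairs that are unreachable (surfaced so downstream analyses
    can exclude pathological subjects rather than hide them)."""
    d = lat.d
    N = d.shape[0]
    off = ~np.eye(N, dtype=bool)
    finite = np.isfinite(d) & off
    n_pairs = N * (N - 1)
    n_finite = int(finite.sum())
    if n_finite == 0:
        raise ValueError("all ordered node pairs are unreachable")
    mean = float(d[finite].mean())
    return mean, float((n_pairs - n_finite) / n_pairs)


# ---------------------------------------------------------------------------
# per-subject orchestration
# ---------------------------------------------------------------------------

def subject_metrics(
    ts: ROITimeSeries,
    scheme: WindowScheme,
    sparsity_grid=None,
    ranking: str = "signed",
    variability_method: str = "nodal_mean",
) -> SubjectMetricsRecord:
    """Full metric profile for one subject.

    Temporal variability is computed once on the weighted layers; the
    temporal correlation coefficient and temporal path length are computed
    at every sparsity of the grid (default 0.10..0.50 step 0.01) and also
    averaged across the grid, which is the value used by the group
    correlation analyses.
    """
    if sparsity_grid is None:
        sparsity_grid = default_sparsity_grid()
    grid = [float(s) for s in sparsity_grid]

    net = window_fc(ts, scheme)
    nodal_var = nodal_temporal_variability(net)
    if variability_method == "nodal_mean":
        global_var = float(nodal_var.values.mean())
    else:
        global_var = global_temporal_variability(net, method=variability_method)

    bins = binarize_grid(net, grid, ranking=ranking)
    A = np.stack([b.layers for b in bins])  # (S, T, N, N)

    nodal_tcc = np.clip(_tcc_from_adjacency(A), 0.0, 1.0)  # (S, N)
    D = _latency_batch(A)  # (S, N, N)

    tcc_by_s: dict = {}
    ctpl_by_s: dict = {}
    unreach_by_s: dict = {}
    nodal_tcc_by_s: dict = {}
    nodal_tpl_by_s: dict = {}
    for si, s in enumerate(grid):
        lat = LatencyMatrix(d=D[si])
        ctpl, unreach = characteristic_temporal_path_length(lat)
        tcc_by_s[s] = float(nodal_tcc[si].mean())
        ctpl_by_s[s] = ctpl
        unreach_by_s[s] = unreach
        nodal_tcc_by_s[s] = NodalMetricVector(
            values=nodal_tcc[si], metric_name="temporal_correlation", sparsity=s
        )
        nodal_tpl = nodal_temporal_path_length(lat)
        nodal_tpl_by_s[s] = NodalMetricVector(
            values=nodal_tpl.values,
            metric_name="temporal_path_length",
            sparsity=s,
            unreachable=nodal_tpl.unreachable,
        )

    gm = GlobalMetrics(
        temporal_variability=global_var,
        temporal_correlation_by_sparsity=tcc_by_s,
        characteristic_temporal_path_length_by_sparsity=ctpl_by_s,
        unreachable_pair_fraction_by_sparsity=unreach_by_s,
        temporal_correlation_mean=float(np.mean(list(tcc_by_s.values()))),
        characteristic_temporal_path_length_mean=float(
            np.mean(list(ctpl_by_s.values()))
        ),
        unreachable_pair_fraction_mean=float(np.mean(list(unreach_by_s.values()))),
    )
    return SubjectMetricsRecord(
        global_metrics=gm,
        nodal_variability=nodal_var,
        nodal_correlation_by_sparsity=nodal_tcc_by_s,
        nodal_path_by_sparsity=nodal_tpl_by_s,
        nodal_correlation_mean=np.stack(
            [nodal_tcc_by_s[s].values for s in grid]
        ).mean(axis=0),
        nodal_path_mean=np.stack(
            [nodal_tpl_by_s[s].values for s in grid]
        ).mean(axis=0),
        node_labels=ts.node_labels,
    )
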