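"""Sliding-window temporal networks, signed multilayer modularity and flexibility.

A regional BOLD series is cut into nonoverlapping windows; each window's
Pearson correlation matrix is one layer of a multilayer network.  The
quality of a multilayer partition G (nodes x windows) is the signed
multilayer modularity

    Q = sum_t sum_ij [(A+_ijt - g*P+_ijt) - (A-_ijt - g*P-_ijt)] d(g_it, g_jt)
        + sum_{t<T_w} sum_i  w * d(g_it, g_i,t+1)

with A+/A- the positive/negative parts of each layer, P+/- the per-layer
Newman-Girvan null k_i k_j / 2m on the corresponding part (zero when a
part has no weight), gamma the resolution and omega the ordinal
inter-layer coupling (defaults 1 and 1).  The inter-layer sum runs over
t = 1..T_w-1 only: couplings are nearest-neighbour and ordinal.  Q is
used unnormalized; only the argmax partition matters downstream.

Maximization is a Louvain-style locally greedy sweep over the supra
representation (node-move passes in seeded random order, then community
aggregation, repeated to convergence).  Nodal flexibility is the
fraction of adjacent window pairs in which a node changes community
label, averaged over optimization restarts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph_metrics import NodalMetricVector, participation_coefficient
from .network_io import Connectome, ModulePartition, RegionalTimeSeries

__all__ = [
    "TemporalNetwork",
    "ModularityParams",
    "MultilayerPartition",
    "build_temporal_network",
    "multilayer_modularity",
    "louvain_multilayer",
    "nodal_flexibility",
    "global_flexibility",
    "windowed_participation",
]

logger = logging.getLogger(__name__)


@dataclass
class TemporalNetwork:
    """Ordered signed correlation layers A_ijt, one per time window."""

    layers: list[np.ndarray]
    node_ids: list[str]

    def __post_init__(self) -> None:
        for t, a in enumerate(self.layers):
            a = np.asarray(a, dtype=float)
            if a.shape != (self.n_nodes, self.n_nodes):
                raise ValueError(f"layer {t} has shape {a.shape}")
            if np.abs(a - a.T).max() > 1e-10:
                raise ValueError(f"layer {t} is not symmetric")
            if np.abs(a).max() > 1 + 1e-9:
                raise ValueError(f"layer {t} has entries outside [-1, 1]")
            np.fill_diagonal(a, 0.0)
            self.layers[t] = a

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_windows(self) -> int:
        return len(self.layers)

    def layer_connectome(self, window: int) -> Connectome:
        """Layer ``window`` (1-based) as a signed Connectome."""
        if not 1 <= window <= self.n_windows:
            raise IndexError(f"window {window} out of range 1..{self.n_windows}")
        return Connectome(
            weights=self.layers[window - 1].copy(),
            node_ids=list(self.node_ids),
            signed=True,
        )

    def subnetwork(self, windows: slice | list[int]) -> "TemporalNetwork":
        """A temporal network restricted to the given 0-based layer indices."""
        idx = (
            range(*windows.indices(self.n_windows))
            if isinstance(windows, slice)
            else windows
        )
        return TemporalNetwork(
            layers=[self.layers[i].copy() for i in idx], node_ids=list(self.node_ids)
        )


@dataclass
class ModularityParams:
    gamma: float = 1.0
    omega: float = 1.0
    n_runs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class MultilayerPartition:
    """Label matrix G (n_nodes x n_windows) with its modularity Q."""

    g: np.ndarray
    quality: float
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=int)
        if self.g.ndim != 2:
            raise ValueError("partition matrix must be 2-D (nodes x windows)")
        if not np.isfinite(self.quality):
            raise ValueError("partition quality must be finite")

    @property
    def n_windows(self) -> int:
        return self.g.shape[1]


# ---------------------------------------------------------------------------
# temporal network construction
# ---------------------------------------------------------------------------


def build_temporal_network(ts: RegionalTimeSeries, n_windows: int = 10) -> TemporalNetwork:
    """Cut the series into contiguous nonoverlapping windows and correlate.

    Window length is floor(T / n_windows); remainder TRs at the end are
    discarded with a logged warning.  A region with zero variance inside
    any window is an error (the correlation would be undefined).
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    t_total = ts.n_timepoints
    wlen = t_total // n_windows
    if wlen < 2:
        raise ValueError(
            f"window too short: T={t_total} gives length {wlen} with "
            f"{n_windows} windows (need >= 2)"
        )
    if wlen == 2:
        warnings.warn(
            "window length 2: correlations are degenerate (+/-1)", stacklevel=2
        )
    dropped = t_total - wlen * n_windows
    if dropped:
        logger.warning("discarding %d trailing TRs (T=%d, %d windows)", dropped, t_total, n_windows)
    layers = []
    for t in range(n_windows):
        block = ts.x[:, t * wlen : (t + 1) * wlen]
        sd = block.std(axis=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"region {ts.node_ids[dead[0]]} has zero variance in window {t + 1}"
            )
        a = np.corrcoef(block)
        np.clip(a, -1.0, 1.0, out=a)
        np.fill_diagonal(a, 0.0)
        layers.append(a)
    return TemporalNetwork(layers=layers, node_ids=list(ts.node_ids))


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------


def _layer_modularity_matrix(a: np.ndarray, gamma: float) -> np.ndarray:
    """(A+ - g*P+) - (A- - g*P-) with Newman-Girvan nulls per signed part."""
    apos = np.where(a > 0, a, 0.0)
    aneg = np.where(a < 0, -a, 0.0)
    b = apos - aneg
    for part, sign in ((apos, -1.0), (aneg, 1.0)):
        k = part.sum(axis=1)
        two_m = k.sum()
        if two_m > 0:
            b += sign * gamma * np.outer(k, k) / two_m
    return b


def multilayer_modularity(
    tnet: TemporalNetwork,
    partition: MultilayerPartition | np.ndarray,
    params: ModularityParams | None = None,
) -> float:
    """Evaluate Q for a given label matrix, directly from the definition."""
    params = params or ModularityParams()
    g = partition.g if isinstance(partition, MultilayerPartition) else np.asarray(partition)
    n, t_w = tnet.n_nodes, tnet.n_windows
    if g.shape != (n, t_w):
        raise ValueError(f"partition shape {g.shape} does not match ({n}, {t_w})")
    q = 0.0
    for t in range(t_w):
        b = _layer_modularity_matrix(tnet.layers[t], params.gamma)
        same = g[:, t][:, None] == g[:, t][None, :]
        q += b[same].sum()
    if t_w > 1:
        q += params.omega * np.sum(g[:, :-1] == g[:, 1:])
    return float(q)


def _supra_matrix(tnet: TemporalNetwork, params: ModularityParams) -> np.ndarray:
    """Dense supra modularity matrix: layer blocks plus omega/2 ordinal coupling.

    Q(g) = sum_pq B_pq d(g_p, g_q) over the supra index p = (t, i); the
    intra-layer sum counts ordered pairs so each off-diagonal coupling
    entry carries omega/2.
    """
    n, t_w = tnet.n_nodes, tnet.n_windows
    size = n * t_w
    b = np.zeros((size, size))
    for t in range(t_w):
        sl = slice(t * n, (t + 1) * n)
        b[sl, sl] = _layer_modularity_matrix(tnet.layers[t], params.gamma)
    half = 0.5 * params.omega
    for t in range(t_w - 1):
        idx = np.arange(n)
        b[t * n + idx, (t + 1) * n + idx] = half
        b[(t + 1) * n + idx, t * n + idx] = half
    return b


def _greedy_pass(b: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """One sweep of locally greedy node moves; returns True if anything moved.

    Ties in the modularity gain are broken toward the incumbent community
    (a move happens only for a strictly positive gain).
    """
    n = b.shape[0]
    improved = False
    n_comm = labels.max() + 1
    order = rng.permutation(n)
    for p in order:
        w = np.bincount(labels, weights=b[p], minlength=n_comm)
        own = labels[p]
        stay = w[own] - b[p, p]
        gains = w - stay
        gains[own] = 0.0
        best = int(np.argmax(gains))
        if gains[best] > 1e-12 and best != own:
            labels[p] = best
            improved = True
    return improved


def _louvain_once(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Full Louvain (move + aggregate) on a dense symmetric quality matrix."""
    n = b.shape[0]
    assignment = np.arange(n)  # supra node -> current community
    b_cur = b
    while True:
        labels = np.arange(b_cur.shape[0])
        moved = False
        while _greedy_pass(b_cur, labels, rng):
            moved = True
        _, labels = np.unique(labels, return_inverse=True)
        if not moved or labels.max() + 1 == b_cur.shape[0]:
            assignment = labels[assignment]
            break
        assignment = labels[assignment]
        k = labels.max() + 1
        onehot = np.zeros((b_cur.shape[0], k))
        onehot[np.arange(b_cur.shape[0]), labels] = 1.0
        b_cur = onehot.T @ b_cur @ onehot
    _, assignment = np.unique(assignment, return_inverse=True)
    return assignment


def louvain_multilayer(
    tnet: TemporalNetwork, params: ModularityParams | None = None
) -> tuple[MultilayerPartition, list[MultilayerPartition]]:
    """Maximize multilayer modularity; return (best run, all runs).

    Each restart sweeps supra nodes in a fresh seeded random order; the
    partition with the highest internally tracked Q is returned first.
    The engine's Q comes from its aggregated bookkeeping and is expected
    to match :func:`multilayer_modularity` recomputed from scratch.
    """
    params = params or ModularityParams()
    n, t_w = tnet.n_nodes, tnet.n_windows
    b = _supra_matrix(tnet, params)
    runs: list[MultilayerPartition] = []
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_runs)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        assignment = _louvain_once(b, rng)
        k = assignment.max() + 1
        onehot = np.zeros((n * t_w, k))
        onehot[np.arange(n * t_w), assignment] = 1.0
        q = float(np.trace(onehot.T @ b @ onehot))
        g = assignment.reshape(t_w, n).T
        runs.append(MultilayerPartition(g=g, quality=q, node_ids=list(tnet.node_ids)))
    best = max(runs, key=lambda r: r.quality)
    return best, runs


# ---------------------------------------------------------------------------
# flexibility
# ---------------------------------------------------------------------------


def nodal_flexibility(
    partitions: MultilayerPartition | list[MultilayerPartition],
    node_ids: list[str] | None = None,
) -> NodalMetricVector:
    """f_i = fraction of adjacent window pairs where node i changes label.

    When several partitions (optimization restarts) are supplied, the
    per-node flexibilities are averaged across them.
    """
    if isinstance(partitions, MultilayerPartition):
        partitions = [partitions]
    if not partitions:
        raise ValueError("need at least one partition")
    fs = []
    for p in partitions:
        if p.n_windows < 2:
            raise ValueError("flexibility needs at least 2 windows")
        fs.append((p.g[:, 1:] != p.g[:, :-1]).mean(axis=1))
    values = np.mean(fs, axis=0)
    ids = node_ids or partitions[0].node_ids or [str(i) for i in range(values.size)]
    return NodalMetricVector(metric_name="flexibility", values=values, node_ids=list(ids))


def global_flexibility(f: NodalMetricVector) -> float:
    """Mean nodal flexibility over the whole network."""
    if len(f) == 0:
        raise ValueError("empty flexibility vector")
    return float(f.values.mean())


def windowed_participation(
    tnet: TemporalNetwork,
    partition: ModulePartition,
    window: int | None = 1,
    mode: str = "positive_only",
) -> NodalMetricVector:
    """Participation coefficient on one layer (1-based window index).

    ``window=None`` returns the arithmetic mean of per-window PC vectors
    over all layers; a ``(lo, hi)`` tuple averages that inclusive range.
    """
    if window is None:
        window = (1, tnet.n_windows)
    if isinstance(window, tuple):
        lo, hi = window
        vecs = [
            participation_coefficient(
                tnet.layer_connectome(t), partition, mode=mode,
                metric_name="functional_pc",
            ).values
            for t in range(lo, hi + 1)
        ]
        return NodalMetricVector(
            metric_name="functional_pc",
            values=np.mean(vecs, axis=0),
            node_ids=list(tnet.node_ids),
        )
    return participation_coefficient(
        tnet.layer_connectome(window), partition, mode=mode,
        metric_name="functional_pc",
    )
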