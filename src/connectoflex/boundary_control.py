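"""Hierarchical boundary controllability of a structural connectome.

Boundary controllability ranks nodes by how early they appear on
inter-community boundaries while the network is recursively partitioned
into ever finer communities.  Starting from a coarse partition (by
default the predefined functional systems), the nodes with at least one
positive-weight edge crossing a community border form the initial
boundary set and receive a value of 1.  Each community is then bisected
(spectral sign split of its modularity matrix), nodes newly exposed on a
boundary receive ``(N - C)/N`` where ``N`` is the total node count and
``C`` counts the nodes already valued, and the recursion continues until
every node is valued or only singletons remain.  Values therefore lie in
``(0, 1]`` and decrease strictly with hierarchy depth: high values mark
nodes positioned to steer integration between large modules.

The ``n_i`` counting convention is exposed because the per-step variant
("nodes on the boundary at this step") does not guarantee monotonically
decreasing values; the cumulative convention is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .graph_metrics import NodalMetricVector
from .network_io import Connectome, ModulePartition

__all__ = [
    "BoundaryHierarchy",
    "find_boundary_nodes",
    "bisect_community",
    "boundary_controllability",
]


@dataclass
class HierarchyLevel:
    """One level of the recursive partition: communities, new boundary, value."""

    communities: list[np.ndarray]
    boundary_nodes: np.ndarray  # newly valued node indices at this level
    assigned_value: float


@dataclass
class BoundaryHierarchy:
    levels: list[HierarchyLevel] = field(default_factory=list)
    final_values: NodalMetricVector | None = None

    def as_records(self) -> list[dict]:
        """Tidy (node, level, value) rows for dumping."""
        rows = []
        for lvl, level in enumerate(self.levels):
            for node in level.boundary_nodes:
                rows.append(
                    {"node": int(node), "level": lvl, "value": level.assigned_value}
                )
        return rows


def find_boundary_nodes(net: Connectome, partition: ModulePartition) -> np.ndarray:
    """Indices of nodes with >= 1 positive-weight edge into another community."""
    if partition.node_ids != net.node_ids:
        raise ValueError("partition nodes do not match connectome nodes")
    w = net.weights
    labels = partition.labels
    cross = (w > 0) & (labels[:, None] != labels[None, :])
    return np.flatnonzero(cross.any(axis=1))


def _modularity_leading_vector(w: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the Newman modularity matrix B = W - kk'/2m."""
    k = w.sum(axis=1)
    two_m = k.sum()
    b = w - np.outer(k, k) / two_m
    vals, vecs = np.linalg.eigh(b)
    return vecs[:, -1]


def bisect_community(
    net: Connectome, members: np.ndarray, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (seeded) two-way split of the induced subgraph.

    Disconnected communities split along connected components (largest
    component vs the rest); connected ones by the sign of the leading
    eigenvector of the subgraph modularity matrix, with seeded random
    sides for zero loadings and a guaranteed non-empty pair.
    """
    members = np.asarray(members, dtype=int)
    if members.size < 2:
        raise ValueError("community must have at least 2 members to bisect")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sub = net.weights[np.ix_(members, members)]
    pos = np.where(sub > 0, sub, 0.0)
    n_comp, comp = connected_components(csr_matrix(pos), directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        big = sizes.argmax()
        mask = comp == big
        return members[mask], members[~mask]
    if pos.sum() == 0:  # unreachable for connected positive graphs; safety net
        mask = np.zeros(members.size, dtype=bool)
        mask[: members.size // 2] = True
        return members[mask], members[~mask]
    v = _modularity_leading_vector(pos)
    tol = 1e-12
    side = v > tol
    zero = np.abs(v) <= tol
    if zero.any():
        side[zero] = rng.random(int(zero.sum())) < 0.5
    if side.all() or not side.any():
        # degenerate spectrum: peel off the node with the extreme loading
        side[:] = False
        side[np.argmax(v)] = True
    return members[side], members[~side]


def boundary_controllability(
    net: Connectome,
    initial_partition: ModulePartition,
    seed: int = 0,
    n_i_convention: str = "cumulative",
) -> tuple[NodalMetricVector, BoundaryHierarchy]:
    """Boundary-controllability value in (0, 1] for every node.

    ``n_i_convention`` selects how the boundary count entering
    ``(N - N_i)/N`` is taken: ``"cumulative"`` (all nodes valued so far;
    values strictly decrease with depth) or ``"per_step"`` (boundary
    nodes found at the current level only).
    """
    if n_i_convention not in ("cumulative", "per_step"):
        raise ValueError(f"unknown n_i_convention '{n_i_convention}'")
    n = net.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)
    values = np.full(n, np.nan)
    hierarchy = BoundaryHierarchy()

    communities = [initial_partition.members(m) for m in range(initial_partition.n_modules)]
    level0 = find_boundary_nodes(net, initial_partition)
    values[level0] = 1.0
    hierarchy.levels.append(
        HierarchyLevel(
            communities=[c.copy() for c in communities],
            boundary_nodes=level0,
            assigned_value=1.0,
        )
    )

    while np.isnan(values).any():
        splittable = [c for c in communities if c.size >= 2]
        if not splittable:
            break
        next_communities: list[np.ndarray] = []
        newly_boundary: list[int] = []
        for comm in communities:
            if comm.size < 2:
                next_communities.append(comm)
                continue
            left, right = bisect_community(net, comm, rng)
            next_communities.extend([left, right])
            # boundary within the parent community: positive edges across the cut
            cut = net.weights[np.ix_(left, right)] > 0
            newly_boundary.extend(left[cut.any(axis=1)])
            newly_boundary.extend(right[cut.any(axis=0)])
        new = np.array(
            sorted({i for i in newly_boundary if np.isnan(values[i])}), dtype=int
        )
        if new.size:
            if n_i_convention == "cumulative":
                n_i = int(np.sum(~np.isnan(values)))
            else:
                n_i = len(set(newly_boundary))
            value = (n - n_i) / n
            # keep strict decrease and positivity even in the per-step variant
            prev_min = np.nanmin(values) if np.any(~np.isnan(values)) else 1.0 + 1.0 / n
            value = min(value, prev_min - 1.0 / n)
            value = max(value, 1.0 / n)
            values[new] = value
            hierarchy.levels.append(
                HierarchyLevel(
                    communities=[c.copy() for c in next_communities],
                    boundary_nodes=new,
                    assigned_value=value,
                )
            )
        communities = next_communities

    if np.isnan(values).any():
        leftover = np.flatnonzero(np.isnan(values))
        prev_min = np.nanmin(values) if np.any(~np.isnan(values)) else 1.0 + 1.0 / n
        value = max(prev_min - 1.0 / n, 1.0 / n)
        values[leftover] = value
        hierarchy.levels.append(
            HierarchyLevel(
                communities=[c.copy() for c in communities],
                boundary_nodes=leftover,
                assigned_value=value,
            )
        )

    vec = NodalMetricVector(
        metric_name="boundary_controllability",
        values=values,
        node_ids=list(net.node_ids),
    )
    hierarchy.final_values = vec
    return vec, hierarchy
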