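"""Static nodal metrics on a single-layer connectome.

The participation coefficient of node *i* under a module partition with
modules *s* is

    pc_i = 1 - sum_s (l_si / d_i)^2

where ``l_si`` is the summed edge weight from *i* into module *s* and
``d_i = sum_s l_si`` is the node strength.  A node whose edges all stay
inside one module scores 0; a node spreading its weight evenly over
``N_m`` modules scores the maximum ``1 - 1/N_m``.  Both structural
(nonnegative) and functional (signed correlation) connectomes are fully
weighted, so "number of links" is computed on strengths; negative
functional weights are excluded by default (``mode='positive_only'``)
because a negative affiliation has no meaning in the squared-fraction
form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network_io import Connectome, ModulePartition

__all__ = ["NodalMetricVector", "node_strength", "participation_coefficient"]

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "structural_pc",
    "functional_pc",
    "boundary_controllability",
    "flexibility",
)


@dataclass
class NodalMetricVector:
    """Per-node values of one nodal metric, in connectome node order."""

    metric_name: str
    values: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.node_ids):
            raise ValueError("metric vector length does not match node_ids")

    def __len__(self) -> int:
        return self.values.size


def _included_weights(net: Connectome, mode: str, binarize: bool) -> np.ndarray:
    if mode not in ("all", "positive_only"):
        raise ValueError(f"unknown mode '{mode}'")
    w = net.weights
    if mode == "positive_only":
        w = np.where(w > 0, w, 0.0)
    if binarize:
        w = (w > 0).astype(float)
    return w


def node_strength(
    net: Connectome, mode: str = "all", binarize: bool = False
) -> np.ndarray:
    """Total degree d_i of each node: the row sum of the included weights."""
    return _included_weights(net, mode, binarize).sum(axis=1)


def participation_coefficient(
    net: Connectome,
    partition: ModulePartition,
    mode: str = "positive_only",
    metric_name: str = "structural_pc",
    binarize: bool = False,
) -> NodalMetricVector:
    """Participation coefficient of every node under ``partition``.

    Isolated nodes (zero included strength) are assigned pc = 0 with a
    logged warning instead of raising, so cohort loops never abort on a
    degenerate subject.
    """
    if partition.node_ids != net.node_ids:
        raise ValueError("partition nodes do not match connectome nodes")
    w = _included_weights(net, mode, binarize)
    n, n_mod = net.n_nodes, partition.n_modules
    # l_si: per-node summed weight into each module, via one-hot aggregation
    onehot = np.zeros((n, n_mod))
    onehot[np.arange(n), partition.labels] = 1.0
    l_sm = w @ onehot  # (n_nodes, n_modules)
    d = l_sm.sum(axis=1)
    pc = np.zeros(n)
    ok = d > 0
    if not ok.all():
        isolated = [net.node_ids[i] for i in np.flatnonzero(~ok)]
        logger.warning(
            "participation coefficient undefined for isolated node(s) %s; set to 0",
            isolated,
        )
    frac = l_sm[ok] / d[ok, None]
    pc[ok] = 1.0 - np.einsum("ij,ij->i", frac, frac)
    np.clip(pc, 0.0, 1.0, out=pc)
    return NodalMetricVector(
        metric_name=metric_name, values=pc, node_ids=list(net.node_ids)
    )
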