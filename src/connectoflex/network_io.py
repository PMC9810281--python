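"""Typed I/O layer for connectomes, partitions, time series, covariates and coordinates.

Every file the pipeline touches is delimited text (comma or tab,
auto-detected).  All downstream modules consume only the validated
in-memory objects defined here; node order is defined by the connectome
file and everything else is aligned to it by label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Connectome",
    "ModulePartition",
    "RegionalTimeSeries",
    "SubjectTable",
    "SphereCoords",
    "read_connectome",
    "read_partition",
    "read_timeseries",
    "read_covariates",
    "read_coords",
    "read_metrics",
    "write_connectome",
    "write_timeseries",
    "write_metrics",
    "write_coords",
    "read_config",
]

#: maximum tolerated asymmetry before a matrix is rejected outright
SYMMETRY_TOL = 1e-10


class ValidationError(ValueError):
    """An input file or matrix violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Connectome:
    """A weighted, symmetric, zero-diagonal adjacency matrix with node labels.

    Structural connectomes carry nonnegative streamline-based weights
    (e.g. mean fractional anisotropy); functional connectomes carry signed
    Pearson correlations in [-1, 1] and must set ``signed=True``.
    """

    weights: np.ndarray
    node_ids: list[str]
    signed: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_ids = [str(n) for n in self.node_ids]
        _validate_adjacency(self.weights, self.node_ids, self.signed)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class ModulePartition:
    """Node -> community assignment at one level of the modular hierarchy.

    ``labels`` are contiguous integers 0..n_modules-1 in connectome node
    order.  Level 0 is reserved for the predefined functional systems
    (eight, in the atlas the method was designed around).
    """

    labels: np.ndarray
    node_ids: list[str]
    level: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.node_ids = [str(n) for n in self.node_ids]
        if self.labels.ndim != 1 or self.labels.size != len(self.node_ids):
            raise ValidationError(
                f"partition has {self.labels.size} labels for "
                f"{len(self.node_ids)} nodes"
            )
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(uniq.size)):
            # re-index to a contiguous 0-based label set, preserving order
            remap = {old: new for new, old in enumerate(uniq)}
            self.labels = np.array([remap[l] for l in self.labels])

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)


@dataclass
class RegionalTimeSeries:
    """Regions-by-time BOLD matrix (N x T), arbitrary signal units."""

    x: np.ndarray
    node_ids: list[str] | None = None
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValidationError("time series must be a 2-D regions x time matrix")
        n, t = self.x.shape
        if n < 2 or t < 2:
            raise ValidationError(f"need N, T >= 2; got N={n}, T={t}")
        if not np.all(np.isfinite(self.x)):
            bad = np.argwhere(~np.isfinite(self.x))[0]
            raise ValidationError(
                f"non-finite BOLD value at region {bad[0]}, timepoint {bad[1]}"
            )
        if self.node_ids is None:
            self.node_ids = [str(i) for i in range(n)]
        elif len(self.node_ids) != n:
            raise ValidationError("node_ids length does not match number of regions")

    @property
    def n_regions(self) -> int:
        return self.x.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.x.shape[1]


@dataclass
class SubjectTable:
    """Per-subject covariates (age, sex, motion) plus appended global metrics."""

    table: pd.DataFrame

    REQUIRED = ("subject", "age", "sex", "motion")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"covariate table missing column '{col}'")
        if self.table["subject"].duplicated().any():
            dup = self.table.loc[self.table["subject"].duplicated(), "subject"].iloc[0]
            raise ValidationError(f"duplicate subject id '{dup}'")
        if (self.table["age"] <= 0).any():
            raise ValidationError("ages must be positive")
        if (self.table["motion"] < 0).any():
            raise ValidationError("motion must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SphereCoords:
    """Unit-sphere region coordinates for the spatial-permutation (spin) test.

    Subcortical regions carry ``cortical=False`` and are excluded from
    rotation: the spherical registration only exists for the cortical mantle.
    """

    xyz: np.ndarray
    hemisphere: np.ndarray  # 'L' or 'R' per node
    cortical: np.ndarray  # bool per node
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        self.cortical = np.asarray(self.cortical, dtype=bool)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValidationError("coordinates must be an n x 3 array")
        norms = np.linalg.norm(self.xyz, axis=1)
        bad = np.flatnonzero(np.abs(norms - 1.0) > 1e-8)
        if bad.size:
            raise ValidationError(
                f"coordinate for node index {bad[0]} has norm {norms[bad[0]]:.6g},"
                " expected unit norm"
            )
        if self.node_ids is None:
            self.node_ids = [str(i) for i in range(len(self.xyz))]

    @property
    def n_nodes(self) -> int:
        return self.xyz.shape[0]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return r"\s+"


def _validate_adjacency(w: np.ndarray, node_ids: Sequence[str], signed: bool) -> None:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"matrix is not square: shape {w.shape}")
    if len(node_ids) != w.shape[0]:
        raise ValidationError("node label count does not match matrix size")
    if not np.all(np.isfinite(w)):
        i, j = np.argwhere(~np.isfinite(w))[0]
        raise ValidationError(
            f"non-finite weight at ({node_ids[i]}, {node_ids[j]})"
        )
    asym = np.abs(w - w.T).max() if w.size else 0.0
    if asym > SYMMETRY_TOL:
        i, j = np.unravel_index(np.abs(w - w.T).argmax(), w.shape)
        raise ValidationError(
            f"matrix asymmetric at ({node_ids[i]}, {node_ids[j]}): |w_ij - w_ji| = {asym:.3g}"
        )
    # symmetrize away numerical noise and zero the diagonal in place
    w += w.T
    w *= 0.5
    np.fill_diagonal(w, 0.0)
    if not signed and (w < 0).any():
        i, j = np.argwhere(w < 0)[0]
        raise ValidationError(
            f"negative weight at ({node_ids[i]}, {node_ids[j]}) in an unsigned connectome"
        )
    if signed and (np.abs(w) > 1 + 1e-9).any():
        i, j = np.argwhere(np.abs(w) > 1 + 1e-9)[0]
        raise ValidationError(
            f"correlation weight outside [-1, 1] at ({node_ids[i]}, {node_ids[j]})"
        )


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited numeric matrix, detecting an optional header row."""
    sep = _sniff_delimiter(path)
    head = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = head.iloc[0].map(
        lambda v: isinstance(v, str) and not _is_number(v)
    ).any()
    if has_header:
        df = pd.read_csv(path, sep=sep)
        labels = [str(c) for c in df.columns]
    else:
        df = pd.read_csv(path, sep=sep, header=None)
        labels = None
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return mat, labels


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_connectome(path: str | Path, signed: bool = False) -> Connectome:
    """Read an N x N delimited adjacency matrix, with optional node-label header.

    The matrix must be square, finite and symmetric to within 1e-10
    (residual asymmetry is averaged away); the diagonal is forced to zero.
    With ``signed=False`` any negative entry is an error.
    """
    path = Path(path)
    mat, labels = _read_matrix(path)
    if not np.all(np.isfinite(mat)):
        i, j = np.argwhere(~np.isfinite(mat))[0]
        raise ValidationError(f"NaN/inf entry at row {i}, column {j} of {path}")
    if labels is None:
        labels = [str(i) for i in range(mat.shape[0])]
    return Connectome(weights=mat, node_ids=labels, signed=signed)


def read_partition(path: str | Path, node_ids: Sequence[str]) -> ModulePartition:
    """Read a two-column (node label, module label) file aligned to ``node_ids``."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, names=["node", "module"], dtype=str)
    if df["node"].iloc[0] == "node":  # optional header
        df = df.iloc[1:]
    mapping: dict[str, str] = {}
    for node, module in zip(df["node"], df["module"]):
        node = str(node)
        if node in mapping:
            raise ValidationError(f"duplicate node '{node}' in partition file")
        mapping[node] = str(module)
    node_ids = [str(n) for n in node_ids]
    unknown = set(mapping) - set(node_ids)
    if unknown:
        raise ValidationError(f"partition labels unknown node '{sorted(unknown)[0]}'")
    missing = [n for n in node_ids if n not in mapping]
    if missing:
        raise ValidationError(f"node missing from partition: '{missing[0]}'")
    module_names = sorted(set(mapping.values()))
    idx = {m: i for i, m in enumerate(module_names)}
    labels = np.array([idx[mapping[n]] for n in node_ids])
    return ModulePartition(labels=labels, node_ids=list(node_ids))


def read_timeseries(
    path: str | Path,
    tr_seconds: float = 3.0,
    transposed: bool = False,
) -> RegionalTimeSeries:
    """Read an N x T regional BOLD matrix (regions as rows).

    A time-as-rows file is accepted only with an explicit ``transposed=True``;
    orientation is never guessed from the shape.
    """
    mat, labels = _read_matrix(Path(path))
    if transposed:
        mat = mat.T
    return RegionalTimeSeries(x=mat, node_ids=labels, tr_seconds=tr_seconds)


def read_covariates(path: str | Path) -> SubjectTable:
    """Read a tidy covariate table with header (subject, age, sex, motion, ...)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    df.columns = [str(c).strip() for c in df.columns]
    df["subject"] = df["subject"].astype(str)
    return SubjectTable(table=df)


def read_coords(path: str | Path) -> SphereCoords:
    """Read region sphere coordinates: node, x, y, z [, hemisphere, cortical]."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    hemi = (
        df["hemisphere"].to_numpy()
        if "hemisphere" in df
        else np.where(xyz[:, 0] < 0, "L", "R")
    )
    cortical = (
        df["cortical"].astype(int).to_numpy(dtype=bool)
        if "cortical" in df
        else np.ones(len(df), dtype=bool)
    )
    return SphereCoords(
        xyz=xyz,
        hemisphere=hemi,
        cortical=cortical,
        node_ids=[str(n) for n in df["node"]],
    )


def read_metrics(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_delimiter(path))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_connectome(net: Connectome, path: str | Path) -> None:
    df = pd.DataFrame(net.weights, columns=net.node_ids)
    df.to_csv(path, index=False, float_format="%.12g")


def write_timeseries(ts: RegionalTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.x).to_csv(path, index=False, header=False, float_format="%.12g")


def write_partition(partition: ModulePartition, path: str | Path) -> None:
    pd.DataFrame(
        {"node": partition.node_ids, "module": partition.labels}
    ).to_csv(path, index=False, header=False)


def write_metrics(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy metric table (one row per node or subject, header row)."""
    table.to_csv(path, index=False, float_format="%.12g")


def write_coords(coords: SphereCoords, path: str | Path) -> None:
    pd.DataFrame(
        {
            "node": coords.node_ids,
            "x": coords.xyz[:, 0],
            "y": coords.xyz[:, 1],
            "z": coords.xyz[:, 2],
            "hemisphere": coords.hemisphere,
            "cortical": coords.cortical.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.15g")


def read_config(path: str | Path) -> dict:
    """Read a nestable key-value text config (YAML subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config file must contain a key-value mapping")
    return cfg
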