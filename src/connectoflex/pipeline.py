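"""Cohort-level orchestration: region-wide, subject-wide and developmental tracks.

Per subject, four nodal metrics are computed: structural participation
coefficient, boundary controllability (both from the structural
connectome and the predefined module partition), functional
participation coefficient from the first BOLD window, and multilayer
flexibility over the remaining windows.  Computing the static
functional metric strictly before the dynamic one builds temporal
directionality into the serial mediation model; a sensitivity mode
computes both from all windows instead.

The region-wide track averages nodal maps across subjects and relates
them with Pearson correlations (spin-test p values for within-modality
pairs), VIF checks and an across-region serial mediation with [0, 1]
rescaling.  The subject-wide track works on per-subject global means
with age, sex and motion as covariates, one Benjamini-Hochberg family
over its six pairwise regressions, covariate-adjusted mediation and an
age-moderated mediation.  The developmental track regresses each global
metric on age (sex and motion partialled out), FDR over the four tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boundary_control import boundary_controllability
from .graph_metrics import NodalMetricVector, participation_coefficient
from .inference import (
    adjusted_regression,
    bh_fdr,
    moderated_mediation,
    pearson,
    serial_mediation,
    spin_test,
    vif,
)
from .network_io import (
    Connectome,
    ModulePartition,
    RegionalTimeSeries,
    SphereCoords,
    SubjectTable,
    read_connectome,
    read_coords,
    read_covariates,
    read_partition,
    read_timeseries,
    write_metrics,
)
from .synthetic_data import Cohort
from .temporal_dynamics import (
    ModularityParams,
    build_temporal_network,
    global_flexibility,
    louvain_multilayer,
    nodal_flexibility,
    windowed_participation,
)

__all__ = [
    "AnalysisConfig",
    "compute_subject_metrics",
    "compute_cohort_metrics",
    "region_wide_analysis",
    "subject_wide_analysis",
    "developmental_trajectories",
]

logger = logging.getLogger(__name__)

METRICS = ("structural_pc", "boundary_controllability", "functional_pc", "flexibility")


@dataclass
class AnalysisConfig:
    """All knobs of a pipeline run, echoed into every report."""

    n_windows: int = 10
    gamma: float = 1.0
    omega: float = 1.0
    n_runs: int = 100
    n_boot: int = 10_000
    n_perm: int = 100_000
    fdr_q: float = 0.05
    seed: int = 0
    functional_pc_mode: str = "positive_only"
    n_i_convention: str = "cumulative"
    # temporal split: static functional PC from window 1, flexibility from
    # the rest; "all_windows" uses every window for both (sensitivity mode)
    temporal_split: str = "window1_vs_rest"

    def modularity_params(self, seed_offset: int = 0) -> ModularityParams:
        return ModularityParams(
            gamma=self.gamma,
            omega=self.omega,
            n_runs=self.n_runs,
            seed=self.seed + seed_offset,
        )

    def echo(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# per-subject metric computation
# ---------------------------------------------------------------------------


def compute_subject_metrics(
    net: Connectome,
    ts: RegionalTimeSeries,
    partition: ModulePartition,
    config: AnalysisConfig,
    seed_offset: int = 0,
) -> dict[str, NodalMetricVector]:
    """The four nodal metric vectors for one subject."""
    spc = participation_coefficient(
        net, partition, mode="all", metric_name="structural_pc"
    )
    bc, _ = boundary_controllability(
        net, partition, seed=config.seed + seed_offset,
        n_i_convention=config.n_i_convention,
    )
    tnet = build_temporal_network(ts, n_windows=config.n_windows)
    if config.temporal_split == "window1_vs_rest":
        fpc = windowed_participation(
            tnet, partition, window=1, mode=config.functional_pc_mode
        )
        flex_net = tnet.subnetwork(slice(1, tnet.n_windows))
    elif config.temporal_split == "all_windows":
        fpc = windowed_participation(
            tnet, partition, window=(1, tnet.n_windows),
            mode=config.functional_pc_mode,
        )
        flex_net = tnet
    else:
        raise ValueError(f"unknown temporal_split '{config.temporal_split}'")
    _, runs = louvain_multilayer(
        flex_net, config.modularity_params(seed_offset=seed_offset)
    )
    flex = nodal_flexibility(runs, node_ids=list(net.node_ids))
    return {
        "structural_pc": spc,
        "boundary_controllability": bc,
        "functional_pc": fpc,
        "flexibility": flex,
    }


def _load_cohort(cohort_dir: str | Path) -> Cohort:
    """Read a cohort directory written by the synthetic generator."""
    d = Path(cohort_dir)
    covariates = read_covariates(d / "covariates.csv")
    subjects = list(covariates.table["subject"])
    connectomes, bolds = [], []
    kept = []
    for subj in subjects:
        cpath, bpath = d / f"{subj}_connectome.csv", d / f"{subj}_bold.csv"
        if not cpath.exists() or not bpath.exists():
            logger.warning("subject %s missing a modality; dropped", subj)
            continue
        net = read_connectome(cpath)
        ts = read_timeseries(bpath)
        if ts.n_regions != net.n_nodes:
            raise ValueError(
                f"subject {subj}: {ts.n_regions} BOLD regions vs "
                f"{net.n_nodes} connectome nodes"
            )
        # BOLD files carry no labels; rows follow the connectome node order
        ts.node_ids = list(net.node_ids)
        connectomes.append(net)
        bolds.append(ts)
        kept.append(subj)
    if len(kept) < 2:
        raise ValueError("need at least 2 complete subjects")
    table = covariates.table[covariates.table["subject"].isin(kept)].reset_index(
        drop=True
    )
    partition = read_partition(d / "partition.csv", connectomes[0].node_ids)
    coords_path = d / "coords.csv"
    coords = read_coords(coords_path) if coords_path.exists() else None
    return Cohort(
        covariates=SubjectTable(table=table),
        partition=partition,
        coords=coords,
        connectomes=connectomes,
        bold=bolds,
        latents=pd.DataFrame(),
        spec=None,
    )


def compute_cohort_metrics(
    cohort: Cohort | str | Path, config: AnalysisConfig
) -> tuple[Cohort, dict[str, np.ndarray]]:
    """Per-subject nodal metrics stacked as (n_subjects x n_nodes) arrays."""
    if not isinstance(cohort, Cohort):
        cohort = _load_cohort(cohort)
    stacks: dict[str, list[np.ndarray]] = {m: [] for m in METRICS}
    for s, (net, ts) in enumerate(zip(cohort.connectomes, cohort.bold)):
        vecs = compute_subject_metrics(
            net, ts, cohort.partition, config, seed_offset=1000 + s
        )
        for m in METRICS:
            stacks[m].append(vecs[m].values)
    return cohort, {m: np.vstack(v) for m, v in stacks.items()}


# ---------------------------------------------------------------------------
# analysis tracks
# ---------------------------------------------------------------------------

_PAIRS = [
    ("structural_pc", "boundary_controllability"),
    ("functional_pc", "flexibility"),
    ("structural_pc", "functional_pc"),
    ("structural_pc", "flexibility"),
    ("boundary_controllability", "functional_pc"),
    ("boundary_controllability", "flexibility"),
]

#: within-modality map pairs that get a spin-test p value
_SPIN_PAIRS = _PAIRS[:2]


def region_wide_analysis(
    cohort: Cohort | str | Path,
    config: AnalysisConfig | None = None,
    precomputed: dict[str, np.ndarray] | None = None,
) -> dict:
    """Across-region analysis of subject-averaged nodal maps."""
    config = config or AnalysisConfig()
    if precomputed is None:
        cohort, stacks = compute_cohort_metrics(cohort, config)
    else:
        stacks = precomputed
        if not isinstance(cohort, Cohort):
            cohort = _load_cohort(cohort)
    if len(cohort.connectomes) < 2:
        raise ValueError("region-wide analysis needs >= 2 subjects")
    maps = {m: stacks[m].mean(axis=0) for m in METRICS}

    corr_rows = []
    for a, b in _PAIRS:
        r, p = pearson(maps[a], maps[b])
        row = {"map_a": a, "map_b": b, "r": r, "p": p, "p_spin": np.nan}
        if (a, b) in _SPIN_PAIRS and cohort.coords is not None:
            spin = spin_test(
                maps[a], maps[b], cohort.coords,
                n_perm=config.n_perm, seed=config.seed,
            )
            row["p_spin"] = spin.p_spin
        corr_rows.append(row)

    vif_struct = vif([maps["structural_pc"], maps["boundary_controllability"]])
    vif_func = vif([maps["functional_pc"], maps["flexibility"]])

    mediation = serial_mediation(
        maps["structural_pc"],
        maps["boundary_controllability"],
        maps["functional_pc"],
        maps["flexibility"],
        covariates=None,
        n_boot=config.n_boot,
        seed=config.seed,
        rescale=True,
    )
    return {
        "maps": pd.DataFrame({"node": cohort.partition.node_ids, **maps}),
        "correlations": pd.DataFrame(corr_rows),
        "vif": pd.DataFrame(
            {
                "family": ["structural", "structural", "functional", "functional"],
                "metric": [
                    "structural_pc",
                    "boundary_controllability",
                    "functional_pc",
                    "flexibility",
                ],
                "vif": np.concatenate([vif_struct, vif_func]),
            }
        ),
        "mediation": mediation,
        "config": config.echo(),
    }


def _global_table(cohort: Cohort, stacks: dict[str, np.ndarray]) -> pd.DataFrame:
    table = cohort.covariates.table.copy()
    for m in METRICS:
        table[m] = stacks[m].mean(axis=1)
    return table


def subject_wide_analysis(
    cohort: Cohort | str | Path,
    config: AnalysisConfig | None = None,
    precomputed: dict[str, np.ndarray] | None = None,
) -> dict:
    """Across-subject analysis of global metric means, covariate adjusted."""
    config = config or AnalysisConfig()
    if precomputed is None:
        cohort, stacks = compute_cohort_metrics(cohort, config)
    else:
        stacks = precomputed
        if not isinstance(cohort, Cohort):
            cohort = _load_cohort(cohort)
    table = _global_table(cohort, stacks)
    covs = table[["age", "sex", "motion"]]

    reg_rows = []
    for a, b in _PAIRS:
        res = adjusted_regression(table[b], table[a], covariates=covs)
        reg_rows.append(
            {"x": a, "y": b, "coef": res.coef, "t": res.t, "p": res.p,
             "partial_r": res.partial_r}
        )
    reg = pd.DataFrame(reg_rows)
    reject, p_adj = bh_fdr(reg["p"], q=config.fdr_q)
    reg["p_fdr"], reg["significant"] = p_adj, reject

    mediation = serial_mediation(
        table["structural_pc"],
        table["boundary_controllability"],
        table["functional_pc"],
        table["flexibility"],
        covariates=covs,
        n_boot=config.n_boot,
        seed=config.seed,
        rescale=True,
    )
    modmed = moderated_mediation(
        table["structural_pc"],
        table["boundary_controllability"],
        table["functional_pc"],
        table["flexibility"],
        moderator=table["age"],
        covariates=table[["sex", "motion"]],
        n_boot=config.n_boot,
        seed=config.seed,
        rescale=True,
    )
    return {
        "globals": table,
        "regressions": reg,
        "mediation": mediation,
        "moderated_mediation": modmed,
        "config": config.echo(),
    }


def developmental_trajectories(
    cohort: Cohort | str | Path,
    config: AnalysisConfig | None = None,
    precomputed: dict[str, np.ndarray] | None = None,
) -> dict:
    """Linear age effects on each global metric, sex and motion adjusted."""
    config = config or AnalysisConfig()
    if precomputed is None:
        cohort, stacks = compute_cohort_metrics(cohort, config)
    else:
        stacks = precomputed
        if not isinstance(cohort, Cohort):
            cohort = _load_cohort(cohort)
    table = _global_table(cohort, stacks)
    covs = table[["sex", "motion"]]
    rows = []
    for m in METRICS:
        res = adjusted_regression(table[m], table["age"], covariates=covs)
        rows.append(
            {"metric": m, "age_coef": res.coef, "t": res.t, "p": res.p,
             "partial_r": res.partial_r}
        )
    out = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(out["p"], q=config.fdr_q)
    out["p_fdr"], out["significant"] = p_adj, reject
    return {"age_regressions": out, "globals": table, "config": config.echo()}


def write_report(report: dict, out_dir: str | Path) -> None:
    """Dump every tabular element of a report plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": report.get("config", {})}
    for key, val in report.items():
        if isinstance(val, pd.DataFrame):
            write_metrics(val, out / f"{key}.csv")
        elif hasattr(val, "__dataclass_fields__"):
            manifest[key] = json.loads(
                json.dumps(asdict(val), default=lambda o: np.asarray(o).tolist())
            )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
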