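"""Synthetic cohorts with known ground truth for every pipeline stage.

Three generators emulate the inputs the analysis expects:

* modular weighted connectomes (dense stochastic-block structure with
  truncated-normal edge weights on [0, 1], mimicking fractional
  anisotropy) whose per-node cross-module edge fraction schedule
  controls each node's expected structural participation coefficient;
* windowed block-covariance BOLD series where each node follows its
  planted community's latent signal plus noise, a fraction rho of nodes
  re-draws its community between consecutive windows, and a mixing
  parameter leaks a global signal into every node (raising functional
  participation);
* a cohort in which four subject-level latents follow a serial causal
  chain X -> M1 -> M2 -> Y of configurable path strengths, each latent
  driving the generator knob that dominantly controls the corresponding
  computed metric (cross-module weight -> structural PC; boundary
  breadth -> boundary controllability; window-1 mixing -> functional
  PC; switch rate -> flexibility), with age optionally loading
  negatively on all four.

Everything is bit-reproducible under a master seed and writes only
delimited-text files that re-validate through :mod:`network_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .network_io import (
    Connectome,
    ModulePartition,
    RegionalTimeSeries,
    SphereCoords,
    SubjectTable,
    write_connectome,
    write_coords,
    write_metrics,
    write_partition,
    write_timeseries,
)

__all__ = [
    "CohortSpec",
    "Cohort",
    "gen_modular_connectome",
    "gen_dynamic_bold",
    "gen_sphere_coords",
    "gen_cohort",
]

#: default serial-chain path strengths on the latent (standardized) scale.
#: The chain is deliberately strong: the generator models the hypothesis
#: under test, and desk-scale cohorts (n ~ 50) must carry detectable signal.
DEFAULT_PATHS = {
    "a1": 0.8,   # X -> M1
    "a2": 0.15,  # X -> M2
    "d21": 0.9,  # M1 -> M2
    "b1": 0.15,  # M1 -> Y
    "b2": 0.9,   # M2 -> Y
    "c_prime": 0.1,  # X -> Y direct
}

NULL_PATHS = {k: 0.0 for k in DEFAULT_PATHS}

# latent -> generator-knob response ranges (fixed properties of the cohort
# model, not tuning dials): each knob moves linearly over its range as the
# squashed latent sweeps 0..1.  The breadth range stays above 0.5, where
# mean boundary controllability responds monotonically (below it, the
# shrinking level-0 set is offset by higher deeper-level values).
_CROSS_SCALE_RANGE = (0.15, 0.70)   # global cross-module weight multiplier
_BREADTH_RANGE = (0.50, 0.90)       # fraction of nodes carrying cross edges
_MIXING_RANGE = (0.00, 0.45)        # window-1 global-signal leak
_RHO_RANGE = (0.05, 0.55)           # per-transition community switch rate


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults are desk-scale: 50 subjects, 60 nodes in 8 modules,
    T = 120 TRs in 10 windows — every stage runs on one CPU in minutes
    while keeping the statistical structure of the full-size design.
    """

    n_subjects: int = 50
    n_nodes: int = 60
    n_modules: int = 8
    t_len: int = 360
    n_windows: int = 10
    within_mean: float = 0.5
    within_sd: float = 0.1
    between_mean: float = 0.3
    between_sd: float = 0.1
    noise_sd: float = 0.5
    rho: float = 0.2
    cross_fraction_lo: float = 0.02
    cross_fraction_hi: float = 1.0
    paths: dict = field(default_factory=lambda: dict(DEFAULT_PATHS))
    latent_noise_sd: float = 0.8
    age_lo: float = 8.0
    age_hi: float = 22.0
    age_slope: float = -0.2
    n_subcortical: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_nodes < 2 or self.n_modules < 2:
            raise ValueError("all counts must be >= 2")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        for name in ("within_sd", "between_sd", "noise_sd", "latent_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Cohort:
    """In-memory cohort: covariates, latents, and per-subject raw data."""

    covariates: SubjectTable
    partition: ModulePartition
    coords: SphereCoords
    connectomes: list[Connectome]
    bold: list[RegionalTimeSeries]
    latents: pd.DataFrame
    spec: CohortSpec


def _truncnorm(rng, mean, sd, size, lo=0.0, hi=1.0):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _module_labels(n_nodes: int, n_modules: int) -> np.ndarray:
    return np.arange(n_nodes) % n_modules


def gen_modular_connectome(
    spec: CohortSpec,
    subject_seed: int,
    cross_fractions: np.ndarray | None = None,
) -> tuple[Connectome, ModulePartition]:
    """Weighted stochastic-block connectome with planted participation.

    ``cross_fractions`` (one value in [0, 1] per node) scales each
    node's expected cross-module weight: an all-zero schedule yields a
    purely block-diagonal network (structural PC identically 0), and an
    increasing schedule yields monotonically increasing PC.  When
    omitted, a geometric schedule over ``[cross_fraction_lo,
    cross_fraction_hi]`` is used: most nodes carry little cross-module
    weight, a few carry a lot, so participation is heterogeneous.
    """
    rng = np.random.default_rng(subject_seed)
    n, n_mod = spec.n_nodes, spec.n_modules
    labels = _module_labels(n, n_mod)
    if cross_fractions is None:
        cross_fractions = np.geomspace(spec.cross_fraction_lo, spec.cross_fraction_hi, n)
    f = np.asarray(cross_fractions, dtype=float)
    if f.size != n or (f < 0).any() or (f > 1).any():
        raise ValueError("cross_fractions must be n_nodes values in [0, 1]")

    w = np.zeros((n, n))
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    within_mask = same[iu]
    n_within = int(within_mask.sum())
    n_between = iu[0].size - n_within
    w_upper = np.zeros(iu[0].size)
    w_upper[within_mask] = _truncnorm(rng, spec.within_mean, spec.within_sd, n_within)
    between_base = _truncnorm(rng, spec.between_mean, spec.between_sd, n_between)
    # multiplicative coupling: a node with f_i = 0 has exactly zero
    # cross-module strength regardless of its partners, and a node with
    # tiny f_i keeps near-zero participation while still counting as a
    # boundary node (any positive cross edge)
    fi, fj = f[iu[0][~within_mask]], f[iu[1][~within_mask]]
    w_upper[~within_mask] = between_base * fi * fj
    w[iu] = w_upper
    w += w.T
    net = Connectome(weights=w, node_ids=[f"r{i}" for i in range(n)], signed=False)
    part = ModulePartition(labels=labels, node_ids=list(net.node_ids))
    return net, part


def gen_dynamic_bold(
    spec: CohortSpec,
    subject_seed: int,
    rho: float | np.ndarray | None = None,
    mixing: float | np.ndarray = 0.0,
    partition: ModulePartition | None = None,
    mixing_windows: str = "all",
) -> tuple[RegionalTimeSeries, np.ndarray]:
    """Windowed block-covariance BOLD with planted community switching.

    Within each window every node follows its planted community's latent
    signal plus independent Gaussian noise (sd ``noise_sd``); with
    probability ``rho`` (scalar or per-node) a node re-draws its
    community at each window transition.  ``mixing`` in [0, 1) leaks a
    network-wide shared signal into every node, raising cross-module
    correlation uniformly.  Returns the series and the planted label
    matrix (n_nodes x n_windows) as ground truth.
    """
    rng = np.random.default_rng(subject_seed)
    n, t_len, n_win = spec.n_nodes, spec.t_len, spec.n_windows
    wlen = t_len // n_win
    if wlen < 2:
        raise ValueError("window too short for the requested T and window count")
    rho_vec = np.full(n, spec.rho if rho is None else rho, dtype=float) \
        if np.isscalar(rho) or rho is None else np.asarray(rho, dtype=float)
    if ((rho_vec < 0) | (rho_vec > 1)).any():
        raise ValueError("rho must lie in [0, 1]")
    labels0 = partition.labels if partition is not None else _module_labels(n, spec.n_modules)
    n_mod = int(labels0.max()) + 1

    planted = np.empty((n, n_win), dtype=int)
    planted[:, 0] = labels0
    for t in range(1, n_win):
        switch = rng.random(n) < rho_vec
        planted[:, t] = planted[:, t - 1]
        if switch.any():
            # re-draw uniformly among the *other* communities
            new = rng.integers(0, n_mod - 1, int(switch.sum()))
            old = planted[switch, t - 1]
            new = np.where(new >= old, new + 1, new)
            planted[switch, t] = new

    if mixing_windows not in ("all", "first"):
        raise ValueError("mixing_windows must be 'all' or 'first'")
    mix_vec = np.clip(np.broadcast_to(np.asarray(mixing, dtype=float), n), 0.0, 0.95)
    zero_mix = np.zeros(n)
    x = np.empty((n, t_len))
    for t in range(n_win):
        mix_t = mix_vec if (mixing_windows == "all" or t == 0) else zero_mix
        amp_comm = np.sqrt(1.0 - mix_t)
        amp_glob = np.sqrt(mix_t)
        z = rng.standard_normal((n_mod, wlen))
        shared = rng.standard_normal(wlen)
        sl = slice(t * wlen, (t + 1) * wlen)
        x[:, sl] = (
            amp_comm[:, None] * z[planted[:, t]]
            + amp_glob[:, None] * shared
            + spec.noise_sd * rng.standard_normal((n, wlen))
        )
    rem = t_len - n_win * wlen
    if rem:  # trailing TRs continue the last window's planted structure
        mix_t = mix_vec if mixing_windows == "all" else zero_mix
        z = rng.standard_normal((n_mod, rem))
        x[:, n_win * wlen :] = (
            np.sqrt(1.0 - mix_t)[:, None] * z[planted[:, -1]]
            + np.sqrt(mix_t)[:, None] * rng.standard_normal(rem)
            + spec.noise_sd * rng.standard_normal((n, rem))
        )
    ts = RegionalTimeSeries(x=x, node_ids=[f"r{i}" for i in range(n)])
    return ts, planted


def gen_sphere_coords(
    n_nodes: int, n_subcortical: int = 0, seed: int = 0
) -> SphereCoords:
    """Quasi-uniform spherical coordinates, one full sphere per hemisphere.

    Following the surface-registration convention, each hemisphere's
    cortical mantle is inflated to its own complete unit sphere, so a
    rotation maps a hemisphere's point set onto itself.  Nodes are placed
    on a Fibonacci lattice with a small seeded jitter; the right
    hemisphere is the x-mirror of an independent lattice.  The last
    ``n_subcortical`` nodes are flagged non-cortical (they still carry
    unit vectors but never enter the spin test).
    """
    if n_nodes < 4:
        raise ValueError("need at least 4 nodes")
    rng = np.random.default_rng(seed)
    n_cort = n_nodes - n_subcortical
    n_left = (n_cort + 1) // 2
    xyz = np.empty((n_nodes, 3))
    hemi = np.empty(n_nodes, dtype="<U1")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for h, (count, offset) in enumerate(((n_left, 0), (n_cort - n_left, n_left))):
        i = np.arange(count)
        z = (i + 0.5) / count * 2 - 1
        theta = golden * i + h * 0.5  # offset so the lattices differ
        r_xy = np.sqrt(1 - z**2)
        pts = np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
        pts += 0.02 * rng.standard_normal(pts.shape)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        if h == 1:
            pts[:, 0] *= -1
        xyz[offset : offset + count] = pts
        hemi[offset : offset + count] = "L" if h == 0 else "R"
    if n_subcortical:
        sub = rng.standard_normal((n_subcortical, 3))
        sub /= np.linalg.norm(sub, axis=1, keepdims=True)
        xyz[n_cort:] = sub
        hemi[n_cort:] = np.where(sub[:, 0] < 0, "L", "R")
    cortical = np.ones(n_nodes, dtype=bool)
    cortical[n_cort:] = False
    return SphereCoords(
        xyz=xyz,
        hemisphere=hemi,
        cortical=cortical,
        node_ids=[f"r{i}" for i in range(n_nodes)],
    )


def _squash(v: np.ndarray) -> np.ndarray:
    """Latent -> (0, 1): Gaussian CDF of the standardized value.

    Standardizing inside the cohort makes every knob sweep its full
    response range (approximately uniformly) whatever the chain's path
    strengths, so no link is starved of dynamic range."""
    return stats.norm.cdf((v - v.mean()) / v.std())


def _knob(latent01: float, lo: float, hi: float) -> float:
    return lo + (hi - lo) * latent01


def gen_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> Cohort:
    """Generate a full cohort with a planted X -> M1 -> M2 -> Y chain.

    Per subject, standardized latents follow the serial chain with path
    strengths ``spec.paths`` plus Gaussian disturbances of sd
    ``spec.latent_noise_sd``; standardized age additionally loads on all
    four latents with weight ``spec.age_slope`` (negative by default,
    emulating developmental decline).  Each latent then sets the
    generator knob that dominantly controls the corresponding computed
    metric.  With all paths zero and ``age_slope = 0`` the four knobs
    vary independently across subjects.

    When ``out_dir`` is given, every file is also written in the
    delimited-text formats of :mod:`network_io`.
    """
    rng = np.random.default_rng(spec.seed)
    p = {**NULL_PATHS, **spec.paths}
    ns = spec.n_subjects
    age = rng.uniform(spec.age_lo, spec.age_hi, ns)
    age_z = (age - age.mean()) / age.std()
    sex = rng.integers(0, 2, ns)
    motion = np.abs(rng.normal(0.1, 0.05, ns)) + 0.01

    e = spec.latent_noise_sd * rng.standard_normal((4, ns))
    lat_x = rng.standard_normal(ns) + spec.age_slope * age_z
    lat_m1 = p["a1"] * lat_x + spec.age_slope * age_z + e[0]
    lat_m2 = p["a2"] * lat_x + p["d21"] * lat_m1 + spec.age_slope * age_z + e[1]
    lat_y = (
        p["c_prime"] * lat_x
        + p["b1"] * lat_m1
        + p["b2"] * lat_m2
        + spec.age_slope * age_z
        + e[2]
    )

    x01, m101, m201, y01 = (_squash(v) for v in (lat_x, lat_m1, lat_m2, lat_y))
    schedule = np.geomspace(spec.cross_fraction_lo, spec.cross_fraction_hi, spec.n_nodes)
    # nodal profiles for the functional knobs follow their own serial
    # chain seeded by the structural schedule rank: participation profile =
    # noisy function of the rank, switching profile = noisy function of the
    # participation profile.  The independent nodal disturbances make the
    # regional cascade identifiable instead of collapsing all four maps
    # onto one deterministic driver.
    ranks = np.argsort(np.argsort(schedule)) / max(spec.n_nodes - 1, 1)
    prof_rng = np.random.default_rng(spec.seed + 7)
    rank_z = (ranks - ranks.mean()) / ranks.std()
    m2n = 0.8 * rank_z + 0.6 * prof_rng.standard_normal(spec.n_nodes)
    yn = 0.8 * (m2n - m2n.mean()) / m2n.std() + 0.6 * prof_rng.standard_normal(
        spec.n_nodes
    )
    mix_profile = 0.4 + 1.2 * np.argsort(np.argsort(m2n)) / max(spec.n_nodes - 1, 1)
    rho_profile = 0.4 + 1.2 * np.argsort(np.argsort(yn)) / max(spec.n_nodes - 1, 1)
    sub_seeds = np.random.SeedSequence(spec.seed).spawn(ns)

    connectomes: list[Connectome] = []
    bolds: list[RegionalTimeSeries] = []
    partition: ModulePartition | None = None
    for s in range(ns):
        srng = np.random.default_rng(sub_seeds[s])
        s1, s2 = int(srng.integers(0, 2**31 - 1)), int(srng.integers(0, 2**31 - 1))
        cross_scale = _knob(x01[s], *_CROSS_SCALE_RANGE)
        breadth = _knob(m101[s], *_BREADTH_RANGE)
        mixing = _knob(m201[s], *_MIXING_RANGE)
        rho = _knob(y01[s], *_RHO_RANGE)

        fractions = schedule * cross_scale
        # boundary breadth: the lowest-schedule nodes lose their cross edges
        # entirely, shrinking the level-0 boundary set without touching the
        # modular layout
        n_zero = int(round((1.0 - breadth) * spec.n_nodes))
        fractions = fractions.copy()
        if n_zero:
            fractions[np.argsort(schedule)[:n_zero]] = 0.0
        net, part = gen_modular_connectome(spec, s1, cross_fractions=fractions)
        # the functional knobs carry a nodal profile tied to the structural
        # schedule, planting the regional cascade (nodes with more
        # cross-module structure participate more and switch more); mixing
        # is planted only in the first window — the one the static
        # functional metric is read from — so it cannot disturb the
        # switching signal in the remaining windows
        ts, _ = gen_dynamic_bold(
            spec, s2, rho=np.clip(rho * rho_profile, 0.0, 1.0),
            mixing=mixing * mix_profile,
            partition=part, mixing_windows="first",
        )
        connectomes.append(net)
        bolds.append(ts)
        partition = part

    coords = gen_sphere_coords(spec.n_nodes, spec.n_subcortical, seed=spec.seed + 1)
    subjects = [f"sub-{s:03d}" for s in range(ns)]
    cov_df = pd.DataFrame(
        {"subject": subjects, "age": age, "sex": sex, "motion": motion}
    )
    lat_df = pd.DataFrame(
        {
            "subject": subjects,
            "lat_x": lat_x,
            "lat_m1": lat_m1,
            "lat_m2": lat_m2,
            "lat_y": lat_y,
        }
    )
    cohort = Cohort(
        covariates=SubjectTable(table=cov_df),
        partition=partition,
        coords=coords,
        connectomes=connectomes,
        bold=bolds,
        latents=lat_df,
        spec=spec,
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_partition(cohort.partition, out_dir / "partition.csv")
    write_coords(cohort.coords, out_dir / "coords.csv")
    write_metrics(cohort.covariates.table, out_dir / "covariates.csv")
    write_metrics(cohort.latents, out_dir / "latents.csv")
    for s, subj in enumerate(cohort.covariates.table["subject"]):
        write_connectome(cohort.connectomes[s], out_dir / f"{subj}_connectome.csv")
        write_timeseries(cohort.bold[s], out_dir / f"{subj}_bold.csv")
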