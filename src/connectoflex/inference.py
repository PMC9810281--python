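"""Statistical layer: correlations, spin tests, VIF, adjusted regression,
FDR, and bootstrap serial / moderated mediation.

The serial mediation model chains an exposure X through two ordered
mediators to an outcome Y with ordinary least squares:

    M1 = i1 + a1*X            (+ covariates)
    M2 = i2 + a2*X + d21*M1   (+ covariates)
    Y  = i3 + c'*X + b1*M1 + b2*M2  (+ covariates)

yielding indirect effects a1*b1, a2*b2 and the serial product
a1*d21*b2; their sum plus the direct effect c' equals the total effect
c from Y ~ X exactly (nested OLS identity).  Uncertainty comes from
percentile bootstrap over case resamples; an indirect effect is deemed
significant when its bootstrap interval excludes zero.

The spin test builds a spatial-autocorrelation-preserving null for the
correlation of two cortical surface maps by rotating one map's spherical
coordinates (mirrored rotation across hemispheres) and re-assigning
values by nearest rotated neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .graph_metrics import NodalMetricVector
from .network_io import SphereCoords

__all__ = [
    "RegressionResult",
    "MediationResult",
    "ModeratedMediationResult",
    "SpinTestResult",
    "pearson",
    "spin_test",
    "vif",
    "adjusted_regression",
    "bh_fdr",
    "rescale_unit",
    "serial_mediation",
    "moderated_mediation",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    coef: float
    se: float
    t: float
    p: float
    partial_r: float
    n: int
    all_coefs: dict[str, float] = field(default_factory=dict)


@dataclass
class MediationResult:
    a1: float
    a2: float
    d21: float
    b1: float
    b2: float
    c_total: float
    c_prime: float
    indirect_m1: float          # X -> M1 -> Y
    indirect_m2: float          # X -> M2 -> Y
    indirect_serial: float      # X -> M1 -> M2 -> Y
    indirect_total: float
    ci: dict[str, tuple[float, float]]
    p_total: float
    p_direct: float
    n: int
    n_boot: int
    seed: int

    def significant(self, effect: str = "indirect_serial") -> bool:
        lo, hi = self.ci[effect]
        return lo > 0 or hi < 0


@dataclass
class ModeratedMediationResult:
    moderator_mean: float
    moderator_sd: float
    effect_low: float           # conditional serial indirect at mean - 1 SD
    effect_high: float          # conditional serial indirect at mean + 1 SD
    ci_low: tuple[float, float]
    ci_high: tuple[float, float]
    n: int
    n_boot: int


@dataclass
class SpinTestResult:
    r_obs: float
    p_spin: float
    n_perm: int
    null_r: np.ndarray
    n_cortical: int


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def _as_values(v) -> np.ndarray:
    if isinstance(v, NodalMetricVector):
        return v.values
    return np.asarray(v, dtype=float)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-based p value."""
    x, y = _as_values(x), _as_values(y)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input to correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def rescale_unit(values) -> np.ndarray:
    """Affine rescale to [0, 1]: (v - min) / (max - min)."""
    v = _as_values(values)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant vector to [0, 1]")
    return (v - lo) / (hi - lo)


def vif(predictors) -> np.ndarray:
    """Variance inflation factor per predictor (columns or list of vectors).

    VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others
    with an intercept.  Perfect collinearity yields inf, never a crash.
    """
    if isinstance(predictors, (list, tuple)):
        x = np.column_stack([_as_values(p) for p in predictors])
    else:
        x = np.asarray(predictors, dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("VIF needs at least two predictors")
    if n <= k:
        raise ValueError("need more observations than predictors")
    out = np.empty(k)
    for j in range(k):
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        y = x[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p values)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def adjusted_regression(y, x, covariates=None) -> RegressionResult:
    """OLS of y on (intercept, x, covariates); reports x's coefficient,
    t, p and the partial correlation of y with x given the covariates."""
    y, x = _as_values(y), _as_values(x)
    cov = _covariate_matrix(covariates, y.size)
    n = y.size
    design = np.column_stack([np.ones(n), x] + ([cov] if cov is not None else []))
    p_dim = design.shape[1]
    if n <= p_dim + 1:
        raise ValueError("too few observations for the requested model")
    if np.linalg.matrix_rank(design) < p_dim:
        raise ValueError("rank-deficient design matrix")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - p_dim
    sigma2 = resid @ resid / dof
    y_var = y.var() if y.var() > 0 else 1.0
    if sigma2 <= 1e-14 * y_var:
        # exact fit: the t statistic is 0/0 noise; decide by whether x
        # itself carries the (perfectly explained) signal
        contributes = abs(beta[1]) * x.std() > 1e-7 * np.sqrt(y_var)
        se = 0.0
        if contributes:
            t_val, p_val, partial = np.inf * np.sign(beta[1]), 0.0, np.sign(beta[1])
        else:
            t_val, p_val, partial = 0.0, 1.0, 0.0
    else:
        cov_beta = sigma2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(cov_beta[1, 1])
        t_val = beta[1] / se
        p_val = 2 * stats.t.sf(abs(t_val), dof)
        partial = t_val / np.sqrt(t_val**2 + dof)
    return RegressionResult(
        coef=float(beta[1]),
        se=float(se),
        t=float(t_val),
        p=float(p_val),
        partial_r=float(partial),
        n=n,
        all_coefs={f"b{j}": float(b) for j, b in enumerate(beta)},
    )


def _covariate_matrix(covariates, n: int) -> np.ndarray | None:
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        cov = covariates.to_numpy(dtype=float)
    elif isinstance(covariates, (list, tuple)):
        cov = np.column_stack([_as_values(c) for c in covariates])
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError("covariate length does not match data")
    return cov


# ---------------------------------------------------------------------------
# spin test
# ---------------------------------------------------------------------------


def _random_rotations(rng: np.random.Generator, k: int) -> np.ndarray:
    """k Haar-uniform rotation matrices via QR of Gaussian matrices."""
    g = rng.standard_normal((k, 3, 3))
    qs = np.empty_like(g)
    for i in range(k):
        q, r = np.linalg.qr(g[i])
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, [0, 1]] = q[:, [1, 0]]
        qs[i] = q
    return qs


def _match_rotation(sim: np.ndarray) -> np.ndarray:
    """Optimal one-to-one matching maximizing total cosine similarity."""
    _, cols = linear_sum_assignment(sim, maximize=True)
    return cols


def spin_test(
    map_a,
    map_b,
    coords: SphereCoords,
    n_perm: int = 100_000,
    seed: int = 0,
) -> SpinTestResult:
    """Spatial-permutation p value for the correlation of two cortical maps.

    Each permutation draws one uniform rotation, applies it to the left
    hemisphere and its x-mirror to the right, re-assigns ``map_a`` by
    nearest rotated neighbour within hemisphere, and correlates with
    ``map_b``.  Non-cortical nodes never enter.  Two-tailed on |r| with
    the +1 permutation correction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a, b = _as_values(map_a), _as_values(map_b)
    if a.size != coords.n_nodes or b.size != coords.n_nodes:
        raise ValueError("map length does not match coordinate count")
    cort = coords.cortical
    if cort.sum() < 3:
        raise ValueError("need at least 3 cortical nodes")
    a_c, b_c = a[cort], b[cort]
    xyz = coords.xyz[cort]
    hemi = coords.hemisphere[cort]
    left = hemi == "L"
    mirror = np.diag([-1.0, 1.0, 1.0])

    r_obs, _ = pearson(a_c, b_c)
    rng = np.random.default_rng(seed)
    null_r = np.empty(n_perm)
    hemis = [np.flatnonzero(left), np.flatnonzero(~left)]
    batch = 2048
    done = 0
    b_centered = b_c - b_c.mean()
    b_norm = np.sqrt(b_centered @ b_centered)
    while done < n_perm:
        k = min(batch, n_perm - done)
        rots = _random_rotations(rng, k)
        for r_i in range(k):
            rot = rots[r_i]
            a_perm = np.empty_like(a_c)
            for h_idx, idx in enumerate(hemis):
                if idx.size == 0:
                    continue
                r_h = rot if h_idx == 0 else mirror @ rot @ mirror
                rotated = xyz[idx] @ r_h.T
                # one-to-one assignment by greedy max cosine similarity: a
                # true permutation of the map, so its variance is preserved
                # under the null (many-to-one nearest-neighbour mapping
                # shrinks it and makes the test anticonservative)
                sim = xyz[idx] @ rotated.T
                perm = _match_rotation(sim)
                a_perm[idx] = a_c[idx][perm]
            ac = a_perm - a_perm.mean()
            denom = np.sqrt(ac @ ac) * b_norm
            null_r[done + r_i] = (ac @ b_centered) / denom if denom > 0 else 0.0
        done += k
    p_spin = (1 + np.sum(np.abs(null_r) >= abs(r_obs))) / (1 + n_perm)
    return SpinTestResult(
        r_obs=float(r_obs),
        p_spin=float(p_spin),
        n_perm=n_perm,
        null_r=null_r,
        n_cortical=int(cort.sum()),
    )


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


def _ols_beta(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design matrix in mediation model")
    return beta


def _ols_p(design: np.ndarray, y: np.ndarray, col: int) -> float:
    n, p_dim = design.shape
    beta = _ols_beta(design, y)
    resid = y - design @ beta
    dof = n - p_dim
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.linalg.inv(design.T @ design)[col, col])
    if se == 0:
        return 0.0
    return float(2 * stats.t.sf(abs(beta[col] / se), dof))


def _serial_paths(
    x: np.ndarray,
    m1: np.ndarray,
    m2: np.ndarray,
    y: np.ndarray,
    cov: np.ndarray | None,
) -> np.ndarray:
    """(a1, a2, d21, b1, b2, c', c) from the four OLS equations."""
    n = x.size
    one = np.ones(n)
    extra = [cov] if cov is not None else []
    b_m1 = _ols_beta(np.column_stack([one, x] + extra), m1)
    b_m2 = _ols_beta(np.column_stack([one, x, m1] + extra), m2)
    b_y = _ols_beta(np.column_stack([one, x, m1, m2] + extra), y)
    b_tot = _ols_beta(np.column_stack([one, x] + extra), y)
    return np.array([b_m1[1], b_m2[1], b_m2[2], b_y[2], b_y[3], b_y[1], b_tot[1]])


def _boot_stats(paths: np.ndarray) -> np.ndarray:
    """(ind_m1, ind_m2, ind_serial, ind_total, direct, total) from paths."""
    a1, a2, d21, b1, b2, c_prime, c = paths
    ind = np.array([a1 * b1, a2 * b2, a1 * d21 * b2])
    return np.concatenate([ind, [ind.sum(), c_prime, c]])


def serial_mediation(
    x,
    m1,
    m2,
    y,
    covariates=None,
    n_boot: int = 10_000,
    seed: int = 0,
    rescale: bool = False,
) -> MediationResult:
    """Two-mediator serial mediation with percentile bootstrap CIs.

    ``rescale=True`` maps X, M1, M2 and Y to [0, 1] first (covariates
    are never rescaled).  Bootstrap resamples cases (rows) with
    replacement ``n_boot`` times under a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    x, m1, m2, y = (_as_values(v) for v in (x, m1, m2, y))
    n = x.size
    if not (m1.size == m2.size == y.size == n):
        raise ValueError("all mediation variables must have equal length")
    cov = _covariate_matrix(covariates, n)
    if rescale:
        x, m1, m2, y = (rescale_unit(v) for v in (x, m1, m2, y))

    paths = _serial_paths(x, m1, m2, y, cov)
    ind = _boot_stats(paths)

    one = np.ones(n)
    extra = [cov] if cov is not None else []
    p_total = _ols_p(np.column_stack([one, x] + extra), y, 1)
    p_direct = _ols_p(np.column_stack([one, x, m1, m2] + extra), y, 1)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 6))
    data = np.column_stack([x, m1, m2, y] + extra)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        d = data[idx]
        cov_b = d[:, 4:] if cov is not None else None
        try:
            bp = _serial_paths(d[:, 0], d[:, 1], d[:, 2], d[:, 3], cov_b)
        except ValueError:  # degenerate resample
            boot[i] = np.nan
            continue
        boot[i] = _boot_stats(bp)
    names = [
        "indirect_m1",
        "indirect_m2",
        "indirect_serial",
        "indirect_total",
        "direct",
        "total",
    ]
    ci = {
        name: tuple(np.nanpercentile(boot[:, j], [2.5, 97.5]))
        for j, name in enumerate(names)
    }
    a1, a2, d21, b1, b2, c_prime, c = paths
    return MediationResult(
        a1=float(a1), a2=float(a2), d21=float(d21), b1=float(b1), b2=float(b2),
        c_total=float(c), c_prime=float(c_prime),
        indirect_m1=float(ind[0]), indirect_m2=float(ind[1]),
        indirect_serial=float(ind[2]), indirect_total=float(ind[3]),
        ci=ci, p_total=p_total, p_direct=p_direct,
        n=n, n_boot=n_boot, seed=seed,
    )


def _conditional_serial(
    x, m1, m2, y, w, cov, w_values: np.ndarray
) -> np.ndarray:
    """Conditional serial indirect (a1 + a1w*w)*d21*(b2 + 0*w) at each w.

    The moderator interacts with X on every X-originating path (a1, a2,
    c'); mediator-to-mediator and mediator-to-outcome paths are not
    X-paths and stay unmoderated.
    """
    n = x.size
    one = np.ones(n)
    xw = x * w
    extra = [w[:, None]] + ([cov] if cov is not None else [])
    b_m1 = _ols_beta(np.column_stack([one, x, xw] + extra), m1)
    b_m2 = _ols_beta(np.column_stack([one, x, xw, m1] + extra), m2)
    b_y = _ols_beta(np.column_stack([one, x, xw, m1, m2] + extra), y)
    a1, a1w = b_m1[1], b_m1[2]
    d21 = b_m2[3]
    b2 = b_y[4]
    return (a1 + a1w * w_values) * d21 * b2


def moderated_mediation(
    x,
    m1,
    m2,
    y,
    moderator,
    covariates=None,
    n_boot: int = 10_000,
    seed: int = 0,
    rescale: bool = False,
) -> ModeratedMediationResult:
    """Serial mediation moderated by ``moderator`` on every X path.

    Reports the conditional serial indirect effect and its percentile
    bootstrap CI at moderator mean - 1 SD and mean + 1 SD.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    x, m1, m2, y = (_as_values(v) for v in (x, m1, m2, y))
    w = _as_values(moderator)
    if w.std() == 0:
        raise ValueError("moderator has zero variance")
    n = x.size
    cov = _covariate_matrix(covariates, n)
    if rescale:
        x, m1, m2, y = (rescale_unit(v) for v in (x, m1, m2, y))
    w_mean, w_sd = w.mean(), w.std(ddof=1)
    wc = w - w_mean
    probe = np.array([-w_sd, w_sd])

    point = _conditional_serial(x, m1, m2, y, wc, cov, probe)
    rng = np.random.default_rng(seed)
    data = np.column_stack([x, m1, m2, y, wc] + ([cov] if cov is not None else []))
    boot = np.empty((n_boot, 2))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        d = data[idx]
        cov_b = d[:, 5:] if cov is not None else None
        try:
            boot[i] = _conditional_serial(
                d[:, 0], d[:, 1], d[:, 2], d[:, 3], d[:, 4], cov_b, probe
            )
        except ValueError:
            boot[i] = np.nan
    ci_low = tuple(np.nanpercentile(boot[:, 0], [2.5, 97.5]))
    ci_high = tuple(np.nanpercentile(boot[:, 1], [2.5, 97.5]))
    return ModeratedMediationResult(
        moderator_mean=float(w_mean),
        moderator_sd=float(w_sd),
        effect_low=float(point[0]),
        effect_high=float(point[1]),
        ci_low=ci_low,
        ci_high=ci_high,
        n=n,
        n_boot=n_boot,
    )
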