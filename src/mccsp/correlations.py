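"""Six pairwise dependence estimators used as between-node connection strengths.

A chain pathway SNP -> gene expression ... -> disease is scored by the product
of between-node "correlations" r_ij.  This module provides the six candidate
estimators of r_ij — Pearson, Spearman, distance correlation, kernel-density
mutual information, the maximal information coefficient (MIC) and the maximal
correlation coefficient (MCC, estimated by alternating conditional
expectations) — plus :func:`edge_strength`, the uniform nonnegative dispatch
used by the network layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from ._mine import approx_mic
from .exceptions import DegenerateInputError

__all__ = [
    "DependenceMethod",
    "METHOD_NAMES",
    "KDEConfig",
    "ACEConfig",
    "pearson",
    "spearman",
    "distance_correlation",
    "mutual_information",
    "mic",
    "ace_transform",
    "mcc",
    "edge_strength",
]


class DependenceMethod(str, Enum):
    """The six between-node dependence measures."""

    PEARSON = "pearson"
    SPEARMAN = "spearman"
    DISTANCE = "distance"
    MI = "mi"
    MIC = "mic"
    MCC = "mcc"


METHOD_NAMES = tuple(m.value for m in DependenceMethod)


@dataclass(frozen=True)
class KDEConfig:
    """Bandwidth rules for the kernel-density mutual-information estimator.

    Both the 1-D marginals and the 2-D joint density use Gaussian kernels.
    The joint bandwidth matrix H is diagonal with the squared per-margin
    bandwidths; ``silverman`` means 0.9 * min(sd, IQR/1.34) * n**(-1/5).
    """

    bandwidth_rule_1d: str = "silverman"
    bandwidth_matrix_rule_2d: str = "silverman-diagonal"


@dataclass(frozen=True)
class ACEConfig:
    """Controls for the alternating-conditional-expectations backfit.

    smoother
        ``local-linear``: nearest-neighbour local linear regression with
        window fraction ``span`` for continuous variables; variables with at
        most ``discrete_threshold`` distinct values use exact per-level
        conditional means (handles 0/1 genotype and disease nodes).
    tolerance
        stop when the change in E[(theta - phi)^2] between sweeps falls
        below this.
    """

    max_iterations: int = 100
    tolerance: float = 1e-6
    smoother: str = "local-linear"
    span: float = 0.5
    discrete_threshold: int = 10

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")


def _as_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape[0] != y.shape[0]:
        raise DegenerateInputError(
            f"paired sample lengths differ: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < min_n:
        raise DegenerateInputError(f"need at least {min_n} observations, got {x.shape[0]}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateInputError("paired sample contains missing or non-finite values")
    return x, y


def _require_variation(v: np.ndarray, name: str) -> None:
    if v.min() == v.max():
        raise DegenerateInputError(f"vector '{name}' is constant (zero variance)")


def pearson(x, y) -> float:
    """Pearson product-moment correlation, in [-1, 1]."""
    x, y = _as_pair(x, y)
    _require_variation(x, "x")
    _require_variation(y, "y")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    return float(np.clip(r, -1.0, 1.0))


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties), in [-1, 1]."""
    x, y = _as_pair(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    _require_variation(rx, "rank(x)")
    _require_variation(ry, "rank(y)")
    return pearson(rx, ry)


def _double_centered_abs_diff(v: np.ndarray) -> np.ndarray:
    a = np.abs(v[:, None] - v[None, :])
    return a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()


def distance_correlation(x, y) -> float:
    """Empirical distance correlation R_n, in [0, 1].

    Returns 0 when the product of the marginal distance variances is zero
    (e.g. a constant margin) — a defined value, not an error.
    """
    x, y = _as_pair(x, y, min_n=2)
    a = _double_centered_abs_diff(x)
    b = _double_centered_abs_diff(y)
    vxy = float((a * b).mean())
    vx = float((a * a).mean())
    vy = float((b * b).mean())
    if vx * vy <= 0.0:
        return 0.0
    r2 = vxy / np.sqrt(vx * vy)
    return float(np.sqrt(max(r2, 0.0)))


def _silverman_1d(v: np.ndarray) -> float:
    n = v.shape[0]
    sd = float(v.std(ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        raise DegenerateInputError("zero bandwidth: vector has no spread")
    return 0.9 * scale * n ** (-0.2)


def mutual_information(x, y, cfg: KDEConfig | None = None) -> float:
    """Plug-in kernel-density mutual information estimate, in nats.

    Marginal densities come from 1-D Gaussian kernel estimates; the joint
    density from a bivariate Gaussian kernel with diagonal bandwidth matrix
    H = diag(h_x^2, h_y^2).  The estimate is the sample average of the point
    mutual information log(p(x,y) / (p(x) p(y))) at the observed points and
    may be slightly negative; :func:`edge_strength` clips it at zero.
    """
    x, y = _as_pair(x, y)
    del cfg  # only the Silverman rules are implemented
    hx = _silverman_1d(x)
    hy = _silverman_1d(y)
    kx = np.exp(-0.5 * ((x[:, None] - x[None, :]) / hx) ** 2)
    ky = np.exp(-0.5 * ((y[:, None] - y[None, :]) / hy) ** 2)
    n = x.shape[0]
    px = kx.mean(axis=1) / (hx * np.sqrt(2.0 * np.pi))
    py = ky.mean(axis=1) / (hy * np.sqrt(2.0 * np.pi))
    pxy = (kx * ky).mean(axis=1) / (2.0 * np.pi * hx * hy)
    return float(np.mean(np.log(pxy) - np.log(px) - np.log(py)))


def mic(x, y, alpha: float = 0.6, c: int = 5) -> float:
    """Maximal information coefficient, in [0, 1].

    Maximum over admissible grid resolutions (nx * ny <= n**alpha) of the
    grid mutual information normalised by log(min(nx, ny)), searched with
    the approximate equipartition-anchored algorithm (see ``_mine``).
    """
    x, y = _as_pair(x, y, min_n=10)
    _require_variation(x, "x")
    _require_variation(y, "y")
    return approx_mic(x, y, alpha=alpha, c=c)


def _local_linear_smooth(z: np.ndarray, t: np.ndarray, span: float) -> np.ndarray:
    """Nearest-neighbour local linear estimate of E[t | z] at each sample point."""
    n = z.shape[0]
    order = np.argsort(z, kind="mergesort")
    zs = z[order]
    ts = t[order]
    half = max(5, int(round(0.5 * span * n)))
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    c1 = np.concatenate(([0.0], np.cumsum(zs)))
    c2 = np.concatenate(([0.0], np.cumsum(zs * zs)))
    d1 = np.concatenate(([0.0], np.cumsum(ts)))
    d1z = np.concatenate(([0.0], np.cumsum(ts * zs)))
    m = (hi - lo).astype(np.float64)
    sz = c1[hi] - c1[lo]
    szz = c2[hi] - c2[lo]
    st = d1[hi] - d1[lo]
    stz = d1z[hi] - d1z[lo]
    zbar = sz / m
    tbar = st / m
    sxx = szz - m * zbar * zbar
    sxy = stz - m * zbar * tbar
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 1e-10 * np.maximum(szz, 1.0), sxy / sxx, 0.0)
    fit = tbar + slope * (zs - zbar)
    out = np.empty(n)
    out[order] = fit
    return out


def _group_mean_smooth(z: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exact conditional mean E[t | z] for a low-cardinality z."""
    vals, inv = np.unique(z, return_inverse=True)
    sums = np.bincount(inv, weights=t, minlength=vals.shape[0])
    counts = np.bincount(inv, minlength=vals.shape[0])
    return (sums / counts)[inv]


def _conditional_expectation(z: np.ndarray, t: np.ndarray, cfg: ACEConfig) -> np.ndarray:
    if np.unique(z).shape[0] <= cfg.discrete_threshold:
        return _group_mean_smooth(z, t)
    return _local_linear_smooth(z, t, cfg.span)


def _standardize(v: np.ndarray) -> tuple[np.ndarray, float]:
    sd = float(v.std())
    if sd < 1e-12:
        return np.zeros_like(v), 0.0
    return (v - v.mean()) / sd, sd


def ace_transform(x, y, cfg: ACEConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Optimal transforms (phi1(x), phi2(y)) by alternating conditional expectations.

    Backfits phi1 = E[phi2(y) | x] and phi2 = E[phi1(x) | y] (re-standardised
    each sweep) until the squared error E[(phi2 - phi1)^2] stabilises within
    ``cfg.tolerance``.  Both returned transforms have mean 0 and variance 1
    (zero vectors in the fully degenerate case).  Non-convergence at
    ``max_iterations`` emits a warning and returns the last iterate.
    """
    x, y = _as_pair(x, y)
    _require_variation(x, "x")
    _require_variation(y, "y")
    cfg = cfg or ACEConfig()
    theta, sd = _standardize(y.copy())
    phi = np.zeros_like(x)
    e2_prev = np.inf
    for _ in range(cfg.max_iterations):
        phi = _conditional_expectation(x, theta, cfg)
        phi = phi - phi.mean()
        theta = _conditional_expectation(y, phi, cfg)
        theta, sd = _standardize(theta)
        if sd == 0.0:  # smoothed transform collapsed: no detectable dependence
            break
        e2 = float(np.mean((theta - phi) ** 2))
        if e2_prev - e2 < cfg.tolerance:  # stop once e2 no longer decreases
            break
        e2_prev = e2
    else:
        warnings.warn("ACE did not converge within max_iterations; returning last iterate",
                      RuntimeWarning, stacklevel=2)
    phi_std, phi_sd = _standardize(phi)
    if phi_sd == 0.0 or sd == 0.0:
        return np.zeros_like(x), np.zeros_like(y)
    return phi_std, theta


def mcc(x, y, cfg: ACEConfig | None = None) -> float:
    """Maximal correlation coefficient via ACE, reported in [0, 1].

    The absolute Pearson correlation of the fitted optimal transforms.
    Degenerates to |Pearson| when the relationship is linear.
    """
    phi, theta = ace_transform(x, y, cfg)
    if phi.std() < 1e-12 or theta.std() < 1e-12:
        return 0.0
    r = abs(pearson(phi, theta))
    return float(min(r, 1.0))


def edge_strength(x, y, method: DependenceMethod | str, cfg=None) -> float:
    """Nonnegative connection strength r_ij for one directed edge.

    Signed measures (Pearson, Spearman) contribute their absolute value;
    the mutual-information estimate is clipped at 0 (it is unbounded above
    and is used unnormalised — only within-method ordering matters for the
    downstream log(1/r) path search).
    """
    method = DependenceMethod(method)
    if method is DependenceMethod.PEARSON:
        return abs(pearson(x, y))
    if method is DependenceMethod.SPEARMAN:
        return abs(spearman(x, y))
    if method is DependenceMethod.DISTANCE:
        return distance_correlation(x, y)
    if method is DependenceMethod.MI:
        return max(mutual_information(x, y, cfg if isinstance(cfg, KDEConfig) else None), 0.0)
    if method is DependenceMethod.MIC:
        return mic(x, y)
    return mcc(x, y, cfg if isinstance(cfg, ACEConfig) else None)
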