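"""Estimators: the Δγ area-model fit, correlation statistics, and a
seeded univariate Gaussian-mixture decomposition of dG distributions.

The area fit regresses measured apparent free energies on computed TMD
side-chain ASA by ordinary least squares (ASA treated as exact, replicate
uncertainties unweighted) and reports the slope back-converted to pN/nm,
i.e. an estimate of the differential interfacial tension Δγ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .physchem import KCAL_PER_MOL_A2_PER_PN_NM


@dataclass(frozen=True)
class FitResult:
    """OLS fit of dG_app (kcal/mol) against ASA (Å²).

    ``slope_pn_per_nm`` is the fitted slope converted to an interfacial
    tension; ``intercept_kcal`` is the constant offset dG_ex. ``p_value``
    and ``slope_se_pn_per_nm`` are None for the exact two-point fit.
    """

    slope_pn_per_nm: float
    intercept_kcal: float
    r: float
    p_value: float | None
    n: int
    residuals: tuple[float, ...]
    slope_kcal_per_A2: float
    slope_se_pn_per_nm: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation r out of range: {self.r}")
        if self.p_value is not None and self.n < 3:
            raise ValueError("a p-value requires n >= 3")


def fit_area_model(points: Sequence[tuple[float, float]]) -> FitResult:
    """Least-squares line dG = m·ASA + b; slope reported as Δγ in pN/nm.

    Two distinct points give the exact interpolating line with no p-value;
    identical ASA values are a degenerate design and an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (asa, dG_app) pairs")
    n = pts.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 points to fit a line, got {n}")
    asa, dg = pts[:, 0], pts[:, 1]
    if np.ptp(asa) == 0:
        raise ValueError("degenerate fit: all ASA values identical")

    if n == 2:
        slope = (dg[1] - dg[0]) / (asa[1] - asa[0])
        intercept = dg[0] - slope * asa[0]
        r = 1.0 if slope > 0 else (-1.0 if slope < 0 else 0.0)
        p = se = None
    else:
        res = stats.linregress(asa, dg)
        slope, intercept, r, p = res.slope, res.intercept, res.rvalue, res.pvalue
        se = res.stderr / KCAL_PER_MOL_A2_PER_PN_NM
    residuals = dg - (slope * asa + intercept)
    return FitResult(
        slope_pn_per_nm=float(slope) / KCAL_PER_MOL_A2_PER_PN_NM,
        intercept_kcal=float(intercept),
        r=float(r),
        p_value=None if p is None else float(p),
        n=int(n),
        residuals=tuple(float(x) for x in residuals),
        slope_kcal_per_A2=float(slope),
        slope_se_pn_per_nm=None if se is None else float(se),
    )


def correlation(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution) for paired samples."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValueError("xs and ys must have equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 for a correlation p-value, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the samples")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class MixtureFit:
    """A univariate Gaussian mixture, components sorted by mean."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    log_likelihood: float
    ll_trajectory: tuple[float, ...]
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


def gaussian_mixture(
    dG_values: Sequence[float],
    k: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """EM fit of a k-component univariate Gaussian mixture.

    Initialization is seeded (means drawn from the data without
    replacement, uniform weights, pooled SD), so the fit is deterministic
    for a fixed seed. On non-convergence within ``max_iter`` the
    best-so-far estimate is returned with ``converged=False``. The
    expectation-maximization log-likelihood is non-decreasing by
    construction; the per-iteration trajectory is reported.
    """
    x = np.asarray(dG_values, dtype=float)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if x.size < 10 * k:
        raise ValueError(f"need at least 10 observations per component (n={x.size}, k={k})")
    rng = np.random.default_rng(seed)
    means = rng.choice(x, size=k, replace=False).astype(float)
    sd0 = float(np.std(x))
    sd_floor = max(1e-8, 1e-6 * (np.ptp(x) if np.ptp(x) > 0 else 1.0))
    sds = np.full(k, max(sd0, sd_floor))
    weights = np.full(k, 1.0 / k)

    traj: list[float] = []
    converged = False
    for _ in range(max_iter):
        log_comp = np.log(weights)[:, None] + stats.norm.logpdf(
            x[None, :], means[:, None], sds[:, None]
        )
        log_total = logsumexp(log_comp, axis=0)
        ll = float(log_total.sum())
        if traj and ll - traj[-1] < tol * max(1.0, abs(ll)):
            traj.append(ll)
            converged = True
            break
        traj.append(ll)
        resp = np.exp(log_comp - log_total[None, :])
        nk = resp.sum(axis=1)
        weights = nk / x.size
        means = resp @ x / nk
        var = resp @ (x**2) / nk - means**2
        sds = np.sqrt(np.maximum(var, sd_floor**2))

    order = np.argsort(means)
    return MixtureFit(
        weights=tuple(float(w) for w in weights[order]),
        means=tuple(float(m) for m in means[order]),
        sds=tuple(float(s) for s in sds[order]),
        log_likelihood=traj[-1],
        ll_trajectory=tuple(traj),
        converged=converged,
        n_iter=len(traj),
    )
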