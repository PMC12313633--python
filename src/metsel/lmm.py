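"""Linear mixed-model core for trial analysis.

Implements REML variance-component estimation and Henderson's mixed-model
equations for the model

    y = X b + Z u + e,    u ~ N(0, v_random * I),   e ~ N(0, v_error * I),

where X codes a single categorical fixed factor (cell-means coding; a plain
intercept when no factor is supplied) and Z codes a single categorical
random factor.

The REML criterion is profiled down to the variance ratio
``lam = v_random / v_error`` and optimised by a bounded scalar search on the
log scale.  All matrix work is carried out on factor-level sufficient
statistics (level counts and cross-tabulations), so a fit scales with the
number of factor levels rather than the number of plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize_scalar

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "EffectEstimates",
    "reml_fit",
    "reml_loglik",
    "solve_mme",
    "heritability",
]

_LOG2PI = np.log(2.0 * np.pi)
#: search bounds for log(v_random / v_error)
_T_LO, _T_HI = -30.0, 30.0


@dataclass
class ModelSpec:
    """One response vector plus factor-level assignments.

    ``fixed`` / ``random`` are per-observation level labels (any hashable
    dtype); ``fixed=None`` means intercept-only.  ``genotype_term`` records
    which factor carries the genotype so callers can pull BLUEs or BLUPs
    without re-deriving the mapping.
    """

    response: np.ndarray
    fixed: np.ndarray | None = None
    random: np.ndarray | None = None
    genotype_term: str = "fixed"

    def __post_init__(self) -> None:
        y = np.asarray(self.response, dtype=float)
        if y.ndim != 1 or y.size == 0:
            raise ValueError("response must be a non-empty 1-D array")
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        self.response = y
        for name in ("fixed", "random"):
            labels = getattr(self, name)
            if labels is None:
                continue
            labels = np.asarray(labels)
            if labels.shape != y.shape:
                raise ValueError(f"factor '{name}' length does not match response")
            if np.unique(labels).size < 2:
                raise ValueError(f"factor '{name}' needs at least 2 levels")
            setattr(self, name, labels)
        if self.genotype_term not in ("fixed", "random"):
            raise ValueError("genotype_term must be 'fixed' or 'random'")


@dataclass
class VarianceComponents:
    """REML estimates for the one-random-factor model."""

    v_random: float
    v_error: float
    reml_loglik: float
    converged: bool
    n_iter: int
    #: estimate sits on (or collapsed to) a parameter-space boundary
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.v_random < 0 or self.v_error < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class EffectEstimates:
    """Solution of the mixed-model equations.

    Fixed-level entries are BLUEs (with standard errors from the inverse
    coefficient matrix); random-level entries are BLUPs with prediction-error
    SDs.
    """

    fixed_levels: np.ndarray
    fixed_estimates: np.ndarray
    fixed_se: np.ndarray
    random_levels: np.ndarray | None
    random_predictions: np.ndarray | None
    random_se: np.ndarray | None
    intercept: float

    def fixed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.fixed_levels,
                "estimate": self.fixed_estimates,
                "se": self.fixed_se,
            }
        )

    def random_frame(self) -> pd.DataFrame:
        if self.random_levels is None:
            raise ValueError("model has no random factor")
        return pd.DataFrame(
            {
                "level": self.random_levels,
                "prediction": self.random_predictions,
                "se": self.random_se,
            }
        )


class _Design:
    """Factor-level sufficient statistics for one ModelSpec."""

    def __init__(self, spec: ModelSpec) -> None:
        # centre the response: exact under cell-means coding (the grand mean
        # lies in the fixed-effect column space) and avoids catastrophic
        # cancellation in y'Py for large offsets
        self.ybar = float(np.mean(spec.response))
        y = spec.response - self.ybar
        n = y.size
        if spec.fixed is None:
            self.flevels = np.array(["(intercept)"], dtype=object)
            fcodes = np.zeros(n, dtype=np.intp)
        else:
            self.flevels, fcodes = np.unique(spec.fixed, return_inverse=True)
        p = self.flevels.size
        self.fcodes = fcodes
        self.n, self.p = n, p
        self.Dx = np.bincount(fcodes, minlength=p).astype(float)
        self.Xty = np.bincount(fcodes, weights=y, minlength=p)
        self.yty = float(y @ y)
        self.logdet_xx = float(np.log(self.Dx).sum())
        if spec.random is None:
            self.rlevels = None
            self.q = 0
            return
        self.rlevels, rcodes = np.unique(spec.random, return_inverse=True)
        q = self.rlevels.size
        self.rcodes = rcodes
        self.q = q
        self.Dz = np.bincount(rcodes, minlength=q).astype(float)
        self.Zty = np.bincount(rcodes, weights=y, minlength=q)
        B = np.zeros((p, q))
        np.add.at(B, (fcodes, rcodes), 1.0)
        self.B = B
        # Z' S Z with S the projector off the fixed-factor column space
        self.ZSZ = np.diag(self.Dz) - (B / self.Dx[:, None]).T @ B
        self.r0 = self.Zty - B.T @ (self.Xty / self.Dx)


def _absorbed_solve(des: _Design, lam: float):
    """Solve the X-absorbed MME at variance ratio ``lam``.

    Returns (beta, u, ypy, logdet of lam*Z'SZ + I).
    """
    Mt = lam * des.ZSZ + np.eye(des.q)
    try:
        cf = cho_factor(Mt, lower=True)
    except LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(
            "mixed-model equations are singular; fixed and random factors "
            "appear aliased/confounded"
        ) from exc
    u = lam * cho_solve(cf, des.r0)
    beta = (des.Xty - des.B @ u) / des.Dx
    ypy = des.yty - beta @ des.Xty - u @ des.Zty
    logdet = 2.0 * float(np.log(np.diag(cf[0])).sum())
    return beta, u, float(max(ypy, 0.0)), logdet


def _profiled_neg2ll(des: _Design, lam: float) -> float:
    """-2 * REML log-likelihood with v_error profiled out, at ratio lam."""
    dfe = des.n - des.p
    _, _, ypy, logdet_m = _absorbed_solve(des, lam)
    sigma2 = max(ypy, 1e-300) / dfe
    return dfe * (_LOG2PI + np.log(sigma2) + 1.0) + des.logdet_xx + logdet_m


def reml_loglik(spec: ModelSpec, v_random: float, v_error: float) -> float:
    """REML log-likelihood at the supplied variance components.

    Uses the same (determinant + quadratic form) criterion as a dense
    evaluation of ``-0.5 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py ]``
    but computed through factor-level statistics.
    """
    if v_error <= 0:
        raise ValueError("v_error must be positive")
    if v_random < 0:
        raise ValueError("v_random must be non-negative")
    des = _Design(spec)
    dfe = des.n - des.p
    if spec.random is None:
        beta = des.Xty / des.Dx
        rss = des.yty - beta @ des.Xty
        return -0.5 * (dfe * (_LOG2PI + np.log(v_error)) + des.logdet_xx + rss / v_error)
    lam = v_random / v_error
    _, _, ypy, logdet_m = _absorbed_solve(des, lam)
    neg2 = dfe * (_LOG2PI + np.log(v_error)) + des.logdet_xx + logdet_m + ypy / v_error
    return -0.5 * neg2


def reml_fit(spec: ModelSpec, *, n_grid: int = 31, xatol: float = 1e-10) -> VarianceComponents:
    """Estimate (v_random, v_error) by REML.

    The profiled criterion is first scanned on a coarse grid of the log
    variance ratio and then refined by bounded scalar minimisation inside
    the bracketing interval; the ratio-zero (pure OLS) boundary is checked
    explicitly.
    """
    if spec.random is None:
        raise ValueError("reml_fit requires a random factor")
    des = _Design(spec)
    dfe = des.n - des.p
    if dfe <= 0:
        raise ValueError(
            "no residual degrees of freedom: the fixed factor saturates the data"
        )
    y = spec.response
    scale = max(float(np.mean(y * y)), 1.0)
    if float(np.var(y)) < 1e-13 * scale:
        warnings.warn("response is (near-)constant; variance components degenerate")
        return VarianceComponents(0.0, 0.0, float("nan"), False, 0, boundary=True)

    ts = np.linspace(_T_LO, _T_HI, n_grid)
    vals = np.array([_profiled_neg2ll(des, float(np.exp(t))) for t in ts])
    i = int(np.argmin(vals))
    lo = ts[max(i - 1, 0)]
    hi = ts[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda t: _profiled_neg2ll(des, float(np.exp(t))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol, "maxiter": 200},
    )
    t_hat = float(res.x)
    lam = float(np.exp(t_hat))
    neg2 = float(res.fun)
    # explicit check of the v_random = 0 boundary
    neg2_zero = _profiled_neg2ll(des, 0.0)
    boundary = False
    if neg2_zero <= neg2:
        lam, neg2, boundary = 0.0, neg2_zero, True

    _, _, ypy, _ = _absorbed_solve(des, lam)
    sigma2 = ypy / dfe
    if sigma2 < 1e-12 * scale:
        warnings.warn("residual variance collapsed to ~0 (zero within-level noise)")
        boundary = True
    if t_hat >= _T_HI - 1e-6 or t_hat <= _T_LO + 1e-6:
        boundary = True
    v_random = lam * sigma2
    return VarianceComponents(
        v_random=float(v_random),
        v_error=float(sigma2),
        reml_loglik=-0.5 * neg2,
        converged=bool(res.success),
        n_iter=n_grid + int(res.nfev),
        boundary=boundary,
    )


def solve_mme(spec: ModelSpec, vc: VarianceComponents) -> EffectEstimates:
    """Solve Henderson's mixed-model equations at the given components.

    Fixed estimates equal GLS estimates; random predictions equal the
    conditional means of u given the data.  Standard errors come from the
    inverse of the coefficient matrix.
    """
    des = _Design(spec)
    ve = max(float(vc.v_error), 0.0)
    vu = max(float(vc.v_random), 0.0)

    if spec.random is None or vu == 0.0:
        beta = des.Xty / des.Dx + des.ybar
        fixed_se = np.sqrt(ve / des.Dx)
        if spec.random is None:
            rl = rp = rse = None
        else:
            rl = des.rlevels
            rp = np.zeros(des.q)
            rse = np.zeros(des.q)
        return EffectEstimates(
            fixed_levels=des.flevels,
            fixed_estimates=beta,
            fixed_se=fixed_se,
            random_levels=rl,
            random_predictions=rp,
            random_se=rse,
            intercept=float(np.mean(beta)),
        )

    # shrinkage ratio; keep strictly positive so the system stays PD even
    # when v_error collapsed to 0 (no-noise limit)
    k = max(ve / vu, 1e-8)
    p, q = des.p, des.q
    C = np.empty((p + q, p + q))
    C[:p, :p] = np.diag(des.Dx)
    C[:p, p:] = des.B
    C[p:, :p] = des.B.T
    C[p:, p:] = np.diag(des.Dz) + k * np.eye(q)
    rhs = np.concatenate([des.Xty, des.Zty])
    try:
        cf = cho_factor(C, lower=True)
    except LinAlgError as exc:
        raise ValueError(
            "mixed-model coefficient matrix is singular: fixed and random "
            "factors are confounded or a level is aliased"
        ) from exc
    theta = cho_solve(cf, rhs)
    cinv_diag = np.diag(cho_solve(cf, np.eye(p + q)))
    beta = theta[:p] + des.ybar
    u = theta[p:]
    fixed_se = np.sqrt(np.clip(ve * cinv_diag[:p], 0.0, None))
    random_se = np.sqrt(np.clip(ve * cinv_diag[p:], 0.0, None))
    return EffectEstimates(
        fixed_levels=des.flevels,
        fixed_estimates=beta,
        fixed_se=fixed_se,
        random_levels=des.rlevels,
        random_predictions=u,
        random_se=random_se,
        intercept=float(np.mean(beta)),
    )


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability v_random / (v_random + v_error)."""
    vg, ve = float(vc.v_random), float(vc.v_error)
    if vg < 0 or ve < 0:
        raise ValueError("variance components must be non-negative")
    if vg + ve == 0:
        raise ValueError("heritability undefined: both variance components are 0")
    return float(np.clip(vg / (vg + ve), 0.0, 1.0))
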