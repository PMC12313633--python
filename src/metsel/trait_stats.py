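"""Descriptive and associative trait statistics.

Covers stress-induced reduction metrics, Pearson correlation matrices
(within-environment across traits, and between environments per trait) and
stepwise multiple regression of yield on secondary traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReductionReport",
    "CorrelationMatrix",
    "RegressionResult",
    "reduction_metrics",
    "trait_correlations",
    "env_correlations",
    "stepwise_regression",
]


@dataclass
class ReductionReport:
    trait: str
    control_mean: float
    stress_mean: float
    absolute: float
    percent: float
    mode: str  # "of-means" | "mean-of-per-genotype"


def reduction_metrics(control, stress, mode: str = "of-means", trait: str = "") -> ReductionReport:
    """Stress-induced reduction of a trait.

    ``of-means`` uses the difference/ratio of the two group means;
    ``mean-of-per-genotype`` averages per-genotype percent reductions (the
    inputs must then be paired by genotype, same length and order).  The
    absolute reduction is always control mean minus stress mean.
    """
    c = np.asarray(control, dtype=float).ravel()
    s = np.asarray(stress, dtype=float).ravel()
    if mode not in ("of-means", "mean-of-per-genotype"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "of-means":
        cm = float(np.nanmean(c))
        sm = float(np.nanmean(s))
        if not np.isfinite(cm) or not np.isfinite(sm):
            raise ValueError("group means are not finite")
        if cm == 0:
            raise ValueError("control mean is 0; percent reduction undefined")
        absolute = cm - sm
        percent = 100.0 * absolute / cm
    else:
        if c.shape != s.shape:
            raise ValueError("paired mode requires control/stress of equal length")
        ok = np.isfinite(c) & np.isfinite(s)
        c, s = c[ok], s[ok]
        if c.size == 0:
            raise ValueError("no complete genotype pairs")
        nz = c != 0
        if not nz.all():
            warnings.warn(f"{(~nz).sum()} genotypes with zero control value dropped")
            c, s = c[nz], s[nz]
        cm = float(c.mean())
        sm = float(s.mean())
        if cm == 0:
            raise ValueError("control mean is 0; percent reduction undefined")
        absolute = cm - sm
        percent = float(np.mean(100.0 * (c - s) / c))
    return ReductionReport(
        trait=trait, control_mean=cm, stress_mean=sm,
        absolute=absolute, percent=percent, mode=mode,
    )


@dataclass
class CorrelationMatrix:
    labels: list[str]
    r: np.ndarray
    p: np.ndarray
    n: np.ndarray
    #: Benjamini-Hochberg adjusted p-values (off-diagonal cells)
    p_adjusted: np.ndarray | None = None

    def to_frame(self, which: str = "r") -> pd.DataFrame:
        mat = {"r": self.r, "p": self.p, "n": self.n, "p_adjusted": self.p_adjusted}[which]
        return pd.DataFrame(mat, index=self.labels, columns=self.labels)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (NaN-aware)."""
    out = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(ranked, 0.0, 1.0)
    out[ok] = adj
    return out


def _pairwise_pearson(values: pd.DataFrame, min_n: int = 3) -> CorrelationMatrix:
    labels = list(values.columns)
    t = len(labels)
    r = np.eye(t)
    p = np.zeros((t, t))
    n = np.zeros((t, t), dtype=int)
    mat = values.to_numpy(dtype=float)
    for i in range(t):
        n[i, i] = int(np.isfinite(mat[:, i]).sum())
    for i in range(t):
        for j in range(i + 1, t):
            ok = np.isfinite(mat[:, i]) & np.isfinite(mat[:, j])
            nij = int(ok.sum())
            n[i, j] = n[j, i] = nij
            if nij < min_n or np.std(mat[ok, i]) == 0 or np.std(mat[ok, j]) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(mat[ok, i], mat[ok, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    iu = np.triu_indices(t, k=1)
    padj_flat = _bh_adjust(p[iu])
    padj = np.zeros((t, t))
    padj[iu] = padj_flat
    padj = padj + padj.T
    np.fill_diagonal(padj, 0.0)
    padj[np.isnan(p)] = np.nan
    np.fill_diagonal(padj, 0.0)
    return CorrelationMatrix(labels=labels, r=r, p=p, n=n, p_adjusted=padj)


def trait_correlations(values: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlations between traits (rows = genotypes).

    Pairwise-complete observations; two-sided p-values from the exact
    t transform; cells with fewer than 3 complete pairs or a zero-variance
    trait are reported missing.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    return _pairwise_pearson(values)


def env_correlations(blues: pd.DataFrame, trait: str | None = None) -> CorrelationMatrix:
    """Between-environment correlation of stage-1 BLUEs for one trait.

    ``blues`` columns: environment, genotype, value (optionally trait, which
    is then filtered on).
    """
    df = blues
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    wide = df.pivot_table(index="genotype", columns="environment", values="value")
    if wide.shape[1] < 2:
        raise ValueError("need BLUEs from at least 2 environments")
    return _pairwise_pearson(wide)


@dataclass
class RegressionResult:
    predictors: list[str]
    coef: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    aic: float
    n: int
    dropped_collinear: list[str] = field(default_factory=list)
    dropped_lowcorr: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "t": self.tvalues, "p": self.pvalues}
        )


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    # matches the usual OLS definition: llf = -n/2 (log 2pi + log(rss/n) + 1)
    llf = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    return float(-2 * llf + 2 * k)


def _ols(y: np.ndarray, X: np.ndarray):
    """Plain least squares; returns coefs, se, t, p, rss, aic, r2 stats."""
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    df_resid = n - k
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if df_resid > 0 and rss > 0:
        sigma2 = rss / df_resid
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        tvals = coef / se
        pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    else:
        se = np.zeros(k)
        tvals = np.full(k, np.nan)
        pvals = np.full(k, np.nan)
    return coef, se, tvals, pvals, rss, r2, df_resid


def subset_aic(y: np.ndarray, X: np.ndarray) -> float:
    """AIC of the OLS fit of y on [1, X] (exposed for oracle comparisons)."""
    n = y.size
    M = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ coef
    return _gaussian_aic(float(resid @ resid), n, M.shape[1])


def stepwise_regression(
    y,
    X: pd.DataFrame,
    criterion: str = "aic",
    corr_threshold: float = 0.1,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 100,
) -> RegressionResult:
    """Bidirectional stepwise regression of y on candidate traits.

    Candidates are pre-filtered to |Pearson r with y| >= ``corr_threshold``.
    ``criterion="aic"`` (default) steps both directions from the
    intercept-only model minimising AIC; ``criterion="pvalue"`` uses the
    classical enter/remove thresholds.  The final model is refit by OLS.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    data = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    yv = data["__y__"].to_numpy()
    Xd = data[X.columns]
    n = len(data)
    if n <= X.shape[1] + 1:
        raise ValueError("need n > number of candidates + 1")

    dropped_lowcorr = []
    keep = []
    for col in Xd.columns:
        x = Xd[col].to_numpy()
        if np.std(x) == 0:
            dropped_lowcorr.append(col)
            continue
        r = np.corrcoef(yv, x)[0, 1]
        if abs(r) >= corr_threshold:
            keep.append(col)
        else:
            dropped_lowcorr.append(col)

    # drop collinear candidate columns via pivoted QR
    dropped_collinear = []
    if keep:
        M = np.column_stack([np.ones(n)] + [Xd[c].to_numpy() for c in keep])
        from scipy.linalg import qr

        _, Rm, piv = qr(M, mode="economic", pivoting=True)
        diag = np.abs(np.diag(Rm))
        bad = diag < 1e-10 * diag.max()
        dead_cols = {piv[i] for i in np.where(bad)[0]}
        if dead_cols:
            names = [keep[i - 1] for i in sorted(dead_cols) if i > 0]
            warnings.warn(f"dropping collinear candidate column(s): {names}")
            dropped_collinear = names
            keep = [c for c in keep if c not in names]

    cols = {c: Xd[c].to_numpy() for c in keep}

    def aic_of(subset: tuple[str, ...]) -> float:
        M = np.column_stack([cols[c] for c in subset]) if subset else np.empty((n, 0))
        return subset_aic(yv, M)

    selected: list[str] = []
    if criterion == "aic":
        current = aic_of(())
        for _ in range(max_steps):
            moves = []
            for c in keep:
                if c not in selected:
                    moves.append((aic_of(tuple(selected + [c])), "add", c))
            for c in selected:
                trial = tuple(x for x in selected if x != c)
                moves.append((aic_of(trial), "drop", c))
            if not moves:
                break
            best = min(moves, key=lambda m: (m[0], m[2]))
            if best[0] < current - 1e-10:
                current = best[0]
                if best[1] == "add":
                    selected.append(best[2])
                else:
                    selected.remove(best[2])
            else:
                break
    elif criterion == "pvalue":
        for _ in range(max_steps):
            changed = False
            # forward: most significant candidate below p_enter
            best_p, best_c = None, None
            for c in keep:
                if c in selected:
                    continue
                M = np.column_stack([np.ones(n)] + [cols[x] for x in selected + [c]])
                _, _, _, pv, *_ = _ols(yv, M)
                if np.isfinite(pv[-1]) and (best_p is None or pv[-1] < best_p):
                    best_p, best_c = pv[-1], c
            if best_c is not None and best_p < p_enter:
                selected.append(best_c)
                changed = True
            # backward: least significant above p_remove
            if selected:
                M = np.column_stack([np.ones(n)] + [cols[x] for x in selected])
                _, _, _, pv, *_ = _ols(yv, M)
                worst = int(np.argmax(pv[1:]))
                if pv[1 + worst] > p_remove:
                    selected.pop(worst)
                    changed = True
            if not changed:
                break
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    # keep deterministic reporting order
    selected = [c for c in keep if c in selected]
    M = np.column_stack([np.ones(n)] + [cols[c] for c in selected])
    coef, se, tvals, pvals, rss, r2, df_resid = _ols(yv, M)
    k = len(selected)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else float("nan")
    if k > 0 and r2 < 1.0:
        fval = (r2 / k) / ((1.0 - r2) / df_resid)
        f_p = float(stats.f.sf(fval, k, df_resid))
    else:
        fval, f_p = float("nan"), float("nan")
    names = ["(intercept)"] + selected
    return RegressionResult(
        predictors=selected,
        coef=pd.Series(coef, index=names),
        se=pd.Series(se, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        r2=float(r2),
        adj_r2=float(adj_r2),
        fvalue=float(fval),
        f_pvalue=f_p,
        df_model=k,
        df_resid=df_resid,
        aic=_gaussian_aic(rss, n, k + 1) if rss > 0 else float("-inf"),
        n=n,
        dropped_collinear=dropped_collinear,
        dropped_lowcorr=dropped_lowcorr,
    )
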