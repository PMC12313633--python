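"""Desired-gain multi-trait selection index.

Trait weights b solve G b = d, where G is the covariance matrix of the
(z-scored) traits and d the vector of desired gains in SD units.  Scores
are b'z per accession; accessions beating every tolerant check's score are
flagged as index-selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve

__all__ = ["IndexSpec", "IndexWeights", "compute_weights", "score_accessions", "beats_all_checks"]

log = logging.getLogger(__name__)

_COND_LIMIT = 1e10
_RESID_LIMIT = 1e-8


@dataclass
class IndexSpec:
    traits: tuple[str, ...]
    #: desired gains in SD units, aligned with ``traits``
    d: tuple[float, ...]
    scaling: bool = True

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.d = tuple(float(x) for x in self.d)
        if len(self.traits) != len(self.d):
            raise ValueError("traits and d must have equal length")
        if len(self.traits) < 2:
            raise ValueError("need at least 2 traits")
        if not any(self.d):
            raise ValueError("at least one desired gain must be nonzero")


@dataclass
class IndexWeights:
    traits: tuple[str, ...]
    b: np.ndarray
    G: np.ndarray
    residual: float
    #: scaling statistics used (kept so scores reuse the same centring/SD)
    means: np.ndarray
    sds: np.ndarray
    scaling: bool


def _collinear_pair(G: np.ndarray, traits: tuple[str, ...]) -> str:
    # name the most correlated trait pair when the solve is hopeless
    sd = np.sqrt(np.diag(G))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = G / np.outer(sd, sd)
    np.fill_diagonal(C, 0.0)
    i, j = np.unravel_index(np.nanargmax(np.abs(C)), C.shape)
    return f"{traits[i]!r} and {traits[j]!r} (|r|={abs(C[i, j]):.4f})"


def compute_weights(values: pd.DataFrame, spec: IndexSpec) -> IndexWeights:
    """Solve G b = d on the (scaled) trait matrix.

    ``values``: genotypes x traits; rows with any missing index trait are
    excluded from the covariance estimate.  With scaling on, G is the trait
    correlation matrix.  The solve uses a symmetric factorization and the
    residual ``max|G b - d|`` is verified.
    """
    missing = [t for t in spec.traits if t not in values.columns]
    if missing:
        raise ValueError(f"trait(s) absent from values: {missing}")
    sub = values[list(spec.traits)].dropna()
    n_traits = len(spec.traits)
    if len(sub) < n_traits + 1:
        raise ValueError(f"need at least {n_traits + 1} complete genotypes, have {len(sub)}")
    means = sub.mean().to_numpy()
    sds = sub.std(ddof=1).to_numpy()
    if np.any(sds == 0):
        dead = [t for t, s in zip(spec.traits, sds) if s == 0]
        raise ValueError(f"zero-variance trait(s): {dead}")
    Z = (sub.to_numpy() - means) / sds if spec.scaling else sub.to_numpy() - means
    G = np.cov(Z, rowvar=False, ddof=1)
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond >= _COND_LIMIT:
        raise ValueError(
            f"index covariance matrix is singular/ill-conditioned "
            f"(cond={cond:.3g}); most collinear pair: {_collinear_pair(G, spec.traits)}"
        )
    d = np.asarray(spec.d, dtype=float)
    try:
        cf = cho_factor(G, lower=True)
    except LinAlgError as exc:
        raise ValueError(
            f"index covariance matrix is not positive definite; most "
            f"collinear pair: {_collinear_pair(G, spec.traits)}"
        ) from exc
    b = cho_solve(cf, d)
    residual = float(np.max(np.abs(G @ b - d)))
    if residual >= _RESID_LIMIT:
        raise ValueError(f"G b = d solve failed verification (residual {residual:.3g})")
    return IndexWeights(
        traits=spec.traits, b=b, G=G, residual=residual,
        means=means, sds=sds, scaling=spec.scaling,
    )


def score_accessions(values: pd.DataFrame, weights: IndexWeights) -> pd.DataFrame:
    """Index score and descending rank per genotype (ties broken by name).

    Trait values are scaled with the same centring/SD used when the weights
    were computed; genotypes with a missing index trait get no score.
    """
    sub = values[list(weights.traits)]
    complete = sub.dropna()
    skipped = sorted(set(sub.index) - set(complete.index))
    if skipped:
        log.info("%d genotypes skipped for missing index traits: %s", len(skipped), skipped)
    Z = (complete.to_numpy() - weights.means)
    if weights.scaling:
        Z = Z / weights.sds
    scores = Z @ weights.b
    out = pd.DataFrame({"genotype": complete.index, "score": scores})
    out = out.sort_values(["score", "genotype"], ascending=[False, True],
                          kind="mergesort", ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def beats_all_checks(
    scores: pd.DataFrame,
    tolerant_checks: list[str] | tuple[str, ...],
    exclude: tuple[str, ...] = (),
) -> list[str]:
    """Accessions scoring strictly above every tolerant check."""
    s = scores.set_index("genotype")["score"]
    names = list(tolerant_checks)
    missing = [c for c in names if c not in s.index]
    if missing:
        raise ValueError(f"check(s) not scored: {missing}")
    threshold = float(s.loc[names].max())
    drop = set(names) | set(exclude)
    cand = s[~s.index.isin(drop)]
    return sorted(cand.index[cand > threshold])
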