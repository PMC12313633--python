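"""Stage-2 (multi-trial) analysis: across-environment BLUPs per genotype.

Stage-1 BLUEs are combined in a genotype-random / environment-fixed model.
Reported "predicted values" are grand mean + BLUP deviation, i.e. on the
trait scale.  The fit is unweighted by default (stage-1 standard errors
ignored); genotypes absent from some environments are handled naturally by
the mixed-model equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import ModelSpec, VarianceComponents, reml_fit, solve_mme

__all__ = ["MtaResult", "fit_mta", "rank_by_prediction", "superiority_fraction"]


@dataclass
class MtaResult:
    trait: str
    #: columns genotype, blup (deviation), predicted (grand mean + blup), se
    predictions: pd.DataFrame
    grand_mean: float
    vc: VarianceComponents
    #: per-environment fixed-effect estimates
    env_effects: pd.Series

    @property
    def kind(self) -> str:
        return "BLUP"


def fit_mta(blues: pd.DataFrame, trait: str = "") -> MtaResult:
    """Fit the across-environment model on stage-1 BLUEs.

    ``blues`` needs columns environment, genotype, value (one trait).  With a
    single environment no variance-ratio is identifiable from one record per
    genotype, so predictions fall back to the centred BLUEs (no shrinkage)
    with a warning.
    """
    df = blues.dropna(subset=["value"])
    if df.empty:
        raise ValueError("no BLUE values supplied")
    envs = sorted(df["environment"].unique())
    if len(envs) == 1:
        warnings.warn(
            f"trait {trait!r}: single environment; stage-2 predictions equal "
            "stage-1 BLUEs (no shrinkage possible)"
        )
        grand = float(df["value"].mean())
        preds = pd.DataFrame(
            {
                "genotype": df["genotype"].to_numpy(),
                "blup": df["value"].to_numpy() - grand,
                "predicted": df["value"].to_numpy(),
                "se": np.zeros(len(df)),
            }
        ).sort_values("genotype", ignore_index=True)
        vc = VarianceComponents(
            v_random=float(df["value"].var(ddof=1)),
            v_error=0.0,
            reml_loglik=float("nan"),
            converged=False,
            n_iter=0,
            boundary=True,
        )
        return MtaResult(trait=trait, predictions=preds, grand_mean=grand, vc=vc,
                         env_effects=pd.Series({envs[0]: grand}))

    spec = ModelSpec(
        response=df["value"].to_numpy(dtype=float),
        fixed=df["environment"].to_numpy(),
        random=df["genotype"].to_numpy(),
        genotype_term="random",
    )
    vc = reml_fit(spec)
    est = solve_mme(spec, vc)
    env_effects = pd.Series(est.fixed_estimates, index=est.fixed_levels)
    grand = float(env_effects.mean())
    preds = pd.DataFrame(
        {
            "genotype": est.random_levels,
            "blup": est.random_predictions,
            "predicted": grand + est.random_predictions,
            "se": est.random_se,
        }
    )
    return MtaResult(trait=trait, predictions=preds, grand_mean=grand, vc=vc,
                     env_effects=env_effects)


def rank_by_prediction(mta: MtaResult) -> list[str]:
    """Genotypes in descending predicted order; ties broken by name."""
    df = mta.predictions.sort_values(
        ["predicted", "genotype"], ascending=[False, True], kind="mergesort"
    )
    return df["genotype"].tolist()


def superiority_fraction(
    mta: MtaResult,
    reference: str | list[str] = "mean",
    check_names: set[str] | frozenset[str] = frozenset(),
) -> tuple[float, list[str]]:
    """Fraction of test accessions strictly above a reference value.

    ``reference`` is either ``"mean"`` (the predicted mean over all scored
    genotypes, checks included) or a list of check names whose maximum
    predicted value forms the threshold.
    """
    preds = mta.predictions.set_index("genotype")["predicted"]
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be 'mean' or a list of check names")
        ref_value = float(preds.mean())
    else:
        names = list(reference)
        if not names:
            raise ValueError("reference check list is empty")
        missing = [n for n in names if n not in preds.index]
        if missing:
            raise ValueError(f"unknown check name(s): {missing}")
        ref_value = float(preds.loc[names].max())
    test = preds[~preds.index.isin(check_names)]
    if test.empty:
        raise ValueError("no test accessions to evaluate")
    members = sorted(test.index[test > ref_value])
    return len(members) / len(test), members
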