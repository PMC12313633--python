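"""Stage-1 (single-trial) analysis of one environment x one trait.

BLUEs are obtained from a genotype-fixed / block-random fit of the
augmented design.  Broad-sense heritability comes from a companion
genotype-random fit on block-adjusted plot values, since a fixed-genotype
fit yields no genetic variance component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import ModelSpec, VarianceComponents, heritability, reml_fit, solve_mme

__all__ = ["StaResult", "fit_sta", "run_all_sta", "sta_summary_table", "blues_table"]

log = logging.getLogger(__name__)


@dataclass
class StaResult:
    environment: str
    trait: str
    #: columns genotype, value (BLUE), se, is_check; kind is always BLUE
    predictions: pd.DataFrame
    #: variance components of the companion genotype-random fit
    vc: VarianceComponents
    h2: float
    #: mean/min/max/cv_pct of the raw plot values
    summary: dict
    #: block variance components from the BLUE (genotype-fixed) fit
    block_vc: VarianceComponents

    @property
    def kind(self) -> str:
        return "BLUE"


def _summary(values: pd.Series) -> dict:
    vals = values.dropna()
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return {
        "mean": mean,
        "min": float(vals.min()),
        "max": float(vals.max()),
        "cv_pct": 100.0 * sd / mean if mean != 0 else float("nan"),
    }


def fit_sta(records: pd.DataFrame, environment: str, trait: str) -> StaResult:
    """Fit the augmented single-trial model for one environment and trait."""
    df = records[(records["environment"] == environment) & (records["trait"] == trait)]
    if df.empty:
        raise ValueError(f"no records for environment={environment!r} trait={trait!r}")
    n_missing = df["value"].isna().sum()
    if n_missing:
        lost = set(df["genotype"]) - set(df.dropna(subset=["value"])["genotype"])
        if lost:
            log.info("%s/%s: %d genotypes lost to missing plots: %s",
                     environment, trait, len(lost), sorted(lost))
        df = df.dropna(subset=["value"])
    if df.empty:
        raise ValueError(f"all values missing for {environment}/{trait}")

    blocks = df["block"].unique()
    if len(blocks) < 2:
        raise ValueError(f"{environment}/{trait}: need >= 2 blocks, found {len(blocks)}")
    checks = df.loc[df["is_check"], "genotype"].unique()
    for check in checks:
        present = set(df.loc[df["genotype"] == check, "block"])
        missing = set(blocks) - present
        if missing:
            warnings.warn(
                f"{environment}/{trait}: check {check!r} missing from blocks "
                f"{sorted(missing)}; proceeding"
            )

    y = df["value"].to_numpy(dtype=float)
    geno = df["genotype"].to_numpy()
    block = df["block"].to_numpy()

    spec_blue = ModelSpec(response=y, fixed=geno, random=block, genotype_term="fixed")
    block_vc = reml_fit(spec_blue)
    est = solve_mme(spec_blue, block_vc)

    is_check_map = df.groupby("genotype")["is_check"].first()
    predictions = pd.DataFrame(
        {
            "genotype": est.fixed_levels,
            "value": est.fixed_estimates,
            "se": est.fixed_se,
        }
    )
    predictions["is_check"] = predictions["genotype"].map(is_check_map).astype(bool)

    # companion genotype-random fit on block-adjusted plot values -> H2
    blup_by_block = dict(zip(est.random_levels, est.random_predictions))
    y_adj = y - np.array([blup_by_block[b] for b in block])
    spec_h2 = ModelSpec(response=y_adj, fixed=None, random=geno, genotype_term="random")
    vc = reml_fit(spec_h2)
    h2 = heritability(vc)

    return StaResult(
        environment=environment,
        trait=trait,
        predictions=predictions,
        vc=vc,
        h2=h2,
        summary=_summary(df["value"]),
        block_vc=block_vc,
    )


def run_all_sta(records: pd.DataFrame, traits: list[str] | None = None) -> list[StaResult]:
    """One StaResult per environment x trait present in the records."""
    if records.empty:
        raise ValueError("no records supplied")
    envs = sorted(records["environment"].unique())
    trait_list = sorted(records["trait"].unique()) if traits is None else list(traits)
    results = []
    for env in envs:
        for trait in trait_list:
            sub = records[(records["environment"] == env) & (records["trait"] == trait)]
            if sub.empty:
                log.info("skipping %s/%s: trait absent in environment", env, trait)
                continue
            results.append(fit_sta(records, env, trait))
    return results


def sta_summary_table(results: list[StaResult]) -> pd.DataFrame:
    """Trial-quality summary shaped like a mean/range/heritability/CV table."""
    rows = [
        {
            "trait": r.trait,
            "environment": r.environment,
            "mean": r.summary["mean"],
            "min": r.summary["min"],
            "max": r.summary["max"],
            "heritability": r.h2,
            "cv_pct": r.summary["cv_pct"],
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def blues_table(results: list[StaResult]) -> pd.DataFrame:
    """Long table of stage-1 BLUEs: environment, trait, genotype, is_check, value, se."""
    frames = []
    for r in results:
        f = r.predictions.copy()
        f.insert(0, "trait", r.trait)
        f.insert(0, "environment", r.environment)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
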