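"""End-to-end orchestration: phenotypes (real or simulated) -> report bundle.

Stage order: single-trial analysis per environment -> summary table;
stress-reduction metrics; between-environment correlations; multi-trial
BLUPs and yield ranking; trait correlations on predicted values; stepwise
regression of yield; check-anchored classification (per stress environment
on BLUEs and across environments on predicted values); desired-gain
selection index.  Every stage writes a CSV; a run log records the seed,
library versions and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as met_io
from .classification import CheckConfig, category_summary, classify, consistent_tolerant, default_checks
from .multi_trial import fit_mta, rank_by_prediction, superiority_fraction
from .selection_index import IndexSpec, beats_all_checks, compute_weights, score_accessions
from .single_trial import blues_table, run_all_sta, sta_summary_table
from .synthetic import SimConfig, default_config, simulate_met
from .trait_stats import env_correlations, reduction_metrics, stepwise_regression, trait_correlations

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    #: phenotype CSV; None -> simulate
    input: str | None = None
    n_test: int = 500
    n_blocks: int = 10
    sim_traits: list[str] | None = None
    dropout: float = 0.0
    seed: int = 0
    control_env: str = "Control"
    stress_envs: tuple[str, ...] = ("ROS", "TPE")
    yield_trait: str = "GY"
    checks: CheckConfig = field(default_factory=default_checks)
    index_traits: tuple[str, ...] = ("GY", "SF", "DFF")
    index_gains: tuple[float, ...] = (1.0, 0.5, 0.0)
    stepwise_criterion: str = "aic"
    corr_threshold: float = 0.1
    outdir: str = "results"
    plots: bool = False

    def sim_config(self) -> SimConfig:
        return default_config(
            n_test=self.n_test,
            n_blocks=self.n_blocks,
            seed=self.seed,
            traits=self.sim_traits,
            dropout=self.dropout,
        )

    def digest(self) -> str:
        payload = yaml.safe_dump(_config_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _config_dict(cfg: PipelineConfig) -> dict:
    return {
        "input": cfg.input,
        "n_test": cfg.n_test,
        "n_blocks": cfg.n_blocks,
        "sim_traits": cfg.sim_traits,
        "dropout": cfg.dropout,
        "seed": cfg.seed,
        "control_env": cfg.control_env,
        "stress_envs": list(cfg.stress_envs),
        "yield_trait": cfg.yield_trait,
        "checks": {
            "tolerant": list(cfg.checks.tolerant),
            "susceptible": list(cfg.checks.susceptible),
            "upper_anchor": cfg.checks.upper_anchor,
            "lower_anchor": cfg.checks.lower_anchor,
        },
        "index_traits": list(cfg.index_traits),
        "index_gains": list(cfg.index_gains),
        "stepwise_criterion": cfg.stepwise_criterion,
        "corr_threshold": cfg.corr_threshold,
    }


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    simple = [
        "input", "n_test", "n_blocks", "sim_traits", "dropout", "seed",
        "control_env", "yield_trait", "stepwise_criterion", "corr_threshold",
        "outdir",
    ]
    for key in simple:
        if key in data:
            kwargs[key] = data[key]
    if "stress_envs" in data:
        kwargs["stress_envs"] = tuple(data["stress_envs"])
    if "index_traits" in data:
        kwargs["index_traits"] = tuple(data["index_traits"])
    if "index_gains" in data:
        kwargs["index_gains"] = tuple(data["index_gains"])
    if "checks" in data:
        c = data["checks"]
        kwargs["checks"] = CheckConfig(
            tolerant=tuple(c["tolerant"]),
            susceptible=tuple(c["susceptible"]),
            upper_anchor=c["upper_anchor"],
            lower_anchor=c["lower_anchor"],
        )
    return PipelineConfig(**kwargs)


class StageError(RuntimeError):
    pass


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns stage objects and written paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loglines = [
        f"seed: {cfg.seed}",
        f"config_hash: {cfg.digest()}",
        f"numpy: {np.__version__}",
        f"pandas: {pd.__version__}",
    ]
    out: dict = {"outdir": outdir}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- input --------------------------------------------------------
    if cfg.input is None:
        records, truth = stage("simulate")(simulate_met, cfg.sim_config())
        met_io.write_phenotypes(records, outdir / "phenotypes.csv")
        truth.genetic_values.to_csv(outdir / "truth_genetic_values.csv", index=False)
        truth.components.to_csv(outdir / "truth_components.csv", index=False)
        out["truth"] = truth
        loglines.append(f"input: simulated (n_test={cfg.n_test}, n_blocks={cfg.n_blocks})")
    else:
        records = stage("read")(met_io.read_phenotypes, cfg.input)
        loglines.append(f"input: {cfg.input} ({len(records)} rows)")
    out["records"] = records
    for env, cnt in records.groupby("environment").size().items():
        loglines.append(f"rows[{env}]: {cnt}")

    # --- stage 1: single-trial analysis -------------------------------
    sta_results = stage("sta")(run_all_sta, records)
    summary = sta_summary_table(sta_results)
    blues = blues_table(sta_results)
    summary.to_csv(outdir / "sta_summary.csv", index=False)
    blues.to_csv(outdir / "blues.csv", index=False)
    out["sta"] = sta_results
    out["blues"] = blues

    # --- reductions on BLUEs ------------------------------------------
    def _reductions():
        rows = []
        wide = blues.pivot_table(index=["trait", "genotype"], columns="environment",
                                 values="value")
        for trait in sorted(blues["trait"].unique()):
            if cfg.control_env not in wide.columns:
                continue
            for stress in cfg.stress_envs:
                if stress not in wide.columns:
                    continue
                sub = wide.loc[trait, [cfg.control_env, stress]].dropna() \
                    if trait in wide.index.get_level_values(0) else pd.DataFrame()
                if sub.empty:
                    continue
                for mode in ("of-means", "mean-of-per-genotype"):
                    rep = reduction_metrics(
                        sub[cfg.control_env], sub[stress], mode=mode, trait=trait
                    )
                    rows.append(
                        {
                            "trait": trait,
                            "stress_env": stress,
                            "mode": mode,
                            "control_mean": rep.control_mean,
                            "stress_mean": rep.stress_mean,
                            "absolute_reduction": rep.absolute,
                            "percent_reduction": rep.percent,
                        }
                    )
        return pd.DataFrame(rows)

    reductions = stage("reductions")(_reductions)
    reductions.to_csv(outdir / "reductions.csv", index=False)
    out["reductions"] = reductions

    # --- between-environment correlations per trait -------------------
    def _env_corr():
        rows = []
        for trait in sorted(blues["trait"].unique()):
            sub = blues[blues["trait"] == trait]
            if sub["environment"].nunique() < 2:
                continue
            cm = env_correlations(sub)
            for i, a in enumerate(cm.labels):
                for j in range(i + 1, len(cm.labels)):
                    rows.append(
                        {
                            "trait": trait,
                            "env_a": a,
                            "env_b": cm.labels[j],
                            "r": cm.r[i, j],
                            "p": cm.p[i, j],
                            "n": cm.n[i, j],
                        }
                    )
        return pd.DataFrame(rows)

    env_corr = stage("env_correlations")(_env_corr)
    env_corr.to_csv(outdir / "env_correlations.csv", index=False)
    out["env_correlations"] = env_corr

    # --- stage 2: multi-trial analysis --------------------------------
    def _mta():
        results = {}
        frames = []
        for trait in sorted(blues["trait"].unique()):
            sub = blues[blues["trait"] == trait]
            mta = fit_mta(sub, trait=trait)
            results[trait] = mta
            f = mta.predictions.copy()
            f.insert(0, "trait", trait)
            frames.append(f)
        return results, pd.concat(frames, ignore_index=True)

    mta_results, mta_table = stage("mta")(_mta)
    out["mta"] = mta_results
    yld = cfg.yield_trait
    if yld in mta_results:
        order = rank_by_prediction(mta_results[yld])
        rank_map = {g: i + 1 for i, g in enumerate(order)}
        mta_table["rank"] = [
            rank_map[g] if t == yld else np.nan
            for t, g in zip(mta_table["trait"], mta_table["genotype"])
        ]
        frac, _ = superiority_fraction(
            mta_results[yld], "mean", check_names=set(cfg.checks.all_checks)
        )
        loglines.append(f"yield_above_predicted_mean: {100 * frac:.2f}%")
    mta_table.to_csv(outdir / "mta_predictions.csv", index=False)
    out["mta_table"] = mta_table

    predicted = mta_table.pivot_table(index="genotype", columns="trait",
                                      values="predicted")
    out["predicted"] = predicted

    # --- trait correlations on predicted values -----------------------
    trait_corr = stage("trait_correlations")(trait_correlations, predicted)
    trait_corr.to_frame("r").to_csv(outdir / "trait_correlations_r.csv")
    trait_corr.to_frame("p").to_csv(outdir / "trait_correlations_p.csv")
    out["trait_correlations"] = trait_corr

    # --- stepwise regression of yield ----------------------------------
    def _regress():
        if yld not in predicted.columns:
            raise ValueError(f"yield trait {yld!r} absent from predictions")
        X = predicted.drop(columns=[yld])
        return stepwise_regression(
            predicted[yld], X,
            criterion=cfg.stepwise_criterion,
            corr_threshold=cfg.corr_threshold,
        )

    regression = stage("regression")(_regress)
    regression.summary_frame().to_csv(outdir / "regression.csv")
    pd.DataFrame(
        [
            {
                "r2": regression.r2,
                "adj_r2": regression.adj_r2,
                "f": regression.fvalue,
                "f_pvalue": regression.f_pvalue,
                "df_model": regression.df_model,
                "df_resid": regression.df_resid,
                "aic": regression.aic,
                "n": regression.n,
            }
        ]
    ).to_csv(outdir / "regression_stats.csv", index=False)
    out["regression"] = regression

    # --- classification ------------------------------------------------
    def _classify():
        rows = []
        summaries = []
        calls_by_env = {}
        yld_blues = blues[blues["trait"] == yld]
        for env in cfg.stress_envs:
            sub = yld_blues[yld_blues["environment"] == env]
            if sub.empty:
                continue
            series = sub.set_index("genotype")["value"]
            calls = classify(series, cfg.checks, environment=env)
            calls_by_env[env] = calls
            rows += [
                {"genotype": c.genotype, "environment": c.environment,
                 "value": c.value, "category": c.category}
                for c in calls
            ]
            s = category_summary(calls)
            s.insert(0, "environment", env)
            summaries.append(s)
        multi_calls = None
        if yld in predicted.columns:
            multi_calls = classify(predicted[yld].dropna(), cfg.checks, environment="multi")
            rows += [
                {"genotype": c.genotype, "environment": "multi",
                 "value": c.value, "category": c.category}
                for c in multi_calls
            ]
            s = category_summary(multi_calls)
            s.insert(0, "environment", "multi")
            summaries.append(s)
        consistent = (
            consistent_tolerant(calls_by_env) if len(calls_by_env) >= 2 else []
        )
        return pd.DataFrame(rows), pd.concat(summaries, ignore_index=True), consistent

    calls_df, calls_summary, consistent = stage("classification")(_classify)
    calls_df.to_csv(outdir / "classification.csv", index=False)
    calls_summary.to_csv(outdir / "classification_summary.csv", index=False)
    out["classification"] = calls_df
    out["classification_summary"] = calls_summary
    out["consistent_tolerant"] = consistent
    loglines.append(f"consistent_tolerant: {','.join(consistent) if consistent else '(none)'}")

    # --- selection index -----------------------------------------------
    def _index():
        spec = IndexSpec(traits=cfg.index_traits, d=cfg.index_gains)
        weights = compute_weights(predicted, spec)
        scores = score_accessions(predicted, weights)
        winners = beats_all_checks(
            scores, list(cfg.checks.tolerant), exclude=cfg.checks.susceptible
        )
        scores["beats_all_checks"] = scores["genotype"].isin(winners)
        return weights, scores, winners

    weights, scores, winners = stage("selection_index")(_index)
    scores.to_csv(outdir / "index_scores.csv", index=False)
    pd.DataFrame({"trait": weights.traits, "weight": weights.b}).to_csv(
        outdir / "index_weights.csv", index=False
    )
    out["index_weights"] = weights
    out["index_scores"] = scores
    out["index_winners"] = winners
    loglines.append(f"index_beats_all_checks: {len(winners)} accessions")

    if cfg.plots:
        from . import plots

        if yld in mta_results:
            plots.rank_bar(mta_results[yld], set(cfg.checks.all_checks),
                           outdir / "yield_blup_ranking.png")
            plots.index_scatter(mta_results[yld], scores, set(cfg.checks.all_checks),
                                outdir / "blup_vs_index.png")

    (outdir / "config.yaml").write_text(yaml.safe_dump(_config_dict(cfg), sort_keys=True))
    (outdir / "run_log.txt").write_text("\n".join(loglines) + "\n")
    return out
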