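"""Synthetic augmented-RCBD multi-environment trial generator.

Produces plot-level long-format phenotype records together with the ground
truth (per-genotype genetic values and the variance components used), so
every downstream stage of the pipeline can be tested against known answers
without any external data.

The default configuration emulates a 500-accession rice screening panel:
seven replicated checks (four drought-tolerant, three susceptible) in 10
blocks, three environments (irrigated Control, managed-stress ROS, natural
stress TPE), ten agronomic traits plus four physiological traits that are
recorded only under Control/ROS (or ROS alone for the visual stress scores).

Genetic effects are multivariate normal.  Between-trait and
cross-environment correlation are combined through a Kronecker-style
construction: one set of trait-correlated standard-normal sources per
environment, mapped per trait through the Cholesky factor of that trait's
environment-correlation matrix.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TraitSpec",
    "EnvSpec",
    "CheckSpec",
    "SimConfig",
    "TruthTable",
    "default_config",
    "simulate_met",
    "realized_summary",
    "TOLERANT_CHECKS",
    "SUSCEPTIBLE_CHECKS",
]

TOLERANT_CHECKS = ("Apo", "Norungan", "CO 53", "Anna (R) 4")
SUSCEPTIBLE_CHECKS = ("IR 64", "Jaya", "Pusa 44")

#: long labels for report tables
TRAIT_LABELS = {
    "DFF": "Days to fifty per cent flowering",
    "PH": "Plant height (cm)",
    "TP": "Tillers per plant",
    "NPT": "Number of productive tillers per plant",
    "PE": "Panicle exsertion",
    "PL": "Panicle length (cm)",
    "PW": "Panicle weight (g)",
    "HSW": "Hundred seed weight (g)",
    "SF": "Spikelet fertility (%)",
    "GY": "Grain yield (t/ha)",
    "RWC": "Relative water content (%)",
    "CCM": "Chlorophyll content index",
    "LR": "Leaf rolling",
    "LTD": "Leaf tip drying",
}


@dataclass
class TraitSpec:
    """One simulated trait.

    ``means``/``h2`` are keyed by environment; environments absent from
    ``means`` are not phenotyped for the trait.  ``genetic_sd`` is on the
    scale of the first (reference) environment and is rescaled in the other
    environments proportionally to the environment mean, so stress
    environments keep a comparable coefficient of genetic variation.
    ``residual_sd`` of ``None`` back-solves the residual SD from the target
    heritability; an explicit value (e.g. 0) overrides it in every
    environment.
    """

    name: str
    means: dict[str, float]
    h2: dict[str, float]
    genetic_sd: float
    block_sd: float
    residual_sd: float | None = None
    ordinal: bool = False
    bounds: tuple[float, float] = (1.0, 9.0)
    #: per-environment genetic SD overrides (otherwise scaled by env mean)
    genetic_sd_env: dict[str, float] | None = None

    @property
    def environments(self) -> list[str]:
        return list(self.means)

    def _multiplier(self, env: str) -> float:
        base = next(iter(self.means.values()))
        if base == 0:
            return 1.0
        return self.means[env] / base

    def genetic_sd_in(self, env: str) -> float:
        if self.genetic_sd_env and env in self.genetic_sd_env:
            return self.genetic_sd_env[env]
        return self.genetic_sd * abs(self._multiplier(env))

    def block_sd_in(self, env: str) -> float:
        base_env = next(iter(self.means))
        base_sd = self.genetic_sd_in(base_env)
        scale = self.genetic_sd_in(env) / base_sd if base_sd > 0 else 1.0
        return self.block_sd * scale

    def residual_sd_in(self, env: str) -> float:
        if self.residual_sd is not None:
            return self.residual_sd
        h2 = self.h2[env]
        vg = self.genetic_sd_in(env) ** 2
        return float(np.sqrt(vg * (1.0 - h2) / h2))


@dataclass
class EnvSpec:
    name: str
    stress: bool


@dataclass
class CheckSpec:
    """A replicated check; ``means[trait][env]`` overrides the environment
    mean (used to anchor grain yield of tolerant vs susceptible checks)."""

    name: str
    role: str  # "tolerant" | "susceptible"
    means: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("tolerant", "susceptible"):
            raise ValueError(f"check role must be tolerant/susceptible, got {self.role!r}")


@dataclass
class TruthTable:
    """Ground truth of a simulation run."""

    #: columns genotype, trait, environment, true_value (genetic deviation
    #: from the environment mean)
    genetic_values: pd.DataFrame
    #: columns environment, trait, vg, vblock, ve
    components: pd.DataFrame


@dataclass
class SimConfig:
    n_test: int
    n_blocks: int
    environments: list[EnvSpec]
    traits: list[TraitSpec]
    checks: list[CheckSpec]
    #: per-trait cross-environment genetic correlation (over the trait's
    #: own environments, in config environment order)
    genetic_corr_env: dict[str, np.ndarray]
    #: between-trait genetic correlation, aligned with ``traits`` order
    genetic_corr_trait: np.ndarray
    seed: int = 0
    dropout: float = 0.0

    def validate(self) -> None:
        if self.n_test < 1:
            raise ValueError("n_test must be >= 1")
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")
        if not self.checks:
            raise ValueError("at least one check is required")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        env_names = [e.name for e in self.environments]
        if len(set(env_names)) != len(env_names):
            raise ValueError("duplicate environment names")
        for tr in self.traits:
            if tr.genetic_sd < 0 or tr.block_sd < 0:
                raise ValueError(f"{tr.name}: SDs must be non-negative")
            if tr.residual_sd is not None and tr.residual_sd < 0:
                raise ValueError(f"{tr.name}: residual SD must be non-negative")
            if tr.genetic_sd_env and any(v < 0 for v in tr.genetic_sd_env.values()):
                raise ValueError(f"{tr.name}: genetic SDs must be non-negative")
            for env in tr.means:
                if env not in env_names:
                    raise ValueError(f"{tr.name}: unknown environment {env!r}")
                if tr.residual_sd is None:
                    h2 = tr.h2.get(env)
                    if h2 is None or not 0.0 < h2 <= 1.0:
                        raise ValueError(f"{tr.name}/{env}: h2 must be in (0, 1]")
            R = np.asarray(self.genetic_corr_env[tr.name], dtype=float)
            _check_corr(R, f"genetic_corr_env[{tr.name}]", len(tr.means))
        _check_corr(
            np.asarray(self.genetic_corr_trait, dtype=float),
            "genetic_corr_trait",
            len(self.traits),
        )

    def trait(self, name: str) -> TraitSpec:
        for tr in self.traits:
            if tr.name == name:
                return tr
        raise KeyError(name)

    def test_genotypes(self) -> list[str]:
        width = max(4, len(str(self.n_test)))
        return [f"RL {i:0{width}d}" for i in range(1, self.n_test + 1)]

    def to_yaml(self) -> str:
        data = {
            "n_test": self.n_test,
            "n_blocks": self.n_blocks,
            "seed": self.seed,
            "dropout": self.dropout,
            "environments": [{"name": e.name, "stress": e.stress} for e in self.environments],
            "traits": [
                {
                    "name": t.name,
                    "means": dict(t.means),
                    "h2": dict(t.h2),
                    "genetic_sd": t.genetic_sd,
                    "block_sd": t.block_sd,
                    "residual_sd": t.residual_sd,
                    "ordinal": t.ordinal,
                    "genetic_sd_env": t.genetic_sd_env,
                }
                for t in self.traits
            ],
            "checks": [
                {"name": c.name, "role": c.role, "means": c.means} for c in self.checks
            ],
            "genetic_corr_env": {k: np.asarray(v).tolist() for k, v in self.genetic_corr_env.items()},
            "genetic_corr_trait": np.asarray(self.genetic_corr_trait).tolist(),
        }
        return yaml.safe_dump(data, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        data = yaml.safe_load(_io.StringIO(text))
        cfg = cls(
            n_test=data["n_test"],
            n_blocks=data["n_blocks"],
            environments=[EnvSpec(**e) for e in data["environments"]],
            traits=[TraitSpec(**t) for t in data["traits"]],
            checks=[CheckSpec(**c) for c in data["checks"]],
            genetic_corr_env={k: np.asarray(v, dtype=float) for k, v in data["genetic_corr_env"].items()},
            genetic_corr_trait=np.asarray(data["genetic_corr_trait"], dtype=float),
            seed=data.get("seed", 0),
            dropout=data.get("dropout", 0.0),
        )
        cfg.validate()
        return cfg


def _check_corr(R: np.ndarray, label: str, size: int) -> None:
    if R.shape != (size, size):
        raise ValueError(f"{label}: expected {size}x{size}, got {R.shape}")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError(f"{label}: not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError(f"{label}: diagonal must be 1")
    if np.linalg.eigvalsh(R).min() < -1e-8:
        raise ValueError(f"{label}: not positive semi-definite")


def _psd_cholesky(R: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerant of semi-definite matrices."""
    R = np.asarray(R, dtype=float)
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        if w.min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


# --- default (Table-1 style) configuration ---------------------------------

# trait -> (per-env mean, per-env target H2, per-env plot CV%); the genetic
# SD in each environment is back-solved as (CV/100) * mean * sqrt(H2)
_DEFAULT_TRAITS: dict[str, tuple[dict, dict, dict]] = {
    "DFF": ({"Control": 85.26, "ROS": 84.78, "TPE": 72.89}, {"Control": 0.98, "ROS": 0.96, "TPE": 0.99},
            {"Control": 10.90, "ROS": 10.22, "TPE": 15.99}),
    "PH": ({"Control": 118.99, "ROS": 115.82, "TPE": 80.99}, {"Control": 0.90, "ROS": 0.95, "TPE": 0.85},
           {"Control": 16.41, "ROS": 22.32, "TPE": 17.52}),
    "TP": ({"Control": 16.63, "ROS": 8.86, "TPE": 6.38}, {"Control": 0.79, "ROS": 0.65, "TPE": 0.75},
           {"Control": 29.65, "ROS": 32.46, "TPE": 30.87}),
    "NPT": ({"Control": 16.84, "ROS": 8.12, "TPE": 6.13}, {"Control": 0.80, "ROS": 0.74, "TPE": 0.76},
            {"Control": 29.18, "ROS": 34.98, "TPE": 30.03}),
    "PE": ({"Control": 7.73, "ROS": 3.62, "TPE": 6.56}, {"Control": 0.78, "ROS": 0.92, "TPE": 0.90},
           {"Control": 26.59, "ROS": 76.58, "TPE": 38.12}),
    "PL": ({"Control": 23.92, "ROS": 23.30, "TPE": 19.48}, {"Control": 0.51, "ROS": 0.66, "TPE": 0.67},
           {"Control": 10.52, "ROS": 13.85, "TPE": 12.52}),
    "PW": ({"Control": 4.28, "ROS": 2.16, "TPE": 3.29}, {"Control": 0.90, "ROS": 0.97, "TPE": 0.85},
           {"Control": 17.75, "ROS": 52.37, "TPE": 17.98}),
    "HSW": ({"Control": 2.32, "ROS": 1.82, "TPE": 2.09}, {"Control": 0.92, "ROS": 0.95, "TPE": 0.91},
            {"Control": 14.67, "ROS": 24.88, "TPE": 18.56}),
    "SF": ({"Control": 87.80, "ROS": 54.48, "TPE": 76.30}, {"Control": 0.60, "ROS": 0.89, "TPE": 0.76},
           {"Control": 8.52, "ROS": 35.52, "TPE": 14.78}),
    "GY": ({"Control": 4.57, "ROS": 1.55, "TPE": 1.37}, {"Control": 0.88, "ROS": 0.85, "TPE": 0.80},
           {"Control": 31.47, "ROS": 61.14, "TPE": 43.06}),
    "RWC": ({"Control": 88.97, "ROS": 75.56}, {"Control": 0.55, "ROS": 0.73},
            {"Control": 6.07, "ROS": 10.47}),
    "CCM": ({"Control": 16.95, "ROS": 9.24}, {"Control": 0.69, "ROS": 0.79},
            {"Control": 24.81, "ROS": 37.38}),
    "LR": ({"ROS": 4.67}, {"ROS": 0.69}, {"ROS": 28.81}),
    "LTD": ({"ROS": 3.15}, {"ROS": 0.87}, {"ROS": 55.55}),
}

_ORDINAL_TRAITS = {"PE", "LR", "LTD"}

# cross-environment correlations per trait (upper-triangle values in
# Control/ROS/TPE order, restricted to the trait's environments)
_DEFAULT_ENV_CORR: dict[str, list[float]] = {
    "DFF": [0.82, 0.68, 0.60],
    "PH": [0.68, 0.74, 0.67],
    "TP": [0.22, 0.10, 0.21],
    "NPT": [0.21, 0.13, 0.20],
    "PE": [0.34, 0.53, 0.26],
    "PL": [0.62, 0.41, 0.20],
    "PW": [0.42, 0.64, 0.20],
    "HSW": [0.65, 0.89, 0.57],
    "SF": [0.33, 0.88, 0.29],
    "GY": [0.26, 0.38, 0.00],
    "RWC": [0.76],
    "CCM": [0.45],
    "LR": [],
    "LTD": [],
}

# published grain-yield reductions of the check groups used to anchor
# tolerant vs susceptible check means under stress
_CHECK_GY_CONTROL = {
    "Apo": 5.2,
    "Norungan": 5.0,
    "CO 53": 4.8,
    "Anna (R) 4": 4.3,
    "IR 64": 4.9,
    "Jaya": 4.6,
    "Pusa 44": 4.4,
}
_CHECK_GY_REDUCTION = {
    "tolerant": {"ROS": 0.3646, "TPE": 0.6454},
    "susceptible": {"ROS": 0.7656, "TPE": 0.8200},
}


def _env_corr_matrix(trait: str, n_env: int) -> np.ndarray:
    vals = _DEFAULT_ENV_CORR[trait]
    R = np.eye(n_env)
    k = 0
    for i in range(n_env):
        for j in range(i + 1, n_env):
            R[i, j] = R[j, i] = vals[k]
            k += 1
    return R


def _default_trait_corr(names: list[str]) -> np.ndarray:
    t = len(names)
    idx = {n: i for i, n in enumerate(names)}
    R = np.full((t, t), 0.10)
    np.fill_diagonal(R, 1.0)

    def put(a: str, b: str, v: float) -> None:
        if a in idx and b in idx:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = v

    put("TP", "NPT", 0.90)
    put("PL", "PW", 0.40)
    put("PW", "SF", 0.30)
    put("LR", "LTD", 0.47)
    for other, v in [
        ("PW", 0.50), ("SF", 0.34), ("PL", 0.30), ("HSW", 0.30), ("PH", 0.26),
        ("NPT", 0.20), ("PE", 0.17), ("TP", 0.14), ("DFF", -0.15),
        ("LR", -0.20), ("LTD", 0.18), ("RWC", 0.15), ("CCM", 0.15),
    ]:
        put("GY", other, v)
    # shrink toward the identity if the hand-set entries broke definiteness
    alpha = 1.0
    while np.linalg.eigvalsh(alpha * R + (1 - alpha) * np.eye(t)).min() < 1e-4:
        alpha -= 0.05
    return alpha * R + (1 - alpha) * np.eye(t)


def default_config(
    n_test: int = 500,
    n_blocks: int = 10,
    seed: int = 0,
    traits: list[str] | None = None,
    dropout: float = 0.0,
) -> SimConfig:
    """Configuration emulating the default 500-accession screening trial.

    ``traits`` restricts the simulated trait set (by short name) which is
    convenient for fast recovery experiments.
    """
    names = list(_DEFAULT_TRAITS) if traits is None else list(traits)
    unknown = set(names) - set(_DEFAULT_TRAITS)
    if unknown:
        raise ValueError(f"unknown trait names: {sorted(unknown)}")
    envs = [EnvSpec("Control", False), EnvSpec("ROS", True), EnvSpec("TPE", True)]
    trait_specs = []
    env_corr = {}
    for name in names:
        means, h2, cv = _DEFAULT_TRAITS[name]
        gsd_env = {
            env: round(cv[env] / 100.0 * means[env] * float(np.sqrt(h2[env])), 4)
            for env in means
        }
        base = next(iter(means))
        trait_specs.append(
            TraitSpec(
                name=name,
                means=dict(means),
                h2=dict(h2),
                genetic_sd=gsd_env[base],
                block_sd=0.2 * gsd_env[base],
                genetic_sd_env=gsd_env,
                ordinal=name in _ORDINAL_TRAITS,
            )
        )
        env_corr[name] = _env_corr_matrix(name, len(means))
    checks = []
    for cname in TOLERANT_CHECKS + SUSCEPTIBLE_CHECKS:
        role = "tolerant" if cname in TOLERANT_CHECKS else "susceptible"
        gy_means = {}
        if "GY" in names:
            c0 = _CHECK_GY_CONTROL[cname]
            gy_means = {
                "GY": {
                    "Control": c0,
                    "ROS": round(c0 * (1 - _CHECK_GY_REDUCTION[role]["ROS"]), 3),
                    "TPE": round(c0 * (1 - _CHECK_GY_REDUCTION[role]["TPE"]), 3),
                }
            }
        checks.append(CheckSpec(name=cname, role=role, means=gy_means))
    cfg = SimConfig(
        n_test=n_test,
        n_blocks=n_blocks,
        environments=envs,
        traits=trait_specs,
        checks=checks,
        genetic_corr_env=env_corr,
        genetic_corr_trait=_default_trait_corr(names),
        seed=seed,
        dropout=dropout,
    )
    cfg.validate()
    return cfg


def simulate_met(config: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate one multi-environment augmented-RCBD trial.

    Observed value = environment mean + genetic effect + block effect +
    residual; checks carry deterministic genetic offsets (their configured
    means) while test entries are drawn from the correlated multivariate
    normal.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    envs = [e.name for e in config.environments]
    n_env = len(envs)
    traits = config.traits
    n_trait = len(traits)
    n_test = config.n_test
    tests = config.test_genotypes()

    # genetic effects: trait-correlated sources per environment, mapped per
    # trait through that trait's environment correlation factor
    Lt = _psd_cholesky(np.asarray(config.genetic_corr_trait, dtype=float))
    sources = np.stack(
        [rng.standard_normal((n_test, n_trait)) @ Lt.T for _ in range(n_env)], axis=2
    )
    g_std = np.full((n_test, n_trait, n_env), np.nan)  # standardized effects
    for ti, tr in enumerate(traits):
        t_envs = [e for e in envs if e in tr.means]
        Le = _psd_cholesky(np.asarray(config.genetic_corr_env[tr.name], dtype=float))
        u = sources[:, ti, : len(t_envs)] @ Le.T
        for j, env in enumerate(t_envs):
            g_std[:, ti, envs.index(env)] = u[:, j]

    # field layout: one block per test entry per environment
    block_of = {}
    for env in envs:
        perm = rng.permutation(n_test)
        assign = np.empty(n_test, dtype=int)
        for b, chunk in enumerate(np.array_split(perm, config.n_blocks), start=1):
            assign[chunk] = b
        block_of[env] = assign

    check_names = [c.name for c in config.checks]
    n_check = len(check_names)
    frames = []
    truth_rows = []
    comp_rows = []
    for env in envs:
        ei = envs.index(env)
        for ti, tr in enumerate(traits):
            if env not in tr.means:
                continue
            mean = tr.means[env]
            gsd = tr.genetic_sd_in(env)
            bsd = tr.block_sd_in(env)
            rsd = tr.residual_sd_in(env)
            beff = rng.normal(0.0, bsd, config.n_blocks) if bsd > 0 else np.zeros(config.n_blocks)
            g_test = g_std[:, ti, ei] * gsd
            eps_test = rng.normal(0.0, rsd, n_test) if rsd > 0 else np.zeros(n_test)
            eps_check = (
                rng.normal(0.0, rsd, n_check * config.n_blocks)
                if rsd > 0
                else np.zeros(n_check * config.n_blocks)
            )

            v_test = mean + g_test + beff[block_of[env] - 1] + eps_test
            check_off = np.array(
                [c.means.get(tr.name, {}).get(env, mean) - mean for c in config.checks]
            )
            blocks_rep = np.repeat(np.arange(1, config.n_blocks + 1), n_check)
            checks_rep = np.tile(np.arange(n_check), config.n_blocks)
            v_check = mean + check_off[checks_rep] + beff[blocks_rep - 1] + eps_check

            if tr.ordinal:
                lo, hi = tr.bounds
                v_test = np.clip(np.rint(v_test), lo, hi)
                v_check = np.clip(np.rint(v_check), lo, hi)

            frames.append(
                pd.DataFrame(
                    {
                        "environment": env,
                        "block": np.concatenate([block_of[env], blocks_rep]),
                        "genotype": tests + [check_names[i] for i in checks_rep],
                        "is_check": [False] * n_test + [True] * len(checks_rep),
                        "trait": tr.name,
                        "value": np.concatenate([v_test, v_check]),
                    }
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "genotype": tests + check_names,
                        "trait": tr.name,
                        "environment": env,
                        "true_value": np.concatenate([g_test, check_off]),
                    }
                )
            )
            comp_rows.append(
                {
                    "environment": env,
                    "trait": tr.name,
                    "vg": gsd**2,
                    "vblock": bsd**2,
                    "ve": rsd**2,
                }
            )

    records = pd.concat(frames, ignore_index=True)
    if config.dropout > 0:
        mask = rng.random(len(records)) < config.dropout
        records.loc[mask, "value"] = np.nan
    truth = TruthTable(
        genetic_values=pd.concat(truth_rows, ignore_index=True),
        components=pd.DataFrame(comp_rows),
    )
    return records, truth


def realized_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per environment x trait: mean, min, max, CV% of plot values.

    CV% = 100 * SD / mean, reported as missing when the mean is 0.
    """
    if records.empty:
        raise ValueError("no records supplied")

    def _agg(g: pd.Series) -> pd.Series:
        vals = g.dropna()
        mean = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        cv = 100.0 * sd / mean if mean != 0 else np.nan
        return pd.Series(
            {"mean": mean, "min": vals.min(), "max": vals.max(), "cv_pct": cv}
        )

    out = (
        records.groupby(["environment", "trait"], sort=True)["value"]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    return out
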