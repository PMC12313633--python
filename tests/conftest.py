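"""Shared fixtures and independent oracles.

The oracle functions here deliberately use dense linear algebra
(inverse-of-V GLS, slogdet-based REML criterion) so they share no code path
with the factor-level implementation they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def one_hot(labels):
    """Indicator matrix with columns in np.unique order."""
    levels, codes = np.unique(np.asarray(labels), return_inverse=True)
    X = np.zeros((len(codes), len(levels)))
    X[np.arange(len(codes)), codes] = 1.0
    return levels, X


def dense_gls_oracle(y, fixed, random, v_random, v_error):
    """GLS fixed estimates and conditional-mean random predictions via a
    dense inverse of V = ve*I + vu*ZZ'."""
    y = np.asarray(y, dtype=float)
    flevels, X = one_hot(fixed if fixed is not None else np.zeros(len(y), int))
    rlevels, Z = one_hot(random)
    V = v_error * np.eye(len(y)) + v_random * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    u = v_random * Z.T @ Vi @ (y - X @ beta)
    # standard errors / PEV from the joint dense formulation
    se_beta = np.sqrt(np.diag(np.linalg.inv(XtViX)))
    return flevels, beta, se_beta, rlevels, u


def dense_reml_loglik_oracle(y, fixed, random, v_random, v_error):
    """REML log-likelihood by brute-force determinants and quadratic form."""
    y = np.asarray(y, dtype=float)
    flevels, X = one_hot(fixed if fixed is not None else np.zeros(len(y), int))
    _, Z = one_hot(random)
    n, p = X.shape
    V = v_error * np.eye(n) + v_random * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ld_v + ld_x + y @ P @ y)


def random_mixed_instance(rng, max_obs=50):
    """A random small mixed-model dataset: labels, response, true variances."""
    n_fixed = rng.integers(2, 6)
    n_random = rng.integers(2, 6)
    n = int(rng.integers(max(n_fixed + n_random + 2, 10), max_obs + 1))
    while True:
        fixed = rng.integers(0, n_fixed, n)
        random = rng.integers(0, n_random, n)
        if len(np.unique(fixed)) >= 2 and len(np.unique(random)) >= 2:
            break
    vu = float(rng.uniform(0.1, 3.0))
    ve = float(rng.uniform(0.1, 3.0))
    beta = rng.normal(0, 2, n_fixed)
    u = rng.normal(0, np.sqrt(vu), n_random)
    y = beta[fixed] + u[random] + rng.normal(0, np.sqrt(ve), n)
    return y, np.char.add("f", fixed.astype(str)), np.char.add("r", random.astype(str)), vu, ve


def augmented_toy(seed=0, n_blocks=2, n_checks=2, n_tests=4):
    """Tiny augmented-design dataset: checks in every block, tests in one."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(1, n_blocks + 1):
        for c in range(n_checks):
            rows.append(("E1", b, f"check{c}", True))
    for i in range(n_tests):
        rows.append(("E1", 1 + i % n_blocks, f"test{i}", False))
    df = pd.DataFrame(rows, columns=["environment", "block", "genotype", "is_check"])
    df["trait"] = "Y"
    geno_eff = {g: rng.normal(0, 1) for g in df["genotype"].unique()}
    block_eff = {b: rng.normal(0, 0.5) for b in df["block"].unique()}
    df["value"] = [
        10 + geno_eff[g] + block_eff[b] + rng.normal(0, 0.3)
        for g, b in zip(df["genotype"], df["block"])
    ]
    return df


@pytest.fixture(scope="session")
def small_sim():
    """One small but full simulated trial shared across tests."""
    from metsel import default_config, simulate_met

    cfg = default_config(n_test=120, n_blocks=5, seed=42)
    records, truth = simulate_met(cfg)
    return cfg, records, truth
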