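# metsel

Two-stage mixed-model analysis and multi-trait selection for augmented
multi-environment trials (METs), built for large unreplicated germplasm
screening panels with replicated checks.

Given plot-level phenotypes from an augmented randomized complete block
design (unreplicated test entries plus checks repeated in every block)
across one or more environments, `metsel` computes:

- **Stage 1 (single-trial analysis):** genotype BLUEs adjusted for block
  effects (genotype fixed, block random), broad-sense heritability
  H² = vg/(vg+ve) from a companion genotype-random fit, and
  mean/range/CV% trial summaries.
- **Stage 2 (multi-trial analysis):** across-environment BLUPs per
  genotype (genotype random, environment fixed) on the stage-1 BLUEs,
  with yield rankings and superiority fractions versus the predicted mean
  or the checks.
- **Trait statistics:** stress-induced reduction metrics (of-means and
  per-genotype modes), between-environment correlations per trait,
  trait correlations on predicted values, and bidirectional AIC stepwise
  regression of yield on secondary traits.
- **Classification:** check-anchored drought-tolerance categories
  (tolerant / moderately resistant / moderately susceptible / highly
  susceptible) per stress environment and across environments.
- **Selection index:** desired-gain weights solving G·b = d on z-scored
  traits, accession scores/ranks, and the set of accessions beating every
  tolerant check.
- **Synthetic data:** a generator for the full trial structure
  (default: 500 test entries + 7 checks × 10 blocks × 3 environments,
  14 traits) with known ground truth, used throughout the test suite.

The mixed-model core implements REML for the one-random-factor model by
profiling the criterion down to the variance ratio and solving Henderson's
mixed-model equations on factor-level sufficient statistics; it is
validated against dense GLS / determinant-based oracles in the tests.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact reduction
arithmetic, classification percentages, oracle equivalence, 20-seed
parameter recovery at full panel scale, end-to-end determinism); the rest
are per-module unit and property tests.

## CLI

```sh
# full pipeline on a simulated default trial
metsel run-all --seed 1 --out results/run1

# or stage by stage on CSV files
metsel simulate --seed 1 --n-test 500 --out pheno.csv
metsel sta --input pheno.csv --out blues.csv --summary-out summary.csv
metsel mta --input blues.csv --out mta.csv
metsel reduce --input blues.csv --out reductions.csv
metsel correlate --input blues.csv --out env_corr.csv
metsel regress --input mta.csv --out regression.csv
metsel classify --input blues.csv --env ROS --out calls_ros.csv
metsel classify --input mta.csv --out calls_multi.csv
metsel index --input mta.csv --traits GY SF DFF --gains 1 0.5 0 --out index.csv
```

`metsel run-all --config cfg.yaml` reads a YAML pipeline configuration
(input path or simulation size, environment roles, check lists and
anchors, index traits and desired gains, stepwise settings); see
`metsel.pipeline.PipelineConfig` for the fields.

Phenotype CSVs are long format with header
`environment,block,genotype,is_check,trait,value` (empty value = missing).

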