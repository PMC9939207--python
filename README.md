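# survscore

Survival-rate risk scoring and additive-interaction analysis for matched
surgical-cancer cohorts: cohort synthesis, metabolic-syndrome derivation,
propensity matching, stratified Cox analysis with additive-interaction
decomposition (RERI / AP / SI), survival-tree risk-score construction, and
calibration / discrimination validation.

## Layout

| module | role |
|---|---|
| `survscore.simulate` | synthetic cohorts with a configurable additive smoking x metabolic-syndrome hazard interaction |
| `survscore.derive` | metabolic-syndrome components (BMI / glucose / blood-pressure / lipid thresholds) and NLR / PLR / LMR / MRR blood ratios |
| `survscore.propensity` | logistic propensity model, greedy 1:1 nearest-neighbor matching on the logit (0.2 SD caliper default), SMD balance diagnostics |
| `survscore.survival` | Kaplan-Meier + Greenwood, two-sample log-rank, Newton Cox PH with Efron/Breslow ties, Schoenfeld PH score test |
| `survscore.interaction` | per-stratum HRs, between-stratum Z-test, joint-exposure cell HRs, RERI / AP / SI with delta-method (or bootstrap) CIs |
| `survscore.scoring` | survival-tree cut-offs, survival-percent/10 integer scores, total score, quantile groups, score-mortality Cox estimates |
| `survscore.validation` | Hosmer-Lemeshow calibration, rank-based AUROC, k-fold cross-validated AUROC with bootstrap CI |
| `survscore.pipeline` / `survscore.cli` | configuration-driven orchestration and the `survscore` command |

The cohort CSV schema ships as `src/survscore/data/cohort_schema.tsv`
(`survscore.schema_table()` returns it as a data frame).

## CLI

```bash
survscore simulate --n 2000 --seed 1 --out cohort.csv
survscore derive   --in cohort.csv --out derived.csv
survscore match    --in cohort.csv --out-pairs pairs.csv --out-balance balance.tsv
survscore interact --in cohort.csv --out interaction.json
survscore run-all  --config run.cfg --out-dir out/
```

`run.cfg` is a flat `key = value` file; simulation keys take a `sim.`
prefix (e.g. `sim.n_subjects = 5000`, `sim.hr11 = 4.08`); see
`survscore.pipeline.AnalysisConfig` for all keys. `run-all` writes
matched-pairs CSV, balance TSV, interaction JSON, score-table TSV, scored
cohort CSV, validation JSON and a run log; outputs are byte-identical across
re-runs of the same config and carry the config hash and seeds.

## Notes

* Time is in months throughout; identical recorded times are genuine ties
  (Efron tie handling by default); 95% CIs use the multiplier 1.959964.
* The total risk score is protective: higher score means lower predicted
  mortality. AUROC helpers expose a `higher_is_event` orientation flag.
* Survival-tree split p-values are Sidak-adjusted for the number of candidate
  cut points by default (`p_adjust="none"` for raw log-rank p-values).
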