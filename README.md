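# voiplan

Resource-rational value-of-information analysis for non-instrumental
information seeking, as a tested, reproducible pipeline:

- **`voi_core`** — the deterministic planning model. An agent facing an
  uncertain future outcome chooses between paying for information, planning
  in uncertainty, or living in denial; the value of information
  `VOI = U_info − max(U_plan, U_leisure)` drives an ordered-logistic
  emission onto a 5-point Likert scale.
- **`synthetic_data`** — fully synthetic studies: truncated-normal agents,
  the 2 × 5 × 3 factorial design grid (win/lose $1000 × five probabilities ×
  three information costs), Likert trial tables, anxiety factor scores with
  planted linear associations to the true parameters, and discretized
  41-item questionnaire tables.
- **`questionnaire_scoring`** — STAIT (20 items, 9 reverse-coded) and
  STICSAT (21 items) coding to 1–4, and Bartlett weighted-least-squares
  factor scores for four oblique trait-anxiety factors against a supplied
  loading configuration.
- **`hierarchical_inference`** — hierarchical Bayesian fits of the planning
  model (full / no-scaling / shared-C_info variants) with a self-contained
  No-U-Turn sampler (dual-averaging step size, windowed diagonal mass
  adaptation; the log-density gradient is analytic and numba-compiled), plus
  PSIS-LOO model comparison via arviz.
- **`validation`** — posterior predictive datasets from per-subject
  posterior means and parameter-recovery reports (Pearson r with
  bootstrapped 95% CIs).
- **`association_analysis`** — mixed-effects ordered-logistic regression of
  responses on design variables and factor scores (random subject intercept,
  maximum likelihood with Gauss–Hermite quadrature) and standardized linear
  regressions of model variables/parameters on the four factor scores.
- **`pipeline_cli`** — `voiplan` command-line pipeline with JSON run
  manifests and per-stage seeding.

## Command-line pipeline

All commands accept `--seed` and `--out-dir`; every stage writes a JSON
manifest recording its config hash, inputs, outputs and diagnostics.

```sh
# synthetic study: trials, questionnaires, factor scores, ground truth
voiplan simulate --seed 1 --n-subjects 40 --out-dir out

# Bartlett factor scores from questionnaire items
voiplan score --items out/questionnaires.csv --loadings out/loadings.yaml --out-dir out

# hierarchical model fit (full / no_scaling / shared_Cinfo)
voiplan fit --trials out/trials.csv --variant full --seed 1 --out-dir out

# PSIS-LOO comparison of the three variants
voiplan compare --trials out/trials.csv --seed 1 --out-dir out

# parameter recovery against the simulation ground truth
voiplan recover --trials out/trials.csv --truth out/agents_true.csv --seed 1 --out-dir out

# posterior predictive dataset on the full design grid
voiplan ppc --trials out/trials.csv --seed 1 --out-dir out

# ordinal mixed regression + parameter regressions
voiplan analyze --trials out/trials.csv --scores out/factor_scores_true.csv \
    --subject-summary out/subject_summary.csv --out-dir out
```

Sampler defaults follow the study configuration: 500 warmup samples and
1000 iterations over 4 chains (2000 retained draws per parameter);
override with `--chains/--iter/--warmup`.

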