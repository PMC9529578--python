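# itakit

Penalized logistic regression with knee-point selection and **iterative
thematic analysis (ITA)** for rare binary outcomes in high-dimensional
survey data.

## The problem

Large household surveys (DHS-style recode files) carry thousands of
categorical questions, while outcomes of interest — such as current IUD use
among married women, at roughly 1–2% prevalence — are rare.  Hypothesis-driven
regression cannot screen that variable space, and p-values from penalized
fits are anti-conservative.  ITA is an exploratory alternative: machine
selection of variables, human (here: theme-map-driven) grouping of the
selection into substantive themes, and iterated elimination of the dominant
theme so that weaker constructs can surface.

## The method

One ITA iteration, on a one-hot-encoded design matrix `X` with binary
outcome `y`:

1. **Lasso reduction.** Maximize the penalized Bernoulli log-likelihood
   `ℓ(θ) = Σᵢ −log(1+e^{−ηᵢ}) − Σ_{yᵢ=0} ηᵢ − λ‖θ‖₁` with `η = Xθ + b`,
   columns standardized and the intercept unpenalized; `λ` is tuned by
   5-fold stratified cross-validation maximizing held-out log-likelihood.
   Nonzero coefficients define the support.
2. **Ridge refit.** On the support, maximize `ℓ(θ) − λ‖θ‖₂²` (again CV-tuned)
   to obtain stable coefficient magnitudes under collinearity.
3. **Knee selection.** Sort coefficients high-to-low and cut the curve at
   its point of maximum curvature (the Kneedle procedure); variables
   strictly above the knee are the iteration's findings.
4. **Theme identification.** Group the findings by an expert-supplied theme
   map; a theme is valid when it holds at least `max(2, ⌈5% · |selected|⌉)`
   members.  Unthemed findings are reported individually.
5. **Theme elimination.** Drop the top-scoring valid theme (max member
   |coefficient| by default); a variable belonging to several themes leaves
   only when its last theme falls.  Repeat until an iteration yields no new
   variables, three consecutive iterations yield no new theme, or no valid
   theme remains.

Each iteration is scored on a single stratified 80/20 train/test split by
ROC-AUC and the balanced error rate `BER = ½(FN/(TP+FN) + FP/(TN+FP))`.
A four-hidden-layer feed-forward network trained on the lasso support, with
permutation importance passed through the same knee detector, provides a
non-linear cross-check of the ridge selection.

Because the motivating microdata are access-restricted, the package ships a
synthetic survey generator (`itakit.synthetic`) that plants theme-structured
effects, correlated question blocks, redundant recodings and a calibrated
rare outcome, so every stage is testable against known ground truth.

## Worked example

```python
from itakit import (SyntheticConfig, generate_survey, default_catalog,
                    build_design_matrix, ThemeMap, ITAConfig, run_ita)

survey = generate_survey(SyntheticConfig(seed=1))     # 20,000 respondents
table = survey.table.assign(outcome=survey.outcome)   # prevalence ~2%
matrix = build_design_matrix(table, default_catalog(survey))
result = run_ita(matrix, ThemeMap(survey.true_theme_map), ITAConfig(seed=1))

print(result.stop_reason, result.n_iterations, len(result.all_themes))
m1 = result.iterations[0].metrics
print(f"round 1: AUC {m1.auc:.3f}  BER {m1.ber:.3f}")
```

prints

```
no_new_variables 2 8
round 1: AUC 0.963  BER 0.121
```

All eight planted themes were valid in round 1 (the planted signal is
strong, so the knee admits most true variables at once); the strongest theme
was dropped, round 2 selected no variable unseen before, and the loop
stopped.  Round-1 AUC 0.963 means a randomly drawn user outscores a randomly
drawn non-user 96.3% of the time on the held-out 4,000 respondents; BER
0.121 averages the two per-class error rates at the balanced decision
threshold chosen on the training data.

The same pipeline is scriptable from the shell:

```bash
ita simulate --out data/ --seed 1
ita preprocess --table data/table.csv --catalog data/catalog.yaml --out matrix/
ita run --matrix matrix/ --themes data/themes.yaml --seed 1 --out run1/
```

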