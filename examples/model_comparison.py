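"""Six-model AIC comparison under two generating regimes.

Fits the 4-class mixture, the 2-class (concordant-only) mixture, the two
unidirectional direction-of-causation models, the bidirectional model and the
correlated-factors (standard bivariate ACE) model to (i) a heterogeneous
sample containing all four causal classes and (ii) a homogeneous sample where
X causes Y in every pair.  The minimum-AIC row identifies the preferred model.
"""
from mixdoc import (
    ClassLabel,
    MixingProportions,
    ScenarioConfig,
    run_model_comparison,
)

heterogeneous = ScenarioConfig(n_mz=1000, n_dz=1000)
table = run_model_comparison(heterogeneous, seed=7, n_starts=2)
print("heterogeneous generation (all four causal classes present):")
print(table.rows[["variant", "df", "minus2LL", "aic", "delta_aic"]]
      .to_string(index=False))
print(f"-> preferred model: {table.best_variant}\n")

homogeneous = ScenarioConfig(
    n_mz=1000, n_dz=1000,
    proportions=MixingProportions(labels=ClassLabel.causal_classes(),
                                  mz=(1, 0, 0, 0), dz=(1, 0, 0, 0)),
    delta_x=0.0, delta_y=0.0,
)
table = run_model_comparison(homogeneous, seed=9, n_starts=2)
print("homogeneous generation (X causes Y in every pair):")
print(table.rows[["variant", "df", "minus2LL", "aic", "delta_aic"]]
      .to_string(index=False))
print(f"-> preferred model: {table.best_variant}")
print()
print("Under heterogeneity the mixture's extra classes earn their parameters")
print("(large AIC margin); under homogeneity they do not, and a single-class")
print("model is preferred.")
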