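"""Simulate a heterogeneous twin sample and fit the 4-class mixture.

Generates 1000 MZ + 1000 DZ twin pairs in which the causal direction between
traits X and Y differs across latent classes (equal 25% class weights,
direction-class mean offsets of 1.5 on both traits), fits the mixDoC model,
and prints the recovered structure.
"""
from mixdoc import ModelSpec, ScenarioConfig, Variant, fit, simulate

config = ScenarioConfig(n_mz=1000, n_dz=1000, delta_x=1.5, delta_y=1.5, seed=11)
data = simulate(config)
print(f"simulated {data.n_pairs} twin pairs "
      f"({data.n_pairs_by_zygosity()})")

result = fit(data, ModelSpec(variant=Variant.MIX4), n_starts=2, seed=1)
print(result.to_report())
print()
print("Reading the output: b_yx and b_xy are the causal effects inside the")
print("X->Y and Y->X classes (truth 0.5 each); mu_*_YX - mu_*_XY recovers the")
print("1.5 mean offset separating the causal subpopulations; the omega_* rows")
print("are per-zygosity class weights (truth 0.25 each, discordant classes")
print("tied); the relative entropy summarises how sharply pairs are assigned")
print("to classes (1 = certain, 0 = uninformative).")
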