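"""Classification entropy as a function of class-mean separation.

For three levels of the phenotypic mean difference between the X->Y and Y->X
subpopulations, fits the 4-class mixture to a few replications and reports the
relative entropy index of the posterior classification.
"""
import dataclasses

from mixdoc import ScenarioConfig, run_entropy_sweep, sweep_frame

base = ScenarioConfig(n_mz=1000, n_dz=1000)
grid = [dataclasses.replace(base, delta_x=d, delta_y=d)
        for d in (0.1, 0.75, 1.5)]
results = run_entropy_sweep(grid, n_reps=3, seed=5, n_starts=1,
                            swept_fields=("delta_x", "delta_y"))
print(sweep_frame(results).to_string(index=False))
print()
print("mean_entropy is averaged over per-replication fits;")
print("entropy_at_averaged_estimates evaluates a fresh dataset at the")
print("replication-averaged parameter estimates.  Larger mean separation")
print("between the causal subpopulations yields sharper classification.")
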