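"""Estimate detection power over a small grid of simulation settings.

Power is the fraction of simulated datasets in which exactly the two
disease loci are selected with no false positives; the relaxed variant
allows up to two false positives.  Ten replicates per cell keep this demo
quick; the study-scale experiment uses 50.
"""

from stsbn import run_power_experiment

grid = [(0.3, 0.5, 0.2), (0.3, 0.5, 0.5)]  # (lambda, r2, maf)
table = run_power_experiment(model=1, grid=grid, reps=10, seed=2)
print(table.to_string(index=False))
# power_exact: both loci, zero extras; power_relaxed: both loci, <= 2 extras.
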