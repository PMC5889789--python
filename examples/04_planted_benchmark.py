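"""Benchmark community recovery on planted-partition networks.

Sweeps edge-noise levels at fixed within/between connection probabilities
and reports how reliably consensus clustering recovers the planted three
communities (mean adjusted Rand index over replicates).
"""

import efsubtype as ef

sweep = ef.robustness_sweep(
    p_within_values=[0.9],
    p_between_values=[0.1],
    noise_values=[0.0, 1.0, 2.0, 4.0],
    n_nodes=120,
    n_communities=3,
    reps=5,
    runs=50,
    seed=0,
)
print(sweep.to_string(index=False))
print()
print(
    "mean_ari = 1 means exact recovery of the planted communities; recovery\n"
    "degrades as the edge-weight noise SD grows relative to the unit edge\n"
    "weight, mapping the regime where the detection is reliable."
)
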