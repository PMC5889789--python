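"""Simulate a questionnaire cohort and recover its subgroups.

Draws 3 x 80 children from the default three-subtype profile model
(cognitive-control, learning, conduct), builds the child-by-child Pearson
correlation network on age-residualized z-scores, and runs signed-modularity
consensus community detection.
"""

import numpy as np

import efsubtype as ef

cohort = ef.generate_cohort(ef.CohortSpec(n_per_group=80, seed=1))
residuals = ef.residualize_age(ef.filter_validity(cohort, exclude_negative=True))
network = ef.build_network(residuals, method="pearson")
result = ef.consensus_cluster(network, runs=100, tau=0.3, seed=1)

partition = result.partition
truth = np.unique(
    cohort.loc[~cohort["negative_impression"], "group_truth"], return_inverse=True
)[1]
ari = ef.adjusted_rand(partition.labels, truth)

print(f"children clustered : {network.n_nodes}")
print(f"communities found  : {partition.n_communities} (planted: 3)")
print(f"community sizes    : {partition.sizes().tolist()}")
print(f"quality index Q    : {partition.q_value:.3f}")
print(f"consensus rounds   : {result.n_rounds}")
print(f"ARI vs planted     : {ari:.3f}")
print()
print(
    "Q is the signed modularity of the consensus partition on the original\n"
    "correlation network (higher = better-separated subgroups); the ARI\n"
    "measures agreement with the generating groups (1 = exact recovery)."
)
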