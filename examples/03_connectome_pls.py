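"""Link group membership to connectome node degree with PLS.

Generates synthetic FA-weighted connectomes for two groups with degree
effects implanted on four regions per group, reduces them to node-degree
features, and fits a PLS model of group membership evaluated by a
permutation test, cross-validated RMSE and bootstrap-ratio loadings.
"""

import numpy as np

import efsubtype as ef
from efsubtype.pls import node_degree
from efsubtype.synthetic import ConnectomeSpec

spec = ConnectomeSpec(seed=3)  # 2 x 30 participants, 34 regions, +8 edges
conn = ef.generate_connectomes(spec)
degrees = node_degree(conn, threshold=0.0)
x = degrees.to_numpy(dtype=float)

model = ef.fit_pls(x, conn.groups, max_components=2)
n_retained = max(ef.retain_components(model.y_explained, floor=5.0), 1)
rmse, rmse_null, p_perm = ef.evaluate_split(
    x, conn.groups, train_frac=0.6, n_perm=199, seed=3, max_components=2
)
cv_mean, cv_se = ef.crossval_rmse(x, conn.groups, k_folds=10, seed=3)
bsr = ef.bootstrap_loadings(
    x, conn.groups, n_boot=500, seed=3, max_components=2, reference=model
)
top = ef.top_loading_report(bsr[:, :n_retained], conn.node_labels)

print(f"explained variance : {np.round(model.y_explained, 2).tolist()} %")
print(f"components retained: {n_retained} (>= 5% floor)")
print(f"test RMSE          : {rmse:.3f} (label-permuted null {rmse_null:.3f})")
print(f"permutation p      : {p_perm:.4f}")
print(f"10-fold CV RMSE    : {cv_mean:.3f} (SE {cv_se:.3f})")
print()
flagged = top[top["significant"]]
effect = sorted(set(spec.effect_nodes[0]) | set(spec.effect_nodes[1]))
print(f"implanted effect regions: {[conn.node_labels[i] for i in effect]}")
print("top-quartile |BSR| regions flagged reliable (|BSR| > 2):")
print(flagged.to_string(index=False))
print()
print(
    "A reliable region loads consistently on the group-separating component\n"
    "across bootstrap refits; recovery of the implanted regions shows the\n"
    "model attributes group differences to the right nodes."
)
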