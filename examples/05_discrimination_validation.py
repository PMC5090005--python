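"""Median-split ROC discrimination and the two validation controls.

Subjects are split into high/low IE groups at the median; a node's metric
discriminates the groups via the Mann-Whitney AUC.  Controls: shuffling IE
across subjects destroys a real association, and random non-selected nodes
explain only the chance-level share of variance.
"""

import numpy as np

import effconn as ec

rng = np.random.default_rng(3)
n_sub, n_nodes = 24, 60
metrics = 1.0 + 0.1 * rng.standard_normal((n_sub, n_nodes))
ie = 530.0 - 300.0 * (metrics[:, 5] - 1.0) + 25.0 * rng.standard_normal(n_sub)

split = ec.median_split(ie)
t, df, p = ec.group_ttest(ie, split)
print(f"high vs low IE groups: t({df}) = {t:.2f}, p = {p:.2g}")

roc = ec.roc_analysis(metrics[:, 5], split)
print(
    f"node 5 ROC: AUC = {roc.auc:.2f} (SE {roc.se:.2f}, p = {roc.p:.3f}), "
    f"sensitivity {roc.sensitivity:.1%}, specificity {roc.specificity:.1%}"
)

sel = ec.select_features(metrics, ie)
chosen = sel.loc[sel["selected"], "node_id"].astype(int).tolist()
shuffle = ec.shuffle_validation(metrics[:, chosen], ie, n_perm=1000, seed=0)
print(
    f"shuffle control: observed F = {shuffle.observed_F:.2f} sits at the "
    f"{shuffle.observed_percentile:.1%} percentile of {len(shuffle.null_F)} shuffled fits"
)

control = ec.random_region_control(metrics, set(chosen), len(chosen), ie, n_draws=500, seed=0)
print(
    f"random-region control: mean R^2 = {control.r2.mean():.2f} over 500 draws "
    f"(chance level k/(n-1) = {len(chosen) / (n_sub - 1):.2f})"
)
print("-> the real association survives both controls: shuffled fits are")
print("   unremarkable and random regions explain only chance-level variance.")
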