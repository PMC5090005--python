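"""Run the complete pipeline on a reduced synthetic cohort.

simulate -> condition -> connectome -> nodal metrics -> plant behavior ->
select + regress -> median-split ROC -> shuffle / random-region controls.
All outputs land as TSV/JSON under the output directory; the run is
bit-reproducible from the master seed.
"""

import effconn as ec

cfg = ec.PipelineConfig(
    cohort=ec.CohortSpec(
        n_subjects=12, n_nodes=40, n_modules=4,
        planted_nodes=(1, 4), planted_betas=(-300.0, -300.0),
    ),
    grid=ec.SparsityGrid(0.1, 0.4, 0.05),
    n_null=20, smallworld_subjects=2, n_perm=200, n_control_draws=200,
    seed=11, out_dir="scratch/example_pipeline",
)
report = ec.run_pipeline(cfg)

cond = report["conditions"]["BMP-Direction"]
local = cond["local"]
print(f"selected nodes (local efficiency): {local['selected']}")
m = local["model"]
print(
    f"full model: F({m['df1']},{m['df2']}) = {m['F']:.2f}, "
    f"p = {m['p_model']:.2g}, R^2 = {m['r2']:.2f}"
)
sw = report["smallworld"]
print(
    f"small-world summary: min gamma {sw['gamma_min']:.2f}, "
    f"max |lambda-1| {sw['lambda_max_abs_dev']:.2f} over {len(sw['levels'])} levels"
)
print(f"planted ground truth: nodes {report['planted']['BMP-Direction']['nodes']}, "
      f"population R^2 {report['planted']['BMP-Direction']['population_r2']:.2f}")
print(f"outputs written under {cfg.out_dir}/ (report.json, TSV tables)")
print("-> selection recovers the planted nodes; the full-model R^2 exceeds the")
print("   planted population value because selection and fitting reuse the same")
print("   subjects (the report annotates this optimism); gamma > 1 confirms the")
print("   synthetic connectomes are small-world across the grid.")
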