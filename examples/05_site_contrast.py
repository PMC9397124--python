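"""Within-patient site contrast (joint vs thumb) with the mixed-effects model.

Runs the pipeline's second statistical contrast: for each community and
post-onset bin, a linear mixed model with site and age as fixed effects and
random intercepts per subject and per site within subject (REML).  In this
simulation both sites share the same generative parameters, so no site
effect should survive FDR.
"""

from painflow import PipelineConfig, SimConfig, run_all, simulate_study

cfg = SimConfig(
    n_patients=10,
    n_controls=2,
    n_nodes=42,
    community_sizes=[6] * 7,
    event_boost_patient=0.12,
    seed=8,
)
pcfg = PipelineConfig(levels=("community",), contrasts=("site",), metrics=("pc",))

bundle = simulate_study(cfg)
results = run_all(bundle, pcfg)
table = results.stats[("site", "community", "pc")]

print("within-patient site contrast on community PC (mixed model, REML):\n")
cols = ["unit", "bin", "estimate", "se", "p", "p_fdr", "converged"]
print(table[cols].round(4).to_string(index=False))
n_sig = int(table["significant"].sum())
print(f"\n{n_sig} FDR-significant cells (expected 0: both sites were")
print("generated with identical coupling dynamics, mirroring the finding")
print("that integration changes do not differ between stimulation sites).")
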