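"""Dispersion null-model tests on a synthetic island survey.

Generates a small regional pool and six local communities assembled under
habitat filtering, then tests each community's MPD and MNTD (phylogenetic and
phenotypic) against 1000 richness-preserving resamples of the pool.  Low
ranks / p < .025 flag clustering (a filtering signal); p > .975 would flag
overdispersion (a competition signal).
"""

from kipuka import SyntheticConfig, dispersion_report, generate_dataset

cfg = SyntheticConfig(
    n_regional=120,
    n_communities=6,
    richness_range=(9, 15),
    assembly_model="filtering",
    tau=2.0,  # strong filtering
    seed=42,
)
ds = generate_dataset(cfg)
report = dispersion_report(
    ds.regional_tree, ds.communities, traits=ds.traits, n_reps=1000, seed=1
)

print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
n_clustered = (report["verdict"] == "clustered").sum()
print(
    f"\n{n_clustered} of {len(report)} tests flag clustering: communities assembled"
    " under strong filtering pack into few clades and narrow trait ranges,"
    " so observed MPD/MNTD sit in the lower tail of the resampling null."
)
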