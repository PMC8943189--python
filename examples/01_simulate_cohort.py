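"""Generate a default synthetic glioma cohort and inspect its demographics.

The generator emulates the modeled study population: 37 subjects, 79-node
whole-brain streamline-count connectomes (two correlated tractography
replicates each), a localized ipsilesional weight reduction, and clinical
covariates matched to the cohort demographics table.
"""

from hemiconn import GeneratorConfig, simulate_cohort

cohort = simulate_cohort(GeneratorConfig(seed=1))
table = cohort.clinical_table

print(f"subjects: {len(table)}")
print(f"lesion side counts: {table.lesion_side.value_counts().to_dict()}")
print(f"WHO grade counts:   {table.who_grade.value_counts().sort_index().to_dict()}")
print(f"MRC counts:         {table.mrc.value_counts().sort_index().to_dict()}")
print(f"mean RMT ratio:     {table.rmt_ratio.mean():.3f} (target 1.02)")
print(f"mean tumor volume:  {table.tumor_volume_cm3.mean():.2f} cm^3 (target 24.97)")
print(f"NIHSS available:    {table.nihss.notna().sum()} of {len(table)}")

# Each value above is a sample statistic of one simulated cohort; targets are
# the population parameters the generator is built around, so cohort means
# scatter around them with n=37 sampling error.
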