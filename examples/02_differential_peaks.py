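"""Plant differential peaks and recover them with per-peak rank tests.

One peak gets a 3.2-fold intensity increase in RR, another a
presence/absence contrast (detected in ~55% of RR, never in PP).  The
per-peak Mann-Whitney comparison should assign both a p-value below 0.01;
the absence peak additionally gets an undefined fold change, mirroring how
a peptide seen in only one group is reported.
"""

from peptidiff import PlantedEffect, SimulationConfig, gen_differential_matrix, peak_statistics

config = SimulationConfig(
    n_samples_per_group={"PP": 10, "RR": 11},
    n_peaks=50,
    planted_effects=(
        PlantedEffect(10, "RR", fold=3.2),
        PlantedEffect(20, "PP", incidence_delta=-1.0),
        PlantedEffect(20, "RR", incidence_delta=-0.45),
    ),
    seed=7,
)
matrix, truth = gen_differential_matrix(config)
result = peak_statistics(matrix, "PP", "RR", alpha=0.01)

print("planted peaks (truth):")
print(truth.to_string(index=False))
print("\nrecovered statistics at those peaks:")
cols = ["mz", "p_value", "fold_change", "direction", "incidence_a", "incidence_b"]
print(result.table.loc[sorted(truth["peak_index"].unique()), cols].to_string())
print(f"\n{len(result.significant_set)} of {matrix.n_peaks} peaks reach p < 0.01")
# incidence_a/b are integer percent of samples detecting the peak; a NaN
# fold change means one group never detected it.
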