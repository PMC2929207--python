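"""Judge an observed significant-peak count against its permutation background.

With 1000 peaks tested at alpha = 0.01 and no group difference, roughly
alpha x 1000 peaks fall below alpha by chance.  Scrambling the group labels
50 times estimates that background; an observed count within the background
band means the two groups are indistinguishable at this sample size.
"""

from peptidiff import (
    SimulationConfig,
    background_count,
    count_significant,
    gen_null_matrix,
    peak_statistics,
)

config = SimulationConfig(
    n_samples_per_group={"PP": 10, "RR": 11}, n_peaks=1000, seed=0
)
matrix = gen_null_matrix(config)

observed = count_significant(peak_statistics(matrix, "PP", "RR", alpha=0.01))
bg = background_count(matrix, "PP", "RR", alpha=0.01, n_iter=50, seed=1)

print(f"observed peaks with p < 0.01:      {observed}")
print(f"scrambled-label background:        {bg.mean:.1f} +/- {bg.sd:.1f} "
      f"({bg.n_iter} scramblings)")
verdict = "within" if abs(observed - bg.mean) <= 2 * bg.sd else "outside"
print(f"observed count is {verdict} 2 SD of the background: an observed count "
      "at background level means no detectable group difference")
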