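"""Label-scrambling permutation background for the significant-peak count.

With many peaks tested at alpha = 0.01 and no multiple-testing correction,
some peaks reach significance by chance.  The background is estimated by
repeatedly permuting the group labels of the compared samples (group sizes
preserved), re-running the full per-peak test, and recording how many peaks
fall below alpha each time.  The mean +/- SD of those counts is the
chance-level reference against which the observed count is judged: an
observed count at or below the background mean indicates no detectable
group difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .matrix import AnalysisMatrix
from .stats import peak_pvalues


@dataclass(frozen=True)
class BackgroundEstimate:
    """Permutation distribution of the count of p < alpha peaks.

    ``counts`` holds one significant-peak count per scrambling; ``sd`` is
    the sample standard deviation (n-1 denominator).
    """

    counts: tuple[int, ...]
    alpha: float
    seed: int | None
    mean: float
    sd: float

    @property
    def n_iter(self) -> int:
        return len(self.counts)


def scramble_labels(
    groups: Mapping[str, str], rng: np.random.Generator
) -> dict[str, str]:
    """Uniformly random permutation of the label multiset over the samples.

    Group sizes are preserved exactly; with a single distinct label this is
    the identity map.
    """
    samples = list(groups)
    labels = [groups[s] for s in samples]
    permuted = rng.permutation(labels)
    return {s: str(l) for s, l in zip(samples, permuted)}


def background_count(
    m: AnalysisMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.01,
    n_iter: int = 50,
    seed: int | None = None,
    missing_policy: str = "zero",
) -> BackgroundEstimate:
    """Estimate the chance-level count of significant peaks by scrambling.

    Restricts the matrix to the samples of the two compared groups, then
    for each of ``n_iter`` scramblings permutes the A/B labels over those
    samples, recomputes every peak's Mann–Whitney p-value and counts peaks
    with p < alpha.  Deterministic for a fixed seed.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter: must be >= 1")
    samples_a = m.group_samples(group_a)
    samples_b = m.group_samples(group_b)
    if not samples_a or not samples_b:
        raise ConfigurationError(
            f"groups: empty group in comparison {group_a!r} vs {group_b!r}"
        )
    sub = m.subset_samples(samples_a + samples_b)
    values = sub.intensities.to_numpy(dtype=float)
    labels = np.array([sub.groups[s] for s in sub.sample_ids])

    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_iter):
        permuted = rng.permutation(labels)
        in_a = permuted == group_a
        in_b = permuted == group_b
        p = peak_pvalues(values, in_a, in_b, missing_policy)
        counts.append(int(np.sum(~np.isnan(p) & (p < alpha))))
    arr = np.asarray(counts, dtype=float)
    sd = float(arr.std(ddof=1)) if len(counts) > 1 else 0.0
    return BackgroundEstimate(
        counts=tuple(counts),
        alpha=alpha,
        seed=seed,
        mean=float(arr.mean()),
        sd=sd,
    )
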