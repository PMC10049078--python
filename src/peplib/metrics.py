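"""Single-dataset diversity and quality statistics.

Covers the Table-1-style derived quantities (percent distinct sequences,
fold differences in unique reads), the frequency-bin composition behind the
stacked-bar view (bins 1..10 and >10, widths = unique sequences, heights =
percent of cleaned reads), the absolute-frequency spectrum with its count
of distinct frequency values (DFV), a Yates-corrected chi-square for 2x2
read-count contrasts, and exact without-replacement subsampling of a
dataset to a lower depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .extraction import CleaningStats, FrequencyMatrix

#: stacked-bar frequency bins: absolute frequency 1..10, then everything above
BIN_LABELS = tuple(str(k) for k in range(1, 11)) + (">10",)


def _unique_cleaned(x) -> int:
    return x.unique_cleaned if isinstance(x, CleaningStats) else int(x)


def percent_distinct(stats: CleaningStats) -> float:
    """Percent distinct sequences: 100 * unique cleaned / absolute cleaned.

    The relative-diversity indicator; 100 iff every peptide is a singleton.
    """
    if stats.absolute_cleaned == 0:
        raise ValueError("percent_distinct is undefined with zero cleaned reads")
    return 100.0 * stats.unique_cleaned / stats.absolute_cleaned


def unique_read_ratio(stats_a, stats_b) -> float:
    """Fold difference in unique cleaned reads, A over B.

    Accepts :class:`CleaningStats` or plain counts.
    """
    a, b = _unique_cleaned(stats_a), _unique_cleaned(stats_b)
    if b == 0:
        raise ValueError("unique_read_ratio is undefined with a zero denominator")
    if a == 0:
        raise ValueError("unique_read_ratio is undefined with zero unique reads")
    return a / b


@dataclass
class BinComposition:
    """Stacked-bar composition: per frequency bin, the number of unique
    sequences (width) and the percent of cleaned reads (height)."""

    labels: tuple[str, ...]
    unique_counts: list[int]
    read_percentages: list[float]
    label: str | None = None

    @property
    def singleton_percentage(self) -> float:
        """Percent of cleaned reads that are singleton peptides (bin 1)."""
        return self.read_percentages[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": list(self.labels),
                "unique_count": self.unique_counts,
                "read_percentage": self.read_percentages,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def bin_composition(matrix: FrequencyMatrix) -> BinComposition:
    """Group peptides into frequency bins 1..10 and >10."""
    if matrix.n_unique == 0:
        raise ValueError("bin_composition requires a nonempty frequency matrix")
    counts = matrix.df["absolute_frequency"].to_numpy()
    total = counts.sum()
    uniques, percents = [], []
    for k in range(1, 11):
        mask = counts == k
        uniques.append(int(mask.sum()))
        percents.append(100.0 * counts[mask].sum() / total)
    mask = counts > 10
    uniques.append(int(mask.sum()))
    percents.append(100.0 * counts[mask].sum() / total)
    return BinComposition(
        labels=BIN_LABELS,
        unique_counts=uniques,
        read_percentages=percents,
        label=matrix.label,
    )


def singleton_percentage(matrix: FrequencyMatrix) -> float:
    return bin_composition(matrix).singleton_percentage


def singleton_contrast(percent_a: float, percent_b: float) -> float:
    """Difference between two singleton percentages, in percentage points."""
    return percent_a - percent_b


@dataclass
class FrequencySpectrum:
    """Mapping absolute frequency f -> number of peptides observed f times."""

    spectrum: dict[int, int]
    label: str | None = None

    @property
    def dfv_count(self) -> int:
        """Number of distinct frequency values present in the dataset."""
        return len(self.spectrum)

    @property
    def total_reads(self) -> int:
        return sum(f * n for f, n in self.spectrum.items())

    @property
    def total_unique(self) -> int:
        return sum(self.spectrum.values())

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.spectrum.items())
        return pd.DataFrame(items, columns=["frequency", "n_peptides"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def frequency_spectrum(matrix: FrequencyMatrix) -> FrequencySpectrum:
    counts = matrix.df["absolute_frequency"].value_counts()
    return FrequencySpectrum(
        spectrum={int(f): int(n) for f, n in counts.items()}, label=matrix.label
    )


def chi_square_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-continuity-corrected chi-square for a 2x2 table [[a, b], [c, d]].

    statistic = N * (max(0, |ad - bc| - N/2))^2
                / ((a+b) (c+d) (a+c) (b+d)),  N = a+b+c+d,
    with the p-value from the chi-square distribution at 1 df.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("all table margins must be positive")
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    statistic = n * num * num / np.prod([float(m) for m in margins])
    p_value = float(_stats.chi2.sf(statistic, df=1))
    return float(statistic), p_value


def subsample(
    matrix: FrequencyMatrix,
    depth: int,
    rng: np.random.Generator,
    label: str | None = None,
) -> FrequencyMatrix:
    """Draw `depth` reads without replacement from a dataset's cleaned reads.

    Exact multivariate hypergeometric draw on the count vector — the in
    silico analogue of sequencing the same cleaned pool at a lower depth.
    """
    total = matrix.total_reads
    if not 0 <= depth <= total:
        raise ValueError(f"depth must be in [0, {total}]")
    counts = matrix.df["absolute_frequency"].to_numpy()
    sub = rng.multivariate_hypergeometric(counts, depth)
    peptides = matrix.df["peptide"].to_numpy()
    kept = sub > 0
    return FrequencyMatrix.from_counts(
        dict(zip(peptides[kept], sub[kept])),
        label=label or (f"{matrix.label}_sub{depth}" if matrix.label else None),
    )
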