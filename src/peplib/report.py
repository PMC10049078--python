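"""Human-readable formatting. All rounding lives here; modules keep full precision."""

from __future__ import annotations

from .extraction import CleaningStats
from .metrics import BinComposition, FrequencySpectrum


def fold_str(x: float) -> str:
    """Fold differences at one decimal place, as conventionally printed."""
    return f"{x:.1f}"


def sci3_str(x: float) -> str:
    """Three-significant-figure scientific notation, e.g. 2.44e-03."""
    return f"{x:.2e}"


def pvalue_str(p: float) -> str:
    return "<0.0001" if p < 1e-4 else f"{p:.4g}"


def summary_lines(
    stats: CleaningStats,
    percent_distinct_value: float,
    bins: BinComposition,
    spectrum: FrequencySpectrum,
) -> list[str]:
    label = stats.label or "dataset"
    return [
        f"[{label}]",
        f"  absolute cleaned reads: {stats.absolute_cleaned}",
        f"  absolute removed reads: {stats.absolute_removed}"
        f" ({stats.absolute_removed_percent:.2f} %)",
        f"  unique cleaned reads:   {stats.unique_cleaned}",
        f"  unique removed reads:   {stats.unique_removed}"
        f" ({stats.unique_removed_percent:.2f} %)",
        f"  percent distinct sequences: {percent_distinct_value:.2f} %",
        f"  singleton percentage:   {bins.singleton_percentage:.2f} %",
        f"  distinct frequency values (DFV): {spectrum.dfv_count}",
    ]
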