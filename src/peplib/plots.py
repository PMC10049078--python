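"""Optional matplotlib renderings of the computed tables (never recomputed here)."""

from __future__ import annotations

import os
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .metrics import BIN_LABELS, BinComposition, FrequencySpectrum


def stacked_bar_plot(bins_by_label: Mapping[str, BinComposition], path: str | os.PathLike) -> None:
    """Stacked bars: per dataset, the percent of reads in each frequency bin."""
    fig, ax = plt.subplots(figsize=(1.8 * len(bins_by_label) + 2, 5))
    cmap = plt.get_cmap("tab20")
    bottoms = {label: 0.0 for label in bins_by_label}
    for k, bin_label in enumerate(BIN_LABELS):
        heights = [bc.read_percentages[k] for bc in bins_by_label.values()]
        ax.bar(
            list(bins_by_label),
            heights,
            bottom=[bottoms[l] for l in bins_by_label],
            color=cmap(k),
            label=bin_label,
        )
        for label, h in zip(bins_by_label, heights):
            bottoms[label] += h
    ax.set_ylabel("% of cleaned reads")
    ax.legend(title="absolute frequency", bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def spectrum_plot(spectra: Mapping[str, FrequencySpectrum], path: str | os.PathLike) -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, spec in spectra.items():
        frame = spec.to_frame()
        ax.plot(frame["frequency"], frame["n_peptides"], marker=".", lw=0.8,
                label=f"{label} (DFV={spec.dfv_count})")
    ax.set_xlabel("absolute frequency")
    ax.set_ylabel("number of peptides")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def positional_difference_heatmap(diff: pd.DataFrame, path: str | os.PathLike) -> None:
    fig, ax = plt.subplots(figsize=(8, 6))
    vmax = max(abs(diff.to_numpy()).max(), 1e-9)
    im = ax.imshow(diff.to_numpy(), cmap="bwr", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(diff.shape[1]), [str(c) for c in diff.columns])
    ax.set_yticks(range(diff.shape[0]), list(diff.index))
    ax.set_xlabel("peptide position")
    fig.colorbar(im, ax=ax, label="percentage-point difference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
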