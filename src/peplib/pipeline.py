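"""End-to-end pipeline: simulate -> process -> per-dataset statistics ->
cross-dataset comparison -> report bundle.

Every figure in the summary report is copied from a value already written to
a CSV by a single module operation; nothing is recomputed at the report
layer.  Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import compare as _compare
from . import metrics as _metrics
from . import report as _report
from .extraction import ExtractionConfig, process_dataset
from .simulate import (
    DEFAULT_DOWNSTREAM_ANCHOR,
    DEFAULT_UPSTREAM_ANCHOR,
    DefectRates,
    SyntheticLibraryConfig,
    sample_true_library,
    simulate_to_fastq,
)

log = logging.getLogger("peplib")

DEFAULT_FREQUENCIES = (20, 25, 30, 35, 40, 45, 50)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    outdir: str
    seed: int = 0
    #: synthetic-run spec: {"true_diversity": .., "abundance_sigma": ..,
    #:  "defect_rates": {..}, "depths": {label: n_reads, ..}}; None to skip
    simulate: dict[str, Any] | None = None
    #: label -> FASTQ path for pre-existing datasets
    datasets: dict[str, str] = field(default_factory=dict)
    #: overrides for ExtractionConfig fields
    extraction: dict[str, Any] = field(default_factory=dict)
    frequencies: list[int] = field(default_factory=lambda: list(DEFAULT_FREQUENCIES))
    alpha: float = 0.05
    m_tests: int | None = None
    z: float | None = None
    weighting: str = "unique"
    plots: bool = False

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "outdir" not in data:
            raise ValueError("config requires 'outdir'")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def extraction_config(self) -> ExtractionConfig:
        base = {
            "upstream_anchor": DEFAULT_UPSTREAM_ANCHOR,
            "downstream_anchor": DEFAULT_DOWNSTREAM_ANCHOR,
        }
        base.update(self.extraction)
        return ExtractionConfig(**base)

    def library_config(self) -> SyntheticLibraryConfig:
        if self.simulate is None:
            raise ValueError("no simulate section in config")
        sim = dict(self.simulate)
        sim.pop("depths", None)
        rates = DefectRates(**sim.pop("defect_rates", {}))
        ext = self.extraction_config()
        return SyntheticLibraryConfig(
            defect_rates=rates,
            peptide_length=ext.peptide_length,
            linker_aa=ext.linker_aa,
            upstream_anchor=ext.upstream_anchor,
            downstream_anchor=ext.downstream_anchor,
            seed=self.seed,
            **sim,
        )


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


@_stage("simulate")
def _run_simulate(cfg: RunConfig, outdir: Path) -> dict[str, str]:
    lib = cfg.library_config()
    pool = sample_true_library(lib)
    pool.write_pool_csv(outdir / "pool.csv")
    depths = cfg.simulate.get("depths", {"deep": 50_000, "shallow": 5_000})
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(depths))
    datasets: dict[str, str] = {}
    for (label, n_reads), seq in zip(depths.items(), seeds):
        fastq = outdir / f"{label}.fastq"
        simulate_to_fastq(
            pool, int(n_reads), fastq, truth_path=outdir / f"{label}_truth.csv",
            rng=np.random.default_rng(seq),
        )
        log.info("simulated %d reads -> %s", n_reads, fastq)
        datasets[label] = str(fastq)
    return datasets


@_stage("process")
def _run_process(cfg: RunConfig, datasets: dict[str, str], outdir: Path):
    ext = cfg.extraction_config()
    matrices, statses = {}, {}
    for label, path in datasets.items():
        if not os.path.exists(path):
            raise FileNotFoundError(f"input FASTQ not found: {path}")
        matrix, stats = process_dataset(path, ext, label=label)
        matrix.to_csv(outdir / f"matrix_{label}.csv")
        stats.to_csv(outdir / f"stats_{label}.csv")
        log.info(
            "%s: %d reads processed, %d cleaned, %d removed",
            label, stats.total_absolute, stats.absolute_cleaned, stats.absolute_removed,
        )
        matrices[label], statses[label] = matrix, stats
    return matrices, statses


@_stage("stats")
def _run_stats(matrices, statses, outdir: Path):
    bins, spectra, summaries = {}, {}, {}
    for label, matrix in matrices.items():
        stats = statses[label]
        bc = _metrics.bin_composition(matrix) if matrix.n_unique else None
        spec = _metrics.frequency_spectrum(matrix)
        if bc is not None:
            bc.to_csv(outdir / f"bins_{label}.csv")
        spec.to_csv(outdir / f"spectrum_{label}.csv")
        summary = stats.to_frame()
        summary["percent_distinct"] = (
            _metrics.percent_distinct(stats) if stats.absolute_cleaned else float("nan")
        )
        summary["singleton_percentage"] = (
            bc.singleton_percentage if bc is not None else float("nan")
        )
        summary["dfv"] = spec.dfv_count
        summary.to_csv(outdir / f"summary_{label}.csv", index=False)
        bins[label], spectra[label], summaries[label] = bc, spec, summary
    return bins, spectra, summaries


@_stage("compare")
def _run_compare(cfg: RunConfig, matrices, statses, outdir: Path):
    if len(matrices) < 2:
        return None
    labels = list(matrices)
    overlap = _compare.peptide_overlap(list(matrices.values()))
    overlap.to_csv(outdir / "overlap.csv")
    for label, matrix in matrices.items():
        pfm = _compare.positional_frequency(matrix, weighting=cfg.weighting)
        pfm.to_csv(outdir / f"posfreq_{label}.csv")
    a, b = labels[0], labels[1]
    diff = _compare.positional_difference(
        _compare.positional_frequency(matrices[a], cfg.weighting),
        _compare.positional_frequency(matrices[b], cfg.weighting),
    )
    diff.to_csv(outdir / "posdiff.csv")
    # ties are read off the shallower dataset and resolved in the deeper one
    shallow, deep = sorted(labels[:2], key=lambda l: statses[l].absolute_cleaned)
    groups = _compare.distinguishing_analysis(
        matrices[shallow], matrices[deep], cfg.frequencies,
        alpha=cfg.alpha, m_tests=cfg.m_tests, z=cfg.z,
    )
    table = _compare.distinguishing_table(groups, shallow, deep)
    table.to_csv(outdir / "ci_table.csv", index=False)
    return {"overlap": overlap, "posdiff": diff, "groups": groups,
            "tie_source": shallow, "tie_reference": deep}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages and write the report bundle to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets = dict(config.datasets)
    if config.simulate is not None:
        datasets.update(_run_simulate(config, outdir))
    if not datasets:
        raise StageError("stage 'process' failed: no datasets configured")
    matrices, statses = _run_process(config, datasets, outdir)
    bins, spectra, summaries = _run_stats(matrices, statses, outdir)
    comparison = _run_compare(config, matrices, statses, outdir)

    lines: list[str] = []
    for label in matrices:
        if bins[label] is None:
            lines.append(f"[{label}] no cleaned reads")
            continue
        stats = statses[label]
        lines.extend(
            _report.summary_lines(
                stats,
                float(summaries[label]["percent_distinct"].iloc[0]),
                bins[label],
                spectra[label],
            )
        )
    if comparison is not None:
        labels = list(matrices)
        a, b = labels[0], labels[1]
        if statses[a].unique_cleaned and statses[b].unique_cleaned:
            fold = _metrics.unique_read_ratio(statses[a], statses[b])
            lines.append(
                f"[compare] unique cleaned reads {a}/{b}: {_report.fold_str(fold)}"
            )
        lines.append(
            f"[compare] identical peptides {a} & {b}: "
            f"{int(comparison['overlap'].loc[a, b])}"
        )
        n_sig = sum(g.significant for g in comparison["groups"])
        lines.append(
            f"[compare] tie groups from {comparison['tie_source']} resolved in "
            f"{comparison['tie_reference']}: {n_sig} of "
            f"{sum(1 for g in comparison['groups'] if g.members)} nonempty significant"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")

    if config.plots:
        from . import plots as _plots

        present = {l: b for l, b in bins.items() if b is not None}
        if present:
            _plots.stacked_bar_plot(present, outdir / "bins.png")
            _plots.spectrum_plot(spectra, outdir / "spectrum.png")
        if comparison is not None:
            _plots.positional_difference_heatmap(
                comparison["posdiff"], outdir / "posdiff.png"
            )

    return {
        "datasets": datasets,
        "matrices": matrices,
        "stats": statses,
        "bins": bins,
        "spectra": spectra,
        "comparison": comparison,
        "outdir": str(outdir),
    }
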