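"""Synthetic NNK phage-display library and amplicon-read generator.

Emulates single-end amplicon reads over the insert of a random 12-mer
library: fixed flanking vector sequence, a 36-nt NNK-encoded insert, the
codons of a GGGS linker, and configurable per-read defect classes (stop
codon in the insert, ambiguous base, one-nucleotide frameshift, mutated
linker) plus optional per-base substitutions.  Every read carries a
ground-truth record so the cleaning pipeline can be audited exactly.

The true peptide pool is sampled residue-wise with probability proportional
to NNK codon multiplicity (the distribution produced by degenerate-oligo
synthesis), and per-peptide abundance weights follow a log-normal by
default — amplification skews clone abundance multiplicatively, which makes
a heavy-tailed, log-scale model the natural stand-in.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from ._codons import (
    AA_INDEX,
    AMINO_ACIDS,
    NNK_CODON_ARRAY,
    NNK_CODON_COUNTS,
    NNK_CODONS,
    NNK_RESIDUE_PROBS,
    STOP_CODONS,
)
from .extraction import (
    REASON_MISSING_LINKER,
    REASON_STOP_OR_X,
    REASON_WRONG_LENGTH,
    ExtractionConfig,
)

DEFAULT_UPSTREAM_ANCHOR = "ATGCCGTTCAACGTGCTAGC"
DEFAULT_DOWNSTREAM_ANCHOR = "GCTAGACCTGAGGTCCATGA"

CLASS_CLEAN = "clean"
CLASS_STOP = "stop_codon"
CLASS_AMBIGUOUS = "ambiguous_base"
CLASS_FRAMESHIFT = "frameshift"
CLASS_MISSING_LINKER = "missing_linker"

#: defect classes in the order they are drawn (one categorical per read)
DEFECT_CLASSES = (CLASS_STOP, CLASS_AMBIGUOUS, CLASS_FRAMESHIFT, CLASS_MISSING_LINKER)

#: removal reason the extraction module assigns to each defect class
EXPECTED_REASON = {
    CLASS_STOP: REASON_STOP_OR_X,
    CLASS_AMBIGUOUS: REASON_STOP_OR_X,
    CLASS_FRAMESHIFT: REASON_WRONG_LENGTH,
    CLASS_MISSING_LINKER: REASON_MISSING_LINKER,
}

_CHUNK = 100_000


@dataclass(frozen=True)
class DefectRates:
    """Per-read defect-class probabilities plus a per-base substitution rate.

    The four class rates are mutually exclusive draws; their sum is the total
    defect probability per read.  Defaults total 0.21, the removed-read
    fraction typical of a naive Ph.D.-type library amplicon run.
    """

    stop_codon_insert: float = 0.08
    ambiguous_base: float = 0.02
    frameshift_indel: float = 0.06
    missing_linker: float = 0.05
    substitution_per_base: float = 0.0

    def class_rates(self) -> tuple[float, float, float, float]:
        return (
            self.stop_codon_insert,
            self.ambiguous_base,
            self.frameshift_indel,
            self.missing_linker,
        )

    @property
    def total_class_rate(self) -> float:
        return sum(self.class_rates())

    def validate(self) -> None:
        for name in (
            "stop_codon_insert",
            "ambiguous_base",
            "frameshift_indel",
            "missing_linker",
            "substitution_per_base",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"defect rate {name}={p} outside [0, 1]")
        if self.total_class_rate > 1.0 + 1e-12:
            raise ValueError(
                f"defect class rates sum to {self.total_class_rate} > 1"
            )


@dataclass(frozen=True)
class SyntheticLibraryConfig:
    """Parameters of the simulated library and its sequencing run."""

    true_diversity: int = 1000
    abundance_model: str = "lognormal"  # "lognormal" | "uniform"
    abundance_sigma: float = 1.0  # log-normal shape; 0 degenerates to equal weights
    peptide_length: int = 12
    linker_aa: str = "GGGS"
    upstream_anchor: str = DEFAULT_UPSTREAM_ANCHOR
    downstream_anchor: str = DEFAULT_DOWNSTREAM_ANCHOR
    defect_rates: DefectRates = field(default_factory=DefectRates)
    seed: int | None = None

    def validate(self) -> None:
        if self.true_diversity < 1:
            raise ValueError("true_diversity must be >= 1")
        if self.abundance_model not in ("lognormal", "uniform"):
            raise ValueError(f"unknown abundance_model {self.abundance_model!r}")
        if self.abundance_sigma < 0:
            raise ValueError("abundance_sigma must be >= 0")
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        if not self.linker_aa:
            raise ValueError("linker_aa must be nonempty")
        if not set(self.linker_aa) <= set(AMINO_ACIDS):
            raise ValueError("linker_aa contains non-standard residues")
        if not self.upstream_anchor or not self.downstream_anchor:
            raise ValueError("anchors must be nonempty")
        self.defect_rates.validate()

    @property
    def insert_length(self) -> int:
        """Nucleotide length of the peptide-encoding insert (3 per residue)."""
        return 3 * self.peptide_length

    def extraction_config(self) -> ExtractionConfig:
        """The matching cleaning configuration for reads from this simulator."""
        return ExtractionConfig(
            upstream_anchor=self.upstream_anchor,
            downstream_anchor=self.downstream_anchor,
            peptide_length=self.peptide_length,
            linker_aa=self.linker_aa,
        )


@dataclass
class GroundTruth:
    """True pool (peptides + normalized weights) and, after simulation, the
    per-read truth log."""

    peptides: list[str]
    weights: np.ndarray
    config: SyntheticLibraryConfig
    #: columns read_id, defect_class, peptide — one row per simulated read
    read_log: pd.DataFrame | None = None

    @property
    def class_totals(self) -> dict[str, int]:
        if self.read_log is None:
            return {}
        return self.read_log["defect_class"].value_counts().to_dict()

    def pool_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"peptide": self.peptides, "weight": self.weights})

    def write_pool_csv(self, path: str | os.PathLike) -> None:
        self.pool_frame().to_csv(path, index=False)

    def write_truth_csv(self, path: str | os.PathLike) -> None:
        if self.read_log is None:
            raise ValueError("no reads simulated yet")
        self.read_log.to_csv(path, index=False)


def _peptide_matrix(peptides: list[str], length: int) -> np.ndarray:
    """Residue-index matrix (n_peptides x length, int64)."""
    flat = np.array(peptides, dtype=f"U{length}").view("U1").reshape(len(peptides), length)
    out = np.empty(flat.shape, dtype=np.int64)
    for aa, idx in AA_INDEX.items():
        out[flat == aa] = idx
    return out


def sample_true_library(config: SyntheticLibraryConfig) -> GroundTruth:
    """Draw the true pool: distinct peptides plus normalized abundance weights.

    Reproducible under ``config.seed``.  Raises if ``true_diversity`` exceeds
    the number of distinct peptides of the configured length.
    """
    config.validate()
    space = 20 ** config.peptide_length
    if config.true_diversity > space:
        raise ValueError(
            f"true_diversity={config.true_diversity} exceeds the "
            f"{space} distinct peptides of length {config.peptide_length}"
        )
    rng = np.random.default_rng(config.seed)
    aa_arr = np.array(AMINO_ACIDS)
    seen: dict[str, None] = {}
    need = config.true_diversity
    while need > 0:
        draw = rng.choice(
            len(aa_arr), size=(max(need, 16), config.peptide_length), p=NNK_RESIDUE_PROBS
        )
        for row in aa_arr[draw]:
            pep = "".join(row)
            if pep not in seen:
                seen[pep] = None
                need -= 1
                if need == 0:
                    break
    peptides = list(seen)
    if config.abundance_model == "uniform" or config.abundance_sigma == 0:
        weights = np.full(len(peptides), 1.0 / len(peptides))
    else:
        raw = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(peptides))
        weights = raw / raw.sum()
    return GroundTruth(peptides=peptides, weights=weights, config=config)


def encode_peptide_nnk(peptide: str, rng: np.random.Generator) -> str:
    """Reverse-translate a peptide choosing uniformly among its NNK codons.

    Every codon of the result matches N-N-[G|T] and translates back to the
    input residue.
    """
    codons = []
    for aa in peptide:
        options = NNK_CODONS.get(aa)
        if options is None:
            raise ValueError(f"residue {aa!r} is not a standard amino acid")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _encode_batch(residue_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized NNK encoding of a residue-index matrix -> array of nt strings."""
    n, length = residue_idx.shape
    if n == 0:
        return np.empty(0, dtype=f"U{3 * length}")
    choice = rng.integers(0, NNK_CODON_COUNTS[residue_idx])
    codons = NNK_CODON_ARRAY[residue_idx, choice]  # (n, length) of 'U3'
    return codons.view(f"U{3 * length}").reshape(n)


def _random_wrong_linker(config: SyntheticLibraryConfig, rng: np.random.Generator) -> str:
    """NNK codons for a random residue string that is not the linker.

    Stop- and ambiguity-free by construction, so downstream classification
    attributes the failure to the linker and nothing else.
    """
    aa_arr = np.array(AMINO_ACIDS)
    while True:
        alt = "".join(aa_arr[rng.choice(len(aa_arr), size=len(config.linker_aa),
                                        p=NNK_RESIDUE_PROBS)])
        if alt != config.linker_aa:
            return encode_peptide_nnk(alt, rng)


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hit:
        current = arr[i]
        options = bases[bases != current]
        arr[i] = options[rng.integers(len(options))]
    return arr.tobytes().decode()


def simulate_read_chunks(
    pool: GroundTruth,
    n_reads: int,
    rng: np.random.Generator,
    start_index: int = 0,
    chunk_size: int = _CHUNK,
) -> Iterator[tuple[list[str], list[str], list[str], list[str]]]:
    """Yield chunks ``(read_ids, sequences, defect_classes, peptides)``.

    The workhorse behind :func:`simulate_reads` and :func:`simulate_to_fastq`;
    chunked so multi-million-read runs stream in bounded memory.
    """
    config = pool.config
    linker_idx = np.array([AA_INDEX[aa] for aa in config.linker_aa])
    pool_matrix = _peptide_matrix(pool.peptides, config.peptide_length)
    rates = config.defect_rates
    edges = np.cumsum(rates.class_rates())
    pep_arr = np.array(pool.peptides)

    produced = 0
    while produced < n_reads:
        n = min(chunk_size, n_reads - produced)
        pick = rng.choice(len(pep_arr), size=n, p=pool.weights)
        inserts = _encode_batch(pool_matrix[pick], rng).astype(object)
        linkers = _encode_batch(
            np.broadcast_to(linker_idx, (n, linker_idx.size)), rng
        ).astype(object)
        cls = np.searchsorted(edges, rng.random(n), side="right")

        for j in np.nonzero(cls == 0)[0]:  # stop codon replaces one insert codon
            pos = 3 * rng.integers(config.peptide_length)
            ins = inserts[j]
            stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
            inserts[j] = ins[:pos] + stop + ins[pos + 3 :]
        for j in np.nonzero(cls == 1)[0]:  # ambiguous base in the insert
            pos = rng.integers(config.insert_length)
            ins = inserts[j]
            inserts[j] = ins[:pos] + "N" + ins[pos + 1 :]
        for j in np.nonzero(cls == 2)[0]:  # one-nt frameshift inside the insert
            ins = inserts[j]
            if rng.random() < 0.5:
                pos = rng.integers(len(ins))
                inserts[j] = ins[:pos] + ins[pos + 1 :]
            else:
                pos = rng.integers(len(ins) + 1)
                base = "ACGT"[rng.integers(4)]
                inserts[j] = ins[:pos] + base + ins[pos:]
        for j in np.nonzero(cls == 3)[0]:  # mutated linker codons
            linkers[j] = _random_wrong_linker(config, rng)

        up, down = config.upstream_anchor, config.downstream_anchor
        seqs = [up + i + l + down for i, l in zip(inserts, linkers)]
        if rates.substitution_per_base > 0:
            seqs = [
                _apply_substitutions(s, rates.substitution_per_base, rng) for s in seqs
            ]
        ids = [f"read_{start_index + produced + k:08d}" for k in range(n)]
        classes = [
            CLASS_CLEAN if c == 4 else DEFECT_CLASSES[c] for c in cls
        ]
        yield ids, seqs, classes, list(pep_arr[pick])
        produced += n


def simulate_reads(
    pool: GroundTruth,
    n_reads: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate reads in memory.

    Returns ``(records, read_log)`` where records are ``(id, sequence,
    quality)`` triples with constant placeholder qualities, and the log has
    one row per read (read_id, defect_class, intended peptide).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if rng is None:
        rng = np.random.default_rng(pool.config.seed)
    records: list[tuple[str, str, str]] = []
    log_ids: list[str] = []
    log_cls: list[str] = []
    log_pep: list[str] = []
    for ids, seqs, classes, peps in simulate_read_chunks(pool, n_reads, rng):
        records.extend((i, s, "I" * len(s)) for i, s in zip(ids, seqs))
        log_ids.extend(ids)
        log_cls.extend(classes)
        log_pep.extend(peps)
    log = pd.DataFrame(
        {"read_id": log_ids, "defect_class": log_cls, "peptide": log_pep}
    )
    pool.read_log = log
    return records, log


def write_fastq(records, path: str | os.PathLike) -> None:
    """Write ``(id, sequence, quality)`` triples as plain 4-line FASTQ."""
    with open(path, "w") as out:
        for read_id, seq, qual in records:
            out.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def simulate_to_fastq(
    pool: GroundTruth,
    n_reads: int,
    fastq_path: str | os.PathLike,
    truth_path: str | os.PathLike | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Stream a simulated dataset to a FASTQ file (and optional truth CSV)."""
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if rng is None:
        rng = np.random.default_rng(pool.config.seed)
    log_frames = []
    with open(fastq_path, "w") as out:
        for ids, seqs, classes, peps in simulate_read_chunks(pool, n_reads, rng):
            out.writelines(
                f"@{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in zip(ids, seqs)
            )
            log_frames.append(
                pd.DataFrame(
                    {"read_id": ids, "defect_class": classes, "peptide": peps}
                )
            )
    pool.read_log = (
        pd.concat(log_frames, ignore_index=True)
        if log_frames
        else pd.DataFrame(columns=["read_id", "defect_class", "peptide"])
    )
    if truth_path is not None:
        pool.write_truth_csv(truth_path)
    return pool


def subsampled_config(config: SyntheticLibraryConfig, seed: int) -> SyntheticLibraryConfig:
    """Same library, different stream seed — convenience for replicate runs."""
    return replace(config, seed=seed)
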