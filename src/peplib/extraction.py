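"""Raw FASTQ reads -> cleaned, frequency-sorted peptide matrix.

The cleaning rule for a single-end amplicon read covering the displayed
peptide insert is:

1. locate the region between the upstream and downstream anchor sequences
   (exact match, first occurrence, forward strand);
2. require the region to span exactly the insert plus the linker,
   3 * (peptide_length + len(linker)) nucleotides;
3. translate with the standard genetic code (stops -> ``*``, any codon
   containing an ambiguous base -> ``X``);
4. remove reads whose translation contains ``*`` or ``X``;
5. remove reads whose translation does not carry the linker (``GGGS`` by
   default) immediately after the displayed peptide.

Reads failing a rule are removed with the first applicable reason, in the
fixed order ``no_anchor``, ``wrong_insert_length``, ``contains_stop_or_X``,
``missing_linker``, so every removed read has exactly one reason.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._codons import CODON_TO_AA

REASON_NO_ANCHOR = "no_anchor"
REASON_WRONG_LENGTH = "wrong_insert_length"
REASON_STOP_OR_X = "contains_stop_or_X"
REASON_MISSING_LINKER = "missing_linker"

#: removal reasons in the order they are tested
REMOVAL_REASONS = (
    REASON_NO_ANCHOR,
    REASON_WRONG_LENGTH,
    REASON_STOP_OR_X,
    REASON_MISSING_LINKER,
)

_VALID_BASES = frozenset("ACGTN")


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ records; the message names the line."""


@dataclass(frozen=True)
class ExtractionConfig:
    """Anchors and geometry defining the peptide-encoding region."""

    upstream_anchor: str
    downstream_anchor: str
    peptide_length: int = 12
    linker_aa: str = "GGGS"

    def __post_init__(self) -> None:
        if not self.upstream_anchor or not self.downstream_anchor:
            raise ValueError("anchor sequences must be nonempty")
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        if not self.linker_aa:
            raise ValueError("linker_aa must be nonempty")

    @property
    def region_length(self) -> int:
        """Expected nucleotide length of insert + linker between the anchors."""
        return 3 * (self.peptide_length + len(self.linker_aa))


@dataclass(frozen=True)
class ReadOutcome:
    """Classification of one read: cleaned with a peptide, or removed with a reason."""

    read_id: str
    status: str  # "cleaned" | "removed"
    peptide: str | None = None
    reason: str | None = None
    #: raw nucleotides between the anchors when extractable (identity key for
    #: removed reads; None when no anchor was found)
    region: str | None = None


def parse_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Stream ``(read_id, uppercase sequence)`` pairs from a 4-line FASTQ file.

    Memory use is one record at a time.  Malformed records and sequences with
    characters outside ACGTN raise :class:`FastqFormatError` naming the
    offending line.
    """
    with open(path) as handle:
        records = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, _qual = next(records)
            except StopIteration:
                return
            except ValueError as exc:  # Biopython's malformed-record error
                raise FastqFormatError(
                    f"{path}: malformed FASTQ record near line {4 * index + 1}: {exc}"
                ) from exc
            seq = seq.upper()
            if not _VALID_BASES.issuperset(seq):
                bad = sorted(set(seq) - _VALID_BASES)
                raise FastqFormatError(
                    f"{path}: invalid sequence character(s) {bad} on line {4 * index + 2}"
                )
            yield title.split()[0], seq
            index += 1


def translate(nt: str) -> str:
    """Translate nucleotides with the standard code.

    Stop codons become ``*``; any codon containing a base outside ACGT
    (e.g. ``N``) becomes ``X``.  The length must be a multiple of 3.
    """
    if len(nt) % 3:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    return "".join(
        CODON_TO_AA.get(nt[i : i + 3], "X") for i in range(0, len(nt), 3)
    )


def extract_insert(
    read: str,
    upstream_anchor: str,
    downstream_anchor: str,
    expected_length: int | None = None,
) -> tuple[str | None, str | None]:
    """Return ``(region, None)`` between the anchors, or ``(region|None, reason)``.

    The region is the subsequence strictly between the first occurrence of the
    upstream anchor and the first subsequent occurrence of the downstream
    anchor.  ``no_anchor`` if either anchor is absent; ``wrong_insert_length``
    if *expected_length* is given and does not match.
    """
    start = read.find(upstream_anchor)
    if start < 0:
        return None, REASON_NO_ANCHOR
    start += len(upstream_anchor)
    end = read.find(downstream_anchor, start)
    if end < 0:
        return None, REASON_NO_ANCHOR
    region = read[start:end]
    if expected_length is not None and len(region) != expected_length:
        return region, REASON_WRONG_LENGTH
    return region, None


def classify_read(read_id: str, seq: str, config: ExtractionConfig) -> ReadOutcome:
    """Apply the full cleaning rule to one read."""
    region, reason = extract_insert(
        seq,
        config.upstream_anchor,
        config.downstream_anchor,
        expected_length=config.region_length,
    )
    if reason is not None:
        return ReadOutcome(read_id, "removed", reason=reason, region=region)
    aa = translate(region)
    if "*" in aa or "X" in aa:
        return ReadOutcome(read_id, "removed", reason=REASON_STOP_OR_X, region=region)
    if aa[config.peptide_length :] != config.linker_aa:
        return ReadOutcome(
            read_id, "removed", reason=REASON_MISSING_LINKER, region=region
        )
    return ReadOutcome(
        read_id, "cleaned", peptide=aa[: config.peptide_length], region=region
    )


@dataclass
class FrequencyMatrix:
    """Frequency-sorted peptide table: every downstream statistic consumes this.

    Rows are sorted by descending absolute frequency, ties broken
    lexicographically by peptide.  ``relative_frequency_percent`` is
    ``100 * count / total_reads``.
    """

    df: pd.DataFrame
    label: str | None = None

    COLUMNS = ("peptide", "absolute_frequency", "relative_frequency_percent")

    @property
    def total_reads(self) -> int:
        return int(self.df["absolute_frequency"].sum())

    @property
    def n_unique(self) -> int:
        return len(self.df)

    @property
    def counts(self) -> pd.Series:
        """Absolute frequencies indexed by peptide."""
        return self.df.set_index("peptide")["absolute_frequency"]

    @property
    def peptides(self) -> set[str]:
        return set(self.df["peptide"])

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], label: str | None = None
    ) -> "FrequencyMatrix":
        items = [(p, int(c)) for p, c in counts.items() if c > 0]
        items.sort(key=lambda pc: (-pc[1], pc[0]))
        df = pd.DataFrame(items, columns=["peptide", "absolute_frequency"])
        total = int(df["absolute_frequency"].sum()) if len(df) else 0
        df["relative_frequency_percent"] = (
            100.0 * df["absolute_frequency"] / total if total else 0.0
        )
        return cls(df=df, label=label)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike, label: str | None = None) -> "FrequencyMatrix":
        df = pd.read_csv(path)
        missing = set(cls.COLUMNS[:2]) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        return cls.from_counts(
            dict(zip(df["peptide"], df["absolute_frequency"])), label=label
        )


@dataclass
class CleaningStats:
    """Accounting of unique/absolute cleaned and removed reads with reasons."""

    unique_cleaned: int
    unique_removed: int
    absolute_cleaned: int
    absolute_removed: int
    reason_counts: dict[str, int] = field(default_factory=dict)
    label: str | None = None

    @property
    def total_unique(self) -> int:
        return self.unique_cleaned + self.unique_removed

    @property
    def total_absolute(self) -> int:
        return self.absolute_cleaned + self.absolute_removed

    @property
    def unique_removed_percent(self) -> float:
        return 100.0 * self.unique_removed / self.total_unique if self.total_unique else 0.0

    @property
    def absolute_removed_percent(self) -> float:
        return (
            100.0 * self.absolute_removed / self.total_absolute
            if self.total_absolute
            else 0.0
        )

    def to_frame(self) -> pd.DataFrame:
        row = {
            "sample": self.label,
            "unique_cleaned_reads": self.unique_cleaned,
            "unique_removed_reads": self.unique_removed,
            "unique_removed_percent": self.unique_removed_percent,
            "total_unique_reads": self.total_unique,
            "absolute_cleaned_reads": self.absolute_cleaned,
            "absolute_removed_reads": self.absolute_removed,
            "absolute_removed_percent": self.absolute_removed_percent,
            "total_absolute_reads": self.total_absolute,
        }
        for reason in REMOVAL_REASONS:
            row[f"removed_{reason}"] = self.reason_counts.get(reason, 0)
        return pd.DataFrame([row])

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def process_reads(
    reads: Iterable[tuple[str, str]],
    config: ExtractionConfig,
    label: str | None = None,
) -> tuple[FrequencyMatrix, CleaningStats]:
    """Classify an iterable of ``(read_id, sequence)`` pairs and tally."""
    cleaned: Counter[str] = Counter()
    removed_keys: set[str] = set()
    reasons: Counter[str] = Counter()
    absolute_removed = 0
    for read_id, seq in reads:
        outcome = classify_read(read_id, seq, config)
        if outcome.status == "cleaned":
            cleaned[outcome.peptide] += 1
        else:
            absolute_removed += 1
            reasons[outcome.reason] += 1
            # identity of a removed read: its raw anchored region when
            # extractable, else the whole read sequence
            removed_keys.add(outcome.region if outcome.region is not None else seq)
    matrix = FrequencyMatrix.from_counts(cleaned, label=label)
    stats = CleaningStats(
        unique_cleaned=len(cleaned),
        unique_removed=len(removed_keys),
        absolute_cleaned=sum(cleaned.values()),
        absolute_removed=absolute_removed,
        reason_counts=dict(reasons),
        label=label,
    )
    return matrix, stats


def process_dataset(
    path: str | os.PathLike,
    config: ExtractionConfig,
    label: str | None = None,
) -> tuple[FrequencyMatrix, CleaningStats]:
    """Run the cleaning pipeline over a FASTQ file.

    Streaming: memory is proportional to the number of distinct peptides and
    removed-read identities, not to the file size.
    """
    if label is None:
        label = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return process_reads(parse_fastq(path), config, label=label)
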