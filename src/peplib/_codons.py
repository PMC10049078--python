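"""Genetic-code and NNK degenerate-codon tables shared across modules.

NNK (N = A/C/G/T, K = G/T) is the degenerate scheme used to synthesize
random-peptide inserts in Ph.D.-type libraries: 32 codons, one stop (TAG),
and at least one codon for every standard residue.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

_STANDARD = unambiguous_dna_by_id[1]

#: codon -> single-letter residue, stops mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

#: the 20 standard residues, alphabetical
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(_STANDARD.forward_table.values())))
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: residue -> tuple of NNK codons encoding it (third base G or T, stops excluded)
NNK_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _codon[2] in "GT" and _aa != "*":
        NNK_CODONS.setdefault(_aa, ())
        NNK_CODONS[_aa] += (_codon,)

#: number of non-stop NNK codons (31 of 32; TAG is the single NNK stop)
NNK_TOTAL = sum(len(v) for v in NNK_CODONS.values())

# dense arrays for vectorized encoding: row = residue index, padded to width 3
_max_codons = max(len(v) for v in NNK_CODONS.values())
NNK_CODON_ARRAY = np.empty((len(AMINO_ACIDS), _max_codons), dtype="U3")
NNK_CODON_COUNTS = np.zeros(len(AMINO_ACIDS), dtype=np.int64)
for _aa, _codons in NNK_CODONS.items():
    _i = AA_INDEX[_aa]
    NNK_CODON_COUNTS[_i] = len(_codons)
    for _j in range(_max_codons):
        NNK_CODON_ARRAY[_i, _j] = _codons[min(_j, len(_codons) - 1)]

#: per-residue probability under uniform draws from the 31 non-stop NNK codons
NNK_RESIDUE_PROBS = NNK_CODON_COUNTS / NNK_TOTAL
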