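# Methods

## Cleaning model

A read is assumed to be a single-end amplicon on the forward strand with
fixed primer orientation, containing
`upstream_anchor + insert + linker codons + downstream_anchor`. The insert
encodes the displayed peptide (12 residues by default, 36 nt); the linker is
GGGS by default. Extraction takes the subsequence strictly between the first
exact occurrence of the upstream anchor and the first subsequent exact
occurrence of the downstream anchor. Anchor matching is exact by design:
tolerant matching would add parameters whose effect on the counts is hard to
audit, and the anchors sit in fixed vector sequence where the dominant error
mode (substitutions) is rare on modern short-read chemistry. No
reverse-complement scan is performed and no quality filtering is applied —
the cleaning rule is purely structural.

Translation uses the standard genetic code. All three stop codons become
`*`; TAG is *not* read through as Gln (amber suppression), because the
analysis removes every `*`-containing read regardless. Any codon containing
a base outside ACGT becomes `X`, even when the translation would be
unambiguous (e.g. GGN): a masked base means the sequencer did not resolve
the codon, and the filter treats that as unusable.

Removal reasons are tested in a fixed order (`no_anchor`,
`wrong_insert_length`, `contains_stop_or_X`, `missing_linker`) so that each
removed read carries exactly one reason and re-runs are reproducible to the
byte. "Unique removed reads" are keyed by the raw nucleotide region between
the anchors when it is extractable, else by the whole read sequence; this is
an interpretation (there is no canonical peptide identity for a read that
fails translation-level filters), and it is the one that keeps the
unique-level conservation law `cleaned + removed = total` exact.

## Statistics

* **Percent distinct sequences** = 100·(unique cleaned)/(absolute cleaned);
  equals 100 iff every peptide is a singleton.
* **Bins**: absolute frequencies 1..10 and >10. Bin width = number of unique
  sequences, bin height = percent of cleaned reads (abundance-weighted; a
  unique-sequence-weighted variant would double-count nothing but answers a
  different question and is not what stacked-abundance plots show). Bin 1
  height is the singleton percentage.
* **Frequency spectrum**: f ↦ number of peptides with absolute frequency f;
  DFV is the number of distinct frequency values (keys). Conservation:
  Σ f·n(f) = absolute cleaned, Σ n(f) = unique cleaned.
* **Chi-square with Yates correction** for 2×2 tables:
  χ² = N·(max(0, |ad−bc| − N/2))² / ((a+b)(c+d)(a+c)(b+d)), p from χ²₁.
  This matches `scipy.stats.chi2_contingency(correction=True)`, which is
  used as an independent oracle in the tests.
* **Subsampling** to a lower depth is an exact multivariate hypergeometric
  draw on the count vector (sampling reads without replacement), not a
  binomial approximation.

## Distinguishing capacity

An observed absolute frequency c is modelled as Poisson, giving the Wald
interval c ± z·√c, rounded half-to-even to integers and clipped at 0. With
many intervals in one analysis the normal quantile z is Bonferroni-corrected:
z = Φ⁻¹(1 − α/(2m)) for m intervals at family level α = 0.05. When neither m
nor z is supplied, `distinguishing_analysis` sets m to the number of
intervals it computes; `wald_poisson_ci` alone falls back to the calibrated
default z = 3.3246. That default was reverse-engineered from published
interval tables of this analysis: every z in (3.3204, 3.3289) reproduces all
19 printed intervals under round-half-to-even, 3.3246 is the midpoint, and
the Bonferroni quantiles for m = 56 and m = 57 lie inside the band. The
underlying report does not state its exact divisor, so the default is a
calibration, not a claim about the original computation.

A group of peptides tied at frequency f in the shallower dataset is called
significantly resolved when at least one pair of their deeper-dataset
intervals is disjoint (no shared integer). Disjointness is the minimal
decision rule consistent with reporting per-peptide CIs; it is conservative
relative to a pairwise rate test.

Poisson–Wald is a rough interval at small counts (lower bounds clip at 0 for
c ≤ 11 at the default z); it is used because it is the form that published
interval tables of this analysis follow, not because it is optimal. A
Garwood/exact interval would be wider at small c.

## Positional amino-acid frequencies

One-hot counting of residues per position over the cleaned peptide set:
cell(r, j) = 100 · #{sequences with residue r at position j}/total. The
default weights each unique sequence once; `weighting="abundance"` weights
by read counts. Columns sum to 100 by construction. The cross-dataset
difference is the elementwise subtraction (test − reference), so positive
cells mark residues overrepresented in the test dataset, and column sums of
the difference are 0.

## Synthetic generator

The generator emulates what the cleaning pipeline assumes and nothing more:

* **Pool**: `true_diversity` distinct peptides drawn residue-wise with
  probability proportional to NNK codon multiplicity (3/31 for Leu/Arg/Ser,
  1/31 for Met/Trp, ...) — the residue distribution of degenerate-oligo
  synthesis restricted to the 31 non-stop NNK codons. Abundance weights are
  i.i.d. log-normal(0, σ), normalized; σ = 1 by default. Real library
  amplification skews clone abundance multiplicatively, which motivates a
  heavy-tailed log-scale family; σ = 0 (or `abundance_model="uniform"`)
  degenerates to equal weights. The true abundance law of a naive library is
  not identified by any of the analyses here, so the family is a pluggable
  stand-in, not a claim.
* **Reads**: anchor + per-read NNK encoding of the drawn peptide + NNK
  encoding of the linker + anchor, constant placeholder qualities (the
  cleaning rule uses none). Defect classes are one categorical draw per
  read: stop codon (one insert codon replaced by TAA/TAG/TGA), ambiguous
  base (one insert base set to N), frameshift (one nucleotide deleted from
  or inserted into the insert), mutated linker (linker re-encoded as a
  random non-linker, stop-free residue string, so the failure is
  attributable to the linker filter alone). Defaults 0.08/0.02/0.06/0.05
  total a 21 % per-read defect rate, the removed-read fraction typical of a
  naive-library amplicon run of this design; per-base substitutions default
  to 0 so that ground-truth class counts map one-to-one onto removal
  reasons. Defective reads remain full-length FASTQ records — their failure
  is detected downstream by the filters, never flagged in the file.
* **Scale**: library diversity is exercised at desk scale (10³–10⁵ distinct
  peptides against 10⁴–10⁶ reads in tests); real naive libraries are orders
  of magnitude more diverse (10⁸–10⁹), so absolute read accountings of real
  runs are out of reach by construction and only *properties* (exact
  recovery at zero defects, binomial removal fractions, depth-direction of
  quality indicators) are asserted.

What the generator does **not** model: PCR amplification bias, chimeric
reads, position- or quality-dependent sequencing error, paired-end reads,
clones without insert, multiple DNA encodings per clone. Passing tests
therefore validate the analysis chain's arithmetic and its qualitative
depth behaviour, not the error profile of any particular instrument.

## Numerical and interface choices

* Frequency matrices sort by descending count with lexicographic tie-break,
  making every CSV byte-reproducible.
* All rounding/formatting (1 d.p. folds, 3-s.f. scientific relative
  frequencies, `<0.0001` p-values) lives in the report layer; modules keep
  full precision.
* CI bounds round half-to-even (`round`), the convention that reproduces the
  published interval tables.
* Empty datasets: empty FASTQ → all-zero stats and an empty matrix;
  percent distinct and fold ratios on zero denominators raise rather than
  return NaN.
* Anchors default to two fixed synthetic 20-mers; the real vector flanks of
  a commercial library are user-supplied configuration, deliberately not
  hard-coded.
* Randomness: a single integer seed per run; the pipeline derives
  per-dataset streams via `numpy` seed sequences, so adding a dataset does
  not perturb the others.
* Test problem sizes: the exact zero-defect recovery check runs 10⁶ reads
  over 10⁵ peptides; binomial removal checks run 20 seeds × 2·10⁴ reads;
  subsampling direction checks run 20 resamples of a 5·10⁴-read dataset at
  10 % depth. These sizes give sampling errors far below the asserted
  margins while keeping the suite fast.

## Known limitations

* Exact anchor matching means a single substitution in an anchor removes
  the read as `no_anchor`; with elevated substitution rates the removal
  accounting shifts between reasons accordingly.
* The distinguishing-capacity default z is calibrated, not derived (see
  above); supply `m_tests` explicitly to use a principled divisor.
* Venn-style rendering of overlaps is not produced; the computed artifact is
  the pairwise intersection-size table.
* No richness extrapolation (Chao1, rarefaction asymptotics): diversity here
  is observed unique sequences, by definition.
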