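"""Cross-dataset analyses: CIs, tie resolution, overlap, positional frequencies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peplib import (
    DEFAULT_Z,
    FrequencyMatrix,
    distinguishing_analysis,
    peptide_overlap,
    positional_difference,
    positional_frequency,
    sample_true_library,
    simulate_reads,
    wald_poisson_ci,
)
from peplib._codons import AMINO_ACIDS, NNK_RESIDUE_PROBS
from peplib.simulate import DefectRates, SyntheticLibraryConfig

# Published Bonferroni-corrected 95% intervals for tied-frequency peptides
# resolved at the higher sequencing depth; frozen as count -> [lower;upper].
PUBLISHED_INTERVALS = [
    (20, 5, 35),
    (25, 8, 42),
    (30, 12, 48),
    (35, 15, 55),
    (87, 56, 118),
    (90, 58, 122),
    (189, 143, 235),
    (85, 54, 116),
    (170, 127, 213),
    (161, 119, 203),
    (144, 104, 184),
    (155, 114, 196),
    (120, 84, 156),
    (128, 90, 166),
    (120, 84, 156),
    (133, 95, 171),
    (256, 203, 309),
    (163, 121, 205),
    (160, 118, 202),
]


class TestWaldPoissonCI:
    @pytest.mark.parametrize("count,lower,upper", PUBLISHED_INTERVALS)
    def test_reproduces_every_published_interval_with_shared_z(
        self, count, lower, upper
    ):
        ci = wald_poisson_ci(count, z=DEFAULT_Z)
        assert (ci.lower, ci.upper) == (lower, upper)

    def test_zero_count_degenerates_to_zero_interval(self):
        ci = wald_poisson_ci(0)
        assert (ci.lower, ci.upper) == (0, 0)

    def test_quantile_from_bonferroni_divisor(self):
        # m=1 reduces to the uncorrected two-sided 95% quantile
        ci = wald_poisson_ci(100, alpha=0.05, m_tests=1)
        assert ci.z == pytest.approx(1.959964, abs=1e-5)
        assert (ci.lower, ci.upper) == (80, 120)

    @pytest.mark.parametrize(
        "kwargs", [{"alpha": 0.0}, {"alpha": 1.0}, {"m_tests": 0}, {"z": -1.0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            wald_poisson_ci(10, **{"alpha": 0.05, **kwargs})

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            wald_poisson_ci(-1)

    @settings(max_examples=100, derandomize=True)
    @given(count=st.integers(0, 5000), m=st.integers(1, 200))
    def test_interval_contains_count_and_widens_with_count_and_m(self, count, m):
        ci = wald_poisson_ci(count, m_tests=m)
        assert 0 <= ci.lower <= count <= ci.upper
        wider_m = wald_poisson_ci(count, m_tests=m + 50)
        assert wider_m.upper - wider_m.lower >= ci.upper - ci.lower
        bigger_count = wald_poisson_ci(count + 100, m_tests=m)
        assert (
            bigger_count.upper - bigger_count.lower >= ci.upper - ci.lower
        )


def _matrix(counts, label=None):
    return FrequencyMatrix.from_counts(counts, label=label)


class TestDistinguishingAnalysis:
    # the published tie group at shallow-depth frequency 20 and its
    # deep-depth counts
    GROUP_20 = {
        "TLHFKPPNVTML": 87,
        "ERSMYWEDITPM": 90,
        "ASNGTDHTRTPF": 189,
        "AHTMQQISPNHC": 85,
        "SDSLFWNMMTDV": 170,
        "AWPPTGILPMLN": 161,
    }

    def test_published_group_is_resolved_at_higher_depth(self):
        shallow = _matrix({p: 20 for p in self.GROUP_20})
        deep = _matrix(self.GROUP_20)
        (group,) = distinguishing_analysis(shallow, deep, [20], z=DEFAULT_Z)
        assert group.significant
        cis = dict(zip(group.members, group.b_cis))
        assert cis["ASNGTDHTRTPF"].disjoint_from(cis["AHTMQQISPNHC"])
        assert (cis["ASNGTDHTRTPF"].lower, cis["ASNGTDHTRTPF"].upper) == (143, 235)
        assert (cis["AHTMQQISPNHC"].lower, cis["AHTMQQISPNHC"].upper) == (54, 116)

    def test_identical_deep_counts_are_not_significant(self):
        shallow = _matrix({"AAA": 20, "CCC": 20})
        deep = _matrix({"AAA": 120, "CCC": 120})
        (group,) = distinguishing_analysis(shallow, deep, [20], z=DEFAULT_Z)
        assert not group.significant

    def test_intervals_sharing_one_integer_are_not_disjoint(self):
        # with the calibrated z, upper(100) = 133 = lower(177)
        assert wald_poisson_ci(100, z=DEFAULT_Z).upper == 133
        assert wald_poisson_ci(177, z=DEFAULT_Z).lower == 133
        shallow = _matrix({"AAA": 20, "CCC": 20})
        deep = _matrix({"AAA": 100, "CCC": 177})
        (group,) = distinguishing_analysis(shallow, deep, [20], z=DEFAULT_Z)
        assert not group.significant

    def test_empty_group_is_allowed(self):
        shallow = _matrix({"AAA": 3})
        deep = _matrix({"AAA": 10})
        (group,) = distinguishing_analysis(shallow, deep, [20], z=DEFAULT_Z)
        assert group.members == [] and not group.significant

    def test_result_invariant_to_input_order(self):
        shallow_counts = {p: 20 for p in self.GROUP_20}
        shallow_fwd = _matrix(shallow_counts)
        reversed_counts = dict(reversed(list(self.GROUP_20.items())))
        deep_rev = _matrix(reversed_counts)
        deep_fwd = _matrix(self.GROUP_20)
        a = distinguishing_analysis(shallow_fwd, deep_fwd, [20], z=DEFAULT_Z)
        b = distinguishing_analysis(shallow_fwd, deep_rev, [20], z=DEFAULT_Z)
        assert a[0].members == b[0].members
        assert a[0].b_counts == b[0].b_counts
        assert a[0].significant == b[0].significant

    def test_default_bonferroni_divisor_counts_all_intervals(self):
        shallow = _matrix({"AAA": 20, "CCC": 20, "GGG": 25})
        deep = _matrix({"AAA": 100, "CCC": 200, "GGG": 50})
        groups = distinguishing_analysis(shallow, deep, [20, 25])
        # 3 member CIs in B plus one A-CI per nonempty group
        assert all(ci.m_tests == 5 for g in groups for ci in g.b_cis)


class TestPeptideOverlap:
    def test_disjoint_sets_share_nothing(self):
        table = peptide_overlap([_matrix({"AAA": 1}, "x"), _matrix({"CCC": 2}, "y")])
        assert table.loc["x", "y"] == 0

    def test_self_overlap_equals_unique_count(self):
        m = _matrix({"AAA": 5, "CCC": 1, "GGG": 2}, "x")
        table = peptide_overlap([m, m])
        assert table.iloc[0, 1] == 3
        assert table.iloc[0, 0] == 3

    def test_symmetry_and_diagonal(self):
        a = _matrix({"AAA": 1, "CCC": 1}, "a")
        b = _matrix({"CCC": 4, "GGG": 4}, "b")
        table = peptide_overlap([a, b])
        assert table.loc["a", "b"] == table.loc["b", "a"] == 1
        assert table.loc["a", "a"] == 2 and table.loc["b", "b"] == 2

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError):
            peptide_overlap([_matrix({"AAA": 1})])

    def test_equal_depth_samples_overlap_matches_multinomial_oracle(self):
        """Two same-depth samples of one pool overlap incompletely; the
        pipeline route (reads -> cleaning -> matrices) must agree with a
        direct multinomial draw on the pool weights."""
        cfg = SyntheticLibraryConfig(
            true_diversity=300, seed=5,
            defect_rates=DefectRates(0.0, 0.0, 0.0, 0.0, 0.0),
        )
        pool = sample_true_library(cfg)
        n_reads, n_seeds = 500, 12
        rng = np.random.default_rng(99)
        oracle = []
        for _ in range(n_seeds):
            c1 = rng.multinomial(n_reads, pool.weights)
            c2 = rng.multinomial(n_reads, pool.weights)
            oracle.append(int(((c1 > 0) & (c2 > 0)).sum()))
        observed = []
        for seed in range(n_seeds):
            mats = []
            for half in range(2):
                _, log = simulate_reads(
                    pool, n_reads, rng=np.random.default_rng(1000 + 2 * seed + half)
                )
                mats.append(
                    _matrix(log["peptide"].value_counts().to_dict(), str(half))
                )
            table = peptide_overlap(mats)
            observed.append(int(table.iloc[0, 1]))
            assert table.iloc[0, 1] < min(table.iloc[0, 0], table.iloc[1, 1])
        sem = np.std(oracle + observed, ddof=1) * np.sqrt(2.0 / n_seeds)
        assert abs(np.mean(observed) - np.mean(oracle)) <= 4 * sem + 1


class TestPositionalFrequency:
    def test_single_peptide_is_100_percent_everywhere(self):
        pfm = positional_frequency(_matrix({"A" * 12: 1}))
        assert (pfm.loc["A"] == 100.0).all()
        assert np.allclose(pfm.sum(axis=0), 100.0)

    def test_equal_counts_split_position_one(self):
        pfm = positional_frequency(_matrix({"AC": 1, "CA": 1}))
        assert pfm.loc["A", 1] == 50.0 and pfm.loc["C", 1] == 50.0

    def test_abundance_weighting_follows_read_counts(self):
        pfm = positional_frequency(_matrix({"AC": 3, "CA": 1}), weighting="abundance")
        assert pfm.loc["A", 1] == 75.0 and pfm.loc["C", 1] == 25.0

    def test_columns_sum_to_100(self, simulated_fastq):
        from peplib import process_dataset

        path, pool, _ = simulated_fastq
        matrix, _ = process_dataset(path, pool.config.extraction_config())
        for weighting in ("unique", "abundance"):
            pfm = positional_frequency(matrix, weighting)
            assert np.allclose(pfm.sum(axis=0), 100.0)

    def test_ragged_peptide_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            positional_frequency(_matrix({"AC": 1, "ACA": 1}))

    def test_unknown_weighting_rejected(self):
        with pytest.raises(ValueError):
            positional_frequency(_matrix({"AC": 1}), weighting="reads")

    def test_large_nnk_pool_approaches_codon_table_expectations(self):
        """Residue frequencies in a random NNK pool follow codon multiplicity:
        e.g. Leu (3 NNK codons) near 3/31, Met (1 codon) near 1/31."""
        n = 20_000
        pool = sample_true_library(
            SyntheticLibraryConfig(true_diversity=n, seed=31)
        )
        pfm = positional_frequency(_matrix({p: 1 for p in pool.peptides}))
        expected = 100.0 * NNK_RESIDUE_PROBS
        sigma = 100.0 * np.sqrt(NNK_RESIDUE_PROBS * (1 - NNK_RESIDUE_PROBS) / n)
        for i, aa in enumerate(AMINO_ACIDS):
            dev = (pfm.loc[aa] - expected[i]).abs()
            assert (dev <= 5 * sigma[i] + 1e-9).all()
        assert (
            pfm.loc["L"].mean() > 2.2 * pfm.loc["M"].mean()
        )  # 3 codons vs 1


class TestPositionalDifference:
    def test_identical_matrices_give_zero(self):
        pfm = positional_frequency(_matrix({"AC": 1, "CA": 2}))
        diff = positional_difference(pfm, pfm)
        assert (diff.to_numpy() == 0).all()

    def test_antisymmetry_and_zero_column_sums(self):
        a = positional_frequency(_matrix({"AC": 1, "CG": 1}))
        b = positional_frequency(_matrix({"CA": 1, "GC": 1}))
        d = positional_difference(a, b)
        assert np.allclose(d.to_numpy(), -positional_difference(b, a).to_numpy())
        assert np.allclose(d.sum(axis=0), 0.0)

    def test_misaligned_matrices_rejected(self):
        a = positional_frequency(_matrix({"AC": 1}))
        b = positional_frequency(_matrix({"ACA": 1}))
        with pytest.raises(ValueError):
            positional_difference(a, b)
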