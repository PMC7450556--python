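import numpy as np
import pytest

from neo3dgenome.epitopes import LabeledEpitope
from neo3dgenome.genome_grid import ContactMatrix, make_bin_table
from neo3dgenome.spatial import (
    inter_chromosome_distributions,
    intra_chromosome_summary,
    pair_contact_frequency,
    write_summary_table,
)
from neo3dgenome.synthetic import (
    alternating_compartment_labels,
    generate_epitope_set,
    generate_hic,
)


def ep(peptide, chrom, bin_index, label, bins):
    ci = bins.chrom_index(chrom)
    pos = (bin_index - bins.bin_offsets[ci]) * bins.bin_size
    return LabeledEpitope(
        peptide=peptide, mhc_allele="HLA-A*02:01",
        positive_rate=1.0 if label == "positive" else 0.0, label=label,
        chrom=chrom, position=pos, bin_index=bin_index,
    )


@pytest.fixture
def four_bin_setup():
    bins = make_bin_table([("chr1", 4 * 500_000)])
    counts = np.zeros((4, 4))
    counts[1, 3] = counts[3, 1] = 7.0
    m = ContactMatrix(bins=bins, counts=counts)
    return bins, m


class TestPairContactFrequency:
    def test_direct_lookup_and_symmetry(self, four_bin_setup):
        bins, m = four_bin_setup
        a = ep("AAAAAAAAA", "chr1", 1, "positive", bins)
        b = ep("CCCCCCCCC", "chr1", 3, "negative", bins)
        assert pair_contact_frequency(a, b, m) == 7.0
        assert pair_contact_frequency(b, a, m) == 7.0

    def test_same_bin_uses_diagonal(self, four_bin_setup):
        bins, m = four_bin_setup
        m.counts[2, 2] = 3.0
        a = ep("AAAAAAAAA", "chr1", 2, "positive", bins)
        b = ep("CCCCCCCCC", "chr1", 2, "positive", bins)
        assert pair_contact_frequency(a, b, m) == 3.0

    def test_unlocated_epitope_rejected(self, four_bin_setup):
        bins, m = four_bin_setup
        a = ep("AAAAAAAAA", "chr1", 1, "positive", bins)
        b = LabeledEpitope("CCCCCCCCC", "HLA-A*02:01", 0.0, "negative")
        with pytest.raises(ValueError, match="located"):
            pair_contact_frequency(a, b, m)


class TestIntraChromosome:
    def test_identical_samples_not_significant(self):
        bins = make_bin_table([("chr1", 4 * 500_000)])
        m = ContactMatrix(bins=bins, counts=np.full((4, 4), 5.0))
        eps = [
            ep("A" * 9, "chr1", 0, "positive", bins),
            ep("C" * 9, "chr1", 1, "positive", bins),
            ep("D" * 9, "chr1", 2, "negative", bins),
            ep("E" * 9, "chr1", 3, "negative", bins),
        ]
        res = intra_chromosome_summary(eps, m, seed=0)
        assert res["chr1"].pos_pos.mean == res["chr1"].neg_neg.mean == 5.0
        assert not res["chr1"].significant

    def test_pair_counts_are_combinatorial(self):
        bins = make_bin_table([("chr1", 10 * 500_000)])
        labels = alternating_compartment_labels(bins, block=5)
        m = generate_hic(bins, labels, seed=1)
        eps = generate_epitope_set(bins, 5, 4, spatial_mode="uniform", seed=2)
        res = intra_chromosome_summary(eps, m, n_permutations=19, seed=0)
        assert res["chr1"].pos_pos.n_pairs == 5 * 4 // 2  # C(5,2)
        assert res["chr1"].neg_neg.n_pairs == 4 * 3 // 2  # C(4,2)

    def test_underpowered_chromosome_skipped(self):
        bins = make_bin_table([("chr1", 4 * 500_000), ("chr2", 4 * 500_000)])
        m = ContactMatrix(bins=bins, counts=np.ones((8, 8)))
        eps = [
            ep("A" * 9, "chr1", 0, "positive", bins),
            ep("C" * 9, "chr1", 1, "positive", bins),
            ep("D" * 9, "chr1", 2, "negative", bins),
            ep("E" * 9, "chr1", 3, "negative", bins),
            ep("F" * 9, "chr2", 4, "positive", bins),  # lone pair on chr2
            ep("G" * 9, "chr2", 5, "negative", bins),
        ]
        res = intra_chromosome_summary(eps, m, seed=0)
        assert "chr2" not in res and "chr1" in res

    def test_planted_shift_detected(self):
        """pos-pos CFs boosted by +2 sigma -> flagged significant."""
        bins = make_bin_table([("chr1", 40 * 500_000)])
        labels = alternating_compartment_labels(bins, block=5)
        hits = 0
        for seed in range(10):
            m = generate_hic(bins, labels, seed=seed)
            eps = generate_epitope_set(bins, 12, 12, spatial_mode="uniform", seed=seed)
            counts = m.counts.copy()
            sigma = counts[np.triu_indices(40)].std()
            pos_bins = np.unique([e.bin_index for e in eps if e.is_positive])
            counts[np.ix_(pos_bins, pos_bins)] += 2 * sigma
            m2 = ContactMatrix(bins=bins, counts=counts)
            res = intra_chromosome_summary(eps, m2, n_permutations=299, seed=seed)
            hits += res["chr1"].significant
        assert hits >= 9

    def test_null_calibration_quick(self):
        """Label permutation null: significance rate compatible with 5%."""
        bins = make_bin_table([("chr1", 40 * 500_000)])
        labels = alternating_compartment_labels(bins, block=5)
        m = generate_hic(bins, labels, seed=42)
        eps = generate_epitope_set(bins, 12, 12, spatial_mode="uniform", seed=7)
        rng = np.random.default_rng(0)
        labs = np.array([e.label for e in eps])
        hits = 0
        n = 200
        for i in range(n):
            perm = rng.permutation(labs)
            for e, l in zip(eps, perm):
                e.label = l
            res = intra_chromosome_summary(eps, m, n_permutations=99, seed=i)
            hits += res["chr1"].significant
        # binomial 99% band around 0.05 at n=200
        assert 0.01 <= hits / n <= 0.10


class TestInterChromosome:
    def test_all_zero_matrix_degenerate(self):
        bins = make_bin_table([("chr1", 2 * 500_000), ("chr2", 2 * 500_000)])
        m = ContactMatrix(bins=bins, counts=np.zeros((4, 4)))
        eps = [
            ep("A" * 9, "chr1", 0, "positive", bins),
            ep("C" * 9, "chr1", 1, "negative", bins),
            ep("D" * 9, "chr2", 2, "positive", bins),
            ep("E" * 9, "chr2", 3, "negative", bins),
        ]
        summaries, pvals = inter_chromosome_distributions(eps, m, seed=0)
        assert all(s.mean == 0.0 for s in summaries.values() if s.n_pairs)
        assert all(not np.isfinite(p) or p > 0.9 for p in pvals.values())

    def test_label_swap_symmetry(self):
        bins = make_bin_table([("chr1", 5 * 500_000), ("chr2", 5 * 500_000)])
        labels = alternating_compartment_labels(bins, block=2)
        m = generate_hic(bins, labels, seed=3)
        eps = generate_epitope_set(bins, 4, 5, spatial_mode="uniform", seed=4)
        s1, _ = inter_chromosome_distributions(eps, m, n_permutations=9, seed=0)
        for e in eps:
            e.label = "negative" if e.label == "positive" else "positive"
        s2, _ = inter_chromosome_distributions(eps, m, n_permutations=9, seed=0)
        np.testing.assert_array_equal(
            np.sort(s1["pos-pos"].cf_values), np.sort(s2["neg-neg"].cf_values)
        )
        np.testing.assert_array_equal(
            np.sort(s1["neg-neg"].cf_values), np.sort(s2["pos-pos"].cf_values)
        )

    def test_planted_hub_ordering(self):
        """Positives share high-contact inter-chromosomal hubs:
        mean(pos-pos) > mean(pos-neg) > mean(neg-neg)."""
        bins = make_bin_table([("chr1", 10 * 500_000), ("chr2", 10 * 500_000)])
        counts = np.ones((20, 20))
        hub_bins = [0, 1, 10, 11]  # hubs on both chromosomes
        counts[hub_bins, :] = 5.0  # hubs contact everything moderately
        counts[:, hub_bins] = 5.0
        for a in hub_bins:
            for b in hub_bins:
                counts[a, b] = 50.0  # and each other strongly
        m = ContactMatrix(bins=bins, counts=counts)
        eps = [
            ep("A" * 9, "chr1", 0, "positive", bins),
            ep("C" * 9, "chr1", 1, "positive", bins),
            ep("D" * 9, "chr2", 10, "positive", bins),
            ep("E" * 9, "chr2", 11, "positive", bins),
            ep("F" * 9, "chr1", 5, "negative", bins),
            ep("G" * 9, "chr1", 6, "negative", bins),
            ep("H" * 9, "chr2", 15, "negative", bins),
            ep("I" * 9, "chr2", 16, "negative", bins),
        ]
        s, _ = inter_chromosome_distributions(eps, m, seed=0)
        assert s["pos-pos"].mean > s["pos-neg"].mean > s["neg-neg"].mean

    def test_pair_count_closed_form(self):
        bins = make_bin_table([("chr1", 5 * 500_000), ("chr2", 5 * 500_000)])
        labels = alternating_compartment_labels(bins, block=2)
        m = generate_hic(bins, labels, seed=6)
        eps = generate_epitope_set(bins, 6, 7, spatial_mode="uniform", seed=8)
        s, _ = inter_chromosome_distributions(eps, m, n_permutations=9, seed=0)
        pos = [e for e in eps if e.is_positive]
        neg = [e for e in eps if not e.is_positive]

        def cross(group_a, group_b, same):
            if same:
                return sum(
                    1
                    for i, a in enumerate(group_a)
                    for b in group_a[i + 1 :]
                    if a.chrom != b.chrom
                )
            return sum(1 for a in group_a for b in group_b if a.chrom != b.chrom)

        assert s["pos-pos"].n_pairs == cross(pos, pos, True)
        assert s["neg-neg"].n_pairs == cross(neg, neg, True)
        assert s["pos-neg"].n_pairs == cross(pos, neg, False)


def test_summary_table_writer(tmp_path, four_bin_setup):
    bins, m = four_bin_setup
    eps = [
        ep("A" * 9, "chr1", 0, "positive", bins),
        ep("C" * 9, "chr1", 1, "positive", bins),
        ep("D" * 9, "chr1", 2, "negative", bins),
        ep("E" * 9, "chr1", 3, "negative", bins),
    ]
    res = intra_chromosome_summary(eps, m, n_permutations=9, seed=0)
    out = tmp_path / "summary.tsv"
    write_summary_table([res["chr1"].pos_pos, res["chr1"].neg_neg], out)
    assert "pos-pos" in out.read_text()
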