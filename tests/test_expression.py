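import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txseq import expression as expr
from txseq.io_formats import AlignedFragment, GeneModel, Transcript


def gene(gid, chrom, strand, *transcripts):
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                     transcripts=[Transcript(f"{gid}.t{i}", list(exons))
                                  for i, exons in enumerate(transcripts)])


def frag(fid, chrom, blocks, sample="a", unique=True):
    return AlignedFragment(fragment_id=fid, sample=sample, chrom=chrom,
                           blocks=list(blocks), unique=unique)


class TestConstitutiveExons:
    def test_intersection_across_isoforms(self):
        e1, e2, e3 = (100, 200), (300, 400), (500, 600)
        g = gene("G", "chr1", "+", [e1, e2, e3], [e1, e3])
        sets = expr.derive_constitutive_exons([g])
        assert sets[0].intervals == [e1, e3]

    def test_single_isoform_all_exons(self):
        g = gene("G", "chr1", "+", [(100, 200), (300, 400)])
        sets = expr.derive_constitutive_exons([g])
        assert sets[0].intervals == [(100, 200), (300, 400)]

    def test_one_bp_overlap_removes_whole_interval(self):
        # brute-force per-base set algebra confirms base 399 is shared; the
        # filter removes the whole overlapped interval, not just the base
        g1 = gene("G1", "chr1", "+", [(100, 200), (300, 400)])
        g2 = gene("G2", "chr1", "-", [(399, 500)])
        shared = set(range(300, 400)) & set(range(399, 500))
        assert shared == {399}
        sets = {s.gene_id: s for s in expr.derive_constitutive_exons([g1, g2])}
        assert sets["G1"].intervals == [(100, 200)]
        assert sets["G2"].intervals == []

    def test_partial_exon_intersection(self):
        g = gene("G", "chr1", "+", [(100, 250)], [(150, 300)])
        sets = expr.derive_constitutive_exons([g])
        assert sets[0].intervals == [(150, 250)]

    def test_empty_gene_warns(self, caplog):
        g = GeneModel("G", "chr1", "+", [])
        with caplog.at_level("WARNING"):
            sets = expr.derive_constitutive_exons([g])
        assert sets[0].intervals == []


class TestCountConstitutive:
    g = gene("G", "chr1", "+", [(1000, 1200), (1500, 1700)])
    sets = expr.derive_constitutive_exons([g])

    def test_paired_fragment_inside_exon(self):
        f = frag("f", "chr1", [(1010, 1060), (1100, 1150)])
        counts = expr.count_constitutive_fragments([f], self.sets, ["a"])
        assert counts.loc["G", "a"] == 1

    def test_exon_intron_straddle_not_counted(self):
        f = frag("f", "chr1", [(1150, 1250)])
        counts = expr.count_constitutive_fragments([f], self.sets, ["a"])
        assert counts.loc["G", "a"] == 0

    def test_spliced_fragment_across_two_exons(self):
        # per-base check: every aligned base inside the constitutive set
        f = AlignedFragment("f", "a", "chr1", [(1150, 1200), (1500, 1550)],
                            junctions=[(1200, 1500)])
        const = set()
        for s, e in self.sets[0].intervals:
            const.update(range(s, e))
        assert all(b in const for bs, be in f.blocks for b in range(bs, be))
        counts = expr.count_constitutive_fragments([f], self.sets, ["a"])
        assert counts.loc["G", "a"] == 1

    def test_non_unique_excluded(self):
        f = frag("f", "chr1", [(1010, 1060)], unique=False)
        counts = expr.count_constitutive_fragments([f], self.sets, ["a"])
        assert counts.loc["G", "a"] == 0


class TestGenicAccounting:
    genes = [gene("G1", "chr1", "+", [(1000, 1200), (1500, 1700)]),
             gene("G2", "chr1", "+", [(5000, 5300)])]

    def classify(self, fragments):
        return expr.genic_accounting(fragments, self.genes, ["a"])["a"]

    def test_exonic_intronic_intergenic(self):
        frags = [
            frag("e1", "chr1", [(1010, 1100)]),
            frag("i1", "chr1", [(1300, 1400)]),          # intron only
            frag("i2", "chr1", [(1150, 1250)]),          # straddles boundary
            frag("x1", "chr1", [(9000, 9100)]),
            frag("e2", "chr1", [(5100, 5200)]),
        ]
        acc = self.classify(frags)
        assert (acc.exonic, acc.intronic, acc.intergenic) == (2, 2, 1)
        assert acc.genic == 4
        assert acc.total_unique == 5

    def test_table1_blastocyst_fraction(self):
        # printed counts: 2,525,630 intronic of 14,121,649 genic -> 17.9%
        assert expr.intronic_of_genic_percent(2_525_630, 14_121_649) == 17.9
        assert 11_596_019 + 2_525_630 == 14_121_649

    def test_table1_degenerative_fraction(self):
        # printed counts: 3,644,395 intronic of 10,748,218 genic -> 33.9%
        assert expr.intronic_of_genic_percent(3_644_395, 10_748_218) == 33.9

    def test_zero_intronic(self):
        acc = self.classify([frag("e", "chr1", [(1010, 1100)])])
        assert acc.intronic_of_genic == 0.0

    def test_zero_genic_fraction_missing(self):
        acc = self.classify([frag("x", "chr1", [(9000, 9050)])])
        assert acc.intronic_of_genic is None
        assert expr.intronic_of_genic_percent(0, 0) is None

    def test_conservation(self, default_sim, default_fragments):
        config, bundle, reads = default_sim
        acc = expr.genic_accounting(default_fragments, bundle.genes,
                                    list(config.samples))
        for sample in config.samples:
            a = acc[sample]
            assert a.exonic + a.intronic + a.intergenic == a.total_unique
            assert a.total_unique == len(reads.fragments[sample])

    def test_constitutive_leq_exonic(self, default_sim, default_fragments):
        config, bundle, _ = default_sim
        sets = expr.derive_constitutive_exons(bundle.genes)
        counts = expr.count_constitutive_fragments(
            default_fragments, sets, list(config.samples))
        acc = expr.genic_accounting(default_fragments, bundle.genes,
                                    list(config.samples))
        for sample in config.samples:
            assert counts[sample].sum() <= acc[sample].exonic


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        out = expr.quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_hand_computed_rank_means(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [4, 5, 6]})
        out = expr.quantile_normalize(df)
        expected = pd.DataFrame({"a": [2.5, 3.5, 4.5], "b": [2.5, 3.5, 4.5]})
        pd.testing.assert_frame_equal(out, expected)

    def test_tie_average_oracle(self):
        # brute-force oracle on a 4x2 matrix with a tie in column a:
        # ref = rowwise mean of sorted columns; tied entries share the mean
        # of the reference values at their ranks
        df = pd.DataFrame({"a": [2, 2, 5, 7], "b": [1, 3, 4, 8]})
        ref = (np.sort(df["a"]) + np.sort(df["b"])) / 2  # [1.5, 2.5, 4.5, 7.5]
        out = expr.quantile_normalize(df)
        assert out["a"][0] == out["a"][1] == pytest.approx((ref[0] + ref[1]) / 2)
        assert list(out["b"]) == pytest.approx(list(ref))

    def test_column_multisets_identical(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(2, 1, size=(200, 2)), columns=["a", "b"])
        out = expr.quantile_normalize(df)
        assert np.allclose(np.sort(out["a"]), np.sort(out["b"]))

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.lognormal(2, 1, size=(300, 2)), columns=["a", "b"])
        once = expr.quantile_normalize(df)
        twice = expr.quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_single_column_identity(self, caplog):
        df = pd.DataFrame({"a": [1, 2, 3]})
        with caplog.at_level("WARNING"):
            out = expr.quantile_normalize(df)
        assert list(out["a"]) == [1.0, 2.0, 3.0]


def enumeration_pvalue(k_a, k_b, pmf):
    """Independent oracle: full enumeration over all splits of the total."""
    total = k_a + k_b
    probs = [pmf(a) * pmf(total - a) for a in range(total + 1)]
    obs = probs[k_a]
    return sum(p for p in probs if p <= obs * (1 + 1e-8)) / sum(probs)


class TestNBExactTest:
    def test_equal_counts_p_one(self):
        assert expr.nb_exact_pvalue(17, 17, alpha=0.05) == pytest.approx(1.0)

    def test_poisson_limit_matches_binomial_enumeration(self):
        # alpha=0: null is Poisson; conditional split is Binomial(10, 1/2)
        p = expr.nb_exact_pvalue(0, 10, alpha=0.0)
        oracle = enumeration_pvalue(0, 10, lambda k: stats.poisson.pmf(k, 5.0))
        assert p == pytest.approx(oracle)
        # closed form: only the two extreme splits qualify
        assert p == pytest.approx(2 * 0.5**10 / 1.0, rel=1e-6)

    @pytest.mark.parametrize("ka,kb,alpha", [
        (3, 12, 0.0), (0, 7, 0.1), (25, 40, 0.02), (5, 5, 0.3), (1, 30, 0.15),
    ])
    def test_matches_enumeration_oracle(self, ka, kb, alpha):
        m = (ka + kb) / 2
        if alpha > 0:
            size = 1 / alpha
            pmf = lambda k: stats.nbinom.pmf(k, size, size / (size + m))
        else:
            pmf = lambda k: stats.poisson.pmf(k, m)
        assert expr.nb_exact_pvalue(ka, kb, alpha) == \
            pytest.approx(enumeration_pvalue(ka, kb, pmf))

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame({"a": rng.poisson(50, 300),
                               "b": rng.poisson(50, 300)})
        fwd = expr.nb_exact_test(counts)
        rev = expr.nb_exact_test(counts[["b", "a"]])
        assert np.allclose(fwd["p"], rev["p"], equal_nan=True)

    def test_zero_sum_feature_excluded(self):
        counts = pd.DataFrame({"a": [0, 10], "b": [0, 10]})
        res = expr.nb_exact_test(counts, alpha=0.0)
        assert np.isnan(res.loc[0, "p"]) and np.isnan(res.loc[0, "q"])
        assert res.loc[1, "q"] == pytest.approx(res.loc[1, "p"])  # BH over 1

    def test_two_columns_required(self):
        with pytest.raises(ValueError):
            expr.nb_exact_test(pd.DataFrame({"a": [1], "b": [2], "c": [3]}))

    def test_null_type_i_error_single_seed(self):
        rng = np.random.default_rng(123)
        m = rng.lognormal(5, 1, 2000)
        size = 1 / 0.1
        counts = pd.DataFrame({
            "a": rng.negative_binomial(size, size / (size + m)),
            "b": rng.negative_binomial(size, size / (size + m))})
        res = expr.nb_exact_test(counts)
        assert 0.03 <= (res["p"] < 0.05).mean() <= 0.07


class TestPremrnaModel:
    def test_zero_premrna(self):
        assert expr.premrna_intronic_model(0.0, 0.05) == 0.0

    def test_all_premrna(self):
        assert expr.premrna_intronic_model(1.0, 1 / 20) == pytest.approx(0.95)

    def test_direct_evaluation(self):
        # f(0.05) = 0.0475 / 0.0975 with e = 1/20
        f = expr.premrna_intronic_model(0.05, 1 / 20)
        assert f == pytest.approx(0.0475 / 0.0975)
        assert f == pytest.approx(0.487, abs=0.001)

    def test_degenerate_convention(self):
        assert expr.premrna_intronic_model(0.0, 0.0) == 0.0

    def test_strictly_increasing_with_steep_start(self):
        e = 1 / 20
        ps = np.linspace(0, 1, 201)
        fs = [expr.premrna_intronic_model(p, e) for p in ps]
        assert all(b > a for a, b in zip(fs, fs[1:]))
        # derivative at 0 is (1-e)/e = 19
        h = 1e-7
        deriv = expr.premrna_intronic_model(h, e) / h
        assert deriv == pytest.approx((1 - e) / e, rel=1e-4)

    def test_length_weighted_sampling_cross_check(self):
        # 1e5 reads over a two-molecule population, sampled by length
        rng = np.random.default_rng(9)
        p, e = 0.05, 1 / 20
        n = 100_000
        pre = rng.random(n) < (p * 1.0) / (p * 1.0 + (1 - p) * e)
        intronic = pre & (rng.random(n) < (1 - e))
        assert abs(intronic.mean() - expr.premrna_intronic_model(p, e)) < 0.01

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expr.premrna_intronic_model(1.5, 0.05)


class TestDESensitivity:
    def test_planted_de_recovered(self, default_sim, default_fragments):
        config, bundle, _ = default_sim
        sets = expr.derive_constitutive_exons(bundle.genes)
        counts = expr.count_constitutive_fragments(
            default_fragments, sets, list(config.samples))
        res = expr.nb_exact_test(expr.quantile_normalize(counts), fdr=0.01)
        res = res.set_index("feature")
        truth = bundle.truth.genes.set_index("gene_id")
        exprs = bundle.truth.expression
        qualifying = [
            g for g in truth.index
            if truth.loc[g, "is_de"] and exprs.loc[g].sum() >= 400
        ]
        assert qualifying
        hits = sum(bool(res.loc[g, "sig"]) for g in qualifying)
        assert hits / len(qualifying) >= 0.9
        # no false positives among unperturbed, non-AS genes
        null = [g for g in truth.index
                if not truth.loc[g, "is_de"] and truth.loc[g, "as_type"] == ""]
        assert res.loc[null, "sig"].sum() <= max(1, 0.02 * len(null))
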