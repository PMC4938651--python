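"""Summary statistics: Hudson F_ST, pi, Tajima's D, SFS projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolscan.sumstats import (
    JointSFS,
    SnpFrequencyPair,
    build_joint_sfs,
    classify_and_count,
    combine_fst,
    compare_site_classes,
    hudson_fst,
    hudson_fst_arrays,
    locus_summaries,
    nucleotide_diversity,
    project_sfs,
    read_sfs_text,
    tajimas_d,
    write_sfs_text,
)

freqs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestHudsonFst:
    def test_complete_fixation(self):
        for n1, n2 in ((96, 96), (10, 50)):
            _, _, fst = hudson_fst(SnpFrequencyPair(1.0, 0.0, n1, n2))
            assert fst == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.9])
    def test_equal_frequencies_give_negative_constant(self, p):
        _, _, fst = hudson_fst(SnpFrequencyPair(p, p, 96, 96))
        assert fst == pytest.approx(-1 / 95, abs=1e-12)

    def test_worked_example(self):
        num, den, fst = hudson_fst(SnpFrequencyPair(0.8, 0.2, 96, 96))
        assert num == pytest.approx(0.3566316, abs=1e-6)
        assert den == pytest.approx(0.68, abs=1e-12)
        assert fst == pytest.approx(0.524458, abs=1e-6)

    def test_zero_denominator_flagged(self):
        _, den, fst = hudson_fst(SnpFrequencyPair(0.0, 0.0, 96, 96))
        assert den == 0 and np.isnan(fst)

    @given(p1=freqs, p2=freqs,
           n1=st.integers(2, 500), n2=st.integers(2, 500))
    @settings(max_examples=300, deadline=None)
    def test_matches_symbol_by_symbol_oracle(self, p1, p2, n1, n2):
        """The implementation equals a literal re-evaluation of the printed
        estimator to 1e-12."""
        num, den, fst = hudson_fst(SnpFrequencyPair(p1, p2, n1, n2))
        o_num = (p1 - p2) ** 2 - (p1 * (1 - p1)) / (n1 - 1) - (p2 * (1 - p2)) / (n2 - 1)
        o_den = p1 * (1 - p2) + p2 * (1 - p1)
        assert num == pytest.approx(o_num, abs=1e-12)
        assert den == pytest.approx(o_den, abs=1e-12)
        if o_den > 0:
            assert fst == pytest.approx(o_num / o_den, abs=1e-12)
            assert fst <= 1.0 + 1e-12
            assert fst >= -1.0 / (min(n1, n2) - 1) - 1e-9

    @given(st.lists(st.tuples(st.integers(0, 96), st.integers(0, 96)),
                    min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_combined_estimators_invariant_to_label_swap(self, count_pairs):
        p1 = np.array([a for a, _ in count_pairs]) / 96
        p2 = np.array([b for _, b in count_pairs]) / 96
        num, den, _ = hudson_fst_arrays(p1, p2)
        num_s, den_s, _ = hudson_fst_arrays(1 - p1, 1 - p2)
        if not (den > 0).any():
            return
        for method in ("ratio_of_sums", "mean_of_ratios"):
            assert combine_fst(num, den, method) == pytest.approx(
                combine_fst(num_s, den_s, method), abs=1e-9
            )

    def test_combined_estimator_order_invariance(self, rng):
        p1, p2 = rng.random(200), rng.random(200)
        num, den, _ = hudson_fst_arrays(p1, p2)
        perm = rng.permutation(200)
        assert combine_fst(num, den) == pytest.approx(
            combine_fst(num[perm], den[perm]), abs=1e-12
        )


class TestCombineFst:
    def test_single_snp_both_methods_agree(self):
        num, den, fst = hudson_fst(SnpFrequencyPair(0.8, 0.2))
        assert combine_fst([num], [den], "ratio_of_sums") == pytest.approx(fst)
        assert combine_fst([num], [den], "mean_of_ratios") == pytest.approx(fst)

    def test_worked_examples(self):
        assert combine_fst([1, -0.01], [1, 1], "ratio_of_sums") == pytest.approx(0.495)
        assert combine_fst([1, -0.01], [1, 1], "mean_of_ratios") == pytest.approx(0.495)
        # a small-denominator SNP drags the mean of ratios but barely moves
        # the ratio of sums
        assert combine_fst([1, -0.01], [1, 0.1], "ratio_of_sums") == pytest.approx(0.9)
        assert combine_fst([1, -0.01], [1, 0.1], "mean_of_ratios") == pytest.approx(0.45)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_fst([], [])
        with pytest.raises(ValueError):
            combine_fst([0.1], [0.0])

    def test_ratio_of_sums_exceeds_mean_with_rare_snps(self, fitted_model):
        """With many rare SNPs (negative per-SNP F_ST, small denominators),
        the ratio of sums exceeds the mean of ratios."""
        from poolscan.models import LocusSpec
        from poolscan.simdata import simulate_genealogy_counts

        loci = [LocusSpec(f"g{i}", 1000) for i in range(30)]
        wins = 0
        for seed in range(10):
            tbl = simulate_genealogy_counts(fitted_model, loci, seed=300 + seed)
            p1, p2 = tbl.frequencies()
            num, den, _ = hudson_fst_arrays(p1, p2)
            if combine_fst(num, den, "ratio_of_sums") >= combine_fst(
                num, den, "mean_of_ratios"
            ):
                wins += 1
        assert wins >= 9


class TestDiversity:
    def test_no_snps_zero(self):
        assert nucleotide_diversity([], 96, 100) == 0.0

    def test_single_snp_example(self):
        assert nucleotide_diversity([0.5], 96, 100) == pytest.approx(0.00505263, abs=1e-8)

    def test_unbiasedness_under_neutral_model(self):
        """E[pi-hat] = theta per site on single-population fixtures."""
        import random as pyrandom
        from poolscan.coalescent import simulate_locus_counts
        from poolscan.models import DemographicModel

        theta = 0.005
        n_dip = 1000.0
        model = DemographicModel(
            n_anc=n_dip, n_fen=n_dip, n_alp=n_dip, t_div=0.0,
            mu_per_year=theta / (4 * n_dip), gen_time=1.0,
        )
        rng = pyrandom.Random(5)
        np_rng = np.random.default_rng(6)
        pis = []
        for _ in range(2000):
            _, c1, c2 = simulate_locus_counts(model, 500, 5, 5, rng, np_rng)
            pis.append(nucleotide_diversity((c1 + c2) / 10, 10, 500))
        pis = np.array(pis)
        se = pis.std() / np.sqrt(len(pis))
        assert abs(pis.mean() - theta) < 3 * se


class TestTajimasD:
    def test_singletons_negative(self):
        assert tajimas_d(np.full(12, 1 / 96), 96) < 0

    def test_intermediate_positive(self):
        assert tajimas_d(np.array([0.5]), 96) > 0

    def test_frozen_oracle_value(self):
        """n=10, derived counts {1,1,5}: frozen value from an independent
        evaluation of the 1989 formulas."""
        d = tajimas_d(np.array([0.1, 0.1, 0.5]), 10)
        assert d == pytest.approx(-0.3559056055, abs=1e-9)

    def test_undefined_without_segregating_sites(self):
        assert np.isnan(tajimas_d(np.array([]), 96))
        assert np.isnan(tajimas_d(np.array([0.0, 1.0]), 96))


class TestAccounting:
    def test_shared_private_counts(self):
        df = pd.DataFrame(
            {"locus": "g", "pos": [1, 2, 3],
             "p_fen": [0.2, 0.0, 0.3], "p_alp": [0.1, 0.4, 0.0]}
        )
        out = classify_and_count(df)
        assert out["shared"] == 1
        assert out["private_fen"] == 1 and out["private_alp"] == 1
        assert out["mean_freq_private_fen"] == pytest.approx(0.3)
        assert out["mean_freq_private_alp"] == pytest.approx(0.4)

    def test_empty_input(self):
        out = classify_and_count(pd.DataFrame(columns=["p_fen", "p_alp"]))
        assert out["n_snps"] == 0 and out["shared"] == 0


class TestJointSfs:
    def test_projection_to_same_size_is_identity(self, rng):
        p1, p2 = rng.integers(0, 11, 50) / 10, rng.integers(0, 11, 50) / 10
        sfs = build_joint_sfs(p1, p2, 10, 10)
        proj = project_sfs(sfs, 10, 10)
        assert np.allclose(proj.counts, sfs.counts)

    def test_hypergeometric_weights_example(self):
        sfs = JointSFS(np.zeros((5, 3)))
        sfs.counts[2, 1] = 1.0
        proj = project_sfs(sfs, 2, 2)
        assert np.allclose(proj.counts[:, 1], [1 / 6, 4 / 6, 1 / 6])

    def test_mass_conservation_and_linearity(self, rng):
        pa1, pa2 = rng.random(300), rng.random(300)
        pb1, pb2 = rng.random(200), rng.random(200)
        a = build_joint_sfs(pa1, pa2)
        b = build_joint_sfs(pb1, pb2)
        pa = project_sfs(a)
        pb = project_sfs(b)
        ab = project_sfs(JointSFS(a.counts + b.counts))
        assert pa.total() == pytest.approx(a.total(), abs=1e-9)
        assert np.allclose(ab.counts, pa.counts + pb.counts, atol=1e-9)

    def test_out_of_range_counts_rejected(self):
        with pytest.raises(ValueError):
            build_joint_sfs([1.2], [0.5])

    def test_text_round_trip(self, rng, tmp_path):
        sfs = project_sfs(build_joint_sfs(rng.random(100), rng.random(100)))
        path = tmp_path / "sfs.txt"
        write_sfs_text(sfs, path)
        back = read_sfs_text(path)
        assert np.allclose(back.counts, sfs.counts, atol=1e-8)


class TestLocusSummaries:
    def test_summary_table(self):
        df = pd.DataFrame(
            {"locus": ["gA", "gA", "gB"], "pos": [1, 2, 1],
             "p_fen": [0.5, 0.0, 0.25], "p_alp": [0.5, 0.3, 0.0]}
        )
        out = locus_summaries(df, {"gA": 100, "gB": 50}, n=96)
        ga = out[out["locus"] == "gA"].iloc[0]
        assert ga["S_fen"] == 1 and ga["S_alp"] == 2
        assert ga["pi_fen"] == pytest.approx(0.00505263, abs=1e-8)


class TestSiteClassComparison:
    def test_identical_distributions(self, rng):
        x = rng.normal(size=60)
        out = compare_site_classes(
            np.concatenate([x, x]), np.array(["a"] * 60 + ["b"] * 60), "a", "b"
        )
        assert out["ks_stat"] == 0.0
        assert out["ks_p"] == pytest.approx(1.0)

    def test_shifted_distribution_detected(self, rng):
        x = rng.normal(size=100)
        scores = np.concatenate([x, x + 1.0])
        labels = np.array(["a"] * 100 + ["b"] * 100)
        out = compare_site_classes(scores, labels, "a", "b")
        assert out["ranksum_p"] < 1e-3
        assert out["mean_b"] - out["mean_a"] == pytest.approx(1.0, abs=0.05)

    def test_degenerate_classes_rejected(self):
        with pytest.raises(ValueError):
            compare_site_classes(np.array([1.0, 2.0]), np.array(["a", "b"]), "a", "b")
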