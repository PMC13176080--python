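import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haploquartet import (
    AtlasSimConfig,
    CountsMatrix,
    SampleSheet,
    de_two_group,
    fit_nb_glm,
    lrt_test,
    nb_lrt_gene,
    overlap_degs,
    simulate_atlas,
    size_factors,
)
from haploquartet.nbglm import design_from_labels, nb_loglik

from _oracles import median_of_ratios


def _two_group_sheet(n_per=4):
    rows = [
        {"sample_id": f"{c}_r{i}", "condition": c, "tissue": "leaf", "replicate": i}
        for c in ("control", "stress")
        for i in range(1, n_per + 1)
    ]
    return SampleSheet(pd.DataFrame(rows))


class TestSizeFactors:
    def test_doubled_sample_gets_double_factor(self):
        df = pd.DataFrame(
            {"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=["g1", "g2", "g3"]
        )
        f = size_factors(df)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_identical_samples_all_one(self):
        df = pd.DataFrame(
            {"s1": [5, 7, 9], "s2": [5, 7, 9], "s3": [5, 7, 9]},
            index=["g1", "g2", "g3"],
        )
        np.testing.assert_allclose(size_factors(df), 1.0)

    def test_matches_independent_median_of_ratios(self):
        rng = np.random.default_rng(0)
        mat = rng.negative_binomial(5, 0.05, size=(50, 6)) + 1
        df = pd.DataFrame(mat, index=[f"g{i}" for i in range(50)],
                          columns=[f"s{j}" for j in range(6)])
        got = size_factors(df)
        expected = median_of_ratios(mat.tolist())
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_fallback_with_sparse_matrix(self):
        rng = np.random.default_rng(1)
        mat = rng.poisson(20, size=(40, 10))
        mat[np.arange(40), rng.integers(0, 10, 40)] = 0  # kill all-positive genes
        df = pd.DataFrame(mat, index=[f"g{i}" for i in range(40)],
                          columns=[f"s{j}" for j in range(10)])
        f = size_factors(df)
        assert (f > 0).all()
        assert np.median(f) == pytest.approx(1.0)


class TestNBFit:
    def test_saturated_one_factor_recovers_group_means(self):
        y = np.array([10.0, 12.0, 8.0, 10.0, 40.0, 38.0, 42.0, 40.0])
        X, levels = design_from_labels(["a"] * 4 + ["b"] * 4)
        fit = fit_nb_glm(y, X)
        mu = fit.mu
        np.testing.assert_allclose(mu[:4], y[:4].mean(), rtol=1e-6)
        np.testing.assert_allclose(mu[4:], y[4:].mean(), rtol=1e-6)

    def test_poisson_group_means_weighted_by_size_factors(self):
        # Poisson (alpha=0) log-link one-factor MLE: mu_g = sum(y)/sum(s)
        y = np.array([10.0, 30.0, 22.0, 44.0])
        s = np.array([1.0, 2.0, 1.0, 2.0])
        X, _ = design_from_labels(["a", "a", "b", "b"])
        fit = fit_nb_glm(y, X, offsets=np.log(s), alpha=0.0)
        m_a = y[:2].sum() / s[:2].sum()
        m_b = y[2:].sum() / s[2:].sum()
        np.testing.assert_allclose(fit.mu, [m_a * 1, m_a * 2, m_b * 1, m_b * 2],
                                   rtol=1e-8)

    def test_poisson_data_yields_small_dispersion(self):
        rng = np.random.default_rng(42)
        X = np.ones((8, 1))
        small = 0
        n_genes = 500
        for _ in range(n_genes):
            y = rng.poisson(100, size=8)
            fit = fit_nb_glm(y, X)
            small += fit.alpha < 0.05
        assert small / n_genes >= 0.90

    def test_loglik_matches_direct_nbinom_evaluation(self):
        y = np.array([3.0, 9.0, 15.0, 4.0, 30.0, 25.0])
        alpha = 0.2
        mu = np.array([5.0, 5.0, 5.0, 20.0, 20.0, 20.0])
        r = 1.0 / alpha
        direct = stats.nbinom.logpmf(y, r, r / (r + mu)).sum()
        assert nb_loglik(y, mu, alpha) == pytest.approx(direct, abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_nb_glm(np.arange(6.0), X)


class TestLRT:
    def test_identical_models_stat_zero(self):
        y = np.array([5.0, 8.0, 6.0, 7.0])
        fit = fit_nb_glm(y, np.ones((4, 1)), alpha=0.1)
        stat, p = lrt_test(fit, fit, df=1)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_stat_equals_hand_evaluated_likelihood_difference(self):
        # two tissues, fixed dispersion: both likelihoods are evaluable
        # directly from the closed-form Poisson-limit group means
        y = np.array([4.0, 6.0, 20.0, 22.0])
        alpha = 0.05
        X_full, _ = design_from_labels(["t1", "t1", "t2", "t2"])
        X_red = np.ones((4, 1))
        full = fit_nb_glm(y, X_full, alpha=alpha)
        red = fit_nb_glm(y, X_red, alpha=alpha)
        stat, p = lrt_test(full, red, df=1)
        hand = 2.0 * (nb_loglik(y, full.mu, alpha) - nb_loglik(y, red.mu, alpha))
        assert stat == pytest.approx(hand, abs=1e-8)
        assert p == pytest.approx(stats.chi2.sf(hand, 1), abs=1e-10)

    def test_chi2_vs_f_reference(self):
        y = np.array([4.0, 6.0, 20.0, 22.0, 9.0, 11.0])
        X_full, _ = design_from_labels(["t1", "t1", "t2", "t2", "t3", "t3"])
        full, red, stat, p_f = nb_lrt_gene(y, X_full, np.ones((6, 1)))
        _, p_chi2 = lrt_test(full, red, df=2)
        # the F reference is strictly more conservative at small n
        assert p_f > p_chi2

    def test_df_must_be_positive(self):
        fit = fit_nb_glm(np.array([1.0, 2.0]), np.ones((2, 1)), alpha=0.1)
        with pytest.raises(ValueError):
            lrt_test(fit, fit, df=0)


class TestDeTwoGroup:
    def _sim_counts(self, seed, lfc_genes=0, lfc=2.0, n_genes=60):
        rng = np.random.default_rng(seed)
        base = rng.uniform(50, 500, size=n_genes)
        mult = np.ones(n_genes)
        mult[:lfc_genes] = 2.0**lfc
        r = 1 / 0.05
        control = rng.negative_binomial(r, r / (r + base[:, None]), size=(n_genes, 4))
        stress = rng.negative_binomial(
            r, r / (r + (base * mult)[:, None]), size=(n_genes, 4)
        )
        sheet = _two_group_sheet()
        df = pd.DataFrame(
            np.hstack([control, stress]),
            index=[f"g{i}" for i in range(n_genes)],
            columns=sheet.sample_ids,
        )
        return CountsMatrix(df), sheet

    def test_flat_gene_is_not_deg(self):
        sheet = _two_group_sheet()
        df = pd.DataFrame(
            np.tile([100, 100, 100, 100, 100, 100, 100, 100], (5, 1)),
            index=[f"g{i}" for i in range(5)], columns=sheet.sample_ids,
        )
        out = de_two_group(CountsMatrix(df), sheet, ("control", "stress"))
        np.testing.assert_allclose(out["log2_fold_change"], 0.0, atol=1e-9)
        assert not out["is_deg"].any()

    def test_planted_fourfold_gene_recovered(self):
        counts, sheet = self._sim_counts(1, lfc_genes=6, lfc=2.0)
        out = de_two_group(counts, sheet, ("control", "stress"))
        planted = out[out["gene_id"].isin([f"g{i}" for i in range(6)])]
        assert planted["is_deg"].mean() >= 0.8
        assert (planted["log2_fold_change"] > 1).mean() >= 0.8

    def test_antisymmetric_in_contrast_direction(self):
        counts, sheet = self._sim_counts(2, lfc_genes=5)
        fwd = de_two_group(counts, sheet, ("control", "stress"))
        rev = de_two_group(counts, sheet, ("stress", "control"))
        np.testing.assert_allclose(
            fwd["log2_fold_change"], -rev["log2_fold_change"], atol=1e-9
        )
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-6)

    def test_within_group_sample_order_irrelevant(self):
        counts, sheet = self._sim_counts(3)
        cols = list(counts.counts.columns)
        cols[0], cols[1] = cols[1], cols[0]  # swap two control replicates
        shuffled = CountsMatrix(counts.counts[cols])
        a = de_two_group(counts, sheet, ("control", "stress"))
        b = de_two_group(shuffled, sheet, ("control", "stress"))
        np.testing.assert_allclose(a["p_value"], b["p_value"], rtol=1e-8)

    def test_single_replicate_group_rejected(self):
        counts, _ = self._sim_counts(4)
        rows = [
            {"sample_id": s, "condition": "control" if i else "stress",
             "tissue": "leaf", "replicate": i + 1}
            for i, s in enumerate(counts.counts.columns)
        ]
        sheet = SampleSheet(pd.DataFrame(rows))
        with pytest.raises(ValueError, match="2 replicates"):
            de_two_group(counts, sheet, ("control", "stress"))

    def test_global_null_deg_rate_controlled(self):
        frac = []
        for seed in range(10):
            counts, sheet = self._sim_counts(100 + seed, lfc_genes=0, n_genes=60)
            out = de_two_group(counts, sheet, ("control", "stress"))
            frac.append((out["q_value"] < 0.05).mean())
        assert np.mean(frac) <= 0.06


class TestOverlap:
    def _de(self, genes, up, down):
        return pd.DataFrame(
            {
                "gene_id": genes,
                "log2_fold_change": [
                    2.0 if g in up else (-2.0 if g in down else 0.0) for g in genes
                ],
                "is_deg": [g in up or g in down for g in genes],
            }
        )

    def test_identical_sets_fully_shared(self):
        genes = [f"g{i}" for i in range(10)]
        de = self._de(genes, {"g1", "g2"}, {"g3"})
        s = overlap_degs(de, de)
        assert (s.up_shared, s.up_only_1, s.up_only_2) == (2, 0, 0)
        assert (s.down_shared, s.down_only_1, s.down_only_2) == (1, 0, 0)

    def test_random_sets_match_set_algebra(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(40)]
        for _ in range(20):
            pick = lambda: set(rng.choice(genes, size=8, replace=False))
            up1, up2 = pick(), pick()
            down1 = set(rng.choice(sorted(set(genes) - up1), 5, replace=False))
            down2 = set(rng.choice(sorted(set(genes) - up2), 5, replace=False))
            s = overlap_degs(self._de(genes, up1, down1), self._de(genes, up2, down2))
            assert s.up_shared == len(up1 & up2)
            assert s.up_only_1 == len(up1 - up2)
            assert s.down_only_2 == len(down2 - down1)

    def test_mismatched_universe_rejected(self):
        de1 = self._de([f"g{i}" for i in range(5)], {"g1"}, set())
        de2 = self._de([f"g{i}" for i in range(6)], {"g1"}, set())
        with pytest.raises(ValueError, match="g5"):
            overlap_degs(de1, de2)
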