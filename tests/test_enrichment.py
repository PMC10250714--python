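"""Threshold rule, Welch t-test, and the two enrichment analyses."""

import math

import numpy as np
import pandas as pd
import pytest

from tretools.enrichment import (
    TreEnrichmentModel,
    choose_threshold,
    deg_tre_enrichment,
    lfc_by_tre_class,
    welch_t_two_tailed,
)

from _oracles import brute_threshold


def _counts(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


def _expr(lfc, padj=None, contrast="T4_27d", prefix="g"):
    n = len(lfc)
    return pd.DataFrame(
        {
            "gene_id": [f"{prefix}{i}" for i in range(n)],
            "contrast": contrast,
            "log2fc": lfc,
            "padj": padj if padj is not None else [0.5] * n,
        }
    )


class TestChooseThreshold:
    def test_largest_threshold_keeping_min_degs(self):
        # 60 DEGs with >= 10 halfsites, only 40 with >= 11 -> K = 10
        values = [10] * 20 + [11] * 40 + [0] * 40
        counts = _counts(values)
        degs = set(counts.index)
        assert choose_threshold(counts, degs, min_degs=50) == 10

    def test_all_zero_counts_falls_back_to_one(self):
        counts = _counts([0] * 60)
        with pytest.warns(UserWarning, match="falling back"):
            assert choose_threshold(counts, set(counts.index), 50) == 1

    def test_empty_deg_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            choose_threshold(_counts([1, 2, 3]), set(), 1)

    def test_only_deg_counts_matter(self):
        values = [100] * 10 + [2] * 60
        counts = _counts(values)
        degs = {f"g{i}" for i in range(10, 70)}  # the low-count genes
        assert choose_threshold(counts, degs, min_degs=50) == 2

    def test_matches_exhaustive_oracle_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(30, 200))
            counts = _counts(rng.poisson(3, size=n))
            deg_ids = set(
                counts.index[rng.random(n) < 0.5]
            )
            if not deg_ids:
                continue
            min_degs = int(rng.integers(1, 30))
            expected = brute_threshold(
                [int(counts[g]) for g in deg_ids], min_degs
            )
            if expected == 1 and all(counts[g] < 1 for g in deg_ids):
                with pytest.warns(UserWarning):
                    got = choose_threshold(counts, deg_ids, min_degs)
            else:
                got = choose_threshold(counts, deg_ids, min_degs)
            assert got == expected


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_t_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swap_negates_t_keeps_p(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        t_xy, p_xy = welch_t_two_tailed(x, y)
        t_yx, p_yx = welch_t_two_tailed(y, x)
        assert t_xy == pytest.approx(-t_yx)
        assert p_xy == pytest.approx(p_yx)

    def test_matches_textbook_computation(self):
        x = [19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0]
        y = [28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7]
        # independent computation from the defining formulas
        mx, my = np.mean(x), np.mean(y)
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        nx, ny = len(x), len(y)
        t_expected = (mx - my) / math.sqrt(vx / nx + vy / ny)
        df_expected = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
        from scipy.stats import t as tdist

        p_expected = 2 * tdist.sf(abs(t_expected), df_expected)
        t, p = welch_t_two_tailed(x, y)
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-9)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            welch_t_two_tailed([1.0], [1.0, 2.0])

    def test_degenerate_zero_variance(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = welch_t_two_tailed([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)


class TestLfcByTreClass:
    def test_constant_identical_groups(self):
        counts = _counts([5] * 10 + [0] * 10)
        expr = _expr([1.5] * 20)
        with pytest.warns(UserWarning, match="zero variance"):
            res = lfc_by_tre_class(counts, expr, "T4_27d", "halfsite", k=5)
        assert res.fold_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_named_in_error(self):
        counts = _counts([5] * 10 + [1] * 10)  # nobody at zero
        expr = _expr(list(np.linspace(-2, 2, 20)))
        with pytest.raises(ValueError, match="zero-TRE"):
            lfc_by_tre_class(counts, expr, "T4_27d", "halfsite", k=5)

    def test_magnitudes_compared_by_default(self):
        counts = _counts([5] * 4 + [0] * 4)
        expr = _expr([-2.0, 2.0, -2.0, 2.0, 0.5, -0.5, 0.5, -0.5])
        res = lfc_by_tre_class(counts, expr, "T4_27d", "halfsite", k=1)
        assert res.mean_abs_lfc_high == pytest.approx(2.0)
        assert res.mean_abs_lfc_zero == pytest.approx(0.5)
        assert res.fold_ratio == pytest.approx(4.0)

    def test_recovers_folded_normal_ratio(self, rng):
        # Monte-Carlo oracle for the expected |log2FC| ratio under an
        # additive effect of random sign.
        delta, sigma = 1.0, 0.5
        draws = rng.normal(delta, sigma, size=1_000_000)
        mc_high = np.abs(draws).mean()
        mc_zero = np.abs(rng.normal(0.0, sigma, size=1_000_000)).mean()
        mc_ratio = mc_high / mc_zero

        n_high, n_zero = 4000, 4000
        counts = _counts([11] * n_high + [0] * n_zero)
        signs = rng.choice([-1, 1], size=n_high)
        lfc = np.concatenate(
            [rng.normal(signs * delta, sigma), rng.normal(0, sigma, size=n_zero)]
        )
        res = lfc_by_tre_class(_counts(lfc).pipe(lambda s: counts), _expr(lfc),
                               "T4_27d", "halfsite", k=11)
        assert res.fold_ratio == pytest.approx(mc_ratio, rel=0.05)
        assert res.p_value < 1e-10


class TestDegTreEnrichment:
    def test_identical_count_distributions_give_unit_fold(self, rng):
        n = 400
        counts = _counts(list(rng.poisson(2, n // 2)) * 2)
        padj = [0.001] * (n // 2) + [0.9] * (n // 2)
        lfc = [2.0] * (n // 2) + [0.0] * (n // 2)
        res = deg_tre_enrichment(counts, _expr(lfc, padj), "T4_27d", "halfsite")
        assert res.count_fold == pytest.approx(1.0)

    def test_no_degs_rejected(self):
        counts = _counts([1, 2, 3, 4])
        expr = _expr([0.1, 0.2, 0.1, 0.0], padj=[0.9] * 4)
        with pytest.raises(ValueError, match="no DEGs"):
            deg_tre_enrichment(counts, expr, "T4_27d", "halfsite")

    def test_deg_needs_both_padj_and_fold(self):
        counts = _counts([3, 3, 0, 0])
        # significant but below 2-fold; large but not significant
        expr = _expr([0.5, 0.5, 2.0, 2.0], padj=[0.01, 0.01, 0.5, 0.5])
        with pytest.raises(ValueError, match="no DEGs"):
            deg_tre_enrichment(counts, expr, "T4_27d", "halfsite")

    def test_gene_order_and_pattern_label_invariance(self, rng):
        n = 200
        counts = _counts(rng.poisson(2, n))
        padj = rng.random(n)
        lfc = rng.normal(0, 1.5, n)
        expr = _expr(lfc, padj)
        base = deg_tre_enrichment(counts, expr, "T4_27d", "halfsite")
        perm = rng.permutation(n)
        shuffled = deg_tre_enrichment(
            counts.iloc[perm], expr.iloc[perm].reset_index(drop=True),
            "T4_27d", "renamed",
        )
        assert shuffled.count_fold == pytest.approx(base.count_fold)
        assert shuffled.p_count == pytest.approx(base.p_count)
        assert shuffled.prop_deg_with_tre == pytest.approx(base.prop_deg_with_tre)

    def test_ztest_presence_alternative(self, rng):
        n = 300
        counts = _counts(rng.poisson(2, n))
        expr = _expr(rng.normal(0, 2, n), rng.random(n))
        res = deg_tre_enrichment(
            counts, expr, "T4_27d", "halfsite", presence_test="ztest"
        )
        assert 0.0 <= res.p_prop <= 1.0


class TestModelInterface:
    def _toy_model(self, rng):
        n = 500
        affected = np.arange(n) < 60
        background = rng.poisson(1.0, n)
        background[~affected & (np.arange(n) % 3 == 0)] = 0  # keep a zero class
        counts = pd.DataFrame(
            {"halfsite": np.where(affected, 12, background)},
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )
        lfc = np.where(affected, rng.choice([-1, 1], n) * 2.0, 0.0) + rng.normal(
            0, 0.3, n
        )
        padj = np.where(affected, 0.001, 0.8)
        expr = _expr(lfc, padj)
        return TreEnrichmentModel(counts, expr)

    def test_fit_chooses_threshold_and_detects_effect(self, rng):
        model = self._toy_model(rng)
        res = model.fit("halfsite", "T4_27d")
        assert res.lfc.threshold_k == 12
        assert res.lfc.fold_ratio > 2
        assert res.lfc.p_value < 1e-6
        assert res.deg.count_fold > 5

    def test_summary_mentions_key_quantities(self, rng):
        res = self._toy_model(rng).fit("halfsite", "T4_27d")
        text = res.summary()
        assert "fold ratio" in text and "K = 12" in text

    def test_fit_all_is_long_form(self, rng):
        table = self._toy_model(rng).fit_all()
        assert set(table["pattern"]) == {"halfsite"}
        assert {"fold_ratio", "count_fold", "p_value"} <= set(table.columns)

    def test_invalid_padj_rejected(self):
        counts = pd.DataFrame({"halfsite": [1]}, index=["g0"])
        expr = _expr([1.0], padj=[1.5], prefix="g")
        with pytest.raises(ValueError, match="padj"):
            TreEnrichmentModel(counts, expr)
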