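"""NB GLM differential expression, DEG calling, Fisher and ORA tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tfact
from tfact.diffexp import (
    DEGSets,
    MarkerPanel,
    call_degs,
    fisher_exact,
    fit_nb_glm_many,
    marker_enrichment,
    overrepresentation,
)


def _two_group(n_a, n_b, subtypes=None):
    ids = [f"s{i}" for i in range(n_a + n_b)]
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "lineage": "B-ALL",
            "subtype": subtypes if subtypes is not None else ["X"] * (n_a + n_b),
        }
    ).set_index("sample_id", drop=False)
    groups = pd.Series(["outlier"] * n_a + ["normal"] * n_b, index=ids)
    return samples, groups


def _nb_draws(rng, mu, alpha, size):
    lam = rng.gamma(1.0 / alpha, alpha * mu, size)
    return rng.poisson(lam)


class TestNbGlm:
    def test_identical_groups_zero_fold_change(self):
        samples, groups = _two_group(4, 4)
        counts = pd.DataFrame([[50, 60, 70, 80, 50, 60, 70, 80]], index=["g"],
                              columns=samples.index)
        offsets = pd.Series(0.0, index=samples.index)
        res = fit_nb_glm_many(counts, samples, groups, offsets=offsets, covariates=())
        assert res.loc["g", "log2_fc"] == pytest.approx(0.0, abs=1e-6)

    def test_doubled_counts_recover_log2fc_one(self, rng):
        """Group at 2x the mean of the other: estimate within 0.05 of 1."""
        n = 30
        samples, groups = _two_group(n, n)
        base = _nb_draws(rng, 1000.0, 0.01, n)
        doubled = _nb_draws(rng, 2000.0, 0.01, n)
        counts = pd.DataFrame([np.concatenate([doubled, base])], index=["g"],
                              columns=samples.index)
        offsets = pd.Series(0.0, index=samples.index)
        res = fit_nb_glm_many(counts, samples, groups, offsets=offsets, covariates=())
        assert res.loc["g", "log2_fc"] == pytest.approx(1.0, abs=0.05)

    def test_all_zero_gene(self):
        samples, groups = _two_group(3, 3)
        counts = pd.DataFrame([[0] * 6], index=["g"], columns=samples.index)
        res = fit_nb_glm_many(counts, samples, groups,
                              offsets=pd.Series(0.0, index=samples.index), covariates=())
        assert res.loc["g", "log2_fc"] == 0.0 and res.loc["g", "p_value"] == 1.0

    def test_agrees_with_statsmodels_nb_glm(self, rng):
        """Independent cross-check: statsmodels NB GLM at the same dispersion."""
        import statsmodels.api as sm

        n = 25
        subtypes = ["A"] * 12 + ["B"] * 13
        samples, groups = _two_group(10, 15, subtypes=np.array(subtypes)[
            rng.permutation(n)].tolist())
        mu = np.where(groups == "outlier", 300.0, 120.0)
        y = _nb_draws(rng, mu, 0.05, n)
        counts = pd.DataFrame([y], index=["g"], columns=samples.index)
        offsets = pd.Series(0.0, index=samples.index)
        mine = fit_nb_glm_many(counts, samples, groups, offsets=offsets,
                               covariates=("subtype",), alpha=0.05)
        from tfact.diffexp import build_design

        X, names, ids = build_design(samples, groups, ("subtype",))
        fit = sm.GLM(
            counts.loc["g", ids].to_numpy(float), X,
            family=sm.families.NegativeBinomial(alpha=0.05),
        ).fit()
        beta_sm = fit.params[names.index("group_outlier")]
        assert mine.loc["g", "log2_fc"] == pytest.approx(beta_sm / math.log(2), abs=1e-4)

    def test_poisson_limit(self, rng):
        """As dispersion -> 0 the NB Wald p matches the Poisson GLM Wald p."""
        import statsmodels.api as sm

        n = 20
        samples, groups = _two_group(n, n)
        y = _nb_draws(rng, np.where(groups == "outlier", 90.0, 60.0), 1e-9, 2 * n)
        counts = pd.DataFrame([y], index=["g"], columns=samples.index)
        offsets = pd.Series(0.0, index=samples.index)
        mine = fit_nb_glm_many(counts, samples, groups, offsets=offsets,
                               covariates=(), alpha=1e-8)
        X = np.column_stack([np.ones(2 * n), (groups == "outlier").to_numpy(float)])
        fit = sm.GLM(y.astype(float), X, family=sm.families.Poisson()).fit()
        # same t reference as the NB fit so only the model limit is compared
        p_pois = 2 * stats.t.sf(abs(fit.params[1] / fit.bse[1]), 2 * n - 2)
        assert mine.loc["g", "p_value"] == pytest.approx(p_pois, abs=1e-3)

    def test_label_swap_negates_fold_change(self, rng):
        n = 15
        samples, groups = _two_group(n, n)
        swapped = groups.map({"outlier": "normal", "normal": "outlier"})
        counts = pd.DataFrame(
            _nb_draws(rng, 200.0, 0.1, (5, 2 * n)),
            index=[f"g{i}" for i in range(5)], columns=samples.index,
        )
        offsets = pd.Series(0.0, index=samples.index)
        a = fit_nb_glm_many(counts, samples, groups, offsets=offsets, covariates=())
        b = fit_nb_glm_many(counts, samples, swapped, offsets=offsets, covariates=())
        np.testing.assert_allclose(a["log2_fc"], -b["log2_fc"], atol=1e-6)
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-6)


class TestCallDegs:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2_fc", "p_value"]).set_index(
            "gene_id"
        )

    def test_fold_change_exactly_at_threshold_excluded(self):
        res = self._frame([("g", math.log2(1.5), 0.001)])
        degs = call_degs(res)
        assert "g" not in degs.up and "g" not in degs.down

    def test_clear_up_gene(self):
        degs = call_degs(self._frame([("g", 1.0, 0.01)]))
        assert degs.up == {"g"}

    def test_brute_force_recheck(self, rng):
        rows = [
            (f"g{i}", float(rng.normal(0, 1.2)), float(rng.uniform(0, 0.2)))
            for i in range(10)
        ]
        degs = call_degs(self._frame(rows))
        for g, lfc, p in rows:
            should_up = 2**lfc > 1.5 and p < 0.05
            should_down = 2**-lfc > 1.5 and p < 0.05
            assert (g in degs.up) == should_up
            assert (g in degs.down) == should_down


def _enumerate_fisher(table):
    """Oracle: exhaustive enumeration of all tables with fixed margins."""
    a, b, c, d = np.asarray(table).ravel()
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    one = sum(v for k, v in pmf.items() if k >= a)
    two = sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-9))
    return min(one, 1.0), min(two, 1.0)


class TestFisher:
    def test_diagonal_table(self):
        res = fisher_exact([[3, 0], [0, 3]])
        assert res.p_one_sided == pytest.approx(1 / math.comb(6, 3))

    def test_independence_modal_table(self):
        res = fisher_exact([[1, 9], [10, 90]])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_zero_margin(self):
        assert fisher_exact([[0, 0], [5, 7]]).p_two_sided == 1.0

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_enumeration_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        while True:
            t = rng.integers(0, 11, (2, 2))
            if t.sum() <= 40 and t.sum() > 0:
                break
        res = fisher_exact(t)
        one, two = _enumerate_fisher(t)
        assert res.p_one_sided == pytest.approx(one, abs=1e-10)
        assert res.p_two_sided == pytest.approx(two, abs=1e-10)


class TestEnrichment:
    def test_oracle_hypergeometric_sum(self):
        """Panel fully inside the DEG set in a small universe."""
        universe = {f"g{i}" for i in range(20)}
        degs = DEGSets(up={f"g{i}" for i in range(8)}, down=set())
        panel = MarkerPanel("p", {"g0", "g1", "g2"})
        res = marker_enrichment(degs, panel, universe, "up")
        # P(all 3 panel genes among 8 draws of 20)
        expected = sum(
            stats.hypergeom.pmf(k, 20, 3, 8) for k in (3,)
        )
        assert res.p_one_sided == pytest.approx(expected, rel=1e-9)

    def test_disjoint_panel_errors(self):
        degs = DEGSets(up={"g1"}, down=set())
        with pytest.raises(ValueError, match="disjoint"):
            marker_enrichment(degs, MarkerPanel("p", {"zz"}), {"g1", "g2"}, "up")

    def test_ora_extremal_case(self):
        universe = {f"g{i}" for i in range(20)}
        genes = {f"g{i}" for i in range(10)}
        sets = {"hit": set(genes), "other": {f"g{i}" for i in range(10, 20)}}
        out = overrepresentation(genes, sets, universe)
        assert out.iloc[0]["set"] == "hit"
        assert out.iloc[0]["p_value"] < out.iloc[1]["p_value"]

    def test_ora_overlap_at_expectation_not_significant(self):
        """k equal to the independence expectation gives p >= 0.5."""
        universe = {f"g{i}" for i in range(100)}
        genes = {f"g{i}" for i in range(20)}  # 20% of universe
        members = {f"g{i}" for i in range(4)} | {f"g{i}" for i in range(80, 96)}
        out = overrepresentation(genes, {"s": members}, universe)  # k=4 = 20*20/100
        assert out.iloc[0]["p_value"] >= 0.5

    def test_ora_planted_set_ranks_first(self, rng):
        universe = {f"g{i}" for i in range(200)}
        genes = {f"g{i}" for i in range(30)}
        planted = {f"g{i}" for i in range(20)} | {"g100", "g101"}
        decoys = {
            f"d{j}": set(rng.choice(sorted(universe), 22, replace=False))
            for j in range(3)
        }
        out = overrepresentation(genes, {"planted": planted, **decoys}, universe)
        assert out.iloc[0]["set"] == "planted"
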