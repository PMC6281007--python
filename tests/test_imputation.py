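"""Chained-equations imputation and Rubin's-rules pooling."""

import numpy as np
import pandas as pd
import pytest

import acekit as ak
from acekit.categories import ACE_CATEGORIES
from acekit.imputation import ImputationError, ImputationSpec, rubin_pool


class TestChooseM:
    @pytest.mark.parametrize("frac,expected", [(0.29, 29), (0.09, 9), (0.0, 2), (1.0, 100)])
    def test_percentage_rule_with_floor(self, frac, expected):
        assert ak.choose_m(frac) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ImputationError):
            ak.choose_m(1.5)


class TestScreenAuxiliaries:
    def _aux(self, exposed):
        n = 200
        df = pd.DataFrame(
            {
                "maternal_age": np.linspace(20, 40, n),
                "adv_rare": [1] * exposed + [0] * (n - exposed),
                "constant": 1.0,
            }
        )
        return df

    def test_exposed_count_boundary(self):
        """49 exposed dropped, 50 retained under the at-least-50 rule."""
        assert "adv_rare" not in ak.screen_auxiliaries(self._aux(49))
        assert "adv_rare" in ak.screen_auxiliaries(self._aux(50))

    def test_constant_column_always_dropped(self):
        retained = ak.screen_auxiliaries(self._aux(60))
        assert "constant" not in retained
        assert "maternal_age" in retained

    def test_sociodemographic_exempt_from_count_rule(self):
        df = self._aux(60)
        df["home_ownership"] = [1] * 10 + [0] * 190  # only 10 "exposed" but not adversity
        assert "home_ownership" in ak.screen_auxiliaries(df)


def _toy_problem(n=300, miss=0.25, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    cons = pd.DataFrame(
        {
            ace: (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))).astype(float)
            for ace in ACE_CATEGORIES[:4]
        },
        index=pd.RangeIndex(1, n + 1),
    )
    mask = rng.random(cons.shape) < miss
    cons_missing = cons.mask(mask)
    aux = pd.DataFrame(
        {
            "sex": np.where(rng.random(n) < 0.5, "M", "F"),
            "proxy": x + rng.standard_normal(n) * 0.5,
        },
        index=cons.index,
    )
    return cons, cons_missing, aux


class TestImputeStratified:
    def test_no_missing_passthrough(self):
        cons, _, aux = _toy_problem(miss=0.0)
        spec = ImputationSpec(m=3, iterations=2, seed=1)
        stack = ak.impute_stratified(cons, aux, spec)
        for d in stack.datasets:
            pd.testing.assert_frame_equal(d, cons)

    def test_observed_cells_preserved(self):
        cons, cons_missing, aux = _toy_problem()
        spec = ImputationSpec(m=4, iterations=3, seed=2)
        stack = ak.impute_stratified(cons_missing, aux, spec)
        observed = cons_missing.notna()
        for d in stack.datasets:
            assert d.notna().all().all()
            assert (d[observed] == cons_missing[observed]).all().all() or (
                d.where(observed).equals(cons_missing.where(observed))
            )

    def test_same_seed_bit_identical(self):
        _, cons_missing, aux = _toy_problem()
        spec = ImputationSpec(m=3, iterations=3, seed=9)
        s1 = ak.impute_stratified(cons_missing, aux, spec)
        s2 = ak.impute_stratified(cons_missing, aux, spec)
        for a, b in zip(s1.datasets, s2.datasets):
            pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        _, cons_missing, aux = _toy_problem()
        s1 = ak.impute_stratified(cons_missing, aux, ImputationSpec(m=2, iterations=2, seed=1))
        s2 = ak.impute_stratified(cons_missing, aux, ImputationSpec(m=2, iterations=2, seed=2))
        assert any(not a.equals(b) for a, b in zip(s1.datasets, s2.datasets))

    def test_constant_column_uses_donor_fallback(self):
        cons, cons_missing, aux = _toy_problem()
        cons_missing["sexual_abuse"] = 0.0
        cons_missing.loc[cons_missing.index[:30], "sexual_abuse"] = np.nan
        spec = ImputationSpec(m=2, iterations=2, seed=3)
        stack = ak.impute_stratified(cons_missing, aux, spec)
        assert any(f[2] == "sexual_abuse" for f in stack.fallbacks)
        for d in stack.datasets:
            assert (d["sexual_abuse"] == 0.0).all()

    def test_incomplete_auxiliaries_rejected(self):
        _, cons_missing, aux = _toy_problem()
        aux.loc[aux.index[0], "proxy"] = np.nan
        with pytest.raises(ImputationError, match="complete"):
            ak.impute_stratified(
                cons_missing, aux, ImputationSpec(m=2, iterations=2, seed=1)
            )

    def test_traces_have_expected_shape(self):
        _, cons_missing, aux = _toy_problem()
        spec = ImputationSpec(m=3, iterations=4, seed=5)
        stack = ak.impute_stratified(cons_missing, aux, spec)
        for level in ("F", "M"):
            arr = stack.traces[level]["physical_abuse"]
            assert arr.shape == (3, 4)


class TestRubinPooling:
    def test_two_dataset_mean(self):
        est = pd.DataFrame({"p": [0.10, 0.20]})
        var = pd.DataFrame({"p": [0.001, 0.001]})
        pooled = rubin_pool(est, var)
        assert pooled.estimate["p"] == pytest.approx(0.15)

    def test_equal_estimates_no_between_variance(self):
        est = pd.DataFrame({"p": [0.3, 0.3, 0.3]})
        var = pd.DataFrame({"p": [0.002, 0.002, 0.002]})
        pooled = rubin_pool(est, var)
        assert pooled.between["p"] == 0.0
        assert pooled.total["p"] == pytest.approx(pooled.within["p"])

    def test_hand_worked_m3_example(self):
        """m=3 with estimates 0.10/0.14/0.18 and within-variances
        0.0009/0.0010/0.0011: W = 0.001, B = 0.0016, T = W + (4/3)B."""
        est = pd.DataFrame({"p": [0.10, 0.14, 0.18]})
        var = pd.DataFrame({"p": [0.0009, 0.0010, 0.0011]})
        pooled = rubin_pool(est, var)
        W = (0.0009 + 0.0010 + 0.0011) / 3
        B = np.var([0.10, 0.14, 0.18], ddof=1)
        assert pooled.estimate["p"] == pytest.approx(0.14, abs=1e-15)
        assert pooled.within["p"] == pytest.approx(W, abs=1e-15)
        assert pooled.between["p"] == pytest.approx(B, abs=1e-15)
        assert pooled.total["p"] == pytest.approx(W + (1 + 1 / 3) * B, abs=1e-12)

    def test_total_never_below_within(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            m = int(rng.integers(2, 10))
            est = pd.DataFrame({"p": rng.random(m)})
            var = pd.DataFrame({"p": rng.random(m) * 0.01})
            pooled = rubin_pool(est, var)
            assert pooled.total["p"] >= pooled.within["p"]
            assert pooled.se["p"] >= 0

    def test_single_dataset_point_estimate_only(self):
        pooled = rubin_pool(pd.DataFrame({"p": [0.2]}), pd.DataFrame({"p": [0.001]}))
        assert pooled.estimate["p"] == 0.2
        assert np.isnan(pooled.se["p"])

    def test_pooled_estimate_within_range_of_components(self):
        rng = np.random.default_rng(12)
        est = pd.DataFrame({"p": rng.random(5)})
        var = pd.DataFrame({"p": np.full(5, 1e-3)})
        pooled = rubin_pool(est, var)
        assert est["p"].min() <= pooled.estimate["p"] <= est["p"].max()


class TestPoolQuantities:
    def test_prevalence_and_scores(self):
        cons, cons_missing, aux = _toy_problem()
        # extend to all 19 columns so scores are defined
        full = cons_missing.copy()
        for ace in ACE_CATEGORIES:
            if ace not in full.columns:
                full[ace] = 0.0
        stack = ak.impute_stratified(
            full[list(ACE_CATEGORIES)], aux, ImputationSpec(m=3, iterations=2, seed=4)
        )
        prev = ak.pool(stack, "prevalence")
        assert set(prev.estimate.index) == set(ACE_CATEGORIES)
        assert ((prev.estimate >= 0) & (prev.estimate <= 1)).all()
        mean_cs = ak.pool(stack, "mean_classic_score")
        assert 0 <= mean_cs.estimate.iloc[0] <= 10
        cats = ak.pool(stack, "classic_category_proportions")
        assert cats.estimate.sum() == pytest.approx(1.0)

    def test_unknown_quantity_errors(self):
        cons, cons_missing, aux = _toy_problem()
        stack = ak.impute_stratified(
            cons_missing, aux, ImputationSpec(m=2, iterations=2, seed=1)
        )
        with pytest.raises(ImputationError):
            ak.pool(stack, "nonsense")
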