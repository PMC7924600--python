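"""Greedy balance selection, CV reproducibility, rank choice, reliability."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clrbalance.balance_selection import (BalanceSelectionResult,
                                          choose_rank,
                                          cross_validated_selection,
                                          evaluate_balance, reliability_filter,
                                          select_balance)
from clrbalance.compositional import Balance, balance_value, impute_zeros_bm
from clrbalance.synthetic_data import (PlantedBalance, SyntheticCohortConfig,
                                       generate_cohort, make_taxonomy)


def auc_pair_counting(values, labels):
    """Brute-force AUC: concordant pairs (ties count half) over n1*n0."""
    pos = [v for v, g in zip(values, labels) if g]
    neg = [v for v, g in zip(values, labels) if not g]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def planted_cohort(seed, n_per_group=30, n_taxa=40, shift=2.0):
    taxa = make_taxonomy(n_taxa)
    cfg = SyntheticCohortConfig(
        seed=seed, n_patients=n_per_group, n_controls=n_per_group,
        timepoint_counts={1: n_per_group}, n_taxa=n_taxa,
        planted_balance=PlantedBalance((taxa[0],), (taxa[3],), shift=shift)
        if shift else None)
    coh = generate_cohort(cfg)
    comp = impute_zeros_bm(coh.counts)
    y = (coh.metadata.frame["cohort"] == "CCI").astype(int).to_numpy()
    return coh, comp, y


class TestEvaluateBalance:
    def test_constant_balance_auc_half(self):
        X = pd.DataFrame({"a": [1.0] * 8, "b": [2.0] * 8})
        b = Balance(("a",), ("b",))
        assert evaluate_balance(b, X, [0, 1] * 4) == pytest.approx(0.5)

    def test_perfect_separation_auc_one(self):
        X = pd.DataFrame({"a": [1, 2, 3, 10, 20, 30],
                          "b": [1.0] * 6}, dtype=float)
        b = Balance(("a",), ("b",))
        assert evaluate_balance(b, X, [0, 0, 0, 1, 1, 1]) == pytest.approx(1.0)

    def test_auc_matches_pair_counting(self, rng):
        for _ in range(20):
            X = pd.DataFrame(rng.uniform(0.1, 5.0, size=(16, 2)),
                             columns=["a", "b"])
            y = rng.integers(0, 2, 16)
            if y.sum() in (0, 16):
                continue
            b = Balance(("a",), ("b",))
            vals = balance_value(X, b)
            assert evaluate_balance(b, X, y) == pytest.approx(
                auc_pair_counting(vals, y), abs=1e-12)

    def test_continuous_is_adjusted_r2(self, rng):
        import statsmodels.api as sm
        X = pd.DataFrame(rng.uniform(0.1, 5.0, size=(20, 2)),
                         columns=["a", "b"])
        y = rng.normal(size=20)
        b = Balance(("a",), ("b",))
        vals = balance_value(X, b).to_numpy()
        fit = sm.OLS(y, sm.add_constant(vals)).fit()
        assert evaluate_balance(b, X, y) == pytest.approx(fit.rsquared_adj,
                                                          abs=1e-10)


class TestGreedySelection:
    def test_perfectly_ordered_pair_selected(self):
        n = 10
        logratio = np.linspace(-2, 2, n)
        X = pd.DataFrame({
            "a": np.exp(logratio), "b": np.ones(n),
            "c": np.exp(np.r_[np.zeros(n - 1), 0.1]),
        })
        y = (logratio > 0).astype(int)
        bal, trace = select_balance(X, y)
        assert set(bal.numerator) == {"a"} and "b" in bal.denominator or \
            trace.criteria[0] == pytest.approx(1.0)
        assert trace.criteria[-1] == pytest.approx(1.0)

    def test_step1_matches_exhaustive_pair_search(self, rng):
        for rep in range(10):
            n_taxa = int(rng.integers(3, 9))
            X = pd.DataFrame(
                rng.uniform(0.05, 5.0, size=(14, n_taxa)),
                columns=[f"t{i}" for i in range(n_taxa)])
            y = np.r_[np.zeros(7), np.ones(7)].astype(int)
            _, trace = select_balance(X, y)
            best = max(
                evaluate_balance(Balance((a,), (b,)), X, y)
                for a, b in itertools.permutations(X.columns, 2))
            assert trace.criteria[0] == pytest.approx(best, abs=1e-12)

    def test_trace_criterion_non_decreasing(self, rng):
        _, comp, y = planted_cohort(17, n_per_group=15, n_taxa=20, shift=1.0)
        _, trace = select_balance(comp, y)
        assert all(b >= a - 1e-12
                   for a, b in zip(trace.criteria, trace.criteria[1:]))

    def test_invariant_to_per_sample_scaling(self):
        coh, comp, y = planted_cohort(23, n_per_group=12, n_taxa=15)
        bal1, _ = select_balance(comp, y)
        scaled = comp.copy()
        scaled.iloc[0] *= 100  # rescale one sample before closure
        scaled = scaled.div(scaled.sum(axis=1), axis=0)
        bal2, _ = select_balance(scaled, y)
        assert bal1 == bal2

    def test_constant_outcome_rejected(self):
        X = pd.DataFrame(np.ones((8, 3)) + 0.1,
                         columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="constant"):
            select_balance(X, np.ones(8))

    def test_planted_pair_recovered_across_seeds(self):
        # shift 2.0 on the log-ratio, n=30+30, 40 taxa: the planted pair is
        # part of the selected balance in >=90% of 20 seeded simulations
        hits = 0
        for rep in range(20):
            coh, comp, y = planted_cohort(3100 + rep, shift=2.0)
            bal, _ = select_balance(comp, y, cv_folds=5, seed=rep)
            planted = {(t, "numerator") for t in coh.truth.balance_numerator}
            planted |= {(t, "denominator")
                        for t in coh.truth.balance_denominator}
            selected = {(t, "numerator") for t in bal.numerator}
            selected |= {(t, "denominator") for t in bal.denominator}
            hits += planted <= selected
        assert hits >= 18


class TestCrossValidatedSelection:
    def test_deterministic_pair_fully_reproducible(self):
        # noise-free planted pair: every fold must select it -> 100%
        rng = np.random.default_rng(3)
        n = 20
        z = np.r_[-np.sort(rng.uniform(0.5, 1.5, n // 2)),
                  np.sort(rng.uniform(0.5, 1.5, n // 2))]
        # distractor names sort after the planted pair so that any chance
        # tie at AUC 1.0 on a small training fold resolves deterministically
        X = pd.DataFrame({
            "a_num": np.exp(z), "b_den": np.ones(n),
            "x1": rng.lognormal(0.0, 2.0, n), "x2": rng.lognormal(0.0, 2.0, n)})
        y = (z > 0).astype(int)
        res = cross_validated_selection(X, y, seed=11)
        rep = res.reproducibility
        for tax, side in (("a_num", "numerator"), ("b_den", "denominator")):
            pct = rep.loc[(rep["taxon"] == tax) & (rep["side"] == side),
                          "percent"]
            assert float(pct.iloc[0]) == pytest.approx(100.0)
        assert res.balance == Balance(("a_num",), ("b_den",))

    def test_same_seed_identical_result(self):
        _, comp, y = planted_cohort(43, n_per_group=15, n_taxa=20)
        r1 = cross_validated_selection(comp, y, seed=5)
        r2 = cross_validated_selection(comp, y, seed=5)
        assert r1.balance == r2.balance
        assert r1.criterion_cv == r2.criterion_cv
        pd.testing.assert_frame_equal(r1.reproducibility, r2.reproducibility)
        assert r1.to_json() == r2.to_json()

    def test_reproducibility_invariant_to_column_order(self):
        _, comp, y = planted_cohort(47, n_per_group=15, n_taxa=15)
        r1 = cross_validated_selection(comp, y, seed=9)
        shuffled = comp[list(comp.columns[::-1])]
        r2 = cross_validated_selection(shuffled, y, seed=9)
        m1 = {(t, s): p for t, s, p in r1.reproducibility.itertuples(False)}
        m2 = {(t, s): p for t, s, p in r2.reproducibility.itertuples(False)}
        assert m1 == m2

    def test_null_outcome_gives_no_reliable_taxa(self):
        # pure-noise outcome: the out-of-fold R^2 gate keeps the reliable
        # set empty even though fold overlap lets noise pairs recur
        reliable = 0
        for rep in range(5):
            _, comp, y = planted_cohort(600 + rep, n_per_group=20,
                                        n_taxa=40, shift=0.0)
            res = cross_validated_selection(comp, y, seed=rep)
            reliable += len(res.reliable_taxa())
            assert res.final_r2 < 0.2
        assert reliable == 0

    def test_fold_without_both_classes_rejected(self):
        X = pd.DataFrame(np.abs(np.random.default_rng(0).normal(
            size=(8, 4))) + 0.1, columns=list("abcd"))
        y = np.r_[np.ones(7), np.zeros(1)]
        with pytest.raises(ValueError, match="folds"):
            cross_validated_selection(X, y, folds=5, repeats=1, seed=0)


class TestRankChoiceAndReliability:
    def test_lowest_fdr_rank_wins(self):
        assert choose_rank({"species": [0.01, 0.5], "genus": [0.03]}) == "species"

    def test_tie_breaks_to_finer_rank(self):
        assert choose_rank({"family": [0.02], "species": [0.02]}) == "species"

    def test_single_rank(self):
        assert choose_rank({"genus": [0.9]}) == "genus"

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            choose_rank({"genus": [np.nan], "species": []})

    @staticmethod
    def _result(percents, r2):
        rep = pd.DataFrame({
            "taxon": [f"t{i}" for i in range(len(percents))],
            "side": ["numerator"] * len(percents),
            "percent": percents})
        return BalanceSelectionResult(
            balance=Balance(("t0",), ("x",)), criterion_kind="AUC",
            criterion_full=0.9, criterion_cv=0.8, reproducibility=rep,
            chosen_size=2, final_r2=r2)

    def test_taxon_above_both_thresholds_reliable(self):
        out = reliability_filter(self._result([76.0], 0.35))
        assert out["taxon"].tolist() == ["t0"]

    def test_low_reproducibility_never_reliable(self):
        assert reliability_filter(self._result([49.0], 0.9)).empty

    def test_low_model_r2_blocks_all(self):
        assert reliability_filter(self._result([90.0, 80.0], 0.1)).empty
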