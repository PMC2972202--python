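import itertools

import numpy as np
import pytest

from rarecomb import (
    GenotypeMatrix,
    PhenotypeVector,
    ModelSet,
    ModelSpec,
    aggregate_score,
    cast_test,
    cmc_test,
    max_over_models,
    score_statistic,
    step_up,
)
from rarecomb.association import CombinedTest, StepUpTest, _phenotype_parts

from conftest import random_dataset
import oracles


class TestAggregateScore:
    def test_gamma_zero_gives_zero(self):
        G = GenotypeMatrix.from_dosages(np.array([[1, 0], [0, 2]]), ["a", "b"])
        m = ModelSpec(np.ones(2), np.ones(2), np.zeros(2), "empty")
        np.testing.assert_array_equal(aggregate_score(G, m), [0, 0])

    def test_row_sums(self):
        G = GenotypeMatrix.from_dosages(np.array([[1, 0], [0, 2]]), ["a", "b"])
        m = ModelSpec(np.ones(2), np.ones(2), np.ones(2), "sum")
        np.testing.assert_array_equal(aggregate_score(G, m), [1, 2])

    def test_weighted_signed_row(self):
        G = GenotypeMatrix.from_dosages(
            np.array([[1, 1], [0, 0], [0, 1]]), ["a", "b"]
        )
        m = ModelSpec(np.array([2.0, 1.0]), np.array([1.0, -1.0]),
                      np.ones(2), "ws")
        assert aggregate_score(G, m)[0] == pytest.approx(1.0)  # 2*1 - 1*1


class TestScoreStatistic:
    def test_hand_computed_value(self):
        # U = 0.5, sigma2_Y = 0.25, sum(S - Sbar)^2 = 0.75 -> T = 4/3
        Y = PhenotypeVector.from_values([1, 1, 0, 0])
        T = score_statistic(np.array([1.0, 0, 0, 0]), Y)
        assert T == pytest.approx(4 / 3)

    def test_constant_score_is_zero(self):
        Y = PhenotypeVector.from_values([1, 0, 1, 0])
        assert score_statistic(np.full(4, 2.5), Y) == 0.0

    def test_affine_invariance(self, rng):
        for _ in range(20):
            n = 25
            S = rng.standard_normal(n)
            Y = PhenotypeVector.from_values(rng.standard_normal(n),
                                            "continuous")
            t = score_statistic(S, Y)
            a, b = rng.uniform(0.1, 5), rng.uniform(-3, 3)
            assert score_statistic(a * S + b, Y) == pytest.approx(t)
            Y2 = PhenotypeVector.from_values(a * Y.values + b, "continuous")
            assert score_statistic(S, Y2) == pytest.approx(t)

    def test_chi2_mean_under_null(self, rng):
        # independent S and Y: mean of T approaches the chi2(1) mean of 1
        ts = []
        for _ in range(2000):
            S = rng.binomial(2, 0.3, size=150).astype(float)
            Y = PhenotypeVector.from_values(
                rng.integers(0, 2, size=150).astype(float)
            )
            ts.append(score_statistic(S, Y))
        assert np.mean(ts) == pytest.approx(1.0, abs=0.08)

    def test_matches_trend_test_single_variant(self, rng):
        for _ in range(25):
            G, Y = random_dataset(rng, n=40, p=1)
            t = score_statistic(G.dosages[:, 0].astype(float), Y)
            t_oracle = oracles.trend_score_oracle(G.dosages[:, 0], Y.values)
            assert t == pytest.approx(t_oracle, abs=1e-10)


class TestMaxOverModels:
    def _models(self, p, rng, k=3):
        specs = []
        for i in range(k):
            gamma = (rng.random(p) < 0.7).astype(float)
            if not gamma.any():
                gamma[0] = 1
            specs.append(
                ModelSpec(
                    rng.uniform(0.5, 2, p),
                    rng.choice([-1.0, 1.0], p),
                    gamma,
                    f"m{i}",
                )
            )
        return ModelSet(specs)

    def test_singleton_equals_score_statistic(self, rng):
        G, Y = random_dataset(rng, n=30, p=4)
        M = self._models(4, rng, k=1)
        res = max_over_models(G, Y, M)
        S = aggregate_score(G, M.specs[0])
        assert res.statistic == pytest.approx(score_statistic(S, Y))

    def test_duplicate_model_first_label_wins(self, rng):
        G, Y = random_dataset(rng, n=30, p=4)
        m = self._models(4, rng, k=1).specs[0]
        m2 = ModelSpec(m.w, m.s, m.gamma, "copy")
        res = max_over_models(G, Y, ModelSet([m, m2]))
        assert res.best_model == m.label

    def test_equals_bruteforce_max(self, rng):
        for _ in range(10):
            G, Y = random_dataset(rng, n=30, p=5)
            M = self._models(5, rng, k=3)
            res = max_over_models(G, Y, M)
            brute = max(
                score_statistic(aggregate_score(G, m), Y) for m in M
            )
            assert res.statistic == pytest.approx(brute, abs=1e-9)

    def test_variant_order_invariance_unsigned_constant(self, rng):
        G, Y = random_dataset(rng, n=30, p=5)
        m = ModelSpec(np.ones(5), np.ones(5), np.ones(5), "all")
        t1 = max_over_models(G, Y, ModelSet([m])).statistic
        perm = rng.permutation(5)
        G2 = GenotypeMatrix.from_dosages(
            G.dosages[:, perm], [G.variant_ids[j] for j in perm]
        )
        t2 = max_over_models(G2, Y, ModelSet([m])).statistic
        assert t1 == pytest.approx(t2)


class TestStepUp:
    def test_single_variant(self, rng):
        G, Y = random_dataset(rng, n=30, p=1)
        res = step_up(G, Y)
        assert res.selected_variants == [G.variant_ids[0]]
        t_uni = score_statistic(G.dosages[:, 0].astype(float), Y)
        assert res.statistic == pytest.approx(t_uni)

    def test_toy_selects_case_variants_only(self, toy_case_control):
        G, Y = toy_case_control
        res = step_up(G, Y, "constant", "unsigned")
        assert set(res.selected_variants) == {"v1", "v2"}
        best, subset = oracles.exhaustive_best_subset(G, Y, np.ones(3))
        assert res.statistic == pytest.approx(best)
        assert set(subset) == {0, 1}

    def test_statistic_at_least_best_univariate(self, rng):
        for _ in range(10):
            G, Y = random_dataset(rng, n=40, p=6)
            res = step_up(G, Y)
            best_uni = max(
                score_statistic(G.dosages[:, j].astype(float), Y)
                for j in range(6)
            )
            assert res.statistic >= best_uni - 1e-12

    def test_never_exceeds_exhaustive(self, rng):
        for _ in range(8):
            G, Y = random_dataset(rng, n=30, p=5)
            res = step_up(G, Y)
            best, _ = oracles.exhaustive_best_subset(G, Y, np.ones(5))
            assert res.statistic <= best + 1e-9

    def test_returns_single_variant_when_no_pair_beats_it(self, rng):
        # search random instances for a case where the best univariate
        # statistic beats every 2-variant group, then check step-up stops
        found = False
        for _ in range(200):
            G, Y = random_dataset(rng, n=25, p=4)
            uni = [
                score_statistic(G.dosages[:, j].astype(float), Y)
                for j in range(4)
            ]
            pair_best = max(
                score_statistic(
                    G.dosages[:, [i, j]].sum(axis=1).astype(float), Y
                )
                for i, j in itertools.combinations(range(4), 2)
            )
            if max(uni) > pair_best:
                res = step_up(G, Y)
                assert len(res.selected_variants) == 1
                assert res.statistic == pytest.approx(max(uni))
                found = True
                break
        assert found


class TestCast:
    def test_matches_definitional_route(self, rng):
        G, Y = random_dataset(rng, n=40, p=5)
        cutoff = float(np.median(G.maf))
        res = cast_test(G, Y, cutoff)
        from rarecomb import maf_threshold_inclusion

        gamma = maf_threshold_inclusion(G.maf, cutoff)
        m = ModelSpec(np.ones(5), np.ones(5), gamma, "cast")
        assert res.statistic == pytest.approx(
            score_statistic(aggregate_score(G, m), Y)
        )

    def test_cutoff_below_all_mafs_is_zero(self, rng):
        G, Y = random_dataset(rng, n=40, p=5)
        res = cast_test(G, Y, cutoff=1e-6)
        assert res.statistic == 0.0


class TestCmc:
    def test_df_rules(self, rng):
        G, Y = random_dataset(rng, n=60, p=4)
        all_rare = cmc_test(G, Y, cutoff=0.5)
        assert all_rare.df == 1  # no common variants -> collapsed term only
        all_common = cmc_test(G, Y, cutoff=1e-9)
        assert all_common.df == 4  # every polymorphic variant individual

    def test_lrt_matches_likelihood_oracle(self, rng):
        G, Y = random_dataset(rng, n=60, p=3)
        cutoff = float(np.median(G.maf))
        res = cmc_test(G, Y, cutoff)
        maf = G.maf
        rare = (maf > 0) & (maf <= cutoff)
        cols = []
        if rare.any():
            cols.append((G.dosages[:, rare].sum(1) > 0).astype(float))
        cols += [G.dosages[:, j].astype(float) for j in np.where(maf > cutoff)[0]]
        X = np.column_stack(cols)
        ll1 = oracles.cmc_loglik_oracle(X, Y.values)
        pbar = Y.values.mean()
        n1 = Y.values.sum()
        ll0 = n1 * np.log(pbar) + (60 - n1) * np.log(1 - pbar)
        assert res.statistic == pytest.approx(2 * (ll1 - ll0), abs=1e-6)

    def test_requires_dichotomous(self, rng):
        G, _ = random_dataset(rng, n=30, p=3)
        Y = PhenotypeVector.from_values(np.random.default_rng(0)
                                        .standard_normal(30), "continuous")
        with pytest.raises(ValueError, match="dichotomous"):
            cmc_test(G, Y)


class TestFastPathConsistency:
    def test_gram_route_equals_definitional_route(self, rng):
        # the quadratic-form fast path and aggregate_score+score_statistic
        # must agree on arbitrary models
        for _ in range(15):
            G, Y = random_dataset(rng, n=35, p=6)
            w = rng.uniform(0.2, 3, 6)
            s = rng.choice([-1.0, 1.0], 6)
            gamma = (rng.random(6) < 0.6).astype(float)
            m = ModelSpec(w, s, gamma, "m")
            fast = max_over_models(G, Y, ModelSet([m])).statistic
            slow = score_statistic(aggregate_score(G, m), Y)
            assert fast == pytest.approx(slow, abs=1e-9)


class TestCombined:
    def test_best_of_union(self, rng):
        G, Y = random_dataset(rng, n=40, p=5)
        t_step = StepUpTest("constant", "unsigned")
        t_step_s = StepUpTest("constant", "signed")
        combo = CombinedTest([t_step, t_step_s])
        res = combo.statistic(G, Y)
        assert res.statistic == pytest.approx(
            max(
                t_step.statistic(G, Y).statistic,
                t_step_s.statistic(G, Y).statistic,
            )
        )
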