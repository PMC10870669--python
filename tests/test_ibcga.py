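import numpy as np
import pandas as pd
import pytest

from elndi.cohort import LabeledCohort, OUTCOMES
from elndi.errors import ConfigurationError, InvalidInputError
from elndi.ibcga import (
    Chromosome,
    GAConfig,
    OrthogonalArray,
    _Evaluator,
    compute_med,
    evaluate_fitness,
    inherit_step,
    init_population,
    intelligent_crossover,
    run_ibcga,
)
from elndi.preprocess import balance_cohort
from elndi.simulate import simulate_logistic

SMALL_GRID = dict(c_grid=[0.5, 8.0, 128.0], gamma_grid=[0.0078125, 0.125, 2.0])


def small_config(**kw) -> GAConfig:
    base = dict(
        population_size=10, generations_per_r=4, r_start=2, r_end=3, seed=0, **SMALL_GRID
    )
    base.update(kw)
    return GAConfig(**base)


def logistic_cohort(n=200, coefs=None, n_noise=6, seed=0, balance=True):
    coefs = coefs or {"f1": 1.6, "f2": 1.1}
    X, y, _ = simulate_logistic(n, coefs, intercept=-0.8, n_noise=n_noise, seed=seed)
    lab = LabeledCohort(X, y, OUTCOMES["CDelay"])
    return balance_cohort(lab, seed=seed) if balance else lab


class TestOrthogonalArray:
    @pytest.mark.parametrize("k", [1, 2, 3, 5, 7, 8, 12, 15])
    def test_pairwise_balance_all_column_pairs(self, k):
        oa = OrthogonalArray(k)
        assert oa.is_orthogonal()
        assert oa.design.shape[1] == k

    def test_row_count_is_smallest_power_of_two(self):
        assert OrthogonalArray(3).n_rows == 4
        assert OrthogonalArray(4).n_rows == 8
        assert OrthogonalArray(7).n_rows == 8
        assert OrthogonalArray(8).n_rows == 16


class TestPopulationOperators:
    def test_init_population_masks_sum_to_r(self):
        pop = init_population(29, 4, small_config(population_size=20))
        assert len(pop) == 20
        assert all(c.r == 4 for c in pop)

    def test_init_full_subset_is_all_ones(self):
        pop = init_population(5, 5, small_config(population_size=3))
        assert all(c.mask.all() for c in pop)

    def test_init_seeded_reproducible(self):
        a = init_population(10, 3, small_config(seed=5))
        b = init_population(10, 3, small_config(seed=5))
        assert all(x.key() == y.key() for x, y in zip(a, b))

    def test_init_r_exceeding_n_rejected(self):
        with pytest.raises(ConfigurationError):
            init_population(3, 4, small_config())

    def test_inherit_step_grows_every_mask_by_one(self):
        rng = np.random.default_rng(0)
        pop = init_population(12, 4, small_config(population_size=8))
        grown = inherit_step(pop, rng)
        assert all(c.r == 5 for c in grown)
        # parameter genes preserved
        assert all(
            (a.c_idx, a.gamma_idx) == (b.c_idx, b.gamma_idx) for a, b in zip(pop, grown)
        )

    def test_inherit_single_zero_is_forced(self):
        rng = np.random.default_rng(1)
        chrom = Chromosome(np.array([True, True, False]), 0, 0)
        (grown,) = inherit_step([chrom], rng)
        assert grown.mask.all()

    def test_inherit_saturated_raises(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ConfigurationError):
            inherit_step([Chromosome(np.ones(3, bool), 0, 0)], rng)


class TestFitness:
    def test_separable_data_reaches_perfect_fitness(self):
        rng = np.random.default_rng(3)
        y = pd.Series(np.r_[np.zeros(50, int), np.ones(50, int)])
        X = pd.DataFrame({"sep": y * 10.0 + rng.normal(0, 0.1, 100), "junk": rng.normal(size=100)})
        lab = LabeledCohort(X, y, OUTCOMES["CDelay"])
        chrom = Chromosome(np.array([True, False]), 1, 1)
        rec = evaluate_fitness(chrom, lab, small_config())
        assert rec.fitness == 1.0
        assert rec.fitness == pytest.approx(np.mean(rec.fold_accuracies))

    def test_permuted_labels_give_chance_fitness(self):
        fits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(400, 3)), columns=list("abc"))
            y = pd.Series(np.tile([0, 1], 200))
            lab = LabeledCohort(X, y, OUTCOMES["CDelay"])
            chrom = Chromosome(np.ones(3, bool), 1, 1)
            fits.append(evaluate_fitness(chrom, lab, small_config(seed=seed)).fitness)
        assert abs(np.mean(fits) - 0.5) < 0.05

    def test_constant_feature_gives_majority_rate(self):
        y = pd.Series(np.tile([0, 1], 100))
        X = pd.DataFrame({"const": np.ones(200), "x": np.arange(200.0)})
        lab = LabeledCohort(X, y, OUTCOMES["CDelay"])
        chrom = Chromosome(np.array([True, False]), 0, 0)
        rec = evaluate_fitness(chrom, lab, small_config())
        assert rec.fitness == pytest.approx(0.5, abs=0.02)

    def test_deterministic_given_seed(self):
        lab = logistic_cohort(seed=4)
        chrom = Chromosome(
            np.array([True, True] + [False] * (lab.features.shape[1] - 2)), 1, 1
        )
        cfg = small_config(seed=4)
        assert (
            evaluate_fitness(chrom, lab, cfg).fitness
            == evaluate_fitness(chrom, lab, cfg).fitness
        )


class TestIntelligentCrossover:
    def test_identical_parents_return_copy(self):
        lab = logistic_cohort(seed=5)
        ev = _Evaluator(lab, small_config(seed=5))
        n = lab.features.shape[1]
        mask = np.zeros(n, bool)
        mask[:3] = True
        a = Chromosome(mask, 1, 1)
        child = intelligent_crossover(a, a.copy(), ev)
        assert child.key() == a.key()

    def test_child_preserves_subset_size(self):
        lab = logistic_cohort(seed=6)
        ev = _Evaluator(lab, small_config(seed=6))
        n = lab.features.shape[1]
        rng = np.random.default_rng(6)
        for _ in range(10):
            ma, mb = np.zeros(n, bool), np.zeros(n, bool)
            ma[rng.choice(n, 3, replace=False)] = True
            mb[rng.choice(n, 3, replace=False)] = True
            child = intelligent_crossover(
                Chromosome(ma, 0, 2), Chromosome(mb, 2, 0), ev
            )
            assert child.r == 3

    def test_unequal_subset_sizes_rejected(self):
        lab = logistic_cohort(seed=7)
        ev = _Evaluator(lab, small_config(seed=7))
        n = lab.features.shape[1]
        a = Chromosome(np.r_[np.ones(2, bool), np.zeros(n - 2, bool)], 0, 0)
        b = Chromosome(np.r_[np.ones(3, bool), np.zeros(n - 3, bool)], 0, 0)
        with pytest.raises(InvalidInputError):
            intelligent_crossover(a, b, ev)

    def test_design_size_bound(self):
        lab = logistic_cohort(seed=8)
        cfg = small_config(seed=8)
        ev = _Evaluator(lab, cfg)
        n = lab.features.shape[1]
        ma = np.zeros(n, bool)
        mb = np.zeros(n, bool)
        ma[[0, 1, 2]] = True
        mb[[3, 4, 5]] = True  # 6 disagreeing feature genes + both params differ
        before = ev.n_evaluations
        intelligent_crossover(Chromosome(ma, 0, 0), Chromosome(mb, 2, 2), ev)
        k = 8
        bound = 2 * 2 ** int(np.ceil(np.log2(k + 1)))
        assert ev.n_evaluations - before <= bound + 2  # rows + child + fallback row

    def test_beats_uniform_crossover_on_average(self):
        # paired comparison against a uniform-crossover oracle, same parents
        lab = logistic_cohort(n=300, seed=9)
        cfg = small_config(seed=9)
        ev = _Evaluator(lab, cfg)
        n = lab.features.shape[1]
        rng = np.random.default_rng(9)
        smart, uniform = [], []
        for _ in range(50):
            ma, mb = np.zeros(n, bool), np.zeros(n, bool)
            ma[rng.choice(n, 3, replace=False)] = True
            mb[rng.choice(n, 3, replace=False)] = True
            pa = Chromosome(ma, int(rng.integers(3)), int(rng.integers(3)))
            pb = Chromosome(mb, int(rng.integers(3)), int(rng.integers(3)))
            smart.append(ev(intelligent_crossover(pa, pb, ev)).fitness)
            # oracle: uniform crossover with count repair by random flips
            mask = ma.copy()
            diff = np.flatnonzero(ma != mb)
            for p in diff:
                mask[p] = (ma if rng.random() < 0.5 else mb)[p]
            ones = np.flatnonzero(mask)
            zeros = np.flatnonzero(~mask)
            while mask.sum() > 3:
                mask[rng.choice(np.flatnonzero(mask))] = False
            while mask.sum() < 3:
                mask[rng.choice(np.flatnonzero(~mask))] = True
            child = Chromosome(
                mask,
                pa.c_idx if rng.random() < 0.5 else pb.c_idx,
                pa.gamma_idx if rng.random() < 0.5 else pb.gamma_idx,
            )
            uniform.append(ev(child).fitness)
        assert np.mean(smart) >= np.mean(uniform)


class TestRunIBCGA:
    def test_perfect_feature_found_with_fitness_one(self):
        rng = np.random.default_rng(10)
        y = pd.Series(np.tile([0, 1], 60))
        X = pd.DataFrame(rng.normal(size=(120, 6)), columns=[f"n{i}" for i in range(6)])
        X["perfect"] = y * 1.0
        lab = LabeledCohort(X, y, OUTCOMES["CDelay"])
        model = run_ibcga(
            lab,
            small_config(
                r_start=1, r_end=2, population_size=20, mutation_rate=0.3, seed=10
            ),
        )
        assert "perfect" in model.selected_features
        assert model.cv_fitness == 1.0
        assert model.m == 1  # tie toward the smaller subset

    def test_reproducible_given_seed(self):
        lab = logistic_cohort(n=150, seed=11)
        cfg = dict(population_size=8, generations_per_r=3, r_start=2, r_end=3, seed=11, **SMALL_GRID)
        a = run_ibcga(lab, GAConfig(**cfg))
        b = run_ibcga(lab, GAConfig(**cfg))
        assert a.model_card() == b.model_card()
        pd.testing.assert_frame_equal(a.fit_log, b.fit_log)

    def test_best_fitness_nondecreasing_within_each_r(self):
        lab = logistic_cohort(n=150, seed=12)
        model = run_ibcga(lab, small_config(seed=12))
        for _, grp in model.fit_log.groupby("r"):
            best = grp["best_fitness"].to_numpy()
            assert np.all(np.diff(best) >= 0)

    def test_too_few_candidates_rejected(self):
        lab = logistic_cohort(seed=13)
        lab.features = lab.features.iloc[:, :2]
        with pytest.raises(ConfigurationError):
            run_ibcga(lab, small_config(r_start=5, r_end=6))

    def test_med_ranks_cover_selected_features_descending(self):
        lab = logistic_cohort(n=150, seed=14)
        model = run_ibcga(lab, small_config(seed=14))
        names = [f for f, _ in model.med_ranks]
        assert sorted(names) == sorted(model.selected_features)
        meds = [v for _, v in model.med_ranks]
        assert meds == sorted(meds, reverse=True)


class TestComputeMED:
    def _linear_model(self, features, X, y, C=1.0):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        from elndi.ibcga import ELNDIModel

        clf = Pipeline([("s", StandardScaler()), ("svm", SVC(kernel="linear", C=C))])
        clf.fit(X[features].values, y.values)
        return ELNDIModel(features, C, 0.0, clf, [], pd.DataFrame(), 0.0, 0)

    def test_zero_weight_feature_has_zero_med(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame({"signal": rng.normal(size=300), "flat": np.ones(300)})
        y = pd.Series((X["signal"] > 0).astype(int))
        lab = LabeledCohort(X, y, OUTCOMES["CDelay"])
        model = self._linear_model(["signal", "flat"], X, y)
        med = dict(compute_med(model, lab))
        assert med["flat"] == 0.0  # constant feature flagged with MED 0
        assert med["signal"] > 0

    def test_single_feature_model_ranks_it_first(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame({"only": rng.normal(size=100)})
        y = pd.Series((X["only"] > 0).astype(int))
        lab = LabeledCohort(X, y, OUTCOMES["CDelay"])
        model = self._linear_model(["only"], X, y)
        ranks = compute_med(model, lab)
        assert ranks[0][0] == "only"
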