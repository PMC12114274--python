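import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

from hbq.hbond_features import FeatureMatrix, VariableKey
from hbq.qsar_ga_mlr import (
    CollinearityError,
    GAConfig,
    exhaustive_select,
    fit_mlr,
    ga_select,
    sign_report,
)
from hbq.synthetic_data import PlantedModelSpec, synth_feature_table


def _matrix(values, response, bridged=None):
    values = np.asarray(values, float)
    p = values.shape[1]
    bridged = bridged or [False] * p
    variables = [VariableKey(j + 1, f"Res{j + 1}", bridged[j]) for j in range(p)]
    return FeatureMatrix(row_ids=[f"r{i}" for i in range(values.shape[0])],
                         variables=variables, values=values,
                         response=np.asarray(response, float), fill=3.0)


def _planted(n=30, p=10, subset=(1, 4, 7), betas=(-80.0, 70.0, -60.0),
             noise_sd=0.0, seed=0, **kw):
    spec = PlantedModelSpec(n_rows=n, p_variables=p, true_subset=subset,
                            betas=betas, noise_sd=noise_sd, seed=seed, **kw)
    return synth_feature_table(spec)


class TestFitMlr:
    def test_exact_linear_two_columns(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(2.4, 3.0, size=(12, 4))
        response = 5.0 + 40.0 * values[:, 0] - 30.0 * values[:, 2]
        fit = fit_mlr(_matrix(values, response), ["V1", "V3"])
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)
        assert fit.intercept == pytest.approx(5.0)
        coefs = {v.label: c for v, c in fit.coefficients.items()}
        assert coefs["V1"] == pytest.approx(40.0)
        assert coefs["V3"] == pytest.approx(-30.0)

    def test_constant_response_r2_zero(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(2.4, 3.0, size=(10, 3))
        fit = fit_mlr(_matrix(values, np.full(10, 50.0)), ["V1"])
        assert fit.r_squared == 0.0

    def test_predictions_cover_all_rows(self):
        matrix, _ = _planted()
        fit = fit_mlr(matrix, ["V2", "V5"])
        assert set(fit.predictions) == set(matrix.row_ids)

    def test_rank_deficient_names_columns(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(2.4, 3.0, size=(10, 3))
        values[:, 2] = values[:, 0]  # exact duplicate column
        with pytest.raises(CollinearityError, match="V[13]"):
            fit_mlr(_matrix(values, rng.uniform(0, 100, 10)), ["V1", "V2", "V3"])

    def test_too_few_rows(self):
        values = np.random.default_rng(4).uniform(2.4, 3.0, size=(4, 5))
        with pytest.raises(ValueError, match="rows"):
            fit_mlr(_matrix(values, np.arange(4.0)), ["V1", "V2", "V3"])

    def test_duplicate_subset_entries(self):
        matrix, _ = _planted()
        with pytest.raises(ValueError, match="duplicate"):
            fit_mlr(matrix, ["V1", "V1"])

    def test_agrees_with_normal_equations(self, rng):
        """Independent hand solver: beta = (X'X)^-1 X'y."""
        for _ in range(10):
            values = rng.uniform(2.0, 3.0, size=(25, 6))
            response = rng.uniform(0, 100, 25)
            matrix = _matrix(values, response)
            fit = fit_mlr(matrix, ["V1", "V2", "V3", "V4"])
            X = np.column_stack([np.ones(25), values[:, :4]])
            beta = np.linalg.solve(X.T @ X, X.T @ response)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
            np.testing.assert_allclose(
                [c for c in fit.coefficients.values()], beta[1:], atol=1e-8)

    def test_agrees_with_sklearn(self, rng):
        values = rng.uniform(2.0, 3.0, size=(30, 5))
        response = rng.uniform(0, 100, 30)
        matrix = _matrix(values, response)
        fit = fit_mlr(matrix, ["V1", "V2", "V3"])
        skl = LinearRegression().fit(values[:, :3], response)
        assert fit.intercept == pytest.approx(skl.intercept_, abs=1e-8)
        np.testing.assert_allclose(list(fit.coefficients.values()), skl.coef_,
                                   atol=1e-8)
        assert fit.r_squared == pytest.approx(
            skl.score(values[:, :3], response), abs=1e-10)

    def test_nesting_monotonicity(self, rng):
        """Adding a variable never lowers in-fit R²."""
        for _ in range(5):
            values = rng.uniform(2.0, 3.0, size=(20, 6))
            response = rng.uniform(0, 100, 20)
            matrix = _matrix(values, response)
            small = fit_mlr(matrix, ["V1", "V2"])
            big = fit_mlr(matrix, ["V1", "V2", "V5"])
            assert big.r_squared >= small.r_squared - 1e-12


class TestExhaustiveSelect:
    def test_p3_k1_exact(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(2.4, 3.0, size=(10, 3))
        response = 2.0 * values[:, 1]
        sel = exhaustive_select(_matrix(values, response), k=1)
        assert [v.label for v in sel.variable_indices] == ["V2"]
        assert sel.fitness == pytest.approx(1.0, abs=1e-12)

    def test_planted_three_of_ten_with_noise(self):
        matrix, truth = _planted(noise_sd=0.5, seed=42)
        sel = exhaustive_select(matrix, k=3)
        assert set(sel.variable_indices) == set(truth.subset)

    def test_k_equals_p(self):
        matrix, _ = _planted(n=30, p=6, subset=(0, 1), betas=(50.0, -50.0))
        sel = exhaustive_select(matrix, k=6)
        full = fit_mlr(matrix, [v.label for v in matrix.variables])
        assert sel.fitness == pytest.approx(full.r_squared, abs=1e-12)

    def test_cap_exceeded(self):
        matrix, _ = _planted(n=40, p=31, subset=(0,), betas=(50.0,))
        with pytest.raises(ValueError, match="ga_select"):
            exhaustive_select(matrix, k=8, enumeration_cap=1000)

    def test_noiseless_recovery_fitness_one(self):
        matrix, truth = _planted(noise_sd=0.0, seed=9)
        sel = exhaustive_select(matrix, k=3)
        assert set(sel.variable_indices) == set(truth.subset)
        assert sel.fitness == pytest.approx(1.0, abs=1e-10)

    def test_invalid_k(self):
        matrix, _ = _planted()
        with pytest.raises(ValueError, match="k must be"):
            exhaustive_select(matrix, k=0)


class TestGaSelect:
    def test_trace_non_decreasing(self):
        matrix, _ = _planted(noise_sd=2.0, seed=1)
        sel = ga_select(matrix, GAConfig(k=3, population_size=20, generations=15,
                                         seed=5))
        assert all(b >= a for a, b in zip(sel.trace, sel.trace[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_small_instance(self, seed):
        matrix, _ = _planted(n=35, p=12, noise_sd=2.0, seed=seed)
        oracle = exhaustive_select(matrix, k=3)
        sel = ga_select(matrix, GAConfig(k=3, population_size=40, generations=30,
                                         seed=seed))
        assert sel.fitness == pytest.approx(oracle.fitness, abs=1e-12)

    def test_recovers_planted_eight_of_31(self):
        spec = PlantedModelSpec(noise_sd=2.0, seed=11)
        matrix, truth = synth_feature_table(spec)
        sel = ga_select(matrix, GAConfig(k=8, population_size=100,
                                         generations=120, seed=11))
        assert set(sel.variable_indices) == set(truth.subset)

    def test_bit_reproducible(self):
        matrix, _ = _planted(noise_sd=3.0, seed=2)
        config = GAConfig(k=3, population_size=30, generations=20, seed=77)
        a = ga_select(matrix, config)
        b = ga_select(matrix, config)
        assert a.variable_indices == b.variable_indices
        assert a.trace == b.trace
        assert a.fitness == b.fitness

    def test_dominates_random_subsets(self, rng):
        matrix, _ = _planted(n=30, p=15, noise_sd=10.0, seed=3)
        sel = ga_select(matrix, GAConfig(k=3, population_size=30, generations=25,
                                         seed=3))
        random_scores = []
        for _ in range(100):
            cols = rng.choice(15, size=3, replace=False)
            fit = fit_mlr(matrix, [f"V{c + 1}" for c in sorted(cols)])
            random_scores.append(fit.r_squared)
        assert sel.fitness >= float(np.median(random_scores))

    def test_k_larger_than_p(self):
        matrix, _ = _planted(n=30, p=5, subset=(0,), betas=(50.0,))
        with pytest.raises(ValueError, match="exceeds"):
            ga_select(matrix, GAConfig(k=8))

    def test_subset_cardinality_preserved(self):
        matrix, _ = _planted(noise_sd=5.0, seed=4)
        sel = ga_select(matrix, GAConfig(k=4, population_size=20, generations=10,
                                         seed=4, mutation_rate=0.5))
        assert len(set(sel.variable_indices)) == 4


class TestGAConfig:
    def test_invalid_population(self):
        with pytest.raises(ValueError, match="population_size"):
            GAConfig(population_size=1)

    def test_invalid_mutation_rate(self):
        with pytest.raises(ValueError, match="mutation_rate"):
            GAConfig(mutation_rate=1.5)

    def test_invalid_elitism(self):
        with pytest.raises(ValueError, match="elitism"):
            GAConfig(population_size=10, elitism_count=10)


class TestSignReport:
    def _fit(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(2.4, 3.0, size=(20, 3))
        response = 50.0 - 60.0 * values[:, 0] + 70.0 * values[:, 1]
        matrix = _matrix(values, response, bridged=[False, True, False])
        matrix.variables[0] = VariableKey(1, "Trp74", False)
        matrix.variables[1] = VariableKey(2, "Ser73", True)
        return fit_mlr(matrix, ["V1", "V2"])

    def test_negative_coefficient_tag(self):
        report = sign_report(self._fit())
        entry = next(e for e in report if e.rendered == "Trp74")
        assert entry.sign == "-"
        assert entry.tag == "short-bond-favors-activity"

    def test_positive_coefficient_on_bridged_variable(self):
        report = sign_report(self._fit())
        entry = next(e for e in report if e.rendered == "WSer73")
        assert entry.sign == "+"
        assert entry.tag == "no-interaction-favors-activity"

    def test_zero_coefficient(self):
        fit = self._fit()
        var = list(fit.coefficients)[0]
        fit.coefficients[var] = 0.0
        report = sign_report(fit)
        entry = next(e for e in report if e.variable == var)
        assert entry.sign == "0" and entry.tag is None

    def test_signs_match_coefficients(self):
        report = sign_report(self._fit())
        for entry in report:
            if entry.coefficient > 0:
                assert entry.sign == "+"
            elif entry.coefficient < 0:
                assert entry.sign == "-"
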