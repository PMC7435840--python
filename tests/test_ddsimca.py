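"""DD-SIMCA: distance algebra, chi-square coverage, optimisation, round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alqc import ddsimca
from alqc.ddsimca import (
    acceptance_boundary,
    classify_set,
    distances,
    fit,
    load_model,
    model_from_dict,
    model_to_dict,
    optimize,
    performance,
    save_model,
)
from alqc.preprocess import PreprocessConfig
from alqc.spectra import SpectraSet
from alqc import screening, synthetic


@pytest.fixture(scope="module")
def gaussian_model():
    r = np.random.default_rng(42)
    X = r.normal(size=(300, 10))
    return fit(X, 2, 0.05), X


class TestFit:
    def test_training_mean_has_zero_distances(self, gaussian_model):
        model, X = gaussian_model
        rec = distances(model, X.mean(axis=0)[None, :]).iloc[0]
        assert rec["h"] == pytest.approx(0.0, abs=1e-18)
        assert rec["v"] == pytest.approx(0.0, abs=1e-18)
        assert rec["accepted"]

    def test_h0_equals_training_mean_h(self, gaussian_model):
        model, X = gaussian_model
        rec = distances(model, X)
        assert rec["h"].mean() == pytest.approx(model.h0, rel=1e-9)
        assert rec["v"].mean() == pytest.approx(model.v0, rel=1e-9)

    def test_moment_estimator_recovers_chi2_dof(self):
        # h ~ chi2(1): the 2*mean^2/var estimator must return 1 at large n
        r = np.random.default_rng(0)
        x = r.chisquare(1, size=20000)
        _, n = ddsimca._moment_dof(x, "test")
        assert n == 1
        x = r.chisquare(7, size=20000)
        _, n = ddsimca._moment_dof(x, "test")
        assert n == 7

    def test_accepts_at_least_1_minus_alpha_of_training(self, default_study):
        train, _ = screening.split_batches(default_study, "Combiart", "licit")
        model = fit(train, 2, 1e-6, preprocess=PreprocessConfig())
        rec = distances(model, train)
        assert rec["accepted"].mean() >= 1 - 1e-6

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit(np.random.default_rng(0).normal(size=(3, 5)), 2, 0.05)

    def test_zero_variance_variables_dropped_with_warning(self):
        r = np.random.default_rng(1)
        X = r.normal(size=(30, 6))
        X[:, 2] = 4.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit(X, 2, 0.05)
        assert model.kept.tolist() == [0, 1, 3, 4, 5]
        rec = distances(model, X)  # dropped variable ignored at prediction
        assert np.isfinite(rec["c"]).all()


class TestDistances:
    def test_acceptance_nested_in_alpha(self, gaussian_model):
        model, X = gaussian_model
        r = np.random.default_rng(3)
        fresh = r.normal(size=(500, 10))
        strict = model.with_alpha(0.05)
        lenient = model.with_alpha(0.001)
        acc_strict = distances(strict, fresh)["accepted"]
        acc_lenient = distances(lenient, fresh)["accepted"]
        assert (acc_strict <= acc_lenient).all()  # accepted at alpha => at alpha' < alpha

    def test_rejection_rate_matches_alpha_on_gaussian_data(self, gaussian_model):
        # MC coverage oracle: data from the model's own Gaussian population
        model, _ = gaussian_model
        r = np.random.default_rng(7)
        fresh = r.normal(size=(2000, 10))
        rate = 1.0 - distances(model, fresh)["accepted"].mean()
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < 3 * se + 0.01  # small slack for estimated dof

    def test_flags_equal_bruteforce_recomputation(self, gaussian_model):
        model, X = gaussian_model
        rec = distances(model, X[:50])
        Z = (X[:50][:, model.kept] - model.mean) / model.sd
        T = Z @ model.loadings
        h = np.sum(T**2 / model.eigenvalues, axis=1)
        v = np.sum((Z - T @ model.loadings.T) ** 2, axis=1)
        c = model.N_h * h / model.h0 + model.N_v * v / model.v0
        np.testing.assert_allclose(rec["c"], c, rtol=1e-12)
        np.testing.assert_array_equal(rec["accepted"], c <= model.c_crit)

    def test_invariant_to_consistent_variable_permutation(self):
        r = np.random.default_rng(5)
        X = r.normal(size=(40, 8))
        Y = r.normal(size=(10, 8))
        perm = r.permutation(8)
        m1, m2 = fit(X, 2, 0.05), fit(X[:, perm], 2, 0.05)
        np.testing.assert_allclose(
            distances(m1, Y)["c"], distances(m2, Y[:, perm])["c"], rtol=1e-9
        )

    def test_invariant_to_global_rescaling(self):
        r = np.random.default_rng(6)
        X = r.normal(size=(40, 8))
        Y = r.normal(size=(10, 8))
        m1, m2 = fit(X, 2, 0.05), fit(X * 37.0, 2, 0.05)
        np.testing.assert_allclose(
            distances(m1, Y)["c"], distances(m2, Y * 37.0)["c"], rtol=1e-9
        )

    def test_empty_set_classifies_to_empty_frame(self, gaussian_model):
        model, _ = gaussian_model
        out = classify_set(model, np.empty((0, 10)))
        assert len(out) == 0


class TestPerformance:
    def test_all_accepted_gives_full_sensitivity(self, gaussian_model):
        model, X = gaussian_model
        lenient = model.with_alpha(1e-12)
        perf = performance(lenient, X[:50], {})
        assert perf.sensitivity == 100.0

    def test_counts_match_bruteforce(self, gaussian_model):
        model, X = gaussian_model
        r = np.random.default_rng(11)
        aliens = {"far": r.normal(loc=50.0, size=(20, 10)), "near": r.normal(size=(20, 10))}
        perf = performance(model, X[:50], aliens)
        rejected = sum(
            int((~distances(model, a)["accepted"]).sum()) for a in aliens.values()
        )
        assert perf.specificity == pytest.approx(100.0 * rejected / 40)
        assert perf.per_alien["far"] == (20, 20)

    def test_empty_target_set_rejected(self, gaussian_model):
        model, _ = gaussian_model
        with pytest.raises(ValueError):
            performance(model, np.empty((0, 10)), {})


class TestBoundary:
    def test_endpoints_match_substitution(self, gaussian_model):
        model, _ = gaussian_model
        b = acceptance_boundary(model, 100)
        assert b[0, 0] == pytest.approx(0.0)
        assert b[0, 1] == pytest.approx(np.log1p(model.c_crit / model.N_v))
        assert b[-1, 0] == pytest.approx(np.log1p(model.c_crit / model.N_h))
        assert b[-1, 1] == pytest.approx(0.0)

    def test_every_point_sits_on_critical_level(self, gaussian_model):
        model, _ = gaussian_model
        b = acceptance_boundary(model, 50)
        h = model.h0 * np.expm1(b[:, 0])
        v = model.v0 * np.expm1(b[:, 1])
        c = model.N_h * h / model.h0 + model.N_v * v / model.v0
        np.testing.assert_allclose(c, model.c_crit, rtol=1e-9)


class TestOptimize:
    def test_singleton_grids_return_that_model(self, gaussian_model):
        _, X = gaussian_model
        res = optimize(X[:100], X[100:150], {"a": X[150:200]}, A_grid=[2], alpha_grid=[1e-3])
        assert res.model.A == 2 and res.model.alpha == 1e-3
        assert len(res.trace) == 1

    def test_trace_equals_exhaustive_evaluation(self, gaussian_model):
        _, X = gaussian_model
        r = np.random.default_rng(2)
        aliens = {"shift": X[200:260] + 8.0}
        A_grid, alpha_grid = [1, 2], [1e-2, 1e-4]
        res = optimize(X[:100], X[100:160], aliens, A_grid=A_grid, alpha_grid=alpha_grid)
        for _, row in res.trace.iterrows():
            m = fit(X[:100], int(row["A"]), row["alpha"])
            p = performance(m, X[100:160], aliens)
            assert p.sensitivity == pytest.approx(row["sensitivity"])
            assert p.specificity == pytest.approx(row["specificity"])

    def test_selects_two_pcs_on_well_separated_brands(self, default_study):
        res = screening.screen_brand(default_study, "Combiart")
        assert res.model.A <= 2  # compact model suffices for a distinct brand
        assert res.reached_full_sensitivity


class TestSerialization:
    def test_round_trip_reproduces_distances_bitwise(self, tmp_path, default_study):
        train, test = screening.split_batches(default_study, "Komefan", "licit")
        model = fit(train, 2, 1e-4, preprocess=PreprocessConfig())
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        a = distances(model, test)
        b = distances(loaded, test)
        np.testing.assert_array_equal(a["h"].to_numpy(), b["h"].to_numpy())
        np.testing.assert_array_equal(a["v"].to_numpy(), b["v"].to_numpy())
        np.testing.assert_array_equal(a["accepted"].to_numpy(), b["accepted"].to_numpy())


class TestScreening:
    def test_split_is_batchwise(self, default_study):
        train, test = screening.split_batches(default_study, "AL Macleods", "licit")
        assert set(train.meta["batch"]).isdisjoint(set(test.meta["batch"]))
        assert train.meta["batch"].nunique() == 3
        assert train.n_samples == 30

    def test_falsified_combiart_rejected_by_licit_model(self, default_study):
        res = screening.screen_brand(default_study, "Combiart")
        fake = default_study.select_product("Combiart", "illicit")
        flags = classify_set(res.model, fake)["accepted"]
        assert not flags.any()

    def test_brand_with_too_few_batches_refused(self, default_study):
        with pytest.raises(ValueError, match="at least 5"):
            screening.screen_brand(default_study, "AL Ipca")

    def test_three_models_built_on_default_study(self, default_study):
        targets = screening.eligible_targets(default_study)
        assert sorted(b for b, _ in targets) == ["AL Macleods", "Combiart", "Komefan"]
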