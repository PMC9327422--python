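"""Model-engine tests: every solver claim is checked against an
independent oracle (L-BFGS-B on the split-variable objective, brute-force
LOO, least squares) rather than against the solver itself."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from amlsig.cohort import binarize_response
from amlsig.models import (
    ALLOWED_COMBOS,
    CVConfig,
    DegeneratePathError,
    EmptySignatureError,
    FitResult,
    ModelSpec,
    SingleClassError,
    Signature,
    assemble_features,
    compare_models,
    default_path,
    evaluate_nested_cv,
    extract_signature,
    fit_penalized,
    kkt_residual,
    lambda_max,
    make_folds,
    penalized_objective,
    select_penalty_loo,
)
from amlsig.synthdata import CohortConfig, generate_cohort


def oracle_min_objective(X, y, family, a, lam):
    """Independent numeric minimizer: split beta = b+ - b- so the
    objective is smooth over nonnegative variables, then L-BFGS-B."""
    n, p = X.shape

    def obj(w):
        b0, bp, bm = w[0], w[1 : p + 1], w[p + 1 :]
        beta = bp - bm
        eta = b0 + X @ beta
        if family == "logistic":
            loss = 2.0 / n * np.sum(np.logaddexp(0.0, eta) - y * eta)
        else:
            loss = np.sum((y - eta) ** 2) / (2 * n)
        pen = lam * ((1 - a) * (beta @ beta) / 2 + a * np.sum(bp + bm))
        return loss + pen

    bounds = [(None, None)] + [(0, None)] * (2 * p)
    res = minimize(obj, np.zeros(2 * p + 1), method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 20_000, "ftol": 1e-15, "gtol": 1e-12})
    return res.fun


class TestFitPenalized:
    def test_matches_numeric_minimizer(self):
        rng = np.random.default_rng(1)
        for family in ("lasso_gauss", "logistic"):
            fam = "logistic" if family == "logistic" else "elasticnet"
            X = rng.standard_normal((12, 6))
            X = (X - X.mean(0)) / X.std(0)
            if fam == "logistic":
                y = (rng.random(12) < 0.5).astype(float)
                y[:2] = [0, 1]  # both classes
            else:
                y = rng.standard_normal(12)
            lam, a = 0.3, 0.5
            coef, b0 = fit_penalized(X, y, fam, a, lam)
            ours = penalized_objective(X, y, fam, a, lam, coef, b0)
            oracle = oracle_min_objective(X, y, fam, a, lam)
            assert ours <= oracle + 1e-5
            assert kkt_residual(X, y, fam, a, lam, coef, b0) <= 1e-6

    def test_lambda_zero_matches_least_squares(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        coef, b0 = fit_penalized(X, y, "lasso", 1.0, 0.0)
        Xi = np.column_stack([np.ones(20), X])
        beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
        assert np.allclose(coef, beta[1:], atol=1e-6)
        assert np.isclose(b0, beta[0], atol=1e-6)

    def test_lambda_above_max_gives_null_model(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((15, 8))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.standard_normal(15)
        lmax = lambda_max(X, y, "lasso", 1.0)
        coef, b0 = fit_penalized(X, y, "lasso", 1.0, lmax * 1.001)
        assert np.all(coef == 0)
        assert np.isclose(b0, y.mean())

    def test_logistic_single_class_rejected(self):
        X = np.eye(4)
        with pytest.raises(SingleClassError):
            fit_penalized(X, np.ones(4), "logistic", 1.0, 0.1)

    def test_path_continuity(self):
        # coefficients along adjacent path points move by O(dlambda)
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 6))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 0] + 0.5 * rng.standard_normal(20)
        path = default_path(lambda_max(X, y, "lasso", 1.0), 30)
        prev = None
        for lam in path:
            coef, _ = fit_penalized(X, y, "lasso", 1.0, lam)
            if prev is not None:
                assert np.abs(coef - prev).max() < 0.35
            prev = coef


class TestSelectPenaltyLoo:
    def test_matches_brute_force_on_explicit_grid(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((8, 4))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 1] + 0.3 * rng.standard_normal(8)
        grid = np.array([1.0, 0.5, 0.2, 0.1, 0.05])
        lam, path, errs = select_penalty_loo(X, y, "lasso", 1.0, path=grid)
        # independent brute force: refit each left-out problem from scratch
        brute = np.zeros(len(grid))
        for k, lam_k in enumerate(grid):
            se = []
            for i in range(8):
                mask = np.arange(8) != i
                coef, b0 = fit_penalized(X[mask], y[mask], "lasso", 1.0, lam_k)
                se.append((b0 + X[i] @ coef - y[i]) ** 2)
            brute[k] = np.mean(se)
        assert np.allclose(errs, brute, atol=1e-4)
        assert lam == grid[np.argmin(brute)]

    def test_noiseless_recovery_selects_true_support(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((15, 5))
        X = (X - X.mean(0)) / X.std(0)
        y = 2.0 * X[:, 2]
        lam, _path, errs = select_penalty_loo(X, y, "lasso", 1.0)
        assert errs.min() < 1e-3
        coef, _ = fit_penalized(X, y, "lasso", 1.0, lam)
        assert np.flatnonzero(coef).tolist() == [2]

    def test_pure_noise_prefers_null_model(self):
        # with p >> n the null (path-top) model should win most of the time
        rng = np.random.default_rng(7)
        wins = 0
        reps = 50
        for _ in range(reps):
            X = rng.standard_normal((10, 40))
            y = rng.standard_normal(10)
            lam, path, _ = select_penalty_loo(X, y, "lasso", 1.0, n_lambda=20)
            if lam >= path[len(path) // 4]:  # top quarter of the path
                wins += 1
        assert wins > reps / 2

    def test_constant_response_is_degenerate(self):
        X = np.random.default_rng(8).standard_normal((10, 3))
        with pytest.raises(DegeneratePathError):
            select_penalty_loo(X, np.ones(10), "lasso", 1.0)

    def test_ties_break_toward_larger_penalty(self):
        # two penalties above lambda_max both give the null model, hence
        # identical LOO errors: the larger one must be selected
        rng = np.random.default_rng(9)
        X = rng.standard_normal((8, 3))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 0] + rng.standard_normal(8)
        lmax = lambda_max(X, y, "lasso", 1.0)
        grid = np.array([10 * lmax, 5 * lmax])
        lam, _p, errs = select_penalty_loo(X, y, "lasso", 1.0, path=grid)
        assert np.isclose(errs[0], errs[1])
        assert lam == grid[0]


class TestAssembleFeatures:
    def test_columns_standardized(self, small_cohort):
        cohort, _r, _t = small_cohort
        X = assemble_features(cohort, ("protein",))
        assert np.allclose(X.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(X.std(axis=0, ddof=0), 1, atol=1e-12)

    def test_combined_count_is_sum_of_kept(self, small_cohort):
        cohort, _r, _t = small_cohort
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            xt = assemble_features(cohort, ("transcript",))
            xp = assemble_features(cohort, ("protein",))
            both = assemble_features(cohort, ("transcript", "protein"))
        assert both.shape[1] == xt.shape[1] + xp.shape[1]

    def test_constant_columns_dropped_with_warning(self, small_cohort):
        cohort, _r, _t = small_cohort
        with pytest.warns(UserWarning, match="constant"):
            X = assemble_features(cohort, ("mutation",))
        assert (X.std(axis=0, ddof=0) > 0).all()

    def test_empty_intersection_rejected(self, small_cohort):
        cohort, _r, _t = small_cohort
        with pytest.raises(ValueError, match="empty sample"):
            assemble_features(cohort, ("protein",), samples=["nope"])


class TestNestedCV:
    def test_noiseless_planted_signature_scores_high(self):
        cfg = CohortConfig(seed=21, n_genes=200, n_drugs=1, noise_sd=0.0,
                           missing_rate=0.0)
        cohort, resp, _t = generate_cohort(cfg)
        X = assemble_features(cohort, ("protein",))
        y = resp.auc.loc["D01"].to_numpy(float)
        fit = evaluate_nested_cv(X, y, ModelSpec("lasso", ("protein",)),
                                 CVConfig(seed=1), fit_full=False)
        assert not fit.excluded
        assert fit.mean_score >= 0.9

    def test_scores_bounded(self, small_cohort):
        cohort, resp, _t = small_cohort
        X = assemble_features(cohort, ("protein",))
        y = resp.auc.loc["D01"].to_numpy(float)
        fit = evaluate_nested_cv(X, y, ModelSpec("elasticnet", ("protein",)),
                                 CVConfig(seed=2), fit_full=False)
        if not fit.excluded:
            assert -1 <= fit.mean_score <= 1
            assert all(-1 <= s <= 1 for s in fit.fold_scores)

    def test_constant_feature_matrix_excluded_not_crash(self):
        X = pd.DataFrame({"protein:GA": np.zeros(20)})
        y = np.random.default_rng(3).standard_normal(20)
        fit = evaluate_nested_cv(X, y, ModelSpec("lasso", ("protein",)),
                                 CVConfig(seed=3))
        assert fit.excluded
        assert fit.mean_score is None

    def test_determinism(self, small_cohort):
        cohort, resp, _t = small_cohort
        X = assemble_features(cohort, ("protein",))
        y = resp.auc.loc["D02"].to_numpy(float)
        spec = ModelSpec("lasso", ("protein",))
        f1 = evaluate_nested_cv(X, y, spec, CVConfig(seed=7), fit_full=False)
        f2 = evaluate_nested_cv(X, y, spec, CVConfig(seed=7), fit_full=False)
        assert f1.fold_scores == f2.fold_scores

    def test_stratified_folds_keep_class_balance(self):
        y = np.array([0] * 30 + [1] * 10, dtype=float)
        folds = make_folds(40, 5, seed=4, y_strata=y)
        assert sorted(np.concatenate(folds).tolist()) == list(range(40))
        for f in folds:
            assert 1 <= y[f].sum() <= 3


class TestSignature:
    def test_planted_support_recovered(self):
        cfg = CohortConfig(seed=31, n_genes=200, n_drugs=1, missing_rate=0.0)
        cohort, resp, truth = generate_cohort(cfg)
        X = assemble_features(cohort, ("protein",))
        y = resp.auc.loc["D01"].to_numpy(float)
        sig = extract_signature(X, y, ModelSpec("lasso", ("protein",)), drug="D01")
        got = {f for f, _m, _c in sig.features}
        planted = truth.support("D01")
        assert len(planted & got) / len(planted) >= 0.8

    def test_forced_max_penalty_raises_empty_signature(self):
        rng = np.random.default_rng(32)
        X = pd.DataFrame(rng.standard_normal((15, 4)),
                         columns=[f"protein:G{i}" for i in range(4)])
        y = rng.standard_normal(15)
        spec = ModelSpec("lasso", ("protein",),
                         penalty_grid=np.array([1e6, 2e6]))
        with pytest.raises(EmptySignatureError):
            extract_signature(X, y, spec, drug="D")

    def test_duplicated_column_handled_deterministically(self):
        rng = np.random.default_rng(33)
        base = rng.standard_normal(20)
        X = pd.DataFrame({
            "protein:GA": base, "protein:GB": base.copy(),
            "protein:GC": rng.standard_normal(20),
        })
        y = 2 * base + 0.1 * rng.standard_normal(20)
        spec = ModelSpec("lasso", ("protein",))
        s1 = extract_signature(X, y, spec, drug="D")
        s2 = extract_signature(X, y, spec, drug="D")
        assert s1.features == s2.features

    def test_json_round_trip(self, tmp_path):
        sig = Signature("D01", ModelSpec("lasso", ("protein",)),
                        [("GA", "protein", 1.5), ("GB-pS1", "phosphosite", -0.2)])
        p = tmp_path / "sig.json"
        sig.to_json(p)
        back = Signature.from_json(p)
        assert back.drug == sig.drug
        assert back.features == sig.features


class TestCompareModels:
    def test_bookkeeping_and_determinism(self, small_cohort):
        cohort, resp, _t = small_cohort
        specs = [ModelSpec("lasso", c) for c in (("mutation",), ("protein",))]
        drugs = list(resp.drugs)[:2]
        t1 = compare_models(cohort, resp, drugs, specs, CVConfig(seed=5))
        t2 = compare_models(cohort, resp, drugs, specs, CVConfig(seed=5))
        assert len(t1) == len(drugs) * len(specs)
        pd.testing.assert_frame_equal(t1, t2)
        # excluded rows are flagged, not dropped
        assert set(t1["excluded"]) <= {True, False}

    def test_allowed_combos_has_seven_entries(self):
        assert len(ALLOWED_COMBOS) == 7


class TestModelSpecValidation:
    def test_lasso_forces_mixing_one(self):
        with pytest.raises(ValueError, match="mixing"):
            ModelSpec("lasso", ("protein",), mixing=0.5)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec("ridge", ("protein",))

    def test_default_mixing_per_family(self):
        assert ModelSpec("elasticnet", ("protein",)).mixing == 0.5
        assert ModelSpec("lasso", ("protein",)).mixing == 1.0
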