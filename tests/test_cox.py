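"""Weighted Cox fitter: closed forms, brute-force oracles, sandwich variance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from stratcox import (
    ConvergenceError,
    InvalidParameterError,
    ModelSpec,
    build_design_matrix,
    fit_weighted_cox,
    sandwich_variance,
)

# the 3-subject instance whose partial-likelihood root is -(ln 2)/2
TOY = dict(
    X=np.array([[1.0], [0.0], [1.0]]),
    time=np.array([1.0, 2.0, 3.0]),
    event=np.array([1.0, 1.0, 0.0]),
    weights=np.ones(3),
)
TOY_BETA = -math.log(2) / 2


def brute_loglik(beta, X, time, event, weights):
    """Independent O(n^2) product-form weighted log partial likelihood."""
    beta = np.atleast_1d(beta)
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            ll += weights[i] * (
                X[i] @ beta - np.log(np.sum(weights[risk] * np.exp(X[risk] @ beta)))
            )
    return ll


def brute_maximizer(X, time, event, weights):
    """Grid search + polish on the brute-force likelihood (oracle path)."""
    p = X.shape[1]
    if p == 1:
        grid = np.linspace(-3, 3, 1201)
        vals = [brute_loglik([b], X, time, event, weights) for b in grid]
        b0 = grid[int(np.argmax(vals))]
        res = optimize.minimize_scalar(
            lambda b: -brute_loglik([b], X, time, event, weights),
            bounds=(b0 - 0.05, b0 + 0.05),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return np.array([res.x])
    res = optimize.minimize(
        lambda b: -brute_loglik(b, X, time, event, weights),
        np.zeros(p),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000},
    )
    return res.x


def random_instance(seed, n=6, p=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    time = rng.exponential(size=n) + 0.05  # continuous, distinct a.s.
    event = (rng.random(n) < 0.7).astype(float)
    if event.sum() == 0:
        event[0] = 1.0
    weights = rng.uniform(0.5, 3.0, size=n)
    return X, time, event, weights


class TestDesignMatrix:
    def _one_row(self, stratum, smoker):
        return pd.DataFrame(
            {"stratum": [stratum], "smoker": [smoker], "time": [1.0], "event": [1],
             "weight": [2.0]}
        )

    def test_full_encoding(self):
        X, names, *_ = build_design_matrix(self._one_row("administrative", 1), "full")
        assert names == (
            "technicians",
            "administrative",
            "smoking:professionals",
            "smoking:technicians",
            "smoking:administrative",
        )
        assert X.tolist() == [[0.0, 1.0, 0.0, 0.0, 1.0]]

    def test_marginal_encoding(self):
        X, names, *_ = build_design_matrix(self._one_row("professionals", 1), "marginal")
        assert names == ("technicians", "administrative", "smoking")
        assert X.tolist() == [[0.0, 0.0, 1.0]]

    def test_smoke_only_encoding(self):
        X, names, *_ = build_design_matrix(self._one_row("technicians", 1), "smoke_only")
        assert names == ("smoking",)
        assert X.tolist() == [[1.0]]

    @pytest.mark.parametrize("model", ["full", "marginal", "smoke_only"])
    def test_reference_row_is_zero(self, model):
        X, *_ = build_design_matrix(self._one_row("professionals", 0), model)
        assert not X.any()

    def test_unknown_model_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModelSpec("saturated")

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_design_matrix(self._one_row("professionals", 0).iloc[:0], "full")


class TestFitter:
    def test_toy_closed_form(self):
        fit = fit_weighted_cox(**TOY, tol=1e-14)
        assert fit.coef[0] == pytest.approx(TOY_BETA, abs=1e-8)
        assert fit.converged and fit.n_events == 2
        assert fit.hr[0] == pytest.approx(math.exp(fit.coef[0]), rel=1e-15)

    def test_toy_matches_grid_search_oracle(self):
        oracle = brute_maximizer(**TOY)
        fit = fit_weighted_cox(**TOY, tol=1e-14)
        assert abs(fit.coef[0] - oracle[0]) < 1e-4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_small_instances_match_brute_force(self, seed):
        """On <=6-subject instances the Newton solution matches a grid-search
        maximizer of the explicit product-form partial likelihood."""
        X, time, event, weights = random_instance(seed)
        try:
            fit = fit_weighted_cox(X, time, event, weights, tol=1e-13)
        except ConvergenceError:
            pytest.skip("degenerate draw (monotone likelihood)")
        oracle = brute_maximizer(X, time, event, weights)
        assert np.allclose(fit.coef, oracle, atol=1e-4)

    def test_constant_weights_match_unit_weights(self):
        fit1 = fit_weighted_cox(**TOY, tol=1e-13)
        fit7 = fit_weighted_cox(
            TOY["X"], TOY["time"], TOY["event"], 7.0 * TOY["weights"], tol=1e-13
        )
        assert np.allclose(fit1.coef, fit7.coef, atol=1e-10)
        assert np.allclose(fit1.robust_cov, fit7.robust_cov, atol=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(1e-3, 1e3))
    def test_weight_scale_invariance(self, c):
        X, time, event, weights = random_instance(11, n=40)
        base = fit_weighted_cox(X, time, event, weights, tol=1e-13)
        scaled = fit_weighted_cox(X, time, event, c * weights, tol=1e-13)
        assert np.allclose(base.coef, scaled.coef, atol=1e-8)
        assert np.allclose(base.robust_cov, scaled.robust_cov, rtol=1e-7, atol=1e-12)

    def test_frequency_weight_equivalence(self):
        """Duplicating a record equals giving it weight 2 (point estimate)."""
        X, time, event, _ = random_instance(5, n=8)
        w = np.ones(8)
        w2 = w.copy()
        w2[3] = 2.0
        Xd = np.vstack([X, X[3]])
        td = np.append(time, time[3])
        dd = np.append(event, event[3])
        wd = np.ones(9)
        f_weighted = fit_weighted_cox(X, time, event, w2, tol=1e-13)
        f_duplicated = fit_weighted_cox(Xd, td, dd, wd, tol=1e-13)
        assert np.allclose(f_weighted.coef, f_duplicated.coef, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unit_weights_match_lifelines(self, seed):
        """Unit-weight fits reproduce an independent unweighted implementation
        (point estimates to 1e-8; robust SEs likewise)."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(seed)
        n = 200
        X = rng.normal(size=(n, 2))
        time = rng.exponential(size=n) * np.exp(-X @ [0.5, -0.3])
        event = (rng.random(n) < 0.7).astype(float)
        fit = fit_weighted_cox(X, time, event, np.ones(n), tol=1e-14)
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = time, event
        cph = CoxPHFitter().fit(
            df, "T", "E", robust=True, fit_options={"precision": 1e-11}
        )
        assert np.abs(fit.coef - cph.params_.to_numpy()).max() < 1e-8
        assert np.abs(fit.robust_se - cph.standard_errors_.to_numpy()).max() < 1e-8

    def test_zero_events_rejected(self):
        with pytest.raises(InvalidParameterError, match="no events"):
            fit_weighted_cox(TOY["X"], TOY["time"], np.zeros(3), TOY["weights"])

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_weighted_cox(TOY["X"], TOY["time"], TOY["event"], np.array([1.0, 0.0, 1.0]))

    def test_monotone_likelihood_raises_with_trace(self):
        """Perfect separation: the exposed group fails strictly first."""
        X = np.array([[1.0], [1.0], [0.0], [0.0]])
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1.0, 1.0, 0.0, 0.0])
        with pytest.raises(ConvergenceError) as exc:
            fit_weighted_cox(X, time, event, np.ones(4))
        assert len(exc.value.trace) > 0

    def test_collinear_columns_named(self):
        X = np.column_stack([TOY["X"], TOY["X"]])
        with pytest.raises(ConvergenceError, match="column"):
            fit_weighted_cox(
                X, TOY["time"], TOY["event"], TOY["weights"], names=("a", "a_copy")
            )


class TestSandwich:
    def test_symmetric_psd_and_scale_invariant(self):
        X, time, event, weights = random_instance(2, n=50)
        fit = fit_weighted_cox(X, time, event, weights, tol=1e-13)
        V = sandwich_variance(X, time, event, weights, fit.coef)
        assert np.allclose(V, V.T)
        assert np.all(np.linalg.eigvalsh(V) >= -1e-12)
        V10 = sandwich_variance(X, time, event, 10.0 * weights, fit.coef)
        assert np.allclose(V, V10, rtol=1e-9)

    def test_matches_delete_one_jackknife(self):
        """On a 30-subject instance the sandwich agrees with the delete-one
        jackknife within a factor 1.5 (they are asymptotically equal; the
        3-subject toy is degenerate under deletion, hence n=30)."""
        X, time, event, weights = random_instance(3, n=30)
        weights = np.ones(30)
        fit = fit_weighted_cox(X, time, event, weights, tol=1e-13)
        betas = []
        for i in range(30):
            keep = np.ones(30, bool)
            keep[i] = False
            betas.append(
                fit_weighted_cox(X[keep], time[keep], event[keep], weights[keep],
                                 tol=1e-13).coef[0]
            )
        betas = np.array(betas)
        jk = (30 - 1) / 30 * np.sum((betas - betas.mean()) ** 2)
        ratio = jk / fit.robust_cov[0, 0]
        assert 1 / 1.5 < ratio < 1.5

    def test_information_identity_under_correct_model(self):
        """Unit weights, correctly specified model, large n: robust and
        model-based SEs agree (sandwich collapses to inverse information)."""
        rng = np.random.default_rng(4)
        n = 4000
        X = rng.normal(size=(n, 1))
        time = rng.exponential(size=n) * np.exp(-0.5 * X[:, 0])
        event = np.ones(n)
        fit = fit_weighted_cox(X, time, event, np.ones(n))
        assert fit.robust_se[0] / fit.se[0] == pytest.approx(1.0, abs=0.05)


def test_fit_result_serialization(tmp_path):
    from stratcox.cox import write_fit

    fit = fit_weighted_cox(**TOY, names=("exposure",))
    frame = fit.to_frame()
    assert list(frame.columns) == ["coefficient", "loghr", "hr", "se", "robust_se"]
    write_fit(fit, csv_path=tmp_path / "f.csv", json_path=tmp_path / "f.json")
    back = pd.read_csv(tmp_path / "f.csv")
    assert back.loc[0, "coefficient"] == "exposure"
    assert back.loc[0, "loghr"] == pytest.approx(fit.coef[0])
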