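"""Path-analysis engine: specification, ML fitting, enumeration, trimming, bootstrap."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from florsel import sem
from florsel.sem import (
    bootstrap_inference,
    build_model,
    compare_nested,
    enumerate_near_saturated,
    fit_ml,
    implied_covariance,
    indirect_effects,
    information_criteria,
    rank_candidates,
    standardized_solution,
    trim_model,
)

VARS6 = list("ABCDEF")
SAT_EDGES = [(VARS6[i], VARS6[j]) for i in range(6) for j in range(i + 1, 6)]


class TestBuildModel:
    def test_saturated_six_variable_model(self):
        spec = build_model(VARS6, ["A"], SAT_EDGES)
        assert spec.n_free_parameters == 21
        assert spec.df == 0
        assert spec.p * (spec.p + 1) // 2 == 21

    def test_removing_two_edges_gives_df_two(self):
        spec = build_model(VARS6, ["A"], SAT_EDGES[:-2])
        assert spec.df == 2

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            build_model(["A", "B"], [], [("A", "B"), ("B", "A")])

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_model(["A", "B"], ["A"], [("A", "Z")])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_model(["A", "B"], ["A"], [("A", "B"), ("A", "B")])

    def test_exogenous_cannot_have_parents(self):
        with pytest.raises(ValueError, match="exogenous"):
            build_model(["A", "B"], ["A"], [("B", "A")])

    def test_json_round_trip(self):
        spec = build_model(list("XYZ"), ["X"], [("X", "Y")], [("Y", "Z")])
        back = sem.PathModelSpec.from_json(spec.to_json())
        assert back == spec


class TestImpliedCovariance:
    def test_edgeless_model_returns_psi(self):
        spec = build_model(list("AB"), [], [])
        sigma = implied_covariance(spec, {("var", "A"): 2.0, ("var", "B"): 3.0})
        np.testing.assert_allclose(sigma, np.diag([2.0, 3.0]))

    def test_chain_cross_covariance_is_product(self):
        spec = build_model(list("XMY"), ["X"], [("X", "M"), ("M", "Y")])
        params = {("X", "M"): 0.7, ("M", "Y"): 0.5,
                  ("var", "X"): 1.0, ("var", "M"): 1.0, ("var", "Y"): 1.0}
        sigma = implied_covariance(spec, params)
        assert sigma[0, 2] == pytest.approx(0.7 * 0.5)

    def test_matches_large_simulation(self):
        """Sigma(theta) agrees with the empirical covariance of 10^6 draws from the
        generating equations."""
        rng = np.random.default_rng(3)
        spec = build_model(list("ABCDE"), ["A"],
                           [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D"), ("D", "E")])
        params = {("A", "B"): 0.8, ("A", "C"): -0.5, ("B", "D"): 0.6,
                  ("C", "D"): 0.3, ("D", "E"): -0.7}
        params.update({("var", v): s for v, s in
                       zip("ABCDE", (1.0, 0.5, 1.5, 0.8, 1.2))})
        sigma = implied_covariance(spec, params)
        n = 1_000_000
        A = rng.normal(0, 1.0, n)
        B = 0.8 * A + rng.normal(0, np.sqrt(0.5), n)
        C = -0.5 * A + rng.normal(0, np.sqrt(1.5), n)
        D = 0.6 * B + 0.3 * C + rng.normal(0, np.sqrt(0.8), n)
        E = -0.7 * D + rng.normal(0, np.sqrt(1.2), n)
        emp = np.cov(np.vstack([A, B, C, D, E]))
        # Monte-Carlo SE of a covariance entry is O(1/sqrt(n)) ~ 3e-3 at this scale
        np.testing.assert_allclose(sigma, emp, atol=0.012)

    def test_path_tracing_identity(self):
        """Implied covariances equal the trek sums A Psi A^T with A accumulated from
        directed-path coefficient products (independent graph-walk oracle)."""
        spec = build_model(list("ABCDE"), ["A"],
                           [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("B", "E")])
        rng = np.random.default_rng(8)
        params = {e: float(rng.normal()) for e in spec.edges}
        params.update({("var", v): float(rng.uniform(0.5, 2)) for v in spec.variables})
        sigma = implied_covariance(spec, params)
        g = nx.DiGraph(spec.edges)
        g.add_nodes_from(spec.variables)
        idx = {v: i for i, v in enumerate(spec.variables)}
        A = np.eye(5)
        for s in spec.variables:
            for t in spec.variables:
                if s == t:
                    continue
                total = 0.0
                if nx.has_path(g, s, t):
                    for path in nx.all_simple_paths(g, s, t):
                        prod = 1.0
                        for c, e in zip(path, path[1:]):
                            prod *= params[(c, e)]
                        total += prod
                A[idx[t], idx[s]] = total
        psi = np.diag([params[("var", v)] for v in spec.variables])
        np.testing.assert_allclose(sigma, A @ psi @ A.T, atol=1e-12)


class TestFitML:
    def test_saturated_model_reproduces_sample_covariance(self, rng):
        data = pd.DataFrame(rng.normal(size=(150, 6)), columns=VARS6)
        fit = fit_ml(build_model(VARS6, ["A"], SAT_EDGES), data)
        assert fit.chi2_ == pytest.approx(0.0, abs=1e-8)
        assert fit.df_ == 0
        np.testing.assert_allclose(fit.implied_cov_, fit.sample_cov_, atol=1e-8)

    def test_ml_equals_per_equation_ols(self, chain_data):
        """For a recursive model without residual covariances the numeric ML optimum
        coincides with per-equation OLS."""
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M"), ("M", "Y")])
        fit = fit_ml(spec, chain_data, solver="numeric")
        d = chain_data
        b_xm = np.cov(d.X, d.M)[0, 1] / np.var(d.X, ddof=1)
        b_my = np.cov(d.M, d.Y)[0, 1] / np.var(d.M, ddof=1)
        assert fit.coefficients_[("X", "M")] == pytest.approx(b_xm, abs=1e-6)
        assert fit.coefficients_[("M", "Y")] == pytest.approx(b_my, abs=1e-6)

    def test_covariance_input_equals_raw_data(self, chain_data):
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M")])
        f_raw = fit_ml(spec, chain_data)
        f_cov = fit_ml(spec, (chain_data.cov(ddof=1), len(chain_data)))
        assert f_cov.chi2_ == pytest.approx(f_raw.chi2_, abs=1e-8)
        for e in spec.edges:
            assert f_cov.coefficients_[e] == pytest.approx(f_raw.coefficients_[e],
                                                           abs=1e-8)

    def test_residual_covariance_model_converges(self, rng):
        n = 500
        X = rng.normal(size=n)
        common = rng.normal(size=n)
        M = 0.5 * X + common + rng.normal(size=n)
        Y = 0.3 * X + common + rng.normal(size=n)
        data = pd.DataFrame({"X": X, "M": M, "Y": Y})
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M"), ("X", "Y")],
                           [("M", "Y")])
        fit = fit_ml(spec, data)
        assert fit.converged_
        assert fit.df_ == 0
        assert fit.chi2_ == pytest.approx(0.0, abs=1e-6)
        assert fit.psi_.loc["M", "Y"] > 0.5  # recovers the induced residual covariance

    def test_nonconvergent_sample_covariance_rejected(self):
        bad = pd.DataFrame(np.ones((10, 3)), columns=list("XYZ"))
        spec = build_model(list("XYZ"), ["X"], [("X", "Y")])
        with pytest.raises(ValueError):
            fit_ml(spec, bad)

    def test_standardized_single_edge_equals_correlation(self, chain_data):
        spec = build_model(["X", "M"], ["X"], [("X", "M")])
        fit = fit_ml(spec, chain_data[["X", "M"]])
        r = np.corrcoef(chain_data.X, chain_data.M)[0, 1]
        assert standardized_solution(fit)[("X", "M")] == pytest.approx(r, abs=1e-9)

    def test_standardized_invariant_to_rescaling(self, chain_data):
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M"), ("M", "Y")])
        base = fit_ml(spec, chain_data)
        scaled = chain_data.copy()
        scaled["M"] = scaled["M"] * 1000
        refit = fit_ml(spec, scaled)
        for e in spec.edges:
            assert refit.standardized_[e] == pytest.approx(base.standardized_[e],
                                                           abs=1e-8)

    def test_r2_in_unit_interval(self, barra_table):
        from florsel.synthetic import SEM_VARIABLES

        edges = [("corolla_color", "flowers_total"),
                 ("flowers_total", "seeds_per_plant")]
        spec = build_model(SEM_VARIABLES, ["corolla_color"], edges)
        fit = fit_ml(spec, barra_table)
        assert all(0 <= v <= 1 for v in fit.r2_.values())


class TestInformationCriteria:
    def test_saturated_aic_is_twice_parameter_count(self, rng):
        data = pd.DataFrame(rng.normal(size=(100, 6)), columns=VARS6)
        fit = fit_ml(build_model(VARS6, ["A"], SAT_EDGES), data)
        aic, bic = information_criteria(fit)
        assert aic == pytest.approx(42.0, abs=1e-6)
        assert bic == pytest.approx(21 * np.log(100), abs=1e-6)

    def test_nested_aic_difference_identity(self, chain_data):
        full = fit_ml(build_model(["X", "M", "Y"], ["X"],
                                  [("X", "M"), ("M", "Y"), ("X", "Y")]), chain_data)
        restr = fit_ml(build_model(["X", "M", "Y"], ["X"],
                                   [("X", "M"), ("M", "Y")]), chain_data)
        d_chi2, d_t = restr.chi2_ - full.chi2_, -1
        assert restr.aic_ - full.aic_ == pytest.approx(d_chi2 + 2 * d_t, abs=1e-9)


class TestEnumeration:
    def test_df_zero_gives_single_class(self):
        cands = enumerate_near_saturated(list("WXYZ"), ["W"], df_set={0})
        assert len(cands) == 1
        assert cands[0].spec.df == 0

    def test_all_returned_models_have_requested_df(self):
        cands = enumerate_near_saturated(list("ABCD"), ["A"], df_set={1, 2})
        assert {c.spec.df for c in cands} == {1, 2}
        for c in cands:
            rebuilt = build_model(c.spec.variables, c.spec.exogenous, c.spec.edges)
            assert rebuilt.df == c.spec.df

    def test_three_variable_classes_match_mutual_fit_oracle(self):
        """Deduplicated class count equals the count obtained by exhaustively testing
        covariance equivalence: two specs are equivalent iff each fits the other's
        implied covariance perfectly for random parameter draws."""
        cands = enumerate_near_saturated(list("XAB"), ["X"], df_set={1})
        rng = np.random.default_rng(0)

        def rand_sigma(spec):
            params = {e: float(rng.uniform(0.3, 1.0)) for e in spec.edges}
            params.update({("var", v): float(rng.uniform(0.5, 1.5))
                           for v in spec.variables})
            return pd.DataFrame(implied_covariance(spec, params),
                                index=spec.variables, columns=spec.variables)

        # raw (pre-dedup) enumeration of all orderings x single-edge removals
        raw = []
        for perm in itertools.permutations(["A", "B"]):
            order = ("X",) + perm
            edges = [(order[i], order[j]) for i in range(3) for j in range(i + 1, 3)]
            for drop in edges:
                raw.append(build_model(list("XAB"), ["X"],
                                       [e for e in edges if e != drop]))

        def equivalent(s1, s2):
            for _ in range(3):
                for a, b in ((s1, s2), (s2, s1)):
                    f = fit_ml(b, (rand_sigma(a), 500))
                    if f.chi2_ > 1e-6:
                        return False
            return True

        classes = []
        for spec in raw:
            if not any(equivalent(spec, rep) for rep in classes):
                classes.append(spec)
        assert len(cands) == len(classes) == 5

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError):
            enumerate_near_saturated([f"v{i}" for i in range(9)], ["v0"])


class TestRankCandidates:
    def test_matches_fit_ml_chi2(self, barra_table):
        from florsel.synthetic import SEM_VARIABLES

        cands = enumerate_near_saturated(SEM_VARIABLES, [SEM_VARIABLES[0]],
                                         df_set={1, 2})
        data = barra_table[list(SEM_VARIABLES)].astype(float)
        S, n = data.cov(ddof=1), len(data)
        ranking = rank_candidates(cands, S, n).set_index("model")
        rng = np.random.default_rng(1)
        for i in rng.choice(len(cands), 12, replace=False):
            f = fit_ml(cands[int(i)].spec, (S, n))
            assert ranking.loc[int(i), "chi2"] == pytest.approx(f.chi2_, abs=1e-7)
            assert ranking.loc[int(i), "aic"] == pytest.approx(f.aic_, abs=1e-7)


class TestCompareNestedAndTrim:
    def test_self_comparison_is_null(self, chain_data):
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M"), ("M", "Y")])
        fit = fit_ml(spec, chain_data)
        d, ddf, p = compare_nested(fit, fit)
        assert d == 0.0 and ddf == 0 and p == 1.0

    def test_non_nested_rejected(self, chain_data):
        f1 = fit_ml(build_model(["X", "M", "Y"], ["X"], [("X", "M")]), chain_data)
        f2 = fit_ml(build_model(["X", "M", "Y"], ["X"], [("M", "Y")]), chain_data)
        with pytest.raises(ValueError, match="nested"):
            compare_nested(f1, f2)

    def test_chi2_monotone_under_nesting(self, rng):
        data = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("ABCD"))
        data["B"] += 0.5 * data["A"]
        data["C"] += 0.4 * data["B"]
        edges = [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("A", "D")]
        full = fit_ml(build_model(list("ABCD"), ["A"], edges), data)
        for k in (1, 2, 3):
            restr = fit_ml(build_model(list("ABCD"), ["A"], edges[:-k]), data)
            d, ddf, _ = compare_nested(full, restr)
            assert d >= 0 and ddf == k

    def test_removing_strong_edge_is_rejected(self, chain_data):
        full = fit_ml(build_model(["X", "M", "Y"], ["X"],
                                  [("X", "M"), ("M", "Y")]), chain_data)
        restr = fit_ml(build_model(["X", "M", "Y"], ["X"], [("X", "M")]), chain_data)
        d, _, p = compare_nested(full, restr)
        assert d > 10 and p < 0.001

    def test_trim_keeps_all_significant_paths(self, chain_data):
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M"), ("M", "Y")])
        final, table = trim_model(chain_data, spec)
        assert set(final.edges) == set(spec.edges)
        assert table["df"].is_monotonic_increasing

    def test_trim_drops_planted_zero_edge(self, chain_data):
        spec = build_model(["X", "M", "Y"], ["X"],
                           [("X", "M"), ("M", "Y"), ("X", "Y")])  # X->Y truly zero
        final, table = trim_model(chain_data, spec)
        assert ("X", "Y") not in final.edges
        assert ("X", "M") in final.edges and ("M", "Y") in final.edges
        assert table["df"].is_monotonic_increasing

    def test_trim_requires_removable_paths(self, chain_data):
        spec = build_model(["X", "M", "Y"], ["X"], [])
        with pytest.raises(ValueError, match="removable"):
            trim_model(chain_data, spec)


class TestBootstrap:
    def test_deterministic_given_seed(self, chain_data):
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M"), ("M", "Y")])
        b1 = bootstrap_inference(spec, chain_data.head(300), B=120, seed=5)
        b2 = bootstrap_inference(spec, chain_data.head(300), B=120, seed=5)
        pd.testing.assert_series_equal(b1.se, b2.se)

    def test_small_B_rejected(self, chain_data):
        spec = build_model(["X", "M"], ["X"], [("X", "M")])
        with pytest.raises(ValueError, match="B"):
            bootstrap_inference(spec, chain_data, B=10, seed=0)

    def test_single_equation_se_close_to_classical_ols(self, rng):
        """Bootstrap SE of a simple-regression path within 15% of the classical SE."""
        import statsmodels.api as smapi

        n = 1000
        X = rng.normal(size=n)
        Y = 0.5 * X + rng.normal(size=n)
        data = pd.DataFrame({"X": X, "Y": Y})
        spec = build_model(["X", "Y"], ["X"], [("X", "Y")])
        boot = bootstrap_inference(spec, data, B=1000, seed=3)
        ols = smapi.OLS(Y, smapi.add_constant(X)).fit()
        assert boot.se["X->Y"] == pytest.approx(ols.bse[1], rel=0.15)


class TestIndirectEffects:
    def test_chain_product(self, chain_data):
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M"), ("M", "Y")])
        fit = fit_ml(spec, chain_data)
        eff = indirect_effects(fit, "X", "Y")
        expect = fit.coefficients_[("X", "M")] * fit.coefficients_[("M", "Y")]
        assert eff.total_indirect == pytest.approx(expect, abs=1e-12)
        assert eff.direct == 0.0
        assert eff.total == pytest.approx(expect)

    def test_hand_computed_product(self):
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M"), ("M", "Y")])
        fake = sem.PathModel(spec=spec)
        fake.spec = spec
        fake.coefficients_ = {("X", "M"): 0.5, ("M", "Y"): 0.4}
        eff = indirect_effects(fake, "X", "Y")
        assert eff.total_indirect == pytest.approx(0.20)

    def test_zero_coefficient_kills_path(self, chain_data):
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M"), ("M", "Y")])
        fake = sem.PathModel(spec=spec)
        fake.coefficients_ = {("X", "M"): 0.0, ("M", "Y"): 0.9}
        eff = indirect_effects(fake, "X", "Y")
        assert eff.total_indirect == 0.0

    def test_total_effect_equals_marginal_regression_in_chain(self, chain_data):
        """Path-tracing identity: the total X -> Y effect equals the implied
        cov(X, Y) / var(X) exactly, and the in-sample marginal slope approximately."""
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M"), ("M", "Y")])
        fit = fit_ml(spec, chain_data)
        eff = indirect_effects(fit, "X", "Y")
        implied_slope = (fit.implied_cov_.loc["X", "Y"]
                         / fit.implied_cov_.loc["X", "X"])
        assert eff.total == pytest.approx(implied_slope, abs=1e-9)
        marginal = fit_ml(build_model(["X", "Y"], ["X"], [("X", "Y")]),
                          chain_data[["X", "Y"]])
        assert eff.total == pytest.approx(marginal.coefficients_[("X", "Y")],
                                          rel=0.15)

    def test_no_path_warns_and_returns_zero(self, chain_data):
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M")])
        fit = fit_ml(spec, chain_data)
        with pytest.warns(UserWarning, match="no directed path"):
            eff = indirect_effects(fit, "M", "Y")
        assert eff.total == 0.0

    def test_bootstrap_z_for_indirect_effect(self, chain_data):
        spec = build_model(["X", "M", "Y"], ["X"], [("X", "M"), ("M", "Y")])
        fit = fit_ml(spec, chain_data)
        boot = bootstrap_inference(spec, chain_data, B=150, seed=2)
        eff = indirect_effects(fit, "X", "Y", boot=boot)
        assert eff.se is not None and eff.se > 0
        assert eff.z == pytest.approx(eff.total_indirect / eff.se)
        assert eff.p < 0.001  # both chain links are strong at n = 2000
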