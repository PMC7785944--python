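"""Linear recursive path analysis: specification, ML covariance fitting, model
enumeration and selection, trimming, bootstrap inference and indirect effects.

A path model over p observed variables consists of a DAG of directed effects (matrix
B), free residual/exogenous variances and optional residual covariances (matrix Psi).
The model-implied covariance is

    Sigma(theta) = (I - B)^-1  Psi  (I - B)^-T

and parameters are estimated by minimizing the normal-theory discrepancy

    F_ML(theta) = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p

against the unbiased sample covariance S.  The chi-square statistic is
T = (N - 1) F_ML at the optimum (the classic covariance-structure convention), with
df = p(p+1)/2 - t free parameters.  Information criteria are reported on the
chi-square-plus-penalty scale, AIC = T + 2t and BIC = T + t ln N, which rank models
identically to their likelihood-based forms on fixed data.

Only the covariance structure is modeled (means are saturated and ignored); the
systems are recursive (no cycles) and fully observed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "PathModelSpec",
    "PathModel",
    "CandidateModel",
    "BootstrapInference",
    "IndirectEffects",
    "build_model",
    "implied_covariance",
    "fit_ml",
    "standardized_solution",
    "bootstrap_inference",
    "indirect_effects",
    "information_criteria",
    "enumerate_near_saturated",
    "rank_candidates",
    "compare_nested",
    "trim_model",
]


# -------------------------------------------------------------------------------------
# model specification
# -------------------------------------------------------------------------------------

@dataclass(frozen=True)
class PathModelSpec:
    """A recursive path model: DAG edges plus free residual covariances.

    ``variables`` fixes the row/column order of all matrices; ``exogenous`` variables
    receive free variances (and pairwise covariances when there are several) and may
    not have parents.  ``residual_covariances`` are unordered pairs of endogenous
    variables whose residuals covary freely (rendering an unresolved, non-causal
    association).
    """

    variables: tuple
    exogenous: tuple
    edges: tuple
    residual_covariances: tuple = ()

    @property
    def p(self):
        return len(self.variables)

    @property
    def endogenous(self):
        return tuple(v for v in self.variables if v not in self.exogenous)

    @property
    def n_free_parameters(self):
        n_exog_cov = len(self.exogenous) * (len(self.exogenous) - 1) // 2
        return (len(self.edges) + len(self.residual_covariances) + self.p + n_exog_cov)

    @property
    def df(self):
        return self.p * (self.p + 1) // 2 - self.n_free_parameters

    def graph(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    def parents(self, var):
        return tuple(c for c, e in self.edges if e == var)

    def drop_edge(self, edge):
        if edge not in self.edges:
            raise ValueError(f"edge {edge} not in model")
        return build_model(
            self.variables,
            self.exogenous,
            tuple(e for e in self.edges if e != edge),
            self.residual_covariances,
        )

    def to_json(self):
        import json

        return json.dumps(
            {
                "variables": list(self.variables),
                "exogenous": list(self.exogenous),
                "edges": [list(e) for e in self.edges],
                "residual_covariances": [list(e) for e in self.residual_covariances],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text):
        import json

        d = json.loads(text)
        return build_model(
            d["variables"], d["exogenous"],
            [tuple(e) for e in d["edges"]],
            [tuple(e) for e in d.get("residual_covariances", [])],
        )


def build_model(variables, exogenous, edges, residual_covariances=()):
    """Validate and construct a :class:`PathModelSpec`.

    Checks unique names, known variables, acyclicity, exogeneity (no incoming edges
    on exogenous variables), duplicate edges, and non-negative degrees of freedom.
    """
    variables = tuple(variables)
    if len(set(variables)) != len(variables):
        raise ValueError("variable names must be unique")
    known = set(variables)
    exogenous = tuple(v for v in variables if v in set(exogenous))
    if set(exogenous) - known:
        raise ValueError(f"unknown exogenous variables: {set(exogenous) - known}")
    edges = tuple((str(c), str(e)) for c, e in edges)
    for c, e in edges:
        if c not in known or e not in known:
            raise ValueError(f"edge ({c}, {e}) references unknown variables")
        if e in exogenous:
            raise ValueError(f"exogenous variable {e!r} cannot have parents")
        if c == e:
            raise ValueError(f"self-loop on {c!r}")
    if len(set(edges)) != len(edges):
        raise ValueError("duplicate edges")
    rescov = tuple(tuple(sorted(pair)) for pair in residual_covariances)
    if len(set(rescov)) != len(rescov):
        raise ValueError("duplicate residual covariances")
    for a, b in rescov:
        if a not in known or b not in known:
            raise ValueError(f"residual covariance ({a}, {b}) references unknown variables")
        if a == b:
            raise ValueError("residual covariance must link two distinct variables")
        if a in exogenous and b in exogenous:
            raise ValueError("exogenous covariances are implicit; do not list them")
    g = nx.DiGraph()
    g.add_nodes_from(variables)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"directed edges contain a cycle: {cycle}")
    spec = PathModelSpec(variables=variables, exogenous=exogenous, edges=edges,
                         residual_covariances=rescov)
    if spec.df < 0:
        raise ValueError(f"negative degrees of freedom ({spec.df}): too many parameters")
    return spec


# -------------------------------------------------------------------------------------
# implied covariance
# -------------------------------------------------------------------------------------

def _matrices(spec, beta_vals, psi_diag, psi_off):
    p = spec.p
    idx = {v: i for i, v in enumerate(spec.variables)}
    B = np.zeros((p, p))
    for (c, e), val in beta_vals.items():
        B[idx[e], idx[c]] = val
    Psi = np.diag([psi_diag[v] for v in spec.variables])
    for (a, b), val in psi_off.items():
        Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = val
    return B, Psi


def implied_covariance(spec, params):
    """Model-implied covariance Sigma = (I-B)^-1 Psi (I-B)^-T.

    ``params`` maps edges to path coefficients, variables to residual/exogenous
    variances (key ``("var", name)``), and pairs to covariances (key
    ``("cov", a, b)``).  (I - B) is invertible for any DAG.
    """
    beta = {k: v for k, v in params.items()
            if isinstance(k, tuple) and len(k) == 2 and k[0] != "var"}
    psi_diag = {k[1]: v for k, v in params.items()
                if isinstance(k, tuple) and k[0] == "var"}
    psi_off = {(k[1], k[2]): v for k, v in params.items()
               if isinstance(k, tuple) and k[0] == "cov"}
    missing = [v for v in spec.variables if v not in psi_diag]
    if missing:
        raise ValueError(f"missing variances for {missing}")
    B, Psi = _matrices(spec, beta, psi_diag, psi_off)
    A = np.linalg.inv(np.eye(spec.p) - B)
    sigma = A @ Psi @ A.T
    return (sigma + sigma.T) / 2.0


# -------------------------------------------------------------------------------------
# maximum-likelihood fitting
# -------------------------------------------------------------------------------------

class _ParamIndex:
    """Maps the free-parameter vector to (B, Psi); variances live on the log scale."""

    def __init__(self, spec):
        self.spec = spec
        self.edges = list(spec.edges)
        exog = list(spec.exogenous)
        self.cov_pairs = [tuple(sorted(p)) for p in spec.residual_covariances]
        self.cov_pairs += [tuple(sorted(p)) for p in itertools.combinations(exog, 2)]
        self.n_edges = len(self.edges)
        self.n_vars = spec.p
        self.size = self.n_edges + self.n_vars + len(self.cov_pairs)
        self.idx = {v: i for i, v in enumerate(spec.variables)}

    def unpack(self, theta):
        p = self.n_vars
        B = np.zeros((p, p))
        for k, (c, e) in enumerate(self.edges):
            B[self.idx[e], self.idx[c]] = theta[k]
        Psi = np.diag(np.exp(theta[self.n_edges:self.n_edges + p]))
        for k, (a, b) in enumerate(self.cov_pairs):
            v = theta[self.n_edges + p + k]
            Psi[self.idx[a], self.idx[b]] = Psi[self.idx[b], self.idx[a]] = v
        return B, Psi

    def pack(self, B, Psi):
        theta = np.empty(self.size)
        for k, (c, e) in enumerate(self.edges):
            theta[k] = B[self.idx[e], self.idx[c]]
        theta[self.n_edges:self.n_edges + self.n_vars] = np.log(
            np.maximum(np.diag(Psi), 1e-10)
        )
        for k, (a, b) in enumerate(self.cov_pairs):
            theta[self.n_edges + self.n_vars + k] = Psi[self.idx[a], self.idx[b]]
        return theta


def _ols_start(spec, S_df):
    """Per-equation OLS warm start computed from the sample covariance."""
    p = spec.p
    idx = {v: i for i, v in enumerate(spec.variables)}
    S = S_df.to_numpy()
    B = np.zeros((p, p))
    Psi = np.zeros((p, p))
    for v in spec.variables:
        pa = spec.parents(v)
        if not pa:
            Psi[idx[v], idx[v]] = S[idx[v], idx[v]]
            continue
        ii = [idx[c] for c in pa]
        b = np.linalg.solve(S[np.ix_(ii, ii)], S[ii, idx[v]])
        for c, bc in zip(pa, b):
            B[idx[v], idx[c]] = bc
        resid = S[idx[v], idx[v]] - b @ S[ii, idx[v]]
        Psi[idx[v], idx[v]] = max(resid, 1e-8)
    for a, b_ in itertools.combinations(spec.exogenous, 2):
        Psi[idx[a], idx[b_]] = Psi[idx[b_], idx[a]] = S[idx[a], idx[b_]]
    return B, Psi


def _fml_and_grad(theta, index, S, logdet_S):
    p = S.shape[0]
    B, Psi = index.unpack(theta)
    A = np.linalg.inv(np.eye(p) - B)
    sigma = A @ Psi @ A.T
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10 + float(np.sum(theta**2)), np.zeros_like(theta)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    sigma_inv = np.linalg.inv(sigma)
    F = logdet - logdet_S + float(np.trace(S @ sigma_inv)) - p
    # gradient: dF = tr[(Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma]
    G = sigma_inv - sigma_inv @ S @ sigma_inv
    grad = np.empty_like(theta)
    SGA = sigma @ G @ A  # for edge derivatives
    AGA = A.T @ G @ A  # for Psi derivatives
    for k, (c, e) in enumerate(index.edges):
        grad[k] = 2.0 * SGA[index.idx[c], index.idx[e]]
    dpsi = np.diag(AGA)
    for k in range(index.n_vars):
        # chain rule through the log-variance parameterization
        grad[index.n_edges + k] = dpsi[k] * Psi[k, k]
    for k, (a, b) in enumerate(index.cov_pairs):
        grad[index.n_edges + index.n_vars + k] = 2.0 * AGA[index.idx[a], index.idx[b]]
    return F, grad


class PathModel(BaseEstimator):
    """Recursive linear path model fitted by maximum likelihood on covariances.

    Parameters
    ----------
    spec : PathModelSpec
        The model structure (see :func:`build_model`).
    rescale : dict or None
        Optional column -> factor map applied to the data before fitting (e.g. total
        seed production divided by 1,000 to tame its variance).  Standardized
        coefficients are invariant to it.
    gtol, ftol, maxiter : optimizer controls.

    Attributes (after :meth:`fit`)
    ------------------------------
    coefficients_ : dict edge -> unstandardized path coefficient
    standardized_ : dict edge -> standardized coefficient (model-implied SDs)
    psi_ : DataFrame of residual/exogenous (co)variances
    implied_cov_ : DataFrame, model-implied covariance
    chi2_, df_, pvalue_, loglik_, aic_, bic_ : fit statistics
    r2_ : dict endogenous variable -> proportion of variance explained
    nobs_, converged_, n_iter_ : bookkeeping
    """

    def __init__(self, spec=None, rescale=None, gtol=1e-8, ftol=1e-12, maxiter=500,
                 solver="numeric"):
        self.spec = spec
        self.rescale = rescale
        self.gtol = gtol
        self.ftol = ftol
        self.maxiter = maxiter
        self.solver = solver

    # -- data handling ---------------------------------------------------------------
    def _sample_cov(self, X):
        spec = self.spec
        if isinstance(X, tuple):
            S_df, nobs = X
            S_df = pd.DataFrame(S_df, index=spec.variables, columns=spec.variables) \
                if not isinstance(S_df, pd.DataFrame) else S_df.loc[
                    list(spec.variables), list(spec.variables)]
            return S_df.astype(float), int(nobs)
        X = pd.DataFrame(X)
        data = X[list(spec.variables)].dropna()
        if self.rescale:
            data = data.copy()
            for col, factor in self.rescale.items():
                if col in data:
                    data[col] = data[col] * factor
        nobs = len(data)
        if nobs <= spec.p + 2:
            raise ValueError(f"need more than p + 2 = {spec.p + 2} complete cases, "
                             f"got {nobs}")
        S = data.cov(ddof=1)
        return S, nobs

    def fit(self, X, y=None):
        spec = self.spec
        if spec is None:
            raise ValueError("a PathModelSpec is required")
        S_df, nobs = self._sample_cov(X)
        S = S_df.to_numpy()
        sign, logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("sample covariance is not positive definite")
        index = _ParamIndex(spec)
        B0, Psi0 = _ols_start(spec, S_df)
        theta0 = index.pack(B0, Psi0)
        # for a recursive model without residual covariances the likelihood factorizes
        # over equations, so the per-equation OLS solution is the exact ML optimum
        closed_exact = not spec.residual_covariances
        if self.solver == "closed" and not closed_exact:
            raise ValueError("closed-form solver requires a model without "
                             "residual covariances")
        use_closed = (self.solver == "closed"
                      or (self.solver == "auto" and closed_exact))
        if use_closed:
            F_opt, _ = _fml_and_grad(theta0, index, S, logdet_S)
            self.converged_ = True
            self.n_iter_ = 0
            B, Psi = B0, Psi0
        else:
            res = optimize.minimize(
                _fml_and_grad, theta0, args=(index, S, logdet_S), jac=True,
                method="L-BFGS-B",
                options={"gtol": self.gtol, "ftol": self.ftol,
                         "maxiter": self.maxiter},
            )
            F_opt = float(res.fun)
            self.converged_ = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-5
            if not self.converged_:
                warnings.warn(f"path-model optimizer did not converge: {res.message}")
            self.n_iter_ = int(res.nit)
            B, Psi = index.unpack(res.x)
        self.nobs_ = nobs
        self._index = index
        self._B = B
        self._Psi = Psi
        A = np.linalg.inv(np.eye(spec.p) - B)
        sigma = A @ Psi @ A.T
        sigma = (sigma + sigma.T) / 2.0
        self.implied_cov_ = pd.DataFrame(sigma, index=spec.variables,
                                         columns=spec.variables)
        self.sample_cov_ = S_df
        self.coefficients_ = {
            (c, e): float(B[index.idx[e], index.idx[c]]) for c, e in spec.edges
        }
        self.psi_ = pd.DataFrame(Psi, index=spec.variables, columns=spec.variables)
        self.fml_ = max(F_opt, 0.0)
        self.chi2_ = max((nobs - 1) * self.fml_, 0.0)
        self.df_ = spec.df
        self.pvalue_ = float(stats.chi2.sf(self.chi2_, self.df_)) if self.df_ > 0 else 1.0
        # normal-theory log-likelihood of the covariance structure
        self.loglik_ = -0.5 * (nobs - 1) * (
            float(np.linalg.slogdet(sigma)[1])
            + float(np.trace(S @ np.linalg.inv(sigma)))
        ) - 0.5 * (nobs - 1) * spec.p * math.log(2 * math.pi)
        t = spec.n_free_parameters
        self.aic_ = self.chi2_ + 2 * t
        self.bic_ = self.chi2_ + t * math.log(nobs)
        sd = np.sqrt(np.diag(sigma))
        self.standardized_ = {
            (c, e): self.coefficients_[(c, e)] * sd[index.idx[c]] / sd[index.idx[e]]
            for c, e in spec.edges
        }
        self.r2_ = {
            v: 1.0 - Psi[index.idx[v], index.idx[v]] / sigma[index.idx[v], index.idx[v]]
            for v in spec.endogenous
        }
        return self

    def parameters(self):
        """Flat name -> estimate mapping (edges, variances, covariances)."""
        out = {f"{c}->{e}": v for (c, e), v in self.coefficients_.items()}
        for v in self.spec.variables:
            out[f"var({v})"] = float(self.psi_.loc[v, v])
        for a, b in self._index.cov_pairs:
            out[f"cov({a},{b})"] = float(self.psi_.loc[a, b])
        return out


def fit_ml(spec, data, rescale=None, **kwargs):
    """Fit ``spec`` to a plant table (DataFrame) or to ``(covariance, nobs)``."""
    return PathModel(spec=spec, rescale=rescale, **kwargs).fit(data)


def standardized_solution(fit):
    """Standardized path coefficients: b * sd(cause) / sd(effect), model-implied SDs."""
    sd = np.sqrt(np.diag(fit.implied_cov_.to_numpy()))
    if np.any(sd <= 0):
        raise ValueError("zero implied SD")
    return dict(fit.standardized_)


def information_criteria(fit):
    """(AIC, BIC) on the chi-square + penalty scale."""
    return fit.aic_, fit.bic_


# -------------------------------------------------------------------------------------
# bootstrap inference
# -------------------------------------------------------------------------------------

@dataclass
class BootstrapInference:
    """Case-resampling bootstrap results for every free parameter.

    ``replicates`` holds one row per successful replicate (columns are parameter
    names as in :meth:`PathModel.parameters`, plus ``std:`` -prefixed standardized
    coefficients); SEs are replicate SDs, CIs are percentile, Z = estimate / SE with
    a normal-approximation two-sided p.
    """

    estimates: pd.Series
    replicates: pd.DataFrame
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    z: pd.Series
    p: pd.Series
    B: int
    seed: int | None
    n_failed: int


def bootstrap_inference(spec, data, B=1000, seed=None, rescale=None, ci_level=0.95,
                        solver="auto"):
    """Nonparametric bootstrap (resampling plants with replacement) of a path model.

    Replicates that fail to converge are dropped and counted; more than 5% failures
    raises a warning, more than 50% an error.  Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for reported standard errors")
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(data)[list(spec.variables)].dropna().reset_index(drop=True)
    full = PathModel(spec=spec, rescale=rescale, solver=solver).fit(data)
    est = pd.Series(full.parameters(), dtype=float)
    for (c, e), v in full.standardized_.items():
        est[f"std:{c}->{e}"] = v
    n = len(data)
    rows = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = PathModel(spec=spec, rescale=rescale, solver=solver).fit(data.iloc[idx])
            if not m.converged_:
                n_failed += 1
                continue
            row = m.parameters()
            for (c, e), v in m.standardized_.items():
                row[f"std:{c}->{e}"] = v
            rows.append(row)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > 0.5 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    if n_failed > 0.05 * B:
        warnings.warn(f"{n_failed}/{B} bootstrap replicates failed to converge")
    reps = pd.DataFrame(rows)[est.index]
    se = reps.std(ddof=1)
    alpha = 1.0 - ci_level
    z = est / se.replace(0.0, np.nan)
    return BootstrapInference(
        estimates=est,
        replicates=reps,
        se=se,
        ci_lower=reps.quantile(alpha / 2),
        ci_upper=reps.quantile(1 - alpha / 2),
        z=z,
        p=2.0 * pd.Series(stats.norm.sf(np.abs(z)), index=z.index),
        B=B,
        seed=seed,
        n_failed=n_failed,
    )


# -------------------------------------------------------------------------------------
# indirect effects
# -------------------------------------------------------------------------------------

@dataclass
class IndirectEffects:
    """Decomposition of the source -> target effect into path products."""

    source: str
    target: str
    paths: dict  # path tuple -> product of unstandardized coefficients
    direct: float
    total_indirect: float
    total: float
    se: float | None = None
    z: float | None = None
    p: float | None = None
    ci: tuple | None = None


def _indirect_from_coefs(spec, coefs, source, target):
    g = nx.DiGraph()
    g.add_nodes_from(spec.variables)
    g.add_edges_from(spec.edges)
    paths = {}
    for path in nx.all_simple_paths(g, source, target):
        prod = 1.0
        for c, e in zip(path, path[1:]):
            prod *= coefs[(c, e)]
        paths[tuple(path)] = prod
    direct = coefs.get((source, target), 0.0)
    indirect = sum(v for k, v in paths.items() if len(k) > 2)
    return paths, direct, indirect


def indirect_effects(fit, source, target, boot=None, ci_level=0.95):
    """All directed-path products from ``source`` to ``target``.

    The total indirect effect sums the products over paths of length >= 2 edges; the
    total effect adds the direct edge (0 if absent).  With ``boot`` (a
    :class:`BootstrapInference` for the same spec) a bootstrap SE, normal Z/p and a
    percentile CI for the total indirect effect are attached.
    """
    spec = fit.spec
    if source not in spec.variables or target not in spec.variables:
        raise ValueError("unknown source or target")
    paths, direct, indirect = _indirect_from_coefs(spec, fit.coefficients_, source, target)
    out = IndirectEffects(
        source=source, target=target, paths=paths, direct=direct,
        total_indirect=indirect, total=direct + indirect,
    )
    if not paths:
        warnings.warn(f"no directed path from {source!r} to {target!r}; effect is 0")
    if boot is not None and paths:
        vals = []
        for _, row in boot.replicates.iterrows():
            coefs = {(c, e): row[f"{c}->{e}"] for c, e in spec.edges}
            _, _, ind = _indirect_from_coefs(spec, coefs, source, target)
            vals.append(ind)
        vals = np.asarray(vals)
        out.se = float(vals.std(ddof=1))
        if out.se > 0:
            out.z = out.total_indirect / out.se
            out.p = float(2.0 * stats.norm.sf(abs(out.z)))
        alpha = 1.0 - ci_level
        out.ci = (float(np.quantile(vals, alpha / 2)),
                  float(np.quantile(vals, 1 - alpha / 2)))
    return out


# -------------------------------------------------------------------------------------
# enumeration of near-saturated models
# -------------------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateModel:
    """An enumerated candidate with its provenance and equivalence-class signature."""

    spec: PathModelSpec
    ordering: tuple
    removed_edges: tuple
    signature: tuple = field(compare=False, default=())


def _equivalence_signature(variables, edges):
    """Skeleton + v-structures: the covariance-equivalence class of a DAG model.

    Two DAGs (with all parameters free) imply the same set of covariance matrices iff
    they share the adjacency skeleton and the set of colliders a -> c <- b with a, b
    non-adjacent (Verma–Pearl).
    """
    adj = {frozenset(e) for e in edges}
    parents = {}
    for c, e in edges:
        parents.setdefault(e, set()).add(c)
    colliders = set()
    for c, pa in parents.items():
        for a, b in itertools.combinations(sorted(pa), 2):
            if frozenset((a, b)) not in adj:
                colliders.add((frozenset((a, b)), c))
    return (frozenset(adj), frozenset(colliders))


def enumerate_near_saturated(variables, exogenous, df_set=(1, 2)):
    """Enumerate covariance-distinct near-saturated recursive models.

    For every ordering of the endogenous variables (exogenous first), the saturated
    recursive model (every earlier variable pointing at every later one) is reduced by
    removing ``k`` edges for each ``k`` in ``df_set``, giving models with df = k.
    Covariance-equivalent duplicates (same skeleton and v-structures) are dropped;
    each returned candidate records the generating ordering and removed edges.
    """
    variables = tuple(variables)
    if len(variables) > 8:
        raise ValueError("enumeration limited to 8 variables")
    exogenous = tuple(v for v in variables if v in set(exogenous))
    endo = [v for v in variables if v not in set(exogenous)]
    n_edges_sat = (len(variables) * (len(variables) - 1) // 2
                   - len(exogenous) * (len(exogenous) - 1) // 2)
    for k in df_set:
        if k > n_edges_sat:
            raise ValueError(f"cannot reach df={k} by removing edges "
                             f"(saturated model has {n_edges_sat})")
    seen = {}
    out = []
    for perm in itertools.permutations(endo):
        order = exogenous + perm
        sat_edges = []
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                if a in exogenous and b in exogenous:
                    continue
                sat_edges.append((a, b))
        for k in sorted(df_set):
            if k == 0:
                removals = [()]
            else:
                removals = itertools.combinations(sat_edges, k)
            for removed in removals:
                edges = tuple(e for e in sat_edges if e not in set(removed))
                sig = _equivalence_signature(variables, edges)
                if sig in seen:
                    continue
                spec = build_model(variables, exogenous, edges)
                cand = CandidateModel(spec=spec, ordering=order,
                                      removed_edges=tuple(removed), signature=sig)
                seen[sig] = cand
                out.append(cand)
    return out


def rank_candidates(candidates, S, nobs):
    """Fit every candidate to the sample covariance ``S`` and rank by (AIC, BIC).

    Exploits the likelihood factorization of recursive DAG models: at the per-equation
    OLS optimum tr(S Sigma^-1) = p, so F_ML reduces to sum_v ln(residual variance) plus
    the exogenous-block log-determinant minus ln|S|; residual variances are cached per
    (variable, parent-set), which repeats heavily across candidates.  Agrees with
    :func:`fit_ml` exactly (checked in the test suite).  Returns a DataFrame sorted by
    AIC with one row per candidate.
    """
    S = pd.DataFrame(S)
    variables = list(S.columns)
    idx = {v: i for i, v in enumerate(variables)}
    Sm = S.to_numpy()
    logdet_S = float(np.linalg.slogdet(Sm)[1])
    cache = {}

    def resid_logvar(v, parents):
        key = (v, frozenset(parents))
        if key not in cache:
            if not parents:
                val = math.log(Sm[idx[v], idx[v]])
            else:
                ii = [idx[c] for c in parents]
                b = np.linalg.solve(Sm[np.ix_(ii, ii)], Sm[ii, idx[v]])
                val = math.log(Sm[idx[v], idx[v]] - float(b @ Sm[ii, idx[v]]))
            cache[key] = val
        return cache[key]

    rows = []
    for i, cand in enumerate(candidates):
        spec = cand.spec
        if spec.residual_covariances:
            f = fit_ml(spec, (S, nobs))
            chi2, df, t = f.chi2_, f.df_, spec.n_free_parameters
        else:
            exog = list(spec.exogenous)
            ii = [idx[v] for v in exog]
            logdet_exog = float(np.linalg.slogdet(Sm[np.ix_(ii, ii)])[1]) if exog else 0.0
            F = logdet_exog - logdet_S
            for v in spec.variables:
                if v in spec.exogenous:
                    continue
                F += resid_logvar(v, spec.parents(v))
            chi2 = max((nobs - 1) * F, 0.0)
            df, t = spec.df, spec.n_free_parameters
        rows.append({"model": i, "df": df, "chi2": chi2,
                     "pvalue": float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0,
                     "aic": chi2 + 2 * t, "bic": chi2 + t * math.log(nobs),
                     "removed_edges": ";".join(f"{a}->{b}"
                                               for a, b in cand.removed_edges)})
    return pd.DataFrame(rows).sort_values(["aic", "bic", "model"]).reset_index(drop=True)


# -------------------------------------------------------------------------------------
# nested comparison and trimming
# -------------------------------------------------------------------------------------

def _is_nested(full_spec, restricted_spec):
    return (
        set(full_spec.variables) == set(restricted_spec.variables)
        and set(restricted_spec.edges) <= set(full_spec.edges)
        and set(restricted_spec.residual_covariances)
        <= set(full_spec.residual_covariances)
        and set(restricted_spec.exogenous) == set(full_spec.exogenous)
    )


def compare_nested(full, restricted):
    """Chi-square difference test of a restricted model against a nesting full model.

    Returns ``(delta_chi2, delta_df, p)``.  Nesting is checked structurally: the
    restricted model's free parameters must be a subset of the full model's.
    """
    if not _is_nested(full.spec, restricted.spec):
        raise ValueError("models are not structurally nested")
    d_chi2 = restricted.chi2_ - full.chi2_
    if d_chi2 < -1e-4:
        warnings.warn(f"restricted chi-square below full ({d_chi2:.2e}); "
                      "possible convergence failure")
    d_chi2 = max(d_chi2, 0.0)
    d_df = restricted.df_ - full.df_
    p = float(stats.chi2.sf(d_chi2, d_df)) if d_df > 0 else 1.0
    return d_chi2, d_df, p


def trim_model(data, baseline, alpha=0.05, rescale=None, solver="auto",
               select="bic"):
    """Backward trimming of non-significant paths from a baseline model.

    At each step, every remaining directed edge is tested by a single-edge
    chi-square-difference (likelihood-ratio) test against the current model; among
    the non-significant edges (p >= alpha) the one with the smallest absolute
    standardized coefficient is removed.  Trimming stops when every path is
    significant or when the reduced model is rejected against the baseline at
    ``alpha``.  The final model is chosen among the visited (never-rejected) models
    by information criterion: ``select="bic"`` (default) prefers BIC with AIC as the
    tie-break, which consistently keeps a removed truly-zero path out of the model;
    ``select="aic"`` reverses the order, ``select="last"`` returns the most reduced
    accepted model.  Returns ``(final_spec, comparison_table)``.
    """
    base_fit = fit_ml(baseline, data, rescale=rescale, solver=solver)
    if not baseline.edges:
        raise ValueError("baseline model has no removable path")
    visited = [base_fit]
    table = [
        {
            "step": 0, "removed_edge": None, "df": base_fit.df_,
            "chi2": base_fit.chi2_, "delta_chi2_vs_baseline": 0.0,
            "delta_df_vs_baseline": 0, "p_vs_baseline": 1.0,
            "aic": base_fit.aic_, "bic": base_fit.bic_,
        }
    ]
    current = base_fit
    step = 0
    while current.spec.edges:
        candidates = []
        for edge in current.spec.edges:
            sub = fit_ml(current.spec.drop_edge(edge), data, rescale=rescale,
                         solver=solver)
            _, _, p_edge = compare_nested(current, sub)
            if p_edge >= alpha:
                candidates.append((abs(current.standardized_[edge]), edge, sub))
        if not candidates:
            break
        candidates.sort(key=lambda t: t[0])
        _, edge, reduced = candidates[0]
        d_chi2, d_df, p_base = compare_nested(base_fit, reduced)
        step += 1
        table.append(
            {
                "step": step, "removed_edge": f"{edge[0]}->{edge[1]}",
                "df": reduced.df_, "chi2": reduced.chi2_,
                "delta_chi2_vs_baseline": d_chi2, "delta_df_vs_baseline": d_df,
                "p_vs_baseline": p_base, "aic": reduced.aic_, "bic": reduced.bic_,
            }
        )
        if p_base < alpha:
            break
        visited.append(reduced)
        current = reduced
    if select == "aic":
        best = min(visited, key=lambda m: (m.aic_, m.bic_))
    elif select == "bic":
        best = min(visited, key=lambda m: (m.bic_, m.aic_))
    elif select == "last":
        best = visited[-1]
    else:
        raise ValueError("select must be 'aic', 'bic' or 'last'")
    return best.spec, pd.DataFrame(table)
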