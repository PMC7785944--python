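"""Lande–Arnold phenotypic selection statistics and univariate comparison tests.

Selection is quantified on variance-standardized traits z (zero mean, unit sample SD
within a population) and relative fitness w (absolute fitness divided by the
population mean, so mean(w) = 1):

* opportunity for selection  I  = sample variance of w;
* selection differential     S' = cov(z_j, w)   (total selection on trait j);
* selection gradient         b' = partial regression coefficient of w on z_j in a
  multiple OLS over all traits jointly (direct selection on trait j).

With sample (n-1) denominators throughout, S' equals the univariate OLS slope of w on
the unit-variance z_j, and S' = b' when the in-sample trait correlations vanish.

The module also houses the univariate machinery of the population comparisons: Welch's
t (from raw samples or printed summaries), the Brown–Forsythe/Levene variance test,
the Wilcoxon rank-sum test (exact enumeration for small samples), Pearson correlation
and the coefficient of variation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "SelectionAnalysis",
    "relativize_fitness",
    "standardize_traits",
    "selection_opportunity",
    "selection_differentials",
    "selection_gradients",
    "welch_t",
    "deviation_variance_test",
    "wilcoxon_rank_sum",
    "pearson_corr",
    "cv_percent",
]


# -------------------------------------------------------------------------------------
# trait / fitness transforms
# -------------------------------------------------------------------------------------

def relativize_fitness(values):
    """Relative fitness w = value / mean(value); mean(w) = 1 over non-missing entries."""
    v = pd.Series(values, dtype=float)
    obs = v.dropna()
    if len(obs) < 2:
        raise ValueError("at least two non-missing fitness values required")
    m = obs.mean()
    if m <= 0:
        raise ValueError("mean fitness must be positive (all-zero fitness?)")
    return v / m


def standardize_traits(df, columns=None, by=None):
    """Standardize trait columns to zero mean and unit sample SD (n-1 denominator).

    With ``by`` (e.g. ``"population"``), standardization is done within each group —
    never pooled.  Constant columns raise.
    """
    df = pd.DataFrame(df)
    if columns is None:
        columns = [c for c in df.columns if c != by and
                   pd.api.types.is_numeric_dtype(df[c])]
    out = df.copy()

    def _z(sub):
        for c in columns:
            col = sub[c].astype(float)
            sd = col.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"constant or degenerate trait column {c!r}")
            sub[c] = (col - col.mean()) / sd
        return sub

    if by is None:
        return _z(out)
    parts = [_z(g.copy()) for _, g in out.groupby(by, sort=False)]
    return pd.concat(parts).loc[df.index]


def selection_opportunity(w):
    """Opportunity for selection: sample variance of relative fitness."""
    w = pd.Series(w, dtype=float).dropna()
    if len(w) < 2:
        raise ValueError("at least two values required")
    return float(w.var(ddof=1))


def selection_differentials(z, w):
    """Standardized selection differentials S' = cov(z_j, w), pairwise complete cases.

    The p-value per trait is from the univariate OLS regression of w on z_j
    (two-sided t), matching the simple-regression identity S' = slope for a
    unit-variance predictor.
    """
    z = pd.DataFrame(z)
    w = pd.Series(np.asarray(w, dtype=float), index=z.index)
    rows = {}
    for c in z.columns:
        pair = pd.concat([z[c].astype(float), w], axis=1).dropna()
        if len(pair) < 3:
            rows[c] = (np.nan, np.nan, len(pair))
            continue
        zc, wc = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        s = float(np.cov(zc, wc, ddof=1)[0, 1])
        res = stats.linregress(zc, wc)
        rows[c] = (s, float(res.pvalue), len(pair))
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["differential", "pvalue", "n"])
    out.index.name = "trait"
    if out["n"].max() < 3:
        raise ValueError("no trait has three or more complete cases")
    return out


def selection_gradients(z, w):
    """Standardized selection gradients: multiple OLS of w on all traits jointly.

    Returns per-trait partial regression coefficients with classical SEs and two-sided
    t p-values, over listwise-complete cases.  Raises on rank deficiency, naming the
    offending columns.
    """
    import statsmodels.api as sm

    z = pd.DataFrame(z)
    w = pd.Series(np.asarray(w, dtype=float), index=z.index)
    full = pd.concat([z.astype(float), w.rename("_w")], axis=1).dropna()
    n, k = len(full), z.shape[1]
    if n <= k + 1:
        raise ValueError(f"need more complete cases ({n}) than traits + 1 ({k + 1})")
    X = full[z.columns].to_numpy()
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        bad = [str(z.columns[i]) for i in range(k)
               if np.any(np.abs(np.delete(corr[i], i)) > 1 - 1e-10)]
        raise ValueError(f"rank-deficient trait matrix; offending columns: {bad or 'unknown'}")
    fit = sm.OLS(full["_w"].to_numpy(), sm.add_constant(X)).fit()
    out = pd.DataFrame(
        {
            "gradient": fit.params[1:],
            "se": fit.bse[1:],
            "pvalue": fit.pvalues[1:],
        },
        index=pd.Index(z.columns, name="trait"),
    )
    out["n"] = n
    return out


# -------------------------------------------------------------------------------------
# sklearn-style estimator wrapping the full per-population analysis
# -------------------------------------------------------------------------------------

class SelectionAnalysis(BaseEstimator):
    """Phenotypic selection analysis for one population and one fitness component.

    Parameters
    ----------
    standardize : bool, default True
        Variance-standardize the trait columns before analysis.
    relativize : bool, default True
        Divide fitness by its mean before analysis.

    Attributes (after :meth:`fit`)
    ------------------------------
    opportunity_ : float
        Variance of relative fitness.
    differentials_ : DataFrame with S', p-value and n per trait (pairwise complete).
    gradients_ : DataFrame with b', SE, p-value per trait (listwise complete).
    relative_fitness_, z_ : the transformed inputs actually analyzed.
    """

    def __init__(self, standardize=True, relativize=True):
        self.standardize = standardize
        self.relativize = relativize

    def fit(self, X, y):
        X = pd.DataFrame(X)
        if isinstance(y, pd.Series):
            y = y.reindex(X.index).astype(float)
        else:
            y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        self.relative_fitness_ = relativize_fitness(y) if self.relativize else y
        self.z_ = standardize_traits(X) if self.standardize else X.astype(float)
        self.opportunity_ = selection_opportunity(self.relative_fitness_)
        self.differentials_ = selection_differentials(self.z_, self.relative_fitness_)
        self.gradients_ = selection_gradients(self.z_, self.relative_fitness_)
        self.traits_ = list(X.columns)
        self.n_ = int(len(self.z_))
        return self


# -------------------------------------------------------------------------------------
# univariate comparison statistics
# -------------------------------------------------------------------------------------

@dataclass
class SampleSummary:
    """Summary of one sample: mean, n, and either the SE of the mean or the SD."""

    mean: float
    n: int
    se: float | None = None
    sd: float | None = None

    def standard_error(self):
        if self.se is not None:
            return float(self.se)
        if self.sd is not None:
            return float(self.sd) / math.sqrt(self.n)
        raise ValueError("either se or sd must be given")

    @classmethod
    def from_sample(cls, x):
        x = np.asarray(x, dtype=float)
        x = x[~np.isnan(x)]
        if len(x) < 2:
            raise ValueError("samples need at least two values")
        return cls(mean=float(x.mean()), n=len(x), sd=float(x.std(ddof=1)))


def welch_t(first, second):
    """Welch's unequal-variance t test from raw samples or :class:`SampleSummary` objects.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom and a two-sided
    p-value.  Raw array inputs are summarized first, so both routes agree exactly.
    """
    s1 = first if isinstance(first, SampleSummary) else SampleSummary.from_sample(first)
    s2 = second if isinstance(second, SampleSummary) else SampleSummary.from_sample(second)
    if s1.n < 2 or s2.n < 2:
        raise ValueError("each sample needs n >= 2")
    v1, v2 = s1.standard_error() ** 2, s2.standard_error() ** 2
    pooled = v1 + v2
    if pooled <= 0:
        raise ValueError("zero pooled standard error")
    t = (s1.mean - s2.mean) / math.sqrt(pooled)
    df = pooled**2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def deviation_variance_test(*groups, center="median"):
    """Brown–Forsythe (``center='median'``) or Levene (``center='mean'``) variance test.

    One-way ANOVA F on absolute deviations from the group center; returns
    ``(F, df1, df2, p)``.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    clean = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[~np.isnan(g)]
        if len(g) < 2:
            raise ValueError("each group needs at least two values")
        clean.append(g)
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    F, p = stats.levene(*clean, center=center)
    df1 = len(clean) - 1
    df2 = sum(len(g) for g in clean) - len(clean)
    return float(F), df1, df2, float(p)


def _rank_sum_statistic(x, pooled_ranks, n_x):
    return float(np.sum(pooled_ranks[:n_x]))


def wilcoxon_rank_sum(x, y, exact_limit=12):
    """Wilcoxon rank-sum test; W is the sum of midranks of ``x`` in the pooled sample.

    For combined n <= ``exact_limit`` the two-sided p-value enumerates all
    C(n, n_x) assignments of the pooled values (handling ties exactly); otherwise a
    normal approximation with midrank tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = float(ranks[:nx].sum())
    n = nx + ny
    mean_W = nx * (n + 1) / 2.0
    if n <= exact_limit:
        obs_dev = abs(W - mean_W)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), nx):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mean_W) >= obs_dev - 1e-12:
                count += 1
        p = count / total
    else:
        # tie-corrected variance of the rank sum
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts)
        var_W = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_W <= 0:
            p = 1.0
        else:
            z = (W - mean_W) / math.sqrt(var_W)
            p = 2.0 * stats.norm.sf(abs(z))
    return W, min(p, 1.0)


def pearson_corr(x, y):
    """Pearson correlation with the exact-t p-value; requires >= 3 complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("at least three complete pairs required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cv_percent(mean, sd):
    """Coefficient of variation, percent: 100 * sd / |mean|."""
    if mean == 0:
        raise ValueError("zero mean")
    if sd < 0:
        raise ValueError("negative SD")
    return 100.0 * sd / abs(mean)
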