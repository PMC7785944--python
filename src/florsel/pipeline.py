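"""End-to-end analysis: plant CSV (or simulation preset) to population summaries,
selection-coefficient tables and best-fitting path models.

Stages: fitness derivation -> within-population relativization/standardization ->
selection opportunities (with a Brown–Forsythe comparison across populations) ->
selection differentials and gradients per fitness component -> near-saturated path
model enumeration -> AIC/BIC ranking -> backward trimming -> bootstrap inference ->
indirect effects of corolla color on total female fitness.  Every reported number is
produced by an operation of the other modules; the orchestrator only composes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import fitness as fit_mod
from . import selection as sel
from . import sem
from . import synthetic

__all__ = ["AnalysisConfig", "ReportBundle", "load_table", "summarize_populations",
           "derive_components", "run_analysis", "DEFAULT_TRAITS", "DEFAULT_COMPONENTS"]

DEFAULT_TRAITS = (
    "corolla_color",
    "calyx_color",
    "corolla_area",
    "calyx_length",
    "ovules_per_flower",
    "floral_display",
    "flowers_total",
)

DEFAULT_COMPONENTS = (
    "fruit_set",
    "fruits_total",
    "seed_set",
    "seeds_per_fruit",
    "seeds_per_plant",
    "dispersed_per_flower",
    "dispersed_per_plant",
)

TOTAL_COMPONENTS = ("seeds_per_plant", "dispersed_per_plant")

# variables compared with Welch's t; everything else uses the Wilcoxon rank-sum test
DEFAULT_PARAMETRIC = ("calyx_color", "ovules_per_flower", "seed_set", "seeds_per_fruit")

SUMMARY_VARIABLES = DEFAULT_TRAITS + (
    "percent_corolla_predated",
    "proportion_ovaries_predated",
    "ovaries_predated",
) + DEFAULT_COMPONENTS


@dataclass
class AnalysisConfig:
    """Configuration for :func:`run_analysis`; see module docstring for the stages."""

    input_path: str | None = None
    presets: tuple = ("barra-like", "melide-like")
    n: int | None = None
    seed: int = 0
    traits: tuple = DEFAULT_TRAITS
    fitness_components: tuple = DEFAULT_COMPONENTS
    sem_variables: tuple = synthetic.SEM_VARIABLES
    df_set: tuple = (1, 2)
    bootstrap_B: int = 1000
    alpha: float = 0.05
    rescale_female_fitness: bool = True
    pollen_production_means: dict | None = None
    anthers_per_flower: int = 10
    parametric_traits: tuple = DEFAULT_PARAMETRIC
    out_dir: str | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be >= 100")

    @classmethod
    def from_file(cls, path):
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        for key in ("presets", "traits", "fitness_components", "sem_variables",
                    "df_set", "parametric_traits"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ReportBundle:
    """All tables of one analysis run, with the config and seeds that produced them."""

    table: pd.DataFrame
    summary: pd.DataFrame
    correlations: pd.DataFrame
    opportunities: pd.DataFrame
    selection: dict
    sem_ranking: dict
    sem_best: dict
    trim_tables: dict
    bootstrap: dict
    indirect: dict
    log: dict = field(default_factory=dict)

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = ("# florsel {v} | seed={s} | config_hash={h}\n").format(
            v=self.log.get("version"), s=self.log.get("seed"),
            h=self.log.get("config_hash"))

        def _tsv(df, name):
            path = out / name
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", float_format="%.6g")

        self.table.to_csv(out / "plant_table.csv", index=False, float_format="%.6g")
        _tsv(self.summary, "population_summary.tsv")
        _tsv(self.correlations, "trait_correlations.tsv")
        _tsv(self.opportunities, "selection_opportunities.tsv")
        for pop, df in self.selection.items():
            _tsv(df, f"selection_{pop}.tsv")
        for pop, df in self.sem_ranking.items():
            _tsv(df.head(50), f"sem_ranking_{pop}.tsv")
        for pop, df in self.trim_tables.items():
            _tsv(df, f"sem_trimming_{pop}.tsv")
        for pop, df in self.bootstrap.items():
            _tsv(df, f"sem_bootstrap_{pop}.tsv")
        with open(out / "sem_best.json", "w") as fh:
            json.dump(self.sem_best, fh, indent=2, sort_keys=True)
        with open(out / "indirect_effects.json", "w") as fh:
            json.dump(self.indirect, fh, indent=2, sort_keys=True)
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2, sort_keys=True)
        return out


# -------------------------------------------------------------------------------------
# ingestion
# -------------------------------------------------------------------------------------

def load_table(config):
    """Load the plant CSV or simulate the configured presets (with pollen assays)."""
    if config.input_path is not None:
        table = pd.read_csv(config.input_path)
        if table.empty:
            raise ValueError("ingestion: input table is empty")
        if "population" not in table.columns:
            raise ValueError("ingestion: 'population' column is required")
        production = dict(config.pollen_production_means or {})
        return table, production
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * len(config.presets))
    parts = []
    production = {}
    for i, name in enumerate(config.presets):
        preset = synthetic.make_preset(name)
        tab = synthetic.simulate_population(
            preset, n=config.n, seed=int(seeds[2 * i] % (2**31)))
        assay = synthetic.simulate_pollen_assay(
            preset, tab, seed=int(seeds[2 * i + 1] % (2**31)))
        tab = tab.merge(assay.drop(columns=["true_dispersal_fraction"]),
                        on="plant_id", how="left")
        parts.append(tab)
        production[preset.name] = preset.pollen_production_mean
    if config.pollen_production_means:
        production.update(config.pollen_production_means)
    return pd.concat(parts, ignore_index=True), production


def derive_components(table, production, anthers_per_flower=10):
    """Join the raw table with all derived fitness components."""
    comp = fit_mod.fitness_table(table, production, anthers_per_flower)
    merged = table.join(comp.drop(columns=["plant_id", "population"]))
    return merged


# -------------------------------------------------------------------------------------
# population summaries
# -------------------------------------------------------------------------------------

def summarize_populations(table, config=None, variables=None):
    """Per-population mean±SD, min, max, n, CV% and a between-population test per variable.

    Parametric variables (per the config map) are compared with Welch's t; all others
    with the Wilcoxon rank-sum test.  Shapiro–Wilk normality p-values are reported per
    population for screening but never switch the test automatically.
    """
    from scipy import stats as sps

    config = config or AnalysisConfig()
    variables = variables or [v for v in SUMMARY_VARIABLES if v in table.columns]
    pops = list(dict.fromkeys(table["population"]))
    if len(pops) < 1:
        raise ValueError("no populations in table")
    rows = []
    for var in variables:
        if var not in table.columns:
            raise ValueError(f"unknown column {var!r}")
        row = {"variable": var}
        samples = []
        for pop in pops:
            x = table.loc[table["population"] == pop, var].dropna().astype(float)
            samples.append(x)
            row[f"{pop}:mean"] = x.mean()
            row[f"{pop}:sd"] = x.std(ddof=1)
            row[f"{pop}:min"] = x.min()
            row[f"{pop}:max"] = x.max()
            row[f"{pop}:n"] = len(x)
            row[f"{pop}:cv_percent"] = (
                sel.cv_percent(x.mean(), x.std(ddof=1)) if x.mean() != 0 else np.nan
            )
            row[f"{pop}:shapiro_p"] = (
                float(sps.shapiro(x).pvalue) if 3 <= len(x) <= 5000 else np.nan
            )
        if len(pops) >= 2:
            x, y = samples[0], samples[1]
            if var in config.parametric_traits:
                t, df, p = sel.welch_t(x.to_numpy(), y.to_numpy())
                row.update({"test": "welch_t", "statistic": t, "df": df, "pvalue": p})
            else:
                W, p = sel.wilcoxon_rank_sum(x.to_numpy(), y.to_numpy())
                row.update({"test": "wilcoxon", "statistic": W, "df": np.nan,
                            "pvalue": p})
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def _stars(p):
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def selection_tables(table, config):
    """Per population: S' and b'(SE) per trait x fitness component, with stars."""
    results = {}
    raw = {}
    for pop, sub in table.groupby("population", sort=False):
        wide = {}
        per_comp = {}
        for comp in config.fitness_components:
            if comp not in sub.columns:
                continue
            mask = sub[comp].notna()
            if mask.sum() < len(config.traits) + 2:
                continue
            traits_df = sub.loc[mask, list(config.traits)]
            w_abs = sub.loc[mask, comp]
            if w_abs.dropna().mean() <= 0:
                continue
            analysis = sel.SelectionAnalysis().fit(traits_df, w_abs)
            per_comp[comp] = analysis
            for trait in config.traits:
                d = analysis.differentials_.loc[trait]
                g = analysis.gradients_.loc[trait]
                wide.setdefault(trait, {})[f"{comp}:S'"] = (
                    f"{d.differential:.2f}{_stars(d.pvalue)}"
                )
                wide[trait][f"{comp}:b'(SE)"] = (
                    f"{g.gradient:.2f}{_stars(g.pvalue)} ({g.se:.2f})"
                )
        results[pop] = pd.DataFrame.from_dict(wide, orient="index").reindex(
            list(config.traits))
        results[pop].index.name = "trait"
        raw[pop] = per_comp
    return results, raw


# -------------------------------------------------------------------------------------
# full run
# -------------------------------------------------------------------------------------

def run_analysis(config):
    """Execute the whole pipeline; deterministic given ``config.seed``."""
    stage = "ingestion"
    try:
        table, production = load_table(config)
        stage = "fitness"
        merged = derive_components(table, production, config.anthers_per_flower)
        pops = list(dict.fromkeys(merged["population"]))

        stage = "summary"
        summary = summarize_populations(merged, config)

        stage = "correlations"
        corr_rows = []
        for pop, sub in merged.groupby("population", sort=False):
            for a, b in (("floral_display", "flowers_total"),
                         ("corolla_color", "floral_display"),
                         ("corolla_color", "flowers_total")):
                pair = sub[[a, b]].dropna()
                r, p = sel.pearson_corr(pair[a], pair[b])
                corr_rows.append({"population": pop, "x": a, "y": b, "r": r,
                                  "pvalue": p, "n": len(pair)})
        correlations = pd.DataFrame(corr_rows)

        stage = "selection"
        sel_tables, sel_raw = selection_tables(merged, config)
        opp_rows = []
        for comp in TOTAL_COMPONENTS:
            pooled = []
            for pop in pops:
                sub = merged[merged["population"] == pop]
                w = sel.relativize_fitness(sub[comp]).dropna()
                pooled.append(w.to_numpy())
                opp_rows.append({"component": comp, "population": pop,
                                 "opportunity": sel.selection_opportunity(w),
                                 "n": len(w)})
            if len(pooled) >= 2:
                F, df1, df2, p = sel.deviation_variance_test(*pooled, center="median")
                opp_rows.append({"component": comp, "population": "between",
                                 "opportunity": np.nan, "n": int(df1 + df2 + len(pooled)),
                                 "brown_forsythe_F": F, "df1": df1, "df2": df2,
                                 "pvalue": p})
        opportunities = pd.DataFrame(opp_rows)

        stage = "sem"
        rescale = ({"seeds_per_plant": 1e-3} if config.rescale_female_fitness else None)
        sem_ranking, sem_best, trim_tables, boot_tables, indirect = {}, {}, {}, {}, {}
        boot_seeds = np.random.SeedSequence(config.seed + 1).generate_state(len(pops))
        candidates = sem.enumerate_near_saturated(
            config.sem_variables, [config.sem_variables[0]], df_set=config.df_set)
        for k, pop in enumerate(pops):
            sub = merged[merged["population"] == pop]
            data = sub[list(config.sem_variables)].dropna().astype(float)
            if rescale:
                data = data.copy()
                for col, f in rescale.items():
                    data[col] = data[col] * f
            S, nobs = data.cov(ddof=1), len(data)
            ranking = sem.rank_candidates(candidates, S, nobs)
            sem_ranking[pop] = ranking
            best_i = int(ranking.loc[0, "model"])
            stage = "sem-trimming"
            trimmed_spec, trim_table = sem.trim_model(
                data, candidates[best_i].spec, alpha=config.alpha)
            trim_tables[pop] = trim_table
            best_fit = sem.fit_ml(trimmed_spec, data)
            stage = "sem-bootstrap"
            boot = sem.bootstrap_inference(
                trimmed_spec, data, B=config.bootstrap_B,
                seed=int(boot_seeds[k] % (2**31)))
            boot_tables[pop] = pd.DataFrame({
                "estimate": boot.estimates, "se": boot.se, "z": boot.z,
                "p": boot.p, "ci_lower": boot.ci_lower, "ci_upper": boot.ci_upper,
            })
            stage = "sem-indirect"
            source, target = config.sem_variables[0], config.sem_variables[-1]
            eff = sem.indirect_effects(best_fit, source, target, boot=boot)
            indirect[pop] = {
                "source": source, "target": target,
                "paths": {" -> ".join(k): v for k, v in eff.paths.items()},
                "direct": eff.direct, "total_indirect": eff.total_indirect,
                "total": eff.total, "se": eff.se, "z": eff.z, "p": eff.p,
                "ci": list(eff.ci) if eff.ci else None,
            }
            sem_best[pop] = {
                "spec": json.loads(trimmed_spec.to_json()),
                "chi2": best_fit.chi2_, "df": best_fit.df_, "pvalue": best_fit.pvalue_,
                "aic": best_fit.aic_, "bic": best_fit.bic_,
                "coefficients": {f"{c}->{e}": v
                                 for (c, e), v in best_fit.coefficients_.items()},
                "standardized": {f"{c}->{e}": v
                                 for (c, e), v in best_fit.standardized_.items()},
                "r2": best_fit.r2_, "nobs": best_fit.nobs_,
            }
            stage = "sem"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    cfg = asdict(config)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}
    log = {
        "version": __version__,
        "seed": config.seed,
        "config": hashed,  # analysis-relevant config; output location excluded
        "config_hash": __import__("hashlib").sha1(
            json.dumps(hashed, sort_keys=True, default=str).encode()).hexdigest()[:12],
        "n_candidate_models": len(candidates),
    }
    bundle = ReportBundle(
        table=merged, summary=summary, correlations=correlations,
        opportunities=opportunities, selection=sel_tables, sem_ranking=sem_ranking,
        sem_best=sem_best, trim_tables=trim_tables, bootstrap=boot_tables,
        indirect=indirect, log=log,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
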