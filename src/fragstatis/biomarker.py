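"""Per-metabolite mixed-effect screen for a domestication-status effect.

Each metabolite's log10 abundance is modelled as

    value ~ stage + replicate + population + (1 | genotype)

with stage, replicate and population (domesticated vs wild) as categorical
fixed effects and a random intercept for genotype; genotype labels are unique
across populations, so the random effect is implicitly nested in population.
Fitting is by REML (statsmodels MixedLM). The population fixed effect is
tested with a t statistic against a between-within degrees-of-freedom
reference (df = number of genotypes − 2), the appropriate reference for a
factor that varies between genotypes. When the genotype variance collapses to
zero (a singular fit), the screen falls back to the fixed-effects-only OLS
model and flags it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AbundanceDataset
from .diffnet import bh_adjust


@dataclass
class BiomarkerResult:
    metabolite_id: str
    pop_effect_estimate: float
    pop_p: float
    pop_q: float = np.nan
    significant: bool = False
    fit_status: str = "ok"  # ok | singular_fallback | failed


LONG_COLUMNS = ("value", "stage", "replicate", "population", "genotype")


def fit_metabolite_mixed_model(long_data: pd.DataFrame,
                               metabolite_id: str = "") -> BiomarkerResult:
    """Fit the mixed model for one metabolite's long-format data.

    ``long_data`` needs columns ``value, stage, replicate, population,
    genotype``. Returns the population-effect estimate and p-value; a constant
    response yields ``fit_status="failed"``.
    """
    import statsmodels.formula.api as smf

    df = long_data.copy()
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long data missing columns {missing}")
    df = df.dropna(subset=["value"])
    df = df.sort_values(["genotype", "stage", "replicate"]).reset_index(drop=True)
    n_geno = df.groupby("population")["genotype"].nunique()
    if len(n_geno) < 2 or (n_geno < 2).any():
        raise ValueError("need at least 2 genotypes per population")
    if df["value"].nunique() <= 1:
        return BiomarkerResult(metabolite_id, np.nan, np.nan,
                               fit_status="failed")

    formula = "value ~ C(stage) + C(replicate) + C(population)"
    df_between = df["genotype"].nunique() - 2  # genotypes − (intercept + pop)

    def _pop_term(params):
        name = [ix for ix in params.index if ix.startswith("C(population)")]
        return name[0] if name else None

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["genotype"])
            fit = model.fit(reml=True)
        singular = (float(np.asarray(fit.cov_re).ravel()[0]) < 1e-8
                    or not np.isfinite(fit.bse_fe).all())
    except Exception:
        singular = True
        fit = None

    if fit is not None and not singular:
        term = _pop_term(fit.fe_params)
        est = float(fit.fe_params[term])
        se = float(fit.bse_fe[term])
        status = "ok"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(formula, df).fit()
        term = _pop_term(ols.params)
        est = float(ols.params[term])
        se = float(ols.bse[term])
        status = "singular_fallback"
    if term.endswith("[T.W]"):
        est = -est  # orient the effect as domesticated minus wild
    if not np.isfinite(se) or se <= 0:
        return BiomarkerResult(metabolite_id, est, np.nan, fit_status="failed")
    tval = est / se
    p = float(2.0 * stats.t.sf(abs(tval), max(df_between, 1)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return BiomarkerResult(metabolite_id, est, p, fit_status=status)


def dataset_to_long(dataset: AbundanceDataset, metabolite_id: str,
                    log_transform: bool = True) -> pd.DataFrame:
    """Long-format frame for one metabolite (log10 values by default)."""
    v = dataset.values[metabolite_id].to_numpy(float)
    if log_transform:
        pos = v[np.isfinite(v) & (v > 0)]
        eps = pos.min() / 2.0 if pos.size else 1.0
        v = np.log10(v + eps)
    s = dataset.samples
    return pd.DataFrame({
        "value": v,
        "stage": s["stage"].to_numpy(),
        "replicate": s["replicate"].astype(str).to_numpy(),
        "population": s["group"].to_numpy(),
        "genotype": s["accession"].to_numpy(),
    })


def screen_biomarkers(dataset: AbundanceDataset, alpha: float = 0.05,
                      log_transform: bool = True) -> pd.DataFrame:
    """Fit every metabolite, BH-adjust across metabolites, flag significance.

    Returns a DataFrame with one row per metabolite: effect estimate, raw and
    adjusted p, significance at ``alpha`` (on the adjusted p), fit status, and
    metabolite class. Failed fits carry NaN and are never significant.
    """
    results = []
    for m in dataset.metabolite_ids:
        res = fit_metabolite_mixed_model(
            dataset_to_long(dataset, m, log_transform=log_transform),
            metabolite_id=m)
        results.append(res)
    p = np.array([r.pop_p for r in results], dtype=float)
    q = bh_adjust(p)
    out = pd.DataFrame({
        "metabolite_id": [r.metabolite_id for r in results],
        "met_class": dataset.metabolites["met_class"].to_numpy(),
        "pop_effect_estimate": [r.pop_effect_estimate for r in results],
        "pop_p": p,
        "pop_q": q,
        "significant_raw": p < alpha,
        "significant": q < alpha,
        "fit_status": [r.fit_status for r in results],
    })
    out.loc[out["fit_status"] == "failed", ["significant", "significant_raw"]
            ] = False
    return out
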