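"""Comparative statistics: correlations, ANOVA, PCA imputation, mixed
models, marginal means, effect sizes and model selection.

This layer mirrors the analysis plan of the cage study: Pearson
correlations and two-way (species x seasonal form) ANOVAs over the
morphological variables; PCA of the flight parameters with iterative
EM-style imputation of missing wingbeat-derived values; per-response
random-intercept LMMs (individual as random factor, log-transformed
responses where positive) with Satterthwaite F tests; Tukey-adjusted
estimated marginal means; Cohen's d as coefficient/SE; and two flavours
of predictor selection over the morphological terms — stepwise backward
elimination on term p-values and all-subsets AICc ranking with Akaike
weights.

Multiple testing across the response variables is deliberately NOT
adjusted, matching the original analysis plan; treat marginal p-values
accordingly.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from pierisflight.lmm import MixedLMResult, RandomInterceptModel

logger = logging.getLogger(__name__)

#: the five morphological variables tested against flight behaviour
MORPHO_VARIABLES = (
    "forewing_area_cm2",
    "aspect_ratio",
    "wing_loading_cm",
    "outer_edge_index",
    "marginal_region_index",
)

#: flight responses modelled per-response (covered distance is a
#: covariate, not a response)
FLIGHT_RESPONSES = (
    "wingbeat_frequency",
    "flight_height",
    "mean_velocity",
    "mean_acceleration",
    "advance_ratio",
    "turning_acceleration",
    "turning_rate",
    "sinuosity",
    "flight_curvature",
    "ascent_angle",
)

DREDGE_MAX_TERMS = 12


# ---------------------------------------------------------------------------
# morphology: correlations and ANOVA
# ---------------------------------------------------------------------------

def pairwise_correlations(morpho: pd.DataFrame,
                          variables: tuple[str, ...] = MORPHO_VARIABLES,
                          ) -> pd.DataFrame:
    """Pearson correlations with two-sided tests over variable pairs.

    Returns a tidy frame (var1, var2, r, p, n); complete-case per pair.
    """
    rows = []
    for v1, v2 in itertools.combinations(variables, 2):
        sub = morpho[[v1, v2]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete cases for {v1}/{v2}")
        for v in (v1, v2):
            if np.isclose(sub[v].std(ddof=0), 0.0):
                raise ValueError(f"correlation undefined: {v} is constant")
        r, p = sps.pearsonr(sub[v1], sub[v2])
        rows.append({"var1": v1, "var2": v2, "r": float(r), "p": float(p),
                     "n": len(sub)})
    return pd.DataFrame(rows)


def anova_morphology(morpho: pd.DataFrame,
                     variables: tuple[str, ...] = MORPHO_VARIABLES,
                     ) -> pd.DataFrame:
    """Two-way ANOVA (species, form, species x form) per variable.

    Type-II sums of squares; requires >= 2 levels per factor and at
    least one replicated cell for the interaction test.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    for fac in ("species", "form"):
        if morpho[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} needs >= 2 levels")
    cell_sizes = morpho.groupby(["species", "form"]).size()
    if (cell_sizes <= 1).all():
        raise ValueError("single observation per cell: interaction "
                         "model is saturated")
    rows = []
    for var in variables:
        data = morpho[[var, "species", "form"]].dropna().rename(
            columns={var: "y"})
        model = smf.ols("y ~ C(species) * C(form)", data=data).fit()
        tab = anova_lm(model, typ=2)
        for term, pretty in [("C(species)", "species"), ("C(form)", "form"),
                             ("C(species):C(form)", "species:form")]:
            rows.append({
                "variable": var, "term": pretty,
                "F": float(tab.loc[term, "F"]),
                "df": float(tab.loc[term, "df"]),
                "df_resid": float(tab.loc["Residual", "df"]),
                "p": float(tab.loc[term, "PR(>F)"]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA with iterative imputation
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    completed: pd.DataFrame
    n_imputed: int
    columns: list[str]


def pca_with_imputation(table: pd.DataFrame, ncp: int = 2,
                        tol: float = 1e-8,
                        max_iter: int = 2000) -> PCAResult:
    """PCA after deterministic iterative (EM-style) imputation.

    Missing cells are initialized at the column mean of the
    standardized table and refined by alternating a rank-``ncp`` SVD
    reconstruction with re-standardization until the imputed values
    move less than ``tol``.  The final PCA runs on the completed,
    standardized table.  Columns may have at most 20% missingness.
    """
    cols = list(table.columns)
    X = table.to_numpy(dtype=float)
    miss = ~np.isfinite(X)
    frac = miss.mean(axis=0)
    if np.any(frac >= 1.0):
        raise ValueError("a column is entirely missing")
    if np.any(frac > 0.2):
        bad = [c for c, f in zip(cols, frac) if f > 0.2]
        raise ValueError(f"missingness above 20% in {bad}")
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant column; PCA undefined")
    Z = (X - mu) / sd
    Z[miss] = 0.0  # column mean of the standardized table
    if miss.any():
        for _ in range(max_iter):
            centre = Z.mean(axis=0)
            U, s, Vt = np.linalg.svd(Z - centre, full_matrices=False)
            recon = (U[:, :ncp] * s[:ncp]) @ Vt[:ncp] + centre
            delta = np.max(np.abs(recon[miss] - Z[miss]))
            Z[miss] = recon[miss]
            if delta < tol:
                break
        else:
            warnings.warn("PCA imputation reached max_iter before "
                          f"tol={tol}", stacklevel=2)
    pca = PCA()
    scores = pca.fit_transform(Z - Z.mean(axis=0))
    completed = pd.DataFrame(Z * sd + mu, columns=cols, index=table.index)
    return PCAResult(scores=scores, loadings=pca.components_.T,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     completed=completed, n_imputed=int(miss.sum()),
                     columns=cols)


# ---------------------------------------------------------------------------
# flight LMMs
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """Tidy wrapper of one fitted flight LMM."""

    response: str
    log_transformed: bool
    formula: str
    fit: MixedLMResult
    coef_table: pd.DataFrame
    n_obs: int
    n_groups: int

    @property
    def aicc(self) -> float:
        return self.fit.aicc

    def summary(self) -> str:
        head = (f"Response: {'log ' if self.log_transformed else ''}"
                f"{self.response}\n")
        return head + self.fit.summary()


def _prepare_response(data: pd.DataFrame, response: str,
                      log_transform: bool | None) -> tuple[pd.Series, bool]:
    y = data[response]
    if log_transform is None:
        log_transform = bool((y.dropna() > 0).all())
        if not log_transform:
            logger.info("response %s has non-positive values; analysed "
                        "untransformed", response)
    if log_transform and (y.dropna() <= 0).any():
        raise ValueError(f"cannot log-transform {response}: non-positive "
                         "values present")
    return (np.log(y) if log_transform else y), log_transform


def fit_flight_lmm(data: pd.DataFrame, response: str,
                   fixed: tuple[str, ...] = ("species", "form", "sex"),
                   covariates: tuple[str, ...] = ("log_covered_distance",),
                   group: str = "specimen_id",
                   log_transform: bool | None = None,
                   reml: bool = True) -> ModelResult:
    """Fit one flight characteristic against the design factors.

    The response is natural-log transformed when strictly positive
    (sign-carrying responses such as ascent angle are analysed
    untransformed); log covered distance enters as a fixed covariate
    and specimen identity as a random intercept.  Missing responses are
    dropped.  A singular random-intercept fit is flagged on the result.
    """
    df = data.copy()
    if "log_covered_distance" in covariates and \
            "log_covered_distance" not in df:
        df["log_covered_distance"] = np.log(df["covered_distance"])
    y, logged = _prepare_response(df, response, log_transform)
    df = df.assign(_y=y).dropna(
        subset=["_y", group, *fixed, *covariates])
    fixed_used = [f for f in fixed if df[f].nunique() > 1]
    terms = [f"C({f})" for f in fixed_used] + list(covariates)
    formula = "_y ~ " + " + ".join(terms) if terms else "_y ~ 1"
    model = RandomInterceptModel.from_formula(formula, df, groups=group)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml)
    return ModelResult(response=response, log_transformed=logged,
                       formula=formula, fit=fit,
                       coef_table=fit.coef_table(),
                       n_obs=fit.n_obs, n_groups=fit.n_groups)


def term_test(result: ModelResult, factor: str) -> dict:
    """Satterthwaite F test of a (two-level) factor's coefficient."""
    names = result.fit.exog_names
    matches = [j for j, nm in enumerate(names) if f"C({factor})" in nm
               or nm == factor]
    if not matches:
        raise ValueError(f"term {factor!r} not in the model")
    j = matches[0]
    c = np.zeros(len(names))
    c[j] = 1.0
    est, se, df, p = result.fit.t_test(c)
    return {"term": factor, "estimate": est, "se": se,
            "F": (est / se) ** 2, "df": df, "p": p}


# ---------------------------------------------------------------------------
# marginal means
# ---------------------------------------------------------------------------

@dataclass
class MarginalMeansTable:
    """Model-based group means and Tukey-adjusted pairwise contrasts."""

    factor: str
    means: pd.DataFrame
    contrasts: pd.DataFrame
    response_scale: bool


def _reference_grid(design_info, data_like: pd.DataFrame) -> pd.DataFrame:
    """Full cross of factor levels with covariates at their means."""
    import patsy

    levels = {}
    covars = {}
    for fac, info in design_info.factor_infos.items():
        name = fac.code
        base = name
        if base.startswith("C(") and base.endswith(")"):
            base = base[2:-1]
        if info.type == "categorical":
            levels[base] = list(info.categories)
        else:
            col = data_like.eval(base) if base not in data_like else \
                data_like[base]
            covars[base] = float(np.mean(col))
    keys = list(levels)
    combos = list(itertools.product(*[levels[k] for k in keys]))
    grid = pd.DataFrame(combos, columns=keys)
    for k, v in covars.items():
        grid[k] = v
    return grid


def marginal_means(result: ModelResult, factor: str,
                   backtransform: bool = False) -> MarginalMeansTable:
    """Estimated marginal means for ``factor`` with Tukey contrasts.

    Other factors are averaged with equal weights; covariates sit at
    their observed means.  With ``backtransform=True`` a log-scale
    model reports exp(mean) with delta-method SEs (contrasts stay on
    the model scale).
    """
    import patsy

    di = result.fit.model.design_info
    if di is None:
        raise ValueError("model was not built from a formula")
    grid = _reference_grid(di, _model_frame(result))
    if factor not in grid.columns:
        raise ValueError(f"factor {factor!r} not in the model")
    lv = grid[factor].unique()
    if len(lv) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    (Xg,) = patsy.build_design_matrices([di], grid)
    Xg = np.asarray(Xg)
    fit = result.fit
    rows = []
    Ls = {}
    for level in lv:
        mask = (grid[factor] == level).to_numpy()
        L = Xg[mask].mean(axis=0)
        Ls[level] = L
        est, se, df, _ = fit.t_test(L)
        if backtransform and result.log_transformed:
            rows.append({"level": level, "emmean": float(np.exp(est)),
                         "se": float(np.exp(est) * se), "df": df})
        else:
            rows.append({"level": level, "emmean": est, "se": se, "df": df})
    k = len(lv)
    contrasts = []
    for a, b in itertools.combinations(lv, 2):
        c = Ls[a] - Ls[b]
        est, se, df, p_unadj = fit.t_test(c)
        t = est / se
        p_tukey = float(sps.studentized_range.sf(
            abs(t) * np.sqrt(2.0), k, df))
        contrasts.append({"contrast": f"{a} - {b}", "estimate": est,
                          "se": se, "df": df, "t": t,
                          "p_unadjusted": p_unadj,
                          "p_tukey": min(p_tukey, 1.0)})
    return MarginalMeansTable(factor=factor, means=pd.DataFrame(rows),
                              contrasts=pd.DataFrame(contrasts),
                              response_scale=backtransform)


def _model_frame(result: ModelResult) -> pd.DataFrame:
    """Reconstruct covariate means from the stored design matrix."""
    X = result.fit.model.X
    return pd.DataFrame(X, columns=result.fit.exog_names)


# ---------------------------------------------------------------------------
# effect sizes and model selection
# ---------------------------------------------------------------------------

def cohens_d_from_fit(coefficient: float, se: float) -> float:
    """Standardized effect size: estimated coefficient over its SE."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return coefficient / se


@dataclass
class SelectionResult:
    """Outcome of stepwise or all-subsets predictor selection."""

    retained: list[str]
    elimination_order: list[str] = field(default_factory=list)
    table: pd.DataFrame | None = None
    variable_weights: pd.Series | None = None
    final: ModelResult | None = None


def _fit_morpho_model(data: pd.DataFrame, response: str,
                      morpho_terms: list[str],
                      covariates: tuple[str, ...],
                      reml: bool) -> ModelResult:
    df = data.copy()
    if "log_covered_distance" in covariates and \
            "log_covered_distance" not in df:
        df["log_covered_distance"] = np.log(df["covered_distance"])
    y, logged = _prepare_response(df, response, None)
    log_terms = []
    for t in morpho_terms:
        lt = f"log_{t}"
        df[lt] = np.log(df[t])
        log_terms.append(lt)
    df = df.assign(_y=y).dropna(subset=["_y", "specimen_id",
                                        *log_terms, *covariates])
    cat = ["C(sex)"] if df["sex"].nunique() > 1 else []
    rhs = log_terms + cat + list(covariates)
    formula = "_y ~ " + (" + ".join(rhs) if rhs else "1")
    model = RandomInterceptModel.from_formula(formula, df,
                                              groups="specimen_id")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml)
    return ModelResult(response=response, log_transformed=logged,
                       formula=formula, fit=fit,
                       coef_table=fit.coef_table(),
                       n_obs=fit.n_obs, n_groups=fit.n_groups)


def morphology_effects(data: pd.DataFrame, response: str,
                       morpho_terms: tuple[str, ...] = MORPHO_VARIABLES,
                       covariates: tuple[str, ...] = (
                           "log_covered_distance",),
                       ) -> tuple[ModelResult, pd.DataFrame]:
    """Full morphology-on-flight LMM with Cohen's d per morphological term.

    All morphological predictors enter log-transformed alongside sex
    and log covered distance, with specimen identity random; the
    returned table carries slope, SE, Cohen's d (= slope/SE), F, df
    and p for each morphological variable.
    """
    res = _fit_morpho_model(data, response, list(morpho_terms), covariates,
                            reml=True)
    rows = []
    for t in morpho_terms:
        row = res.coef_table.loc[res.coef_table.term == f"log_{t}"]
        if row.empty:
            continue
        r = row.iloc[0]
        rows.append({"response": response, "trait": t,
                     "slope": r.estimate, "se": r.se,
                     "cohens_d": cohens_d_from_fit(r.estimate, r.se),
                     "F": r.F, "df": r.df, "p": r.p})
    return res, pd.DataFrame(rows)


def stepwise_backward(data: pd.DataFrame, response: str,
                      morpho_terms: tuple[str, ...] = MORPHO_VARIABLES,
                      covariates: tuple[str, ...] = (
                          "log_covered_distance",),
                      alpha: float = 0.05) -> SelectionResult:
    """Backward elimination of morphological terms on Satterthwaite p.

    Iteratively drops the least significant morphological predictor
    (largest p > alpha) and refits, until every retained morphological
    term is significant; sex and the covariates always stay.
    Deterministic; the elimination order is recorded.
    """
    terms = list(morpho_terms)
    order: list[str] = []
    res = _fit_morpho_model(data, response, terms, covariates, reml=True)
    while terms:
        tab = res.coef_table.set_index("term")
        pvals = {t: tab.loc[f"log_{t}", "p"] for t in terms}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            break
        terms.remove(worst)
        order.append(worst)
        res = _fit_morpho_model(data, response, terms, covariates,
                                reml=True)
    return SelectionResult(retained=terms, elimination_order=order,
                           final=res)


def dredge_all_subsets(data: pd.DataFrame, response: str,
                       morpho_terms: tuple[str, ...] = MORPHO_VARIABLES,
                       covariates: tuple[str, ...] = (
                           "log_covered_distance",),
                       ) -> SelectionResult:
    """All-subsets AICc ranking of the morphological predictors.

    Fits every subset of ``morpho_terms`` (sex and covariates always
    included) by ML, ranks by AICc, and reports Akaike weights plus
    per-variable weight sums (the importance measure).  Capped at 12
    candidate terms (4096 models).
    """
    terms = list(morpho_terms)
    if len(terms) > DREDGE_MAX_TERMS:
        raise ValueError(
            f"{len(terms)} candidate terms exceed the {DREDGE_MAX_TERMS}-"
            "term cap; reduce the candidate set")
    rows = []
    for k in range(len(terms) + 1):
        for subset in itertools.combinations(terms, k):
            res = _fit_morpho_model(data, response, list(subset),
                                    covariates, reml=False)
            rows.append({"terms": subset, "k": len(subset),
                         "aicc": res.aicc,
                         "loglik_ml": res.fit.loglik_ml})
    tab = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    rel = np.exp(-0.5 * tab["delta_aicc"])
    tab["weight"] = rel / rel.sum()
    weights = pd.Series(
        {t: tab.loc[[t in s for s in tab.terms], "weight"].sum()
         for t in terms}, name="weight_sum")
    best = list(tab.iloc[0]["terms"])
    return SelectionResult(retained=best, table=tab,
                           variable_weights=weights)


# ---------------------------------------------------------------------------
# temperature models
# ---------------------------------------------------------------------------

def temperature_models(data: pd.DataFrame, response: str,
                       ) -> dict[str, ModelResult]:
    """The two ambient-temperature LMM specifications.

    'full': temperature + species + form fixed, individual random;
    'daily': mean recording-day temperature as sole fixed effect,
    individual random.  Rows without temperature are dropped (count
    logged).
    """
    df = data.copy()
    if df["temperature_c"].nunique() <= 1:
        raise ValueError("constant temperature; effect not estimable")
    n0 = len(df)
    df = df.dropna(subset=["temperature_c"])
    if len(df) < n0:
        logger.info("dropped %d rows without temperature", n0 - len(df))
    out = {}
    out["full"] = fit_flight_lmm(
        df, response, fixed=("species", "form"),
        covariates=("temperature_c",))
    daily = df.groupby("day")["temperature_c"].transform("mean")
    df = df.assign(day_mean_temperature=daily)
    out["daily"] = fit_flight_lmm(
        df, response, fixed=(), covariates=("day_mean_temperature",))
    return out
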