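"""Seasonal factors, co-infestation designs, and abundance/incidence GLMs.

Abundance side.  Per taxon x and site, steer-month adult counts are modelled
with negative-binomial GLMs (log link).  The seasonal factor s_x is built by
agglomerative month merging: starting from one level per month, the pair of
levels whose abundance estimates differ least (largest pairwise Wald p) is
merged while that p exceeds alpha, and the surviving levels are ranked by
fitted mean (low < medium < high, or L1..Lk beyond three).  The maximal
model is s_x * PI_all_but_x, where PI_all_but_x collects presence/absence
indicators of every co-occurring taxon except x plus their products up to a
configurable order.  Backward elimination drops the least-significant
eliminable term (p > alpha), preferring the drop that minimizes AIC, and
never removes a term contained in a retained higher-order interaction
(marginality).

Incidence side.  The per steer-month presence of taxon x is modelled with
binomial GLMs (logit link), maximal model SITE * s_x + PI_all_but_x, same
elimination.  Overdispersion is checked a posteriori via residual deviance /
residual df; past a threshold the model is refit as quasibinomial (standard
errors scaled by sqrt(Pearson X^2 / df)).  Minimal models explaining < 10 %
of the null deviance are flagged as not considered.

Negative-binomial fitting mirrors R's glm.nb: the size parameter theta is
estimated by full maximum likelihood (NB2), then coefficient inference is
conditional on theta via the corresponding GLM.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .survey_io import ANALYSIS_TAXA, SHORT_CODE

logger = logging.getLogger(__name__)

LEVEL_NAMES = ("low", "medium", "high")


def _drop_absent(data: pd.DataFrame) -> pd.DataFrame:
    if "season" in data.columns:
        return data.loc[data["season"] != "absent"].copy()
    return data.copy()


# ---------------------------------------------------------------------------
# Model terms


@dataclass(frozen=True)
class ModelTerm:
    """One model term: its patsy code and the set of factors it involves."""

    code: str  # e.g. "C(season)", "A_H", "C(season):A_H"
    factors: frozenset  # e.g. {"season", "A", "H"}

    def contains(self, other: "ModelTerm") -> bool:
        return other.factors < self.factors


def eliminable_terms(terms: tuple[ModelTerm, ...]) -> tuple[ModelTerm, ...]:
    """Terms not contained in any retained higher-order term (marginality)."""
    return tuple(
        t for t in terms if not any(o.contains(t) for o in terms if o is not t)
    )


# ---------------------------------------------------------------------------
# Fit container


@dataclass
class GlmFit:
    """Uniform fitted-model contract for the NB and binomial models."""

    family: str  # negative_binomial | binomial | quasibinomial
    link: str
    formula: str
    terms: tuple[ModelTerm, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    term_pvalues: pd.Series
    aic: float | None
    deviance: float
    null_deviance: float
    df_resid: int
    converged: bool
    theta: float | None = None  # NB size estimate
    dispersion: float | None = None  # Pearson X^2 / df when quasibinomial
    flags: tuple[str, ...] = ()
    result: object = field(default=None, repr=False)

    @property
    def explained_deviance(self) -> float:
        if self.null_deviance <= 0:
            return float("nan")
        return 1.0 - self.deviance / self.null_deviance


@dataclass
class SeasonalFactor:
    """Month -> abundance-level mapping for one taxon at one site."""

    taxon: str | None
    site: str | None
    levels_by_month: dict[int, str]  # month_index -> level label (or "absent")
    level_means: dict[str, float]
    sporadic: bool = False
    flags: tuple[str, ...] = ()

    @property
    def n_levels(self) -> int:
        return len([l for l in set(self.levels_by_month.values()) if l != "absent"])

    def season_series(self, month_index: pd.Series) -> pd.Series:
        return month_index.map(self.levels_by_month).rename("season")


@dataclass
class CoinfestationDesign:
    """PI_all_but_x: partner presence indicators and their products."""

    focal_taxon: str
    partners: tuple[str, ...]  # short codes
    columns: dict[str, frozenset]  # design column -> set of partner codes
    frame: pd.DataFrame  # 0/1 columns, aligned with the modelling rows
    dropped: tuple[str, ...] = ()

    def augment(self, data: pd.DataFrame) -> pd.DataFrame:
        """Return ``data`` with any missing design columns attached."""
        missing = [c for c in self.frame.columns if c not in data.columns]
        if not missing:
            return data
        return data.join(self.frame[missing])


# ---------------------------------------------------------------------------
# Seasonal factor construction


def classify_sporadic(series: pd.Series | np.ndarray, min_months: int = 3) -> bool:
    """True when the taxon is present in fewer than ``min_months`` months.

    ``series`` holds the monthly totals of one taxon at one site.  A series
    with fewer than three support months cannot identify a seasonal factor.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size < 1:
        raise ValueError("empty series")
    return int((arr > 0).sum()) < min_months


def _nb_loglike(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(stats.nbinom.logpmf(y, theta, theta / (theta + mu)).sum())


def _fit_nb_formula(formula: str, data: pd.DataFrame):
    """Two-step NB fit: MLE for theta, then GLM conditional on theta.

    Returns (glm_result, theta, aic, converged).  AIC counts theta as a
    fitted parameter, matching glm.nb conventions.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mle = smf.negativebinomial(formula, data).fit(
            method="bfgs", maxiter=500, disp=0
        )
        converged = bool(mle.mle_retvals.get("converged", False))
        alpha = float(mle.params.get("alpha", np.nan))
        if not np.isfinite(alpha) or alpha <= 1e-8:
            alpha = 1e-8
        theta = 1.0 / alpha
        glm = smf.glm(
            formula, data, family=sm.families.NegativeBinomial(alpha=alpha)
        ).fit()
    k = len(glm.params) + 1  # + theta
    aic = -2.0 * _nb_loglike(
        np.asarray(glm.model.endog), np.asarray(glm.fittedvalues), theta
    ) + 2.0 * k
    return glm, theta, aic, converged


def _month_homogeneity_p(df: pd.DataFrame, months: list[int]) -> float:
    """LR p-value for 'these months share one NB mean' at month granularity.

    Both the month-factor and the intercept-only fit re-estimate theta, as in
    glm.nb model comparisons; the LR statistic is referred to chi2 on
    (#months - 1) df.
    """
    sub = df[df["month_index"].isin(months)].copy()
    sub["grp"] = sub["month_index"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.negativebinomial("count ~ C(grp)", sub).fit(
            method="bfgs", maxiter=500, disp=0
        )
        null = smf.negativebinomial("count ~ 1", sub).fit(
            method="bfgs", maxiter=500, disp=0
        )
    if not (full.mle_retvals.get("converged") and null.mle_retvals.get("converged")):
        raise RuntimeError("NB MLE did not converge in homogeneity test")
    lr = max(0.0, 2.0 * (full.llf - null.llf))
    return float(stats.chi2.sf(lr, len(months) - 1))


def _pairwise_level_pvalues(glm_result, factor_name: str, levels: list[str]):
    """Wald p for every pair of levels of a treatment-coded factor."""
    names = list(glm_result.params.index)
    eff = {lev: 0.0 for lev in levels}
    idx = {lev: None for lev in levels}
    for i, nm in enumerate(names):
        for lev in levels:
            if nm == f"C({factor_name})[T.{lev}]":
                eff[lev] = float(glm_result.params.iloc[i])
                idx[lev] = i
    V = np.asarray(glm_result.cov_params())
    out = []
    for a, b in itertools.combinations(levels, 2):
        ia, ib = idx[a], idx[b]
        var = 0.0
        if ia is not None:
            var += V[ia, ia]
        if ib is not None:
            var += V[ib, ib]
        if ia is not None and ib is not None:
            var -= 2.0 * V[ia, ib]
        diff = eff[a] - eff[b]
        if var <= 0:
            p = 1.0
        else:
            z = diff / np.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
        out.append((a, b, diff, p))
    return out


def merge_months_to_seasons(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    taxon: str | None = None,
    site: str | None = None,
) -> SeasonalFactor:
    """Agglomerate months into seasonal abundance levels.

    ``counts`` has one row per steer-month with columns ``month_index`` and
    ``count``.  Months with zero total count form the "absent" level and do
    not enter the GLM.  The procedure has three parts, all at ``alpha``:

    1. a global LR test of the full month factor — when non-significant,
       every month collapses into a single level (pairwise agglomeration
       alone over-splits homogeneous series, because each merge decision is
       a selection-biased comparison);
    2. iterative agglomeration otherwise: fit count ~ level (NB GLM), merge
       the pair with the largest pairwise Wald p above a Sidak-adjusted
       threshold over the month-pair family (ties broken by the smaller
       fitted-mean difference), refit, repeat;
    3. a cleanup pass that re-tests each pair of surviving levels with an
       honest month-granularity LR homogeneity test on their pooled months,
       merging while any pair passes.

    On non-convergence the nearest-mean pair is merged instead and the
    factor is flagged.
    """
    df = counts[["month_index", "count"]].copy()
    monthly = df.groupby("month_index")["count"].sum()
    present = monthly[monthly > 0].index.tolist()
    if len(present) < 3:
        raise ValueError(
            "sporadic series (present in < 3 months): no seasonal factor identifiable"
        )
    absent = [int(m) for m in monthly.index if m not in present]

    group_of = {int(m): f"g{int(m):02d}" for m in present}
    flags: list[str] = []
    fitted_means: dict[str, float] = {}
    # pairwise merge threshold: family-wise alpha over all month pairs
    n_pairs = len(present) * (len(present) - 1) / 2
    pair_thresh = 1.0 - (1.0 - alpha) ** (1.0 / n_pairs)

    # global homogeneity pre-test on the full month-level factor
    try:
        global_p = _month_homogeneity_p(df, present)
    except Exception:
        global_p = 0.0  # undecidable: fall through to agglomeration
        flags.append("global_test_failed")
    if global_p > alpha:
        one = sorted(set(group_of.values()))[0]
        group_of = {m: one for m in group_of}

    while True:
        work = df[df["month_index"].isin(present)].copy()
        work["grp"] = work["month_index"].map(group_of)
        levels = sorted(set(group_of.values()))
        if len(levels) == 1:
            fitted_means = {levels[0]: float(work["count"].mean())}
            break
        emp_means = work.groupby("grp")["count"].mean().to_dict()
        try:
            glm, theta, _, converged = _fit_nb_formula("count ~ C(grp)", work)
            if not converged:
                raise RuntimeError("NB MLE did not converge")
            mu = glm.predict(pd.DataFrame({"grp": levels}))
            fitted_means = dict(zip(levels, map(float, mu)))
            pairs = _pairwise_level_pvalues(glm, "grp", levels)
        except Exception as exc:  # non-convergence fallback: merge nearest means
            if "seasonal_fallback" not in flags:
                flags.append("seasonal_fallback")
            logger.debug("season merge fallback (%s/%s): %s", taxon, site, exc)
            fitted_means = {lev: float(emp_means[lev]) for lev in levels}
            a, b = min(
                itertools.combinations(levels, 2),
                key=lambda ab: abs(emp_means[ab[0]] - emp_means[ab[1]]),
            )
            group_of = {m: (a if g == b else g) for m, g in group_of.items()}
            continue

        candidates = [(a, b, d, p) for a, b, d, p in pairs if p > pair_thresh]
        if not candidates:
            break
        a, b, _, _ = max(candidates, key=lambda t: (t[3], -abs(t[2])))
        group_of = {m: (a if g == b else g) for m, g in group_of.items()}

    # cleanup: merge level pairs whose pooled months are homogeneous
    while len(set(group_of.values())) > 1:
        levels = sorted(set(group_of.values()))
        best_pair, best_p = None, alpha
        for a, b in itertools.combinations(levels, 2):
            months_ab = [m for m, g in group_of.items() if g in (a, b)]
            try:
                p_ab = _month_homogeneity_p(df, months_ab)
            except Exception:
                continue
            if p_ab > best_p:
                best_pair, best_p = (a, b), p_ab
        if best_pair is None:
            break
        a, b = best_pair
        group_of = {m: (a if g == b else g) for m, g in group_of.items()}
    # final level means: empirical group means (= saturated-factor NB MLE)
    work = df[df["month_index"].isin(present)].copy()
    work["grp"] = work["month_index"].map(group_of)
    fitted_means = {g: float(v) for g, v in work.groupby("grp")["count"].mean().items()}

    # rank surviving levels by fitted mean, ascending; name them
    levels_sorted = sorted(fitted_means, key=fitted_means.get)
    k = len(levels_sorted)
    names = list(LEVEL_NAMES[-k:]) if k <= 3 else [f"L{i + 1}" for i in range(k)]
    rename = dict(zip(levels_sorted, names))
    levels_by_month = {m: rename[g] for m, g in group_of.items()}
    for m in absent:
        levels_by_month[m] = "absent"
    return SeasonalFactor(
        taxon=taxon,
        site=site,
        levels_by_month=dict(sorted(levels_by_month.items())),
        level_means={rename[g]: fitted_means[g] for g in levels_sorted},
        sporadic=False,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Co-infestation design


def build_coinfestation_design(
    presence: pd.DataFrame,
    focal_taxon: str,
    max_order: int = 2,
    partners: tuple[str, ...] | None = None,
    min_cells: int = 1,
) -> CoinfestationDesign:
    """Indicator + product columns for every co-occurring taxon but the focal.

    ``presence`` holds 0/1 columns named by the model variable codes
    (H, A, R, Rm, Ra, Rd, Rg) per steer-month row.  Partners default to the
    non-constant indicator columns, excluding the focal taxon.  Product
    columns are named by joining codes with "_" (e.g. ``A_H``); constant or
    duplicated columns are dropped with a log note.
    """
    focal_code = SHORT_CODE.get(focal_taxon, focal_taxon)
    all_codes = [SHORT_CODE[t] for t in ANALYSIS_TAXA]
    if partners is None:
        partners = tuple(
            c
            for c in all_codes
            if c != focal_code and c in presence.columns and presence[c].nunique() > 1
        )
    else:
        partners = tuple(c for c in partners if c != focal_code)

    columns: dict[str, frozenset] = {}
    frame = pd.DataFrame(index=presence.index)
    dropped: list[str] = []
    seen: dict[tuple, str] = {}
    for order in range(1, max_order + 1):
        for combo in itertools.combinations(partners, order):
            name = "_".join(combo)
            col = presence[list(combo)].prod(axis=1).astype(int)
            ones = int(col.sum())
            if min(ones, len(col) - ones) < max(min_cells, 1):
                dropped.append(name)
                logger.info("design column %s dropped (constant or too sparse)", name)
                continue
            fingerprint = tuple(col.to_numpy())
            if fingerprint in seen:
                dropped.append(name)
                logger.info(
                    "design column %s dropped (duplicates %s)", name, seen[fingerprint]
                )
                continue
            seen[fingerprint] = name
            columns[name] = frozenset(combo)
            frame[name] = col
    return CoinfestationDesign(
        focal_taxon=focal_taxon,
        partners=partners,
        columns=columns,
        frame=frame,
        dropped=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# Abundance model (negative binomial)


def _match_term_pvalues(glm_result, terms: tuple[ModelTerm, ...]) -> pd.Series:
    """Per-term Wald chi-square p-values, matched by factor composition."""
    table = glm_result.wald_test_terms(scalar=True).table
    norm = {}
    for name in table.index:
        key = frozenset(name.split(":"))
        norm[key] = float(table.loc[name, "pvalue"])
    out = {}
    for t in terms:
        key = frozenset(t.code.split(":"))
        out[t.code] = norm.get(key, float("nan"))
    return pd.Series(out, name="term_pvalue")


def _build_terms(
    season_levels: int, design: CoinfestationDesign | None, with_site: bool = False,
    season_interactions: bool = True,
) -> tuple[ModelTerm, ...]:
    terms: list[ModelTerm] = []
    has_season = season_levels > 1
    if with_site:
        terms.append(ModelTerm("C(site)", frozenset({"site"})))
        if has_season:
            terms.append(ModelTerm("C(season)", frozenset({"season"})))
            terms.append(
                ModelTerm("C(site):C(season)", frozenset({"site", "season"}))
            )
    elif has_season:
        terms.append(ModelTerm("C(season)", frozenset({"season"})))
    if design is not None:
        for col, factors in design.columns.items():
            terms.append(ModelTerm(col, factors))
            if has_season and season_interactions:
                terms.append(
                    ModelTerm(f"C(season):{col}", frozenset({"season"}) | factors)
                )
    return tuple(terms)


def _formula(terms: tuple[ModelTerm, ...], response: str = "count") -> str:
    rhs = " + ".join(t.code for t in terms) if terms else "1"
    return f"{response} ~ {rhs}"


def fit_abundance_model(
    data: pd.DataFrame,
    design: CoinfestationDesign | None = None,
    season_interactions: bool = True,
) -> GlmFit:
    """Maximal NB model s_x * PI_all_but_x on steer-month counts.

    ``data`` carries ``count``, a ``season`` level column (rows of the
    "absent" level are excluded), and the design's 0/1 columns.  Raises on
    all-zero counts (no finite NB fit exists).
    """
    if design is not None:
        data = design.augment(data)
    df = _drop_absent(data)
    if (df["count"] <= 0).all():
        raise ValueError("all counts zero: no finite negative-binomial fit")
    n_levels = df["season"].nunique() if "season" in df else 1
    terms = _build_terms(n_levels, design, season_interactions=season_interactions)
    return _fit_nb_glmfit(df, terms)


def _fit_nb_glmfit(df: pd.DataFrame, terms: tuple[ModelTerm, ...]) -> GlmFit:
    formula = _formula(terms, "count")
    flags: list[str] = []
    try:
        glm, theta, aic, converged = _fit_nb_formula(formula, df)
        term_p = _match_term_pvalues(glm, terms) if terms else pd.Series(dtype=float)
    except Exception as exc:
        logger.warning("NB fit failed for %s: %s", formula, exc)
        nan = float("nan")
        return GlmFit(
            family="negative_binomial",
            link="log",
            formula=formula,
            terms=terms,
            params=pd.Series(dtype=float),
            bse=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float),
            term_pvalues=pd.Series(dtype=float),
            aic=None,
            deviance=nan,
            null_deviance=nan,
            df_resid=0,
            converged=False,
            theta=None,
            flags=("fit_failed",),
        )
    if not converged:
        flags.append("theta_mle_not_converged")
    return GlmFit(
        family="negative_binomial",
        link="log",
        formula=formula,
        terms=terms,
        params=glm.params,
        bse=glm.bse,
        pvalues=glm.pvalues,
        term_pvalues=term_p,
        aic=aic,
        deviance=float(glm.deviance),
        null_deviance=float(glm.null_deviance),
        df_resid=int(glm.df_resid),
        converged=converged,
        theta=theta,
        flags=tuple(flags),
        result=glm,
    )


# ---------------------------------------------------------------------------
# Backward elimination


def backward_eliminate(
    fit: GlmFit,
    data: pd.DataFrame,
    alpha: float = 0.05,
    max_aic_candidates: int = 3,
) -> GlmFit:
    """Drop non-significant eliminable terms, preferring AIC-improving drops.

    At each step the candidates are the marginality-respecting terms with
    Wald p > alpha; the ``max_aic_candidates`` least-significant candidate
    removals are refit and the one with the lowest AIC is adopted.  Stops
    when every eliminable term is significant (or the model is empty,
    returning the flagged intercept-only fit).  Quasibinomial fits carry no
    AIC; candidates then fall back to largest-p-first.
    """
    refit = _REFITTERS[fit.family]
    data = _drop_absent(data)
    current = fit
    while current.terms:
        if not current.converged and "fit_failed" in current.flags:
            return current
        elim = eliminable_terms(current.terms)
        candidates = [
            t
            for t in elim
            if not np.isnan(current.term_pvalues.get(t.code, np.nan))
            and current.term_pvalues[t.code] > alpha
        ]
        if not candidates:
            break
        if current.aic is None:
            # quasibinomial: no AIC, fall back to largest-p-first
            cand = max(candidates, key=lambda t: current.term_pvalues[t.code])
            trial = refit(data, tuple(t for t in current.terms if t != cand))
            if "fit_failed" in trial.flags:
                break
            current = trial
            continue
        candidates = sorted(
            candidates, key=lambda t: -current.term_pvalues[t.code]
        )[:max_aic_candidates]
        best: tuple[float, ModelTerm, GlmFit] | None = None
        for cand in candidates:
            reduced_terms = tuple(t for t in current.terms if t != cand)
            trial = refit(data, reduced_terms)
            if "fit_failed" in trial.flags or trial.aic is None:
                continue
            if best is None or trial.aic < best[0]:
                best = (trial.aic, cand, trial)
        if best is None:
            break
        current = best[2]
    if not current.terms:
        current = replace(current, flags=current.flags + ("intercept_only",))
    return current


# ---------------------------------------------------------------------------
# Incidence model (binomial / quasibinomial)


def _fit_binomial_glmfit(
    df: pd.DataFrame, terms: tuple[ModelTerm, ...], scale=None
) -> GlmFit:
    formula = _formula(terms, "y")
    flags: list[str] = []
    family = sm.families.Binomial()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(formula, df, family=family)
        try:
            res = model.fit(scale=scale)
            converged = bool(res.converged)
        except Exception as exc:
            logger.warning("binomial fit failed for %s: %s", formula, exc)
            try:  # penalized fallback under (quasi-)separation
                res = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
                params = pd.Series(res.params, index=model.exog_names)
                nan = pd.Series(np.nan, index=model.exog_names)
                return GlmFit(
                    family="binomial",
                    link="logit",
                    formula=formula,
                    terms=terms,
                    params=params,
                    bse=nan,
                    pvalues=nan,
                    term_pvalues=pd.Series(np.nan, index=[t.code for t in terms]),
                    aic=None,
                    deviance=float("nan"),
                    null_deviance=float("nan"),
                    df_resid=len(df) - len(params),
                    converged=False,
                    flags=("separation_penalized",),
                )
            except Exception:
                raise
        term_p = _match_term_pvalues(res, terms) if terms else pd.Series(dtype=float)
    is_quasi = scale is not None
    dispersion = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan")
    if not converged:
        flags.append("irls_not_converged")
    return GlmFit(
        family="quasibinomial" if is_quasi else "binomial",
        link="logit",
        formula=formula,
        terms=terms,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        term_pvalues=term_p,
        aic=None if is_quasi else float(res.aic),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        df_resid=int(res.df_resid),
        converged=converged,
        dispersion=dispersion if is_quasi else None,
        flags=tuple(flags),
        result=res,
    )


_REFITTERS = {
    "negative_binomial": _fit_nb_glmfit,
    "binomial": _fit_binomial_glmfit,
    "quasibinomial": lambda df, terms: _fit_binomial_glmfit(df, terms, scale="X2"),
}


def fit_incidence_model(
    data: pd.DataFrame,
    design: CoinfestationDesign | None = None,
    alpha: float = 0.05,
    min_explained: float = 0.10,
    overdispersion_threshold: float = 1.5,
) -> GlmFit:
    """Binomial GLM of presence with maximal model SITE * s_x + PI_all_but_x.

    ``data`` carries ``y`` (0/1 presence per steer-month), ``season``,
    optionally ``site`` (omitted when a single site is modelled), and the
    design's columns.  The maximal fit is backward-eliminated, checked for
    overdispersion (quasibinomial refit past the threshold), and flagged
    ``not_considered`` when the minimal model explains less than
    ``min_explained`` of the null deviance.
    """
    if design is not None:
        data = design.augment(data)
    df = _drop_absent(data)
    with_site = "site" in df.columns and df["site"].nunique() > 1
    n_levels = df["season"].nunique() if "season" in df else 1
    terms = _build_terms(n_levels, design, with_site=with_site, season_interactions=False)
    fit = _fit_binomial_glmfit(df, terms)
    fit = backward_eliminate(fit, df, alpha=alpha)
    if fit.df_resid > 0 and np.isfinite(fit.deviance):
        ratio = fit.deviance / fit.df_resid
        if ratio > overdispersion_threshold:
            quasi = _fit_binomial_glmfit(df, fit.terms, scale="X2")
            quasi = backward_eliminate(quasi, df, alpha=alpha)
            fit = replace(quasi, flags=quasi.flags + ("overdispersed_refit",))
    if np.isfinite(fit.explained_deviance) and fit.explained_deviance < min_explained:
        fit = replace(fit, flags=fit.flags + ("not_considered",))
    return fit


@dataclass
class OverdispersionResult:
    ratio: float
    refit_needed: bool
    quasi_fit: GlmFit | None = None


def overdispersion_check(
    fit: GlmFit, data: pd.DataFrame | None = None, threshold: float = 1.5
) -> OverdispersionResult:
    """Residual deviance / residual df; quasibinomial refit past threshold."""
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ratio = fit.deviance / fit.df_resid
    if ratio <= threshold:
        return OverdispersionResult(ratio=ratio, refit_needed=False)
    quasi = None
    if data is not None:
        quasi = _fit_binomial_glmfit(_drop_absent(data), fit.terms, scale="X2")
    return OverdispersionResult(ratio=ratio, refit_needed=True, quasi_fit=quasi)


# ---------------------------------------------------------------------------
# Incidence estimates and dynamics correlations


def compute_incidence(
    presence: pd.DataFrame, keys: list[str], taxa: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Proportion of steer-month records with presence = 1 within each group."""
    codes = [SHORT_CODE[t] for t in ANALYSIS_TAXA] if taxa is None else [
        SHORT_CODE.get(t, t) for t in taxa
    ]
    codes = [c for c in codes if c in presence.columns]
    grouped = presence.groupby(keys)[codes]
    out = grouped.mean()
    out["n"] = grouped.size()
    return out.reset_index()


def correlate_dynamics(series_a, series_b) -> tuple[float, float]:
    """Pearson r (two-sided p) between two aligned monthly series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 3:
        raise ValueError("need at least 3 paired months")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(a, b)
    return (float(r), float(p))
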