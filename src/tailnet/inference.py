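"""Statistical layer: screens, rank tests, mixed models, and odds models.

The analysis treats each pen as an independent replicate network.  The
workflow is:

1. **Correlation screen** — pairwise Pearson correlations among candidate
   network metrics; of any pair with |r| above a threshold (default 0.8)
   one member is dropped, preferring to drop the unweighted twin of a
   weighted metric.
2. **Kruskal-Wallis rank-sum tests** (tie-corrected) for litter-origin
   effects on non-normal metrics, with a pooled-rank pairwise post hoc.
3. **Linear mixed models** (REML) per metric with pen (and pig nested in
   pen, for pig-level repeated measures) as random effects; results as
   estimated marginal means (EMMs) with Tukey-adjusted pairwise
   treatment contrasts.
4. **Proportional-odds model** for the ordinal maximal tail score on
   pig-level network metrics (no pen random effect), with a
   proportional-odds diagnostic; odds ratios withheld when it fails.
5. **Mixed-effects binomial logit** for victimization (MTS >= 2) with a
   pen random intercept, fitted by variational Bayes.
6. **AIC comparison** of candidate models on identical rows.

EMMs average model predictions over the levels of the other factors with
equal weights, so on balanced designs they equal arithmetic cell means.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.regression.mixed_linear_model import MixedLM

from .data import ValidationError
from .glmm import fit_logit_random_intercept

__all__ = [
    "FitResult",
    "assign_size_classes",
    "aggregate_size_class",
    "correlation_screen",
    "kruskal_wallis",
    "KruskalWallisResult",
    "fit_metric_lmm",
    "fit_ordinal_mts",
    "fit_victim_logit",
    "compare_models_aic",
]

SIZE_CLASSES = ("small", "medium", "large")


# ---------------------------------------------------------------------------
# Size classes


def assign_size_classes(weights: Mapping[str, float]) -> dict[str, str]:
    """Relative within-pen weight ranking: small / medium / large.

    For the standard 8-pig pen the split is 3 lightest = small, middle
    2 = medium, 3 heaviest = large.  Other pen sizes split proportionally
    37.5 / 25 / 37.5 % with round-half-up on the outer groups (the middle
    group absorbs the remainder).  Weight ties break by pig_id order.
    """
    pigs = sorted(weights, key=lambda p: (weights[p], p))
    n = len(pigs)
    if n == 0:
        raise ValidationError("cannot rank an empty pen")
    n_small = int(np.floor(0.375 * n + 0.5))
    n_large = int(np.floor(0.375 * n + 0.5))
    if n_small + n_large > n:
        n_large = n - n_small
    out: dict[str, str] = {}
    for i, pig in enumerate(pigs):
        if i < n_small:
            out[pig] = "small"
        elif i >= n - n_large:
            out[pig] = "large"
        else:
            out[pig] = "medium"
    return out


def aggregate_size_class(classes_by_period: Sequence[str]) -> str:
    """Modal class across periods; ties resolve to the middle period."""
    if not classes_by_period:
        raise ValidationError("no per-period classes to aggregate")
    counts = {c: classes_by_period.count(c) for c in set(classes_by_period)}
    best = max(counts.values())
    winners = [c for c, k in counts.items() if k == best]
    if len(winners) == 1:
        return winners[0]
    return classes_by_period[len(classes_by_period) // 2]


# ---------------------------------------------------------------------------
# Correlation screen

_UNWEIGHTED_TWIN = {
    "degree": "strength",
    "in_degree": "in_strength",
    "out_degree": "out_strength",
}


def correlation_screen(
    table: pd.DataFrame, metrics: Sequence[str], threshold: float = 0.8
) -> tuple[list[str], pd.DataFrame]:
    """Drop one member of every metric pair with |Pearson r| > threshold.

    When the pair is an (unweighted, weighted) twin, the unweighted
    member is dropped; otherwise the later-listed metric goes.  Constant
    columns have undefined correlations and are reported but retained.
    Returns (retained metrics, report of examined pairs).
    """
    if len(table) < 3:
        raise ValidationError("correlation screen needs at least 3 rows")
    report_rows = []
    dropped: set[str] = set()
    constant = {m for m in metrics if table[m].nunique() <= 1}
    for m1, m2 in combinations(metrics, 2):
        if m1 in constant or m2 in constant:
            report_rows.append(
                {"metric_a": m1, "metric_b": m2, "r": np.nan, "dropped": ""}
            )
            continue
        r = float(table[m1].corr(table[m2]))
        drop = ""
        if abs(r) > threshold and m1 not in dropped and m2 not in dropped:
            if _UNWEIGHTED_TWIN.get(m1) == m2:
                drop = m1
            elif _UNWEIGHTED_TWIN.get(m2) == m1:
                drop = m2
            else:
                drop = m2  # later-listed
            dropped.add(drop)
        report_rows.append({"metric_a": m1, "metric_b": m2, "r": r, "dropped": drop})
    retained = [m for m in metrics if m not in dropped]
    report = pd.DataFrame(report_rows, columns=["metric_a", "metric_b", "r", "dropped"])
    return retained, report


# ---------------------------------------------------------------------------
# Kruskal-Wallis with post hoc


@dataclass(frozen=True)
class KruskalWallisResult:
    H: float
    df: int
    p: float
    group_mean_ranks: dict[str, float]
    posthoc: pd.DataFrame


def kruskal_wallis(
    values: Sequence[float],
    groups: Sequence[str],
    adjust: str = "none",
) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H with pairwise rank post hoc.

    The post hoc compares pooled mean ranks with the rank-LSD criterion
    (t reference with N - k df, tie- and H-adjusted variance, as in the
    classical Conover procedure); ``adjust="bonferroni"`` multiplies the
    pairwise p-values by the number of pairs.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = sorted(set(g))
    if len(labels) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    if v.size < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 observations")
    samples = [v[g == lab] for lab in labels]
    if np.all(v == v[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*samples)
    N, k = v.size, len(labels)
    ranks = stats.rankdata(v)  # mid-ranks for ties
    mean_ranks = {lab: float(ranks[g == lab].mean()) for lab in labels}
    S2 = (np.sum(ranks**2) - N * (N + 1) ** 2 / 4) / (N - 1)
    rows = []
    n_pairs = k * (k - 1) // 2
    for a, b in combinations(labels, 2):
        na, nb = int(np.sum(g == a)), int(np.sum(g == b))
        diff = abs(mean_ranks[a] - mean_ranks[b])
        if N - k <= 0 or S2 <= 0:
            t_stat, pp = np.nan, np.nan
        else:
            se = np.sqrt(S2 * (N - 1 - H) / (N - k) * (1 / na + 1 / nb))
            t_stat = diff / se if se > 0 else np.inf
            pp = 2 * stats.t.sf(t_stat, N - k)
            if adjust == "bonferroni":
                pp = min(1.0, pp * n_pairs)
        rows.append(
            {"group_a": a, "group_b": b, "rank_diff": diff, "t": t_stat, "p": pp}
        )
    posthoc = pd.DataFrame(rows, columns=["group_a", "group_b", "rank_diff", "t", "p"])
    return KruskalWallisResult(
        H=float(H), df=k - 1, p=float(p), group_mean_ranks=mean_ranks, posthoc=posthoc
    )


# ---------------------------------------------------------------------------
# Fit results


@dataclass
class FitResult:
    """Uniform container for model fits.

    Coefficients and standard errors are on the model's link scale;
    ``odds_ratios`` (logit-scale models) exponentiates them with 95 %
    CIs.  ``emm`` and ``contrasts`` are populated for mixed linear
    models.  ``data_hash`` fingerprints the analyzed rows so AIC
    comparisons can verify they ran on identical data.
    """

    description: str
    formula: str
    params: pd.Series
    se: pd.Series
    aic: float
    nobs: int
    converged: bool
    data_hash: str
    odds_ratios: pd.DataFrame | None = None
    emm: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)


def _hash_frame(df: pd.DataFrame) -> str:
    payload = pd.util.hash_pandas_object(df.reset_index(drop=True), index=False).values
    return hashlib.sha256(payload.tobytes()).hexdigest()[:16]


def _wald_or_table(params: pd.Series, se: pd.Series, names: Sequence[str]) -> pd.DataFrame:
    rows = []
    for name in names:
        est, s = float(params[name]), float(se[name])
        rows.append(
            {
                "term": name,
                "estimate": est,
                "odds_ratio": float(np.exp(est)),
                "ci_low": float(np.exp(est - 1.96 * s)),
                "ci_high": float(np.exp(est + 1.96 * s)),
                "p": float(2 * stats.norm.sf(abs(est / s))) if s > 0 else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["term", "estimate", "odds_ratio", "ci_low", "ci_high", "p"]
    )


# ---------------------------------------------------------------------------
# Linear mixed models with EMMs and Tukey contrasts


def _emm_grid(
    data: pd.DataFrame, factors: Sequence[str], covariates: Sequence[str],
    focus: str, level,
) -> pd.DataFrame:
    """Reference grid: focus factor pinned, others crossed with equal
    weight, numeric covariates at their observed means."""
    others = [f for f in factors if f != focus]
    level_sets = [sorted(data[f].unique()) for f in others]
    rows = []
    for combo in product(*level_sets) if others else [()]:
        row = {focus: level}
        row.update(dict(zip(others, combo)))
        for c in covariates:
            row[c] = float(data[c].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def fit_metric_lmm(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str] = ("treatment",),
    covariates: Sequence[str] = (),
    group: str = "pen_id",
    nested: str | None = None,
    focus: str = "treatment",
    sqrt_transform: bool = False,
) -> FitResult:
    """REML linear mixed model for one network metric.

    ``group`` is the random-intercept grouping (pen); ``nested`` adds a
    second variance component (pig within pen) for pig-level repeated
    measures.  ``sqrt_transform`` square-roots the response first (used
    for skewed association-network betweenness).  EMMs for ``focus`` are
    equal-weight averages over the other factor levels; all pairwise
    focus contrasts carry Tukey-style adjusted p-values from the
    studentized-range distribution with containment df
    (n_groups - n_focus_levels).
    """
    df = table.dropna(subset=[response]).copy()
    if sqrt_transform:
        if (df[response] < 0).any():
            raise ValidationError("cannot square-root a negative response")
        df["_y"] = np.sqrt(df[response])
    else:
        df["_y"] = df[response].astype(float)
    terms = [f"C({f})" for f in factors] + list(covariates)
    formula = "_y ~ " + (" + ".join(terms) if terms else "1")
    vc = {"nested": f"0 + C({nested})"} if nested else None
    model = MixedLM.from_formula(
        formula, data=df, groups=df[group], re_formula="1", vc_formula=vc
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    converged = bool(res.converged) and not np.any(np.isnan(res.bse_fe))
    fe_names = list(res.fe_params.index)
    k_params = len(fe_names) + res.cov_re.shape[0] + (len(vc) if vc else 0) + 1
    aic = float(-2 * res.llf + 2 * k_params)

    design_info = model.data.design_info
    levels = sorted(df[focus].unique())
    cov_fe = res.cov_params().loc[fe_names, fe_names].to_numpy()
    emm_rows, lvecs = [], {}
    n_groups = df[group].nunique()
    dof = max(n_groups - len(levels), 1)
    for lev in levels:
        grid = _emm_grid(df, factors, covariates, focus, lev)
        X = np.asarray(patsy.build_design_matrices([design_info], grid)[0])
        L = X.mean(axis=0)
        lvecs[lev] = L
        est = float(L @ res.fe_params.to_numpy())
        se = float(np.sqrt(L @ cov_fe @ L))
        tcrit = stats.t.ppf(0.975, dof)
        emm_rows.append(
            {
                "level": lev,
                "emm": est,
                "se": se,
                "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se,
            }
        )
    contrast_rows = []
    for a, b in combinations(levels, 2):
        L = lvecs[a] - lvecs[b]
        est = float(L @ res.fe_params.to_numpy())
        se = float(np.sqrt(L @ cov_fe @ L))
        tval = est / se if se > 0 else np.inf
        # Tukey: studentized-range reference, q = |t| * sqrt(2)
        p_adj = float(stats.studentized_range.sf(abs(tval) * np.sqrt(2), len(levels), dof))
        contrast_rows.append(
            {"level_a": a, "level_b": b, "estimate": est, "se": se, "t": tval,
             "df": dof, "p_tukey": p_adj}
        )
    return FitResult(
        description=f"LMM {response}" + (" (sqrt)" if sqrt_transform else ""),
        formula=formula + f" + (1|{group})" + (f" + (1|{group}:{nested})" if nested else ""),
        params=res.fe_params,
        se=res.bse_fe,
        aic=aic,
        nobs=int(res.nobs),
        converged=converged,
        data_hash=_hash_frame(df.drop(columns="_y")),
        emm=pd.DataFrame(emm_rows),
        contrasts=pd.DataFrame(contrast_rows),
        diagnostics={"singular": bool(np.any(np.diag(res.cov_re) < 1e-8))},
    )


# ---------------------------------------------------------------------------
# Proportional-odds model for MTS


def fit_ordinal_mts(
    table: pd.DataFrame,
    metrics: Sequence[str],
    factors: Sequence[str] = ("treatment", "sex"),
    response: str = "mts",
    sqrt_metrics: Sequence[str] = (),
    collapse_sparse_levels: bool = False,
) -> FitResult:
    """Proportional-odds (cumulative logit) model for the ordinal MTS.

    Continuous network metrics enter per-unit; odds ratios > 1 mean
    higher odds of a more severe score.  No pen random effect is
    included.  A likelihood-ratio diagnostic against the unconstrained
    multinomial logit probes the proportional-odds assumption; when it
    fails (p < 0.05) the odds ratios are withheld
    (``diagnostics["proportional_odds_ok"]`` is False and
    ``odds_ratios`` is None).
    """
    df = table.dropna(subset=[response, *metrics]).copy()
    for m in sqrt_metrics:
        df[m] = np.sqrt(df[m])
    y = df[response].astype(int)
    if collapse_sparse_levels:
        y = y.clip(upper=2)
    if y.nunique() < 2:
        raise ValidationError("ordinal response has a single observed level")
    df["_mts"] = pd.Categorical(y, categories=sorted(y.unique()), ordered=True)
    terms = list(metrics) + [f"C({f})" for f in factors]
    formula = "_mts ~ " + " + ".join(terms) if terms else "_mts ~ 1"
    model = OrderedModel.from_formula(formula, data=df, distr="logit")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    if not res.mle_retvals.get("converged", False):
        raise ValidationError(
            "proportional-odds fit failed to converge (possible complete separation)"
        )
    slope_names = [n for n in res.params.index if "/" not in n]
    po_p = _proportional_odds_lr_test(df, terms, y, float(res.llf))
    po_ok = bool(np.isnan(po_p) or po_p >= 0.05)
    or_table = _wald_or_table(res.params, res.bse, slope_names) if po_ok else None
    return FitResult(
        description="proportional-odds MTS model",
        formula=formula,
        params=res.params,
        se=res.bse,
        aic=float(res.aic),
        nobs=int(res.nobs),
        converged=True,
        data_hash=_hash_frame(df.drop(columns="_mts")),
        odds_ratios=or_table,
        diagnostics={"proportional_odds_ok": po_ok, "proportional_odds_p": po_p},
    )


def _proportional_odds_lr_test(
    df: pd.DataFrame, terms: Sequence[str], y: pd.Series, llf_po: float
) -> float:
    """LR test of the cumulative-logit model against multinomial logit."""
    import warnings

    import statsmodels.api as sm

    try:
        X = patsy.dmatrix(" + ".join(terms) if terms else "1", df, return_type="dataframe")
        codes = y.astype("category").cat.codes
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mn = sm.MNLogit(codes, X).fit(method="bfgs", maxiter=500, disp=False)
        J = y.nunique()
        k_slopes = X.shape[1] - 1
        extra_df = (J - 2) * k_slopes
        if extra_df <= 0 or not np.isfinite(mn.llf):
            return np.nan
        lr = 2 * (mn.llf - llf_po)
        return float(stats.chi2.sf(max(lr, 0.0), extra_df))
    except Exception:
        return np.nan


# ---------------------------------------------------------------------------
# Mixed-effects binomial logit for victimization


def fit_victim_logit(
    table: pd.DataFrame,
    metrics: Sequence[str],
    factors: Sequence[str] = (),
    use_association_metrics: bool = False,
    response: str = "victim",
    group: str = "pen_id",
) -> FitResult:
    """Binomial logit for victim status with a pen random intercept.

    Fitted by marginal maximum likelihood (Gauss-Hermite quadrature over
    the pen effect); odds ratios carry Wald 95 % intervals.  The
    association-network variant square-root-transforms betweenness
    before fitting.
    """
    df = table.dropna(subset=[response, *metrics]).copy()
    y = df[response].astype(int)
    if y.nunique() < 2:
        raise ValidationError("victim response is constant (all or no victims)")
    if use_association_metrics and "betweenness" in metrics:
        df["betweenness"] = np.sqrt(df["betweenness"])
    terms = list(metrics) + [f"C({f})" for f in factors]
    formula = " + ".join(terms) if terms else "1"
    X = patsy.dmatrix(formula, df, return_type="dataframe")
    res = fit_logit_random_intercept(
        y.to_numpy(), X.to_numpy(), df[group].to_numpy()
    )
    params = pd.Series(res.params, index=list(X.columns))
    se = pd.Series(res.se, index=list(X.columns))
    slope_names = [n for n in X.columns if n != "Intercept"]
    return FitResult(
        description="victimization mixed logit"
        + (" (association metrics)" if use_association_metrics else ""),
        formula=f"{response} ~ {formula} + (1|{group})",
        params=params,
        se=se,
        aic=res.aic,
        nobs=len(df),
        converged=res.converged,
        data_hash=_hash_frame(df),
        odds_ratios=_wald_or_table(params, se, slope_names),
        diagnostics={"sigma_pen": res.sigma_u, "n_pens": res.n_groups},
    )


# ---------------------------------------------------------------------------
# AIC comparison


def compare_models_aic(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank candidate fits by AIC (ascending) with delta-AIC.

    Requires at least two fits on identical data rows.
    """
    if len(fits) < 2:
        raise ValidationError("AIC comparison needs at least 2 fits")
    nobs = {f.nobs for f in fits}
    if len(nobs) != 1:
        raise ValidationError("fits were computed on differing row counts")
    hashes = {f.data_hash for f in fits}
    if len(hashes) != 1:
        raise ValidationError("fits were computed on differing data rows")
    rows = sorted(fits, key=lambda f: (np.isnan(f.aic), f.aic))
    best = rows[0].aic
    return pd.DataFrame(
        [
            {
                "description": f.description,
                "formula": f.formula,
                "aic": f.aic,
                "delta_aic": f.aic - best,
            }
            for f in rows
        ]
    )
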