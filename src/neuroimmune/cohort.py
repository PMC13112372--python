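"""Clinical-cohort statistics for peripheral inflammation indices.

Implements the clinical arm of the analysis: record-level gating,
derivation of NLR / SII / CRP from complete blood counts, Table-1-style
group summaries (Shapiro–Wilk gate choosing Welch t vs Mann–Whitney;
chi-square for categoricals), Z-standardized covariate-adjusted
per-marker logistic models, restricted-cubic-spline dose–response
curves, ROC analysis with a combined marker panel, and the mouse
phenotype group statistics / Pearson correlations.

Groups: ``SeLECTS`` (self-limited epilepsy with centrotemporal spikes,
the benign control) vs ``DRE`` (drug-resistant epilepsy, the outcome of
interest); logistic models code DRE = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_FIELDS",
    "DEFAULT_WBC_LIMITS",
    "GatingResult",
    "apply_gating",
    "compute_indices",
    "VariableSummary",
    "summarize_cohort",
    "zscore",
    "LogisticFit",
    "fit_logistic",
    "rcs_basis",
    "RCSCurve",
    "rcs_dose_response",
    "ROCResult",
    "roc_auc",
    "combined_panel",
    "mouse_group_stats",
    "pearson_correlation",
]

REQUIRED_FIELDS = (
    "group",
    "age_onset_years",
    "sex",
    "bmi",
    "wbc",
    "neutrophil_pct",
    "lymphocyte_pct",
    "platelets",
    "crp",
)

# Conservative pediatric upper reference limits for total WBC (10^9/L),
# keyed by exclusive age upper bound in years.
DEFAULT_WBC_LIMITS: tuple[tuple[float, float], ...] = (
    (1.0, 17.5),
    (2.0, 17.0),
    (6.0, 15.5),
    (12.0, 13.5),
    (15.0, 13.0),
)


def _wbc_limit(age: float, limits=DEFAULT_WBC_LIMITS) -> float:
    for upper, lim in limits:
        if age < upper:
            return lim
    return limits[-1][1]


@dataclass
class GatingResult:
    table: pd.DataFrame
    removed: dict = field(default_factory=dict)
    reasons: pd.Series | None = None


def apply_gating(
    records: pd.DataFrame,
    max_age: float = 14.0,
    wbc_limits=DEFAULT_WBC_LIMITS,
    exclusion_flags: tuple = ("acute_infection", "hematologic_disorder", "steroid_exposure"),
) -> GatingResult:
    """Record-level inclusion/exclusion gating.

    Rules: age <= ``max_age`` (an ``age_years`` column is used when
    present, otherwise ``age_onset_years``); total WBC within the
    age-band upper limit; any truthy exclusion-flag column removes the
    record; records missing a required field are rejected with reason
    ``missing_field``.  Per-rule removal counts are returned.
    """
    df = records.copy()
    removed = {"missing_field": 0, "age": 0, "wbc_limit": 0}
    for flag in exclusion_flags:
        removed[flag] = 0
    reasons = pd.Series("", index=df.index, dtype=object)

    for idx, row in df.iterrows():
        missing = [f for f in REQUIRED_FIELDS if f not in row or pd.isna(row[f])]
        if missing:
            reasons[idx] = "missing_field"
            removed["missing_field"] += 1
            continue
        age = row["age_years"] if "age_years" in row and pd.notna(row.get("age_years")) else row["age_onset_years"]
        if age > max_age:
            reasons[idx] = "age"
            removed["age"] += 1
            continue
        if row["wbc"] > _wbc_limit(float(age), wbc_limits):
            reasons[idx] = "wbc_limit"
            removed["wbc_limit"] += 1
            continue
        for flag in exclusion_flags:
            if flag in row and bool(row[flag]):
                reasons[idx] = flag
                removed[flag] += 1
                break
    kept = df.loc[reasons == ""]
    return GatingResult(table=kept, removed=removed, reasons=reasons)


def compute_indices(records: pd.DataFrame) -> pd.DataFrame:
    """Derive NLR, SII (and pass CRP through) from CBC fields.

    absolute neutrophils = WBC x neutrophil% / 100 (likewise
    lymphocytes); NLR = neut/lymph; SII = platelets x neut/lymph.
    Adds pooled z-scored columns ``z_nlr``, ``z_sii``, ``z_crp``.
    A zero platelet count yields SII = 0 and sets ``implausible``.
    """
    df = records.copy()
    for col in ("wbc", "neutrophil_pct", "lymphocyte_pct", "platelets", "crp"):
        if col not in df:
            raise KeyError(f"missing required column: {col}")
    if (df["lymphocyte_pct"] <= 0).any() or (df["wbc"] <= 0).any():
        raise ValueError("zero or negative lymphocyte count; NLR undefined")
    abs_neut = df["wbc"] * df["neutrophil_pct"] / 100.0
    abs_lymph = df["wbc"] * df["lymphocyte_pct"] / 100.0
    df["abs_neutrophils"] = abs_neut
    df["abs_lymphocytes"] = abs_lymph
    df["nlr"] = abs_neut / abs_lymph
    df["sii"] = df["platelets"] * abs_neut / abs_lymph
    df["implausible"] = df["platelets"] <= 0
    for marker in ("nlr", "sii", "crp"):
        x = df[marker].to_numpy(dtype=float)
        # degenerate (tiny or constant) inputs get NaN z-scores, not an error
        if x.size >= 2 and np.ptp(x) > 0:
            df[f"z_{marker}"] = zscore(x)
        else:
            df[f"z_{marker}"] = np.nan
    return df


def zscore(values) -> np.ndarray:
    """(x - mean) / SD with ddof=1; rejects constant input."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("zscore needs n >= 2")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant input; z-score undefined")
    return (x - x.mean()) / sd


@dataclass
class VariableSummary:
    variable: str
    kind: str  # "normal", "skewed", "categorical"
    per_group: dict
    test: str
    p: float
    flag: str = ""


def _format_group(stats_dict, kind):
    if kind == "normal":
        return f"{stats_dict['mean']:.2f} ({stats_dict['sd']:.2f})"
    if kind == "skewed":
        return f"{stats_dict['median']:.2f} [{stats_dict['q25']:.2f}, {stats_dict['q75']:.2f}]"
    return ", ".join(f"{lvl}: {c} ({p:.1f})" for lvl, (c, p) in stats_dict.items())


def summarize_cohort(
    cohort: pd.DataFrame,
    group_col: str = "group",
    continuous: tuple = (
        "age_onset_years",
        "bmi",
        "wbc",
        "neutrophil_pct",
        "lymphocyte_pct",
        "platelets",
        "crp",
        "nlr",
        "sii",
    ),
    categorical: tuple = ("sex",),
    shapiro_alpha: float = 0.05,
) -> dict[str, VariableSummary]:
    """Table-1-style two-group summary.

    Continuous variables pass a per-group Shapiro–Wilk gate: if both
    groups look normal (p >= alpha) report mean (SD) and a Welch t-test,
    otherwise median [IQR] and Mann–Whitney U.  Categorical variables
    report counts (percentages) and a chi-square test (no continuity
    correction by default).
    """
    from scipy import stats

    groups = [g for g in pd.unique(cohort[group_col])]
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {groups}")
    g1, g2 = groups
    out: dict[str, VariableSummary] = {}

    for var in continuous:
        if var not in cohort:
            continue
        x1 = cohort.loc[cohort[group_col] == g1, var].dropna().to_numpy(dtype=float)
        x2 = cohort.loc[cohort[group_col] == g2, var].dropna().to_numpy(dtype=float)
        if np.ptp(x1) == 0 and np.ptp(x2) == 0:
            out[var] = VariableSummary(
                var, "skewed",
                {g1: _quantile_stats(x1), g2: _quantile_stats(x2)},
                "none", float("nan"), flag="constant",
            )
            continue
        normal = all(
            np.ptp(x) > 0 and stats.shapiro(x).pvalue >= shapiro_alpha for x in (x1, x2)
        )
        if normal:
            p = float(stats.ttest_ind(x1, x2, equal_var=False).pvalue)
            per_group = {
                g1: {"mean": x1.mean(), "sd": x1.std(ddof=1), "n": x1.size},
                g2: {"mean": x2.mean(), "sd": x2.std(ddof=1), "n": x2.size},
            }
            out[var] = VariableSummary(var, "normal", per_group, "welch_t", p)
        else:
            p = float(stats.mannwhitneyu(x1, x2, alternative="two-sided").pvalue)
            per_group = {g1: _quantile_stats(x1), g2: _quantile_stats(x2)}
            out[var] = VariableSummary(var, "skewed", per_group, "mann_whitney_u", p)

    for var in categorical:
        if var not in cohort:
            continue
        tab = pd.crosstab(cohort[var], cohort[group_col])
        per_group = {}
        for g in (g1, g2):
            counts = tab[g] if g in tab else pd.Series(0, index=tab.index)
            total = counts.sum()
            per_group[g] = {
                lvl: (int(counts[lvl]), 100.0 * counts[lvl] / total) for lvl in tab.index
            }
        if tab.shape[0] < 2:
            out[var] = VariableSummary(var, "categorical", per_group, "none",
                                       float("nan"), flag="single_level")
            continue
        chi2 = stats.chi2_contingency(tab.to_numpy(), correction=False)
        out[var] = VariableSummary(var, "categorical", per_group, "chi_square",
                                   float(chi2.pvalue))
    return out


def _quantile_stats(x: np.ndarray) -> dict:
    return {
        "median": float(np.median(x)),
        "q25": float(np.percentile(x, 25)),
        "q75": float(np.percentile(x, 75)),
        "n": int(x.size),
    }


@dataclass
class LogisticFit:
    """Per-coefficient log-odds, Wald SEs, ORs with 95% CI and p-values."""

    table: pd.DataFrame  # index term; estimate, se, or_, ci_low, ci_high, p
    marker: str
    covariates: tuple
    n: int
    linear_predictor: np.ndarray | None = None


def _encode_design(cohort: pd.DataFrame, terms, intercept: bool = True) -> pd.DataFrame:
    cols = {}
    if intercept:
        cols["intercept"] = np.ones(len(cohort))
    for t in terms:
        v = cohort[t]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.dropna().unique())
            if len(levels) != 2:
                raise ValueError(f"categorical covariate {t!r} must be binary")
            # code the lexicographically later level as 1 (male=1 for sex)
            cols[f"{t}[{levels[1]}]"] = (v == levels[1]).astype(float).to_numpy()
        else:
            cols[t] = v.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cohort.index)


def fit_logistic(
    cohort: pd.DataFrame,
    outcome: str,
    marker: str,
    covariates: tuple = ("age_onset_years", "sex", "bmi"),
    extra_design: pd.DataFrame | None = None,
) -> LogisticFit:
    """Covariate-adjusted logistic model for one (z-scored) marker.

    Maximum likelihood by IRLS (statsmodels GLM/Binomial, tol 1e-8,
    max 100 iterations); Wald SEs; 95% CI = exp(estimate +/- 1.96 SE).
    ``extra_design`` appends pre-built columns (e.g. a spline basis).
    Raises on single-class outcomes and on (quasi-)separation.
    """
    import statsmodels.api as sm

    work_cols = [outcome] + ([marker] if marker else []) + list(covariates)
    work = cohort[work_cols].copy()
    if extra_design is not None:
        work = pd.concat([work, extra_design], axis=1)
    work = work.dropna()
    y = work[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic model undefined")
    design = _encode_design(work, ([marker] if marker else []) + list(covariates))
    if extra_design is not None:
        design = pd.concat([design, work[extra_design.columns]], axis=1)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("singular design matrix")

    model = sm.GLM(y, design, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("separation detected: diverging coefficients")
    # diverging fits show up as huge effects on the per-SD scale
    col_sd = design.to_numpy().std(axis=0)
    effect = np.abs(params[col_sd > 0] * col_sd[col_sd > 0])
    if effect.size and effect.max() > 15:
        raise ValueError("separation detected: diverging coefficients")
    se = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(se)):
        raise ValueError("separation detected: non-finite standard errors")
    z = params / se
    from scipy import stats as _st

    p = 2.0 * _st.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "estimate": params,
            "se": se,
            "or_": np.exp(params),
            "ci_low": np.exp(params - 1.96 * se),
            "ci_high": np.exp(params + 1.96 * se),
            "p": p,
        },
        index=design.columns,
    )
    return LogisticFit(
        table=table,
        marker=marker,
        covariates=tuple(covariates),
        n=len(work),
        linear_predictor=design.to_numpy() @ params,
    )


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis with k knots.

    Returns ``len(x) x (k-1)`` columns: the linear term plus k-2
    nonlinear terms, constructed so the spline is linear beyond the
    boundary knots (Harrell parameterization).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing (no duplicates)")
    k = t.size
    tau = (t[-1] - t[0]) ** 2
    cols = [x]

    def cube(u):
        return np.where(u > 0, u**3, 0.0)

    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / tau
        cols.append(term)
    return np.column_stack(cols)


@dataclass
class RCSCurve:
    knots: np.ndarray
    grid: np.ndarray
    prob: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    fit: LogisticFit | None = None


def rcs_dose_response(
    cohort: pd.DataFrame,
    outcome: str,
    marker: str,
    covariates: tuple = ("age_onset_years", "sex", "bmi"),
    knot_quantiles: tuple = (0.05, 0.35, 0.65, 0.95),
    grid: np.ndarray | None = None,
) -> RCSCurve:
    """Restricted-cubic-spline logistic dose-response curve.

    Fits outcome ~ rcs(marker) + covariates and returns the predicted
    outcome probability over a marker grid at covariate reference
    values (continuous covariates at their mean, binary at the modal
    level), with pointwise 95% Wald CIs on the linear-predictor scale.
    """
    from scipy.special import expit

    x = cohort[marker].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"marker {marker!r} is constant")
    knots = np.quantile(x, knot_quantiles)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knot quantiles collapse to duplicate knots")
    basis = rcs_basis(x, knots)
    basis_df = pd.DataFrame(
        basis, index=cohort.index, columns=[f"rcs{j}" for j in range(basis.shape[1])]
    )
    lf = fit_logistic(cohort, outcome, marker="", covariates=covariates,
                      extra_design=basis_df)

    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    gbasis = rcs_basis(grid, knots)
    design_cols = lf.table.index.tolist()
    ref = {}
    for col in design_cols:
        if col == "intercept":
            ref[col] = 1.0
        elif col.startswith("rcs"):
            ref[col] = None  # filled from gbasis
        elif "[" in col:  # binary covariate at modal level
            base = col.split("[")[0]
            lvl = col.split("[")[1].rstrip("]")
            ref[col] = float((cohort[base] == lvl).mean() >= 0.5)
        else:
            ref[col] = float(cohort[col].mean())
    X = np.zeros((grid.size, len(design_cols)))
    for j, col in enumerate(design_cols):
        if col.startswith("rcs"):
            X[:, j] = gbasis[:, int(col[3:])]
        else:
            X[:, j] = ref[col]

    import statsmodels.api as sm

    # refit to recover the covariance matrix on the same design
    work = cohort[[outcome] + list(covariates)].join(basis_df).dropna()
    design = _encode_design(work, list(covariates))
    design = pd.concat([design, work[basis_df.columns]], axis=1)[design_cols]
    res = sm.GLM(work[outcome].to_numpy(dtype=float), design,
                 family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    eta = X @ np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    return RCSCurve(
        knots=knots,
        grid=grid,
        prob=expit(eta),
        ci_low=expit(eta - 1.96 * se),
        ci_high=expit(eta + 1.96 * se),
        fit=lf,
    )


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC via the Mann–Whitney U identity (midrank ties)."""
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1, False, True}:
        raise ValueError("labels must be binary 0/1")
    y = y.astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    sorted_s = s[order]
    sorted_y = y[order]
    # one operating point per distinct threshold
    distinct = np.r_[np.nonzero(np.diff(sorted_s))[0], sorted_s.size - 1]
    tp = np.cumsum(sorted_y)[distinct]
    fp = np.cumsum(~sorted_y)[distinct]
    thresholds = sorted_s[distinct]
    sens = np.r_[0.0, tp / n_pos]
    spec = np.r_[1.0, 1.0 - fp / n_neg]
    return ROCResult(
        thresholds=np.r_[np.inf, thresholds],
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
    )


def combined_panel(
    cohort: pd.DataFrame, outcome: str, markers: tuple = ("nlr", "sii", "crp")
) -> ROCResult:
    """ROC of the in-sample logistic linear predictor over z-scored markers."""
    import statsmodels.api as sm

    work = cohort[[outcome] + list(markers)].dropna()
    y = work[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    X = np.column_stack(
        [np.ones(len(work))] + [zscore(work[m].to_numpy()) for m in markers]
    )
    # drop duplicated marker columns to keep the design full rank
    _, keep = np.unique(np.round(X, 12), axis=1, return_index=True)
    keep = np.sort(keep)
    res = sm.GLM(y, X[:, keep], family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    lp = X[:, keep] @ np.asarray(res.params)
    return roc_auc(lp, y.astype(int))


def mouse_group_stats(
    table: pd.DataFrame,
    group_col: str = "genotype",
    markers: tuple = ("nlr", "crp", "il6", "pstat3"),
) -> pd.DataFrame:
    """Per-marker group means +/- SD with two-sided Welch t-tests."""
    from scipy import stats

    groups = list(pd.unique(table[group_col]))
    if len(groups) != 2:
        raise ValueError("exactly two genotypes required")
    g1, g2 = groups
    rows = []
    for m in markers:
        x1 = table.loc[table[group_col] == g1, m].to_numpy(dtype=float)
        x2 = table.loc[table[group_col] == g2, m].to_numpy(dtype=float)
        if min(x1.size, x2.size) < 3:
            raise ValueError("need n >= 3 per group")
        t = stats.ttest_ind(x1, x2, equal_var=False)
        rows.append(
            {
                "marker": m,
                f"{g1}_mean": x1.mean(),
                f"{g1}_sd": x1.std(ddof=1),
                f"{g2}_mean": x2.mean(),
                f"{g2}_sd": x2.std(ddof=1),
                "welch_t": float(t.statistic),
                "p": float(t.pvalue),
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a t-reference p-value (df = n - 2)."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
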