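"""Descriptive comparisons, logistic association models and dose-response.

Implements the association side of the analysis: quartile-stratified
descriptives (median/IQR with Kruskal-Wallis, counts with chi-square),
2x2 odds ratios with Woolf confidence intervals, maximum-likelihood
logistic models for the FI-Lab as a continuous (per 0.01-score) or
quartile exposure with crude and adjusted covariate sets, ordinal trend
tests across quartiles, a restricted-cubic-spline dose-response curve,
and per-item univariate screens (OR and C-statistic per deficit).

Logistic fits are delegated to statsmodels (Newton MLE, Wald inference);
design matrices are built explicitly here so the coding of every term
(reference levels, per-0.01 scaling) is unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .registry import ReferenceRegistry, default_registry
from .scoring import QUARTILE_LABELS, deficit_table
from .cohort import SEVERITY_SCORES

Z95 = stats.norm.ppf(0.975)

OUTCOMES = ("death_inhospital", "death_1yr")

#: adjustment sets used throughout the analysis
MODEL1_ADJUST = ("age", "gender")
MODEL2_ADJUST = ("age", "gender", "ethnicity", "ami_type", "troponin_t", "sofa")
#: adjustment used for the spline dose-response curves
SPLINE_ADJUST = ("age", "gender", "ethnicity", "ami_type", "sofa")


# ---------------------------------------------------------------------------
# 2x2 odds ratios


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cells: a exposed-dead, b exposed-alive, c reference-dead, d reference-alive."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be nonnegative")


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell


def or_from_2x2(table: ContingencyTable2x2) -> OddsRatioResult:
    """Cross-product odds ratio with the Woolf (log-scale Wald) 95% CI.

    Equals the crude logistic odds ratio for a single binary predictor.
    A zero cell triggers the Haldane-Anscombe continuity correction (0.5
    added to every cell), flagged in the result.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - Z95 * se), np.exp(np.log(or_) + Z95 * se)
    return OddsRatioResult(float(or_), float(lo), float(hi), corrected)


# ---------------------------------------------------------------------------
# model specification and fitting


@dataclass(frozen=True)
class ModelSpec:
    """What to regress: outcome, exposure coding, adjustment covariates.

    ``exposure`` is one of ``"filab_per001"`` (FI-Lab score scaled so the
    coefficient is per 0.01-score increase), ``"filab_quartile"`` (indicator
    terms vs Q1), ``"filab_trend"`` (quartile as ordinal 1-4),
    ``"item:<name>"`` (a single deficit indicator), a covariate/severity
    name, or ``None`` (adjustment terms only, e.g. a base severity model).
    ``age_per5`` reports the age term per 5 years.
    """

    outcome: str
    exposure: Optional[str] = "filab_per001"
    adjustment_set: tuple[str, ...] = ()
    age_per5: bool = False

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; expected one of {OUTCOMES}")


@dataclass
class ModelFit:
    """A fitted logistic model with Wald inference and in-sample predictions."""

    terms: list[str]
    coefficients: pd.Series
    covariance: pd.DataFrame
    or_table: pd.DataFrame  # term, estimate, OR, CI_low, CI_high, p
    predicted: pd.Series  # indexed like the complete-case rows used
    converged: bool
    n_used: int
    n_dropped: int

    def odds_ratio(self, term: str) -> tuple[float, float, float]:
        row = self.or_table.set_index("term").loc[term]
        return float(row["OR"]), float(row["CI_low"]), float(row["CI_high"])

    def p_value(self, term: str) -> float:
        return float(self.or_table.set_index("term").loc[term, "p"])


def _term_columns(cohort: pd.DataFrame, name: str, age_per5: bool) -> pd.DataFrame:
    """Expand one model term into its design column(s)."""
    if name == "age":
        scale = 5.0 if age_per5 else 1.0
        label = "age_per5" if age_per5 else "age"
        return pd.DataFrame({label: cohort["age"] / scale})
    if name == "gender":
        return pd.DataFrame({"male": (cohort["gender"] == "male").astype(float)})
    if name == "ethnicity":  # reference: Other
        return pd.DataFrame(
            {
                "ethnicity_White": (cohort["ethnicity"] == "White").astype(float),
                "ethnicity_Black": (cohort["ethnicity"] == "Black").astype(float),
            }
        )
    if name == "ami_type":
        return pd.DataFrame({"stemi": (cohort["ami_type"] == "STEMI").astype(float)})
    if name == "filab_per001":
        return pd.DataFrame({"filab_per001": cohort["fi_lab_score"] / 0.01})
    if name == "filab_quartile":
        q = cohort["fi_lab_quartile"]
        cols = {
            f"filab_{lab}": (q == lab).astype(float) for lab in QUARTILE_LABELS[1:]
        }
        out = pd.DataFrame(cols)
        out[q.isna()] = np.nan
        return out
    if name == "filab_trend":
        ordinal = cohort["fi_lab_quartile"].map(
            {lab: i + 1 for i, lab in enumerate(QUARTILE_LABELS)}
        )
        return pd.DataFrame({"filab_trend": ordinal.astype(float)})
    if name.startswith("item:"):
        raise ValueError("single-item terms must be expanded by the caller (per_item_screen)")
    if name in cohort.columns:  # numeric covariate or severity score
        return pd.DataFrame({name: pd.to_numeric(cohort[name])})
    raise KeyError(f"unknown model term {name!r}")


def build_design(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    """Outcome vector and design matrix (without intercept), full rows only kept later."""
    y = pd.to_numeric(cohort[spec.outcome]).astype(float)
    parts = []
    if spec.exposure is not None:
        parts.append(_term_columns(cohort, spec.exposure, spec.age_per5))
    for name in spec.adjustment_set:
        parts.append(_term_columns(cohort, name, spec.age_per5))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=cohort.index)
    return y, X


def fit_logistic(cohort: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Maximum-likelihood logistic fit with Wald 95% CIs on the OR scale.

    Complete-case: rows missing the outcome or any design column are
    dropped and counted in ``n_dropped``. Non-convergence or separation is
    flagged via ``converged`` rather than silently reported.
    """
    y, X = build_design(cohort, spec)
    mask = y.notna() & X.notna().all(axis=1)
    n_dropped = int((~mask).sum())
    y, X = y[mask], X[mask]
    if y.nunique() < 2:
        raise ValueError("outcome has a single class after complete-case filtering")
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            # singular Hessian under (quasi-)separation: fall back to a
            # gradient method so the flagged fit still carries estimates
            res = model.fit(method="bfgs", disp=0, maxiter=500, gtol=1e-4)
            converged = False
    params = res.params
    try:
        raw_cov = np.asarray(res.cov_params())
        if not np.all(np.isfinite(raw_cov)):
            raise np.linalg.LinAlgError
    except Exception:
        raw_cov = np.full((len(params), len(params)), np.nan)
        converged = False
    # absurd standard errors also signal (quasi-)separation
    if converged and np.any(np.sqrt(np.diag(raw_cov)) > 50):
        converged = False
    cov = pd.DataFrame(raw_cov, index=params.index, columns=params.index)
    se = np.sqrt(np.diag(cov))
    terms = [t for t in params.index if t != "const"]
    rows = []
    for t, est, s in zip(params.index, params.values, se):
        if t == "const":
            continue
        rows.append(
            {
                "term": t,
                "estimate": est,
                "OR": np.exp(est),
                "CI_low": np.exp(est - Z95 * s),
                "CI_high": np.exp(est + Z95 * s),
                "p": 2 * stats.norm.sf(abs(est / s)),
            }
        )
    or_table = pd.DataFrame(rows, columns=["term", "estimate", "OR", "CI_low", "CI_high", "p"])
    predicted = pd.Series(res.predict(Xc), index=y.index).clip(1e-12, 1 - 1e-12)
    return ModelFit(
        terms=terms,
        coefficients=params,
        covariance=cov,
        or_table=or_table,
        predicted=predicted,
        converged=converged,
        n_used=int(mask.sum()),
        n_dropped=n_dropped,
    )


def trend_test(cohort: pd.DataFrame, spec: ModelSpec) -> float:
    """P for trend: quartile entered as a single ordinal term (1..4), Wald p."""
    tspec = ModelSpec(
        outcome=spec.outcome,
        exposure="filab_trend",
        adjustment_set=spec.adjustment_set,
        age_per5=spec.age_per5,
    )
    fit = fit_logistic(cohort, tspec)
    return fit.p_value("filab_trend")


# ---------------------------------------------------------------------------
# descriptives


_DEFAULT_CONTINUOUS = ("age", "troponin_t", "fi_lab_score", *SEVERITY_SCORES)
_DEFAULT_CATEGORICAL = ("gender", "ethnicity", "ami_type", "death_inhospital", "death_1yr")


def describe_by_group(
    cohort: pd.DataFrame,
    group: str = "fi_lab_quartile",
    continuous: Sequence[str] = _DEFAULT_CONTINUOUS,
    categorical: Sequence[str] = _DEFAULT_CATEGORICAL,
) -> pd.DataFrame:
    """Quartile-stratified baseline table.

    Continuous variables: median (25th-75th percentile) per group with a
    Kruskal-Wallis H test. Categorical variables: n (%) per group and level
    with a Pearson chi-square test.
    """
    groups = [g for g in QUARTILE_LABELS if (cohort[group] == g).any()]
    if not groups:
        raise ValueError(f"no populated groups in column {group!r}")
    rows = []
    for var in continuous:
        samples = [
            pd.to_numeric(cohort.loc[cohort[group] == g, var]).dropna() for g in groups
        ]
        if any(len(s) == 0 for s in samples):
            raise ValueError(f"empty group for variable {var!r}")
        try:
            _, p = stats.kruskal(*samples)
        except ValueError:  # all numbers identical across groups: no rank information
            p = 1.0
        cells = {
            g: f"{s.median():.2f} ({s.quantile(0.25):.2f}-{s.quantile(0.75):.2f})"
            for g, s in zip(groups, samples)
        }
        rows.append({"variable": var, "level": "", **cells, "p": p})
    for var in categorical:
        tab = pd.crosstab(cohort[var], cohort[group])
        tab = tab[[g for g in groups if g in tab.columns]]
        if tab.shape[0] > 1:
            _, p, _, _ = stats.chi2_contingency(tab.to_numpy())
        else:
            p = 1.0
        totals = tab.sum(axis=0)
        for level, counts in tab.iterrows():
            cells = {
                g: f"{int(counts[g])} ({100 * counts[g] / totals[g]:.1f}%)" for g in tab.columns
            }
            rows.append({"variable": var, "level": str(level), **cells, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# restricted cubic spline dose-response


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted (natural) cubic spline basis, linear beyond the end knots.

    With k knots t_1 < ... < t_k the basis is x plus k-2 truncated-cubic
    terms constrained to be linear in the tails, each normalized by
    (t_k - t_1)^2 so coefficients stay on a comparable scale.
    """
    t = np.asarray(knots, dtype=float)
    if len(t) < 3 or np.any(np.diff(t) <= 0):
        raise ValueError("need at least 3 strictly increasing knots")
    x = np.asarray(x, dtype=float)
    denom = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(len(t) - 2):
        cub = lambda u: np.clip(u, 0.0, None) ** 3
        term = (
            cub(x - t[j])
            - cub(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cub(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / denom)
    return np.column_stack(cols)


def rcs_dose_response(
    cohort: pd.DataFrame,
    outcome: str = "death_inhospital",
    adjustment_set: Sequence[str] = SPLINE_ADJUST,
    reference: Optional[float] = None,
    knot_quantiles: Sequence[float] = (0.10, 0.50, 0.90),
    n_grid: int = 101,
) -> pd.DataFrame:
    """Spline dose-response of mortality odds against the FI-Lab score.

    Fits a logistic model with a restricted-cubic-spline expansion of the
    FI-Lab (default 3 knots at the 10th/50th/90th percentiles) plus the
    adjustment covariates, then reports the odds ratio relative to the
    reference score (default: the cohort 25th percentile) on an even grid
    spanning the observed score range, with a delta-method 95% band.
    """
    score = pd.to_numeric(cohort["fi_lab_score"])
    obs = score.dropna()
    if reference is None:
        reference = float(obs.quantile(0.25))
    if not (obs.min() <= reference <= obs.max()):
        raise ValueError(
            f"reference {reference} outside observed score range "
            f"[{obs.min():.3f}, {obs.max():.3f}]"
        )
    knots = obs.quantile(list(knot_quantiles)).to_numpy()

    spline = rcs_basis(score.to_numpy(), knots)
    spline_cols = [f"filab_rcs{i}" for i in range(spline.shape[1])]
    work = cohort.copy()
    for i, c in enumerate(spline_cols):
        work[c] = spline[:, i]

    y = pd.to_numeric(work[outcome]).astype(float)
    parts = [work[spline_cols]]
    for name in adjustment_set:
        parts.append(_term_columns(work, name, age_per5=False))
    X = pd.concat(parts, axis=1)
    mask = y.notna() & X.notna().all(axis=1)
    Xc = sm.add_constant(X[mask], has_constant="add")
    res = sm.Logit(y[mask], Xc).fit(disp=0, maxiter=200)

    beta = res.params[spline_cols].to_numpy()
    cov = pd.DataFrame(res.cov_params(), index=res.params.index, columns=res.params.index)
    cov_s = cov.loc[spline_cols, spline_cols].to_numpy()

    grid = np.linspace(obs.min(), obs.max(), n_grid)
    b_grid = rcs_basis(grid, knots)
    b_ref = rcs_basis(np.array([reference]), knots)
    diff = b_grid - b_ref  # basis contrast vs the reference score
    log_or = diff @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", diff, cov_s, diff))
    return pd.DataFrame(
        {
            "fi_lab_score": grid,
            "odds_ratio": np.exp(log_or),
            "ci_low": np.exp(log_or - Z95 * se),
            "ci_high": np.exp(log_or + Z95 * se),
            "reference": reference,
        }
    )


# ---------------------------------------------------------------------------
# per-item univariate screens


def per_item_screen(
    cohort: pd.DataFrame,
    outcome: str = "death_inhospital",
    registry: Optional[ReferenceRegistry] = None,
) -> pd.DataFrame:
    """Univariate OR and C-statistic of each item's deficit for mortality.

    For every registry item the deficit indicator is cross-tabulated with
    the outcome (Woolf CI; Haldane correction on zero cells, flagged) and
    its single-item discrimination is the rank-based C-statistic. Items
    with no variance among complete pairs are flagged and skipped.
    """
    from .incremental import c_statistic

    registry = registry or default_registry()
    defs = deficit_table(cohort, registry)
    y = pd.to_numeric(cohort[outcome]).astype(float)
    rows = []
    for name in registry.names:
        d = defs[name]
        mask = d.notna() & y.notna()
        dd, yy = d[mask].astype(int), y[mask].astype(int)
        if dd.nunique() < 2 or yy.nunique() < 2:
            rows.append(
                {"item": name, "n": int(mask.sum()), "OR": np.nan, "CI_low": np.nan,
                 "CI_high": np.nan, "c_statistic": np.nan, "flag": "zero_variance"}
            )
            continue
        a = int(((dd == 1) & (yy == 1)).sum())
        b = int(((dd == 1) & (yy == 0)).sum())
        c = int(((dd == 0) & (yy == 1)).sum())
        dcell = int(((dd == 0) & (yy == 0)).sum())
        orr = or_from_2x2(ContingencyTable2x2(a, b, c, dcell))
        cstat, _ = c_statistic(dd.to_numpy(float), yy.to_numpy())
        rows.append(
            {"item": name, "n": int(mask.sum()), "OR": orr.odds_ratio,
             "CI_low": orr.ci_low, "CI_high": orr.ci_high, "c_statistic": cstat,
             "flag": "haldane" if orr.corrected else ""}
        )
    return pd.DataFrame(rows)
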