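"""Incremental predictive value: paired C-statistics, DeLong, IDI, NRI.

Measures what the FI-Lab adds on top of each ICU disease-severity score
(SOFA, APS III, SAPS II, LODS, OASIS, SIRS). For each score and outcome a
base logistic model (score only) and an augmented model (score + FI-Lab
continuous) are fit on the same records; the gain is summarized by

* the change in C-statistic (AUROC) with DeLong's structural-component
  variance for the paired difference and a two-sided normal p-value;
* the integrated discrimination improvement (IDI): the change in mean
  predicted risk separation between events and non-events, identical to
  the change in discrimination slope;
* the category-free net reclassification improvement (NRI): the net
  proportion of events whose predicted risk rises plus the net proportion
  of non-events whose risk falls (exact ties count toward neither).

The C-statistic is the rank-based (Mann-Whitney) estimator with ties
credited one half; all confidence intervals are normal-approximation,
with a stratified bootstrap available for IDI/NRI as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import ModelSpec, fit_logistic
from .cohort import SEVERITY_SCORES

Z95 = stats.norm.ppf(0.975)


@dataclass
class PairedPredictions:
    """Predicted risks from a base and an augmented model on the same records."""

    labels: np.ndarray
    p_base: np.ndarray
    p_new: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels).astype(int)
        self.p_base = np.asarray(self.p_base, dtype=float)
        self.p_new = np.asarray(self.p_new, dtype=float)
        if not (len(self.labels) == len(self.p_base) == len(self.p_new)):
            raise ValueError("labels, p_base and p_new must have identical length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        for name, p in (("p_base", self.p_base), ("p_new", self.p_new)):
            if np.any((p <= 0) | (p >= 1)):
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        if self.n_events < 1 or self.n_nonevents < 1:
            raise ValueError("need at least one event and one non-event")

    @property
    def n_events(self) -> int:
        return int(self.labels.sum())

    @property
    def n_nonevents(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass
class IncrementalResult:
    """One base-vs-augmented comparison, one row of the incremental table."""

    base_score: str
    outcome: str
    c_base: float
    c_base_ci: tuple[float, float]
    c_new: float
    c_new_ci: tuple[float, float]
    delta_c: float
    p_delta: float
    idi: float
    idi_ci: tuple[float, float]
    nri: float
    nri_ci: tuple[float, float]
    n: int


# ---------------------------------------------------------------------------
# C-statistic and the DeLong machinery


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _placements(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong placement values (structural components).

    V10[i] for event i is the fraction of non-events it outranks (ties
    half); V01[j] symmetric for non-events. The AUC is the mean of either.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute a C-statistic")
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r = _midranks(pos)
    neg_r = _midranks(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = v10.mean()
    return auc, v10, v01


def c_statistic(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, tuple[float, float]]:
    """Rank-based AUROC with a DeLong-variance 95% CI, clipped to [0, 1].

    C = P(score_event > score_nonevent) + 0.5 P(tie) over all pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (v01.var(ddof=1) / n if n > 1 else 0.0)
    half = Z95 * np.sqrt(var)
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def delong_compare(pred: PairedPredictions) -> tuple[float, float, float]:
    """DeLong test for the paired AUC difference: (delta_c, var, p two-sided).

    The variance of C_new - C_base uses the placement-value covariance
    across the two score vectors, which accounts for both models being
    evaluated on the same subjects.
    """
    auc_b, v10_b, v01_b = _placements(pred.p_base, pred.labels)
    auc_n, v10_n, v01_n = _placements(pred.p_new, pred.labels)
    m, n = pred.n_events, pred.n_nonevents
    s10 = np.cov(np.vstack([v10_n, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_n, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n  # 2x2 covariance of (C_new, C_base)
    delta = auc_n - auc_b
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
        return float(delta), float(max(var, 0.0)), p
    z = delta / np.sqrt(var)
    return float(delta), float(var), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# IDI and continuous NRI


def idi(
    pred: PairedPredictions, bootstrap: int = 0, seed: Optional[int] = None
) -> tuple[float, tuple[float, float]]:
    """Integrated discrimination improvement with a 95% CI.

    IDI = [mean improvement among events] - [mean improvement among
    non-events], where improvement is p_new - p_base per subject; the
    analytic CI treats the two group means as independent. ``bootstrap >
    0`` switches to a stratified percentile bootstrap.
    """
    d = pred.p_new - pred.p_base
    ev, ne = d[pred.labels == 1], d[pred.labels == 0]
    est = ev.mean() - ne.mean()
    if bootstrap:
        reps = _stratified_bootstrap(pred, bootstrap, seed, _idi_stat)
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        se = np.sqrt(
            (ev.var(ddof=1) / len(ev) if len(ev) > 1 else 0.0)
            + (ne.var(ddof=1) / len(ne) if len(ne) > 1 else 0.0)
        )
        lo, hi = est - Z95 * se, est + Z95 * se
    return float(est), (float(lo), float(hi))


def nri_continuous(
    pred: PairedPredictions, bootstrap: int = 0, seed: Optional[int] = None
) -> tuple[float, tuple[float, float]]:
    """Category-free NRI with a 95% CI; exact ties count toward neither.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) -
    P(up|non-event)], range [-2, 2]. The analytic CI combines the two
    net-proportion variances as independent binomial-style terms.
    """
    est, (se_e, se_ne) = _nri_parts(pred)
    if bootstrap:
        reps = _stratified_bootstrap(pred, bootstrap, seed, _nri_stat)
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        se = np.sqrt(se_e**2 + se_ne**2)
        lo, hi = est - Z95 * se, est + Z95 * se
    return float(est), (float(lo), float(hi))


def _nri_parts(pred: PairedPredictions):
    up = pred.p_new > pred.p_base
    down = pred.p_new < pred.p_base
    e, ne = pred.labels == 1, pred.labels == 0
    m, n = pred.n_events, pred.n_nonevents
    net_e = up[e].mean() - down[e].mean()
    net_ne = down[ne].mean() - up[ne].mean()
    # var of (p_up - p_down) for a trinomial: p_up + p_down - (p_up - p_down)^2
    var_e = (up[e].mean() + down[e].mean() - net_e**2) / m
    var_ne = (down[ne].mean() + up[ne].mean() - net_ne**2) / n
    return float(net_e + net_ne), (np.sqrt(max(var_e, 0.0)), np.sqrt(max(var_ne, 0.0)))


def _idi_stat(pred: PairedPredictions) -> float:
    d = pred.p_new - pred.p_base
    return float(d[pred.labels == 1].mean() - d[pred.labels == 0].mean())


def _nri_stat(pred: PairedPredictions) -> float:
    return _nri_parts(pred)[0]


def _stratified_bootstrap(pred, n_rep, seed, statistic) -> np.ndarray:
    rng = np.random.default_rng(seed)
    ev = np.flatnonzero(pred.labels == 1)
    ne = np.flatnonzero(pred.labels == 0)
    out = np.empty(n_rep)
    for r in range(n_rep):
        idx = np.concatenate(
            [rng.choice(ev, size=len(ev)), rng.choice(ne, size=len(ne))]
        )
        out[r] = statistic(
            PairedPredictions(pred.labels[idx], pred.p_base[idx], pred.p_new[idx])
        )
    return out


# ---------------------------------------------------------------------------
# the full incremental-value table


def paired_predictions(
    cohort: pd.DataFrame, base_score: str, outcome: str
) -> PairedPredictions:
    """Fit base (severity only) and augmented (+ FI-Lab) models, jointly refit."""
    base = fit_logistic(cohort, ModelSpec(outcome=outcome, exposure=None, adjustment_set=(base_score,)))
    aug = fit_logistic(
        cohort,
        ModelSpec(outcome=outcome, exposure="filab_per001", adjustment_set=(base_score,)),
    )
    common = base.predicted.index.intersection(aug.predicted.index)
    labels = pd.to_numeric(cohort.loc[common, outcome]).to_numpy()
    return PairedPredictions(
        labels=labels,
        p_base=base.predicted.loc[common].to_numpy(),
        p_new=aug.predicted.loc[common].to_numpy(),
    )


def incremental_table(
    cohort: pd.DataFrame,
    base_scores: Sequence[str] = SEVERITY_SCORES,
    outcomes: Sequence[str] = ("death_inhospital", "death_1yr"),
) -> pd.DataFrame:
    """One row per (outcome, base score): C_new, C_base, dC, p, IDI, NRI."""
    rows = []
    for outcome in outcomes:
        for score in base_scores:
            pred = paired_predictions(cohort, score, outcome)
            c_b, ci_b = c_statistic(pred.p_base, pred.labels)
            c_n, ci_n = c_statistic(pred.p_new, pred.labels)
            delta, _, p = delong_compare(pred)
            idi_est, idi_ci = idi(pred)
            nri_est, nri_ci = nri_continuous(pred)
            rows.append(
                {
                    "outcome": outcome,
                    "comparison": f"{score.upper()} + FI-Lab vs. {score.upper()}",
                    "base_score": score,
                    "n": len(pred.labels),
                    "C_new": c_n, "C_new_lo": ci_n[0], "C_new_hi": ci_n[1],
                    "C_base": c_b, "C_base_lo": ci_b[0], "C_base_hi": ci_b[1],
                    "delta_C": delta, "p_delta_C": p,
                    "IDI": idi_est, "IDI_lo": idi_ci[0], "IDI_hi": idi_ci[1],
                    "NRI": nri_est, "NRI_lo": nri_ci[0], "NRI_hi": nri_ci[1],
                }
            )
    return pd.DataFrame(rows)
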