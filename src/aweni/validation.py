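"""Validation of an abbreviated index against the full one and outcomes.

Four families of checks:

* rank concordance between the full and abbreviated composite scores —
  Kendall's tau-a and tau-b (tie-corrected), with the Kendall score
  S = concordant - discordant pairs and its normal-approximation p-value;
* ROC analysis of how well the abbreviated score classifies full-index
  empowerment status — AUC as the Mann-Whitney concordance probability
  (ties count 1/2), standard error by the Hanley-McNeil formula, symmetric
  normal bounds clipped to [0, 1];
* outcome regressions — OLS with HC1-robust errors for BMI and log BMI,
  probit with sandwich-robust errors for normal-BMI and minimum dietary
  diversity; the BMI-family models are fit on the non-overweight,
  non-pregnant subsample (BMI < 25), MDD on the full sample with pregnancy
  as a control;
* group comparisons — Welch two-sample t-tests of outcome means and pooled
  two-sample proportion z-tests by demographic group and pooled, plus a
  per-DD comparison of empowerment proportions under the two indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "TauResult",
    "AucResult",
    "RegressionResult",
    "kendall_tau",
    "roc_auc",
    "outcome_regression",
    "group_tests",
    "dd_comparison",
    "cdf_plot",
    "OUTCOMES",
]

log = logging.getLogger(__name__)

OUTCOMES = ("bmi", "normal-bmi", "log-bmi", "mdd")

#: Food-group count at or above which minimum dietary diversity is met
#: (the MDD-W convention: >= 5 of 10 groups).
MDD_CUTOFF = 5

NORMAL_BMI_LOW, NORMAL_BMI_HIGH = 18.5, 25.0


# ---------------------------------------------------------------------------
# Rank concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TauResult:
    tau_a: float
    tau_b: float
    score: float  # S = concordant - discordant pairs
    se_score: float
    p_value: float
    n: int


def _tie_sums(v: np.ndarray):
    _, counts = np.unique(v, return_counts=True)
    t = counts[counts > 1].astype(float)
    return (
        float(np.sum(t * (t - 1) / 2.0)),
        float(np.sum(t * (t - 1) * (2 * t + 5))),
        float(np.sum(t * (t - 1) * (t - 2))),
    )


def kendall_tau(x, y) -> TauResult:
    """Kendall rank correlation with tie corrections.

    tau-a divides S by all n(n-1)/2 pairs; tau-b divides by the geometric
    mean of the numbers of untied pairs in x and y.  The p-value uses the
    normal approximation to S with the standard tie-adjusted variance.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("tau-b is undefined for a constant vector")

    # S via pairwise signs; survey-scale n keeps this affordable
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    S = float(np.sum(np.triu(sx * sy, k=1)))

    n0 = n * (n - 1) / 2.0
    n1, vt, wt = _tie_sums(x)
    n2, vu, wu = _tie_sums(y)
    tau_a = S / n0
    tau_b = S / np.sqrt((n0 - n1) * (n0 - n2))

    v0 = n * (n - 1) * (2 * n + 5)
    var_s = (v0 - vt - vu) / 18.0
    if n > 2:
        var_s += wt * wu / (9.0 * n * (n - 1) * (n - 2))
    var_s += (2.0 * n1) * (2.0 * n2) / (2.0 * n * (n - 1))
    se = float(np.sqrt(var_s))
    p = 2.0 * stats.norm.sf(abs(S) / se) if se > 0 else float("nan")
    return TauResult(tau_a=tau_a, tau_b=tau_b, score=S, se_score=se, p_value=p, n=n)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    lower: float
    upper: float
    n_positive: int
    n_negative: int


def roc_auc(score, truth) -> AucResult:
    """AUC as the probability a positive outranks a negative (ties = 1/2).

    The standard error is Hanley & McNeil's, with exponential
    approximations Q1 = A/(2-A), Q2 = 2A^2/(1+A); bounds are
    auc +- 1.96 se clipped to [0, 1].
    """
    score = np.asarray(score, float).ravel()
    truth = np.asarray(truth).ravel().astype(int)
    if score.size != truth.size:
        raise ValueError("score and truth must have equal length")
    if not set(np.unique(truth)) <= {0, 1}:
        raise ValueError("truth must be binary")
    n_pos = int(np.sum(truth == 1))
    n_neg = int(np.sum(truth == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(score)  # midranks handle ties
    auc = float((np.sum(ranks[truth == 1]) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return AucResult(
        auc=auc,
        se=se,
        lower=max(0.0, auc - 1.96 * se),
        upper=min(1.0, auc + 1.96 * se),
        n_positive=n_pos,
        n_negative=n_neg,
    )


# ---------------------------------------------------------------------------
# Outcome regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    model: str  # "ols" or "probit"
    outcome: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    fit_stat: dict
    n: int
    restriction: str
    reference_levels: dict

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "robust_se": self.bse,
                "stat": self.tvalues,
                "p": self.pvalues,
            }
        )


class SeparationError(RuntimeError):
    pass


def _design(df: pd.DataFrame, controls: Sequence[str]):
    """Dummy-code categorical controls; reference = first sorted level."""
    cols = {}
    refs = {}
    for ctrl in controls:
        if ctrl in ("site", "group"):
            levels = sorted(df[ctrl].astype(str).unique())
            refs[ctrl] = levels[0]
            for lev in levels[1:]:
                cols[f"{ctrl}[{lev}]"] = (df[ctrl].astype(str) == lev).astype(float)
        elif ctrl == "age":
            cols["age"] = df["age"].astype(float)
        elif ctrl == "pregnant":
            cols["pregnant"] = df["pregnant"].astype(float)
        else:
            raise ValueError(f"unsupported control {ctrl!r}")
    return pd.DataFrame(cols, index=df.index), refs


def _find_separator(X: pd.DataFrame, y: np.ndarray) -> str:
    for col in X.columns:
        v = X[col].to_numpy()
        if set(np.unique(v)) <= {0.0, 1.0}:
            for val in (0.0, 1.0):
                sub = y[v == val]
                if sub.size and (sub.min() == sub.max()):
                    return col
    return "unknown"


def outcome_regression(
    data: pd.DataFrame,
    status,
    outcome: str,
    controls: Sequence[str] = ("group", "age"),
) -> RegressionResult:
    """Regress a nutritional outcome on empowerment status plus controls.

    ``bmi``/``log-bmi`` are OLS with HC1 standard errors; ``normal-bmi``
    (1 = BMI in [18.5, 25), 0 = underweight) and ``mdd`` (1 = at least
    5 of 10 food groups) are probit with robust sandwich errors.  The
    BMI-family models restrict to respondents with observed BMI < 25 who
    are not pregnant; MDD uses all rows with an observed food-group count
    and controls for pregnancy.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    df = data.copy()
    df["_status"] = np.asarray(status, float)

    if outcome == "mdd":
        df = df.loc[df["food_groups"].notna()]
        y = (df["food_groups"].astype(float) >= MDD_CUTOFF).astype(float)
        controls = list(controls)
        if "pregnant" not in controls:
            controls = controls + ["pregnant"]
        restriction = "full sample with observed food-group count; pregnancy controlled"
    else:
        df = df.loc[df["bmi"].notna() & (df["bmi"] < NORMAL_BMI_HIGH) & ~df["pregnant"].astype(bool)]
        restriction = "BMI < 25 (overweight/obese excluded), non-pregnant"
        if outcome == "bmi":
            y = df["bmi"].astype(float)
        elif outcome == "log-bmi":
            y = np.log(df["bmi"].astype(float))
        else:  # normal-bmi
            y = (df["bmi"].astype(float) >= NORMAL_BMI_LOW).astype(float)
    if len(df) == 0:
        raise ValueError(f"no observations survive the restriction for {outcome!r}")

    Xc, refs = _design(df, controls)
    constant = [c for c in Xc.columns if Xc[c].nunique() <= 1]
    if constant:
        log.info("dropping constant control column(s): %s", constant)
        Xc = Xc.drop(columns=constant)
    X = pd.concat([pd.Series(df["_status"], name="empowered"), Xc], axis=1)
    X = sm.add_constant(X, has_constant="add")

    if outcome in ("bmi", "log-bmi"):
        res = sm.OLS(np.asarray(y, float), X).fit(cov_type="HC1")
        fit_stat = {"r_squared": float(res.rsquared), "adj_r_squared": float(res.rsquared_adj)}
        model = "ols"
    else:
        yv = np.asarray(y, float)
        if yv.min() == yv.max():
            raise SeparationError(f"outcome {outcome!r} is constant after restriction")
        try:
            res = sm.Probit(yv, X).fit(disp=0, cov_type="HC1", maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(
                f"probit separation for outcome {outcome!r}; "
                f"suspect variable: {_find_separator(X, yv)}"
            ) from exc
        if not np.all(np.isfinite(res.bse)):
            raise SeparationError(
                f"probit separation for outcome {outcome!r}; "
                f"suspect variable: {_find_separator(X, yv)}"
            )
        fit_stat = {"chi_squared": float(res.llr), "pseudo_r_squared": float(res.prsquared)}
        model = "probit"

    return RegressionResult(
        model=model,
        outcome=outcome,
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        tvalues=pd.Series(res.tvalues, index=X.columns),
        pvalues=pd.Series(res.pvalues, index=X.columns),
        conf_int=pd.DataFrame(
            np.asarray(res.conf_int()), index=X.columns, columns=["lower", "upper"]
        ),
        fit_stat=fit_stat,
        n=int(res.nobs),
        restriction=restriction,
        reference_levels=refs,
    )


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def group_tests(
    outcome,
    status,
    groups,
    binary=None,
) -> pd.DataFrame:
    """Empowered-vs-disempowered comparisons per group and pooled.

    For the continuous ``outcome``: Welch unequal-variance two-sample t.
    For ``binary`` (if given): pooled two-sample proportion z.  Strata with
    only one status class get NaN p-values and ``flag='one-class'``.
    """
    outcome = np.asarray(outcome, float).ravel()
    status = np.asarray(status).ravel().astype(int)
    groups = np.asarray(groups).ravel()
    binary = None if binary is None else np.asarray(binary).ravel().astype(float)

    rows = []
    labels = list(pd.unique(groups)) + ["all"]
    for lab in labels:
        sel = np.ones_like(status, bool) if lab == "all" else groups == lab
        keep = sel & ~np.isnan(outcome)
        o, s = outcome[keep], status[keep]
        b = binary[keep] if binary is not None else None
        d, e = o[s == 0], o[s == 1]
        row = {
            "group": lab,
            "mean_disempowered": float(d.mean()) if d.size else float("nan"),
            "n_disempowered": int(d.size),
            "mean_empowered": float(e.mean()) if e.size else float("nan"),
            "n_empowered": int(e.size),
        }
        if d.size < 2 or e.size < 2:
            row.update(t_stat=float("nan"), p_mean=float("nan"), flag="one-class")
        else:
            t, p = stats.ttest_ind(e, d, equal_var=False)
            row.update(t_stat=float(t), p_mean=float(p), flag="")
        if b is not None:
            bd, be = b[s == 0], b[s == 1]
            row["prop_disempowered"] = float(bd.mean()) if bd.size else float("nan")
            row["prop_empowered"] = float(be.mean()) if be.size else float("nan")
            if bd.size == 0 or be.size == 0:
                row.update(z_stat=float("nan"), p_prop=float("nan"), flag="one-class")
            else:
                z, p = proportions_ztest(
                    [be.sum(), bd.sum()], [be.size, bd.size], alternative="two-sided"
                )
                row.update(z_stat=float(z), p_prop=float(p))
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# DD-level comparison
# ---------------------------------------------------------------------------

def dd_comparison(
    full_scores: pd.DataFrame,
    abbreviated_scores: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Percent empowered per DD (and overall) under each index, side by side.

    DD-level empowerment applies the same >= threshold rule to the DD
    scores as the composite uses; this convention is recorded in the
    result's ``attrs``.
    """
    if not full_scores.index.equals(abbreviated_scores.index):
        raise ValueError("score sets cover different respondents")
    dims = [c for c in full_scores.columns if c not in ("composite", "status")]
    rows = []
    for dim in ["composite"] + dims:
        if dim not in abbreviated_scores.columns:
            continue
        rows.append(
            {
                "dimension": dim,
                "full_pct": 100.0 * float((full_scores[dim] >= threshold).mean()),
                "abbreviated_pct": 100.0
                * float((abbreviated_scores[dim] >= threshold).mean()),
            }
        )
    out = pd.DataFrame(rows).set_index("dimension")
    out.attrs["dd_empowerment_rule"] = f"dd score >= {threshold} (same cutoff as composite)"
    return out


def cdf_plot(full_composite, abbreviated_composite, path) -> None:
    """Empirical CDF comparison of the two composite scores (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for values, label in (
        (full_composite, "full index"),
        (abbreviated_composite, "abbreviated index"),
    ):
        v = np.sort(np.asarray(values, float))
        ax.step(v, np.arange(1, v.size + 1) / v.size, where="post", label=label)
    ax.set_xlabel("composite empowerment score")
    ax.set_ylabel("cumulative share of respondents")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
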