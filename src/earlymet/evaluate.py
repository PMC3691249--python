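"""Validation-suite statistics: ROC/AUC, odds ratios, Kaplan-Meier,
reclassification and follow-up.

All estimators here are the standard epidemiological ones:

* AUC as the Mann-Whitney concordance probability (ties count 1/2), with a
  class-stratified percentile-bootstrap 95% CI (DeLong available);
* odds ratios from 2x2 tables, OR = ad/(bc), with Wald CIs on the log scale
  (z = 1.959964) and, for continuous predictors, from logistic regression —
  classifier scores are reported per 0.10 score increment;
* Kaplan-Meier product-limit curves with the unweighted two-group log-rank
  test (lifelines);
* a Gleason-by-classifier-risk reclassification table;
* potential median follow-up by the reverse Kaplan-Meier construction
  (deaths censored, end of contact treated as the event).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from ._rng import substream

__all__ = [
    "ContingencyTable2x2",
    "ORResult",
    "AUCResult",
    "KMResult",
    "odds_ratio_2x2",
    "univariable_logistic_or",
    "multivariable_logistic",
    "auc_with_ci",
    "km_logrank",
    "reclassification_table",
    "median_followup",
]

Z95 = 1.959964


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @classmethod
    def from_labels(cls, exposed, is_case) -> "ContingencyTable2x2":
        exposed = np.asarray(exposed, dtype=bool)
        is_case = np.asarray(is_case, dtype=bool)
        return cls(
            a=int((exposed & is_case).sum()),
            b=int((exposed & ~is_case).sum()),
            c=int((~exposed & is_case).sum()),
            d=int((~exposed & ~is_case).sum()),
        )


@dataclass(frozen=True)
class ORResult:
    or_: float
    ci_low: float
    ci_high: float
    p: float
    method: str  # "wald_2x2" | "logistic"
    corrected: bool = False  # Haldane-Anscombe +0.5 applied


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int


@dataclass
class KMResult:
    """Per-group product-limit curves, medians and the log-rank p-value."""

    event: str
    curves: dict  # group -> DataFrame(time, survival, at_risk)
    medians: dict  # group -> float or nan (never crosses 0.5)
    logrank_p: float

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g, df in self.curves.items():
            ax.step(df["time"], df["survival"], where="post", label=str(g))
        ax.set_xlabel("years")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend(title=self.event)
        return ax


def odds_ratio_2x2(t: ContingencyTable2x2, level: float = 0.95) -> ORResult:
    """OR = ad/(bc) with a Wald CI on the log scale.

    A single zero cell triggers the Haldane-Anscombe +0.5 correction to every
    cell (flagged in the result); a fully zero row or column leaves the OR
    undefined and raises.
    """
    from scipy.stats import norm

    a, b, c, d = t.a, t.b, t.c, t.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("a zero row or column leaves the odds ratio undefined")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + level / 2) if level != 0.95 else Z95
    log_or = np.log(or_)
    p = 2 * norm.sf(abs(log_or) / se)
    return ORResult(
        or_=float(or_),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p=float(p),
        method="wald_2x2",
        corrected=corrected,
    )


_TRANSFORMS = {
    "identity": lambda x: x,
    "per_10pct_score": lambda x: x / 0.10,  # OR per 0.10 increment of a [0,1] score
    "log2": np.log2,
}


def univariable_logistic_or(
    covariate, is_case, transform: str = "identity"
) -> ORResult:
    """Logistic-regression OR per unit of the transformed covariate."""
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    x = _TRANSFORMS[transform](np.asarray(covariate, dtype=float))
    y = np.asarray(is_case, dtype=bool).astype(float)
    if np.unique(x).size < 2:
        raise ValueError("covariate has no variation")
    X = sm.add_constant(pd.DataFrame({"x": x}))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise ValueError("logistic fit failed (separation?)") from exc
    if not np.isfinite(res.params).all() or abs(res.params["x"]) > 1e4:
        raise ValueError("logistic fit diverged: complete separation")
    ci = res.conf_int().loc["x"]
    return ORResult(
        or_=float(np.exp(res.params["x"])),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p=float(res.pvalues["x"]),
        method="logistic",
    )


def multivariable_logistic(
    covariates: pd.DataFrame,
    is_case,
    treatment: pd.DataFrame | None = None,
    adjust_for_treatment: bool = False,
) -> pd.DataFrame:
    """Joint logistic fit; adjusted ORs with Wald CIs per covariate.

    ``treatment`` holds the four adjuvant/salvage binaries appended when
    ``adjust_for_treatment``. Rank-deficient (collinear or constant) columns
    are dropped with a warning. Returns a DataFrame indexed by covariate with
    columns or, ci_low, ci_high, p. An intercept-only design returns an
    empty frame.
    """
    X = covariates.astype(float).copy()
    if adjust_for_treatment:
        if treatment is None:
            raise ValueError("adjust_for_treatment requires a treatment table")
        X = pd.concat([X, treatment.astype(float)], axis=1)
    y = np.asarray(is_case, dtype=bool).astype(float)

    # prune constant, then greedily rank-deficient columns
    for c in list(X.columns):
        if X[c].nunique() <= 1:
            warnings.warn(f"dropping constant covariate {c!r}", stacklevel=2)
            X = X.drop(columns=c)
    kept: list[str] = []
    for c in X.columns:
        trial = X[kept + [c]].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), trial])) == len(kept) + 2:
            kept.append(c)
        else:
            warnings.warn(f"dropping rank-deficient covariate {c!r}", stacklevel=2)
    if not kept:
        return pd.DataFrame(columns=["or", "ci_low", "ci_high", "p"])
    Xk = sm.add_constant(X[kept], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xk).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError("newton did not converge")
        except Exception:
            # singular Hessian / separation: quasi-Newton still returns a fit
            res = sm.Logit(y, Xk).fit(disp=0, method="bfgs", maxiter=1000)
    if np.abs(res.params.drop("const", errors="ignore")).max() > 15:
        warnings.warn(
            "multivariable fit unstable (separation suspected); odds ratios and "
            "intervals are unreliable",
            stacklevel=2,
        )
    ci = res.conf_int()
    out = pd.DataFrame(
        {
            "or": np.exp(res.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p": res.pvalues,
        }
    )
    return out.drop(index="const", errors="ignore")


def _auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _delong_ci(scores: np.ndarray, y: np.ndarray, level: float) -> tuple[float, float]:
    """DeLong variance of the AUC via placement values."""
    from scipy.stats import norm, rankdata

    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


def auc_with_ci(
    scores,
    is_case,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    method: str = "bootstrap",
) -> AUCResult:
    """AUC (Mann-Whitney concordance, ties count 1/2) with a 95% CI.

    The default CI is a class-stratified percentile bootstrap over samples;
    ``method='delong'`` uses the DeLong asymptotic variance instead.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("AUC needs both classes present")
    auc = _auc_mann_whitney(scores, y)
    if method == "delong":
        lo, hi = _delong_ci(scores, y, level)
        return AUCResult(auc=auc, ci_low=lo, ci_high=hi, n_boot=0)
    rng = substream(seed, "aucboot")
    idx_case = np.flatnonzero(y)
    idx_ctrl = np.flatnonzero(~y)
    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx_case, size=len(idx_case), replace=True),
                rng.choice(idx_ctrl, size=len(idx_ctrl), replace=True),
            ]
        )
        stats_[b] = _auc_mann_whitney(scores[take], y[take])
    alpha = 1 - level
    lo, hi = np.quantile(stats_, [alpha / 2, 1 - alpha / 2])
    lo, hi = min(lo, auc), max(hi, auc)
    return AUCResult(auc=auc, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


def km_logrank(times, events, groups, event_label: str = "event") -> KMResult:
    """Kaplan-Meier curves per group with a log-rank test.

    Median survival is the first time the curve reaches <= 0.5 (NaN when the
    curve never crosses). With two groups the unweighted two-sample log-rank
    test is used; with more, its k-group generalisation; with one group the
    p-value is NaN.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if (times < 0).any():
        raise ValueError("negative survival times")
    if len(times) == 0:
        raise ValueError("empty input")

    curves: dict = {}
    medians: dict = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], event_observed=events[mask])
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index).to_numpy()
        curves[g] = pd.DataFrame(
            {"time": surv.index.to_numpy(), "survival": surv.to_numpy(), "at_risk": at_risk}
        )
        med = kmf.median_survival_time_
        medians[g] = float(med) if np.isfinite(med) else float("nan")

    uniq = pd.unique(groups)
    if len(uniq) == 1:
        p = float("nan")
    elif len(uniq) == 2:
        m = groups == uniq[0]
        p = float(
            logrank_test(times[m], times[~m], events[m], events[~m]).p_value
        )
    else:
        p = float(multivariate_logrank_test(times, groups, events).p_value)
    return KMResult(event=event_label, curves=curves, medians=medians, logrank_p=p)


def plot_roc(scores, is_case, ax=None, label=None):
    """ROC curve of a score vector (matplotlib axis returned)."""
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    if ax is None:
        _, ax = plt.subplots()
    fpr, tpr, _ = roc_curve(np.asarray(is_case, dtype=int), np.asarray(scores, float))
    ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if label:
        ax.legend()
    return ax


GS_CATEGORIES = ("<=6", "7", "8", ">=9")


def _gs_category(gs: np.ndarray) -> np.ndarray:
    if ((gs < 2) | (gs > 10)).any():
        raise ValueError("Gleason scores must lie in 2..10")
    return np.select([gs <= 6, gs == 7, gs == 8], GS_CATEGORIES[:3], default=GS_CATEGORIES[3])


def reclassification_table(gs, gc_scores, met_events, pcsm_events) -> pd.DataFrame:
    """Counts of metastasis and PCSM events by Gleason category x GC risk.

    Rows: GS {<=6, 7, 8, >=9} x GC {<=0.5, >0.5}; columns: n, n_met,
    pct_met, n_pcsm, pct_pcsm. Percentages use one decimal below 10, integer
    rounding otherwise.
    """
    gs = np.asarray(gs, dtype=int)
    sc = np.asarray(gc_scores, dtype=float)
    met = np.asarray(met_events, dtype=bool)
    pcsm = np.asarray(pcsm_events, dtype=bool)
    cat = _gs_category(gs)
    high = sc > 0.5
    rows = []
    for c in GS_CATEGORIES:
        for is_high, label in ((False, "GC<=0.5"), (True, "GC>0.5")):
            m = (cat == c) & (high == is_high)
            n = int(m.sum())
            n_met = int(met[m].sum())
            n_pcsm = int(pcsm[m].sum())
            rows.append(
                {
                    "gs": c,
                    "gc_risk": label,
                    "n": n,
                    "n_met": n_met,
                    "pct_met": _paper_pct(n_met, n),
                    "n_pcsm": n_pcsm,
                    "pct_pcsm": _paper_pct(n_pcsm, n),
                }
            )
    return pd.DataFrame(rows).set_index(["gs", "gc_risk"])


def _paper_pct(k: int, n: int) -> float:
    if n == 0:
        return 0.0
    pct = 100.0 * k / n
    return round(pct, 1) if pct < 10 else float(round(pct))


def median_followup(times_to_last_contact, death_events) -> float:
    """Median potential follow-up by the reverse Kaplan-Meier construction.

    Deaths are censored and end of contact is the event, estimating how long
    patients *would* have been followed absent death. NaN when the reverse
    curve never reaches 0.5 (reported as not reached).
    """
    times = np.asarray(times_to_last_contact, dtype=float)
    deaths = np.asarray(death_events, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=~deaths)
    med = kmf.median_survival_time_
    return float(med) if np.isfinite(med) else float("nan")
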