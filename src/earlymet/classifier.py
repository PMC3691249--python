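"""Classifier assembly: genomic (random forest), clinical-only (logistic) and
integrated genomic-clinical models.

The genomic classifier (GC) is a probability random forest over the
stability-selected markers, after two more steps:

* backward elimination — repeatedly drop the 10% of features with the lowest
  mean-decrease-Gini importance and record the 10-fold cross-validated mean
  squared error (Brier score) of the shrinking model; keep the feature set at
  the minimum of that curve (the knee, smaller set on ties);
* grid tuning of ``mtry`` (features tried per split) and ``nodesize``
  (minimum terminal-node size) by repeated 1/3-train / 2/3-test resampling of
  the training set, maximising held-out accuracy at the 0.5 score threshold.

The clinical classifier (CC) is a logistic regression on six
clinicopathologic covariates (Gleason >= 8, log2 pre-operative PSA, surgical
margins, seminal vesicle invasion, extra-capsular extension, nodal status);
the integrated classifier (GCC) is a logistic regression on the GC and CC
scores. All three score on [0, 1]; scores above 0.5 are called high risk.

Model classes follow the fit -> Results pattern: construct a model from
data, call ``fit()``, and use the returned results object for prediction,
summaries and serialisation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from ._rng import child_seed, substream

__all__ = [
    "ForestConfig",
    "EliminationCurve",
    "RiskCall",
    "backward_eliminate",
    "tune_forest",
    "train_gc",
    "classify_risk",
    "risk_calls",
    "GenomicClassifier",
    "GenomicClassifierResults",
    "ClinicalClassifier",
    "ClinicalClassifierResults",
    "IntegratedClassifier",
    "IntegratedClassifierResults",
    "CLINICAL_COVARIATES",
]


# ---------------------------------------------------------------------------
# configuration and small value types


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 1000
    mtry_grid: tuple[int, ...] | None = None  # None -> {1, ceil(sqrt p), p/3, p/2, p}
    nodesize_grid: tuple[int, ...] = (1, 2, 5, 10, 20)
    cv_folds: int = 10
    drop_frac: float = 0.10
    tune_boot: int = 1000
    tune_train_frac: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.drop_frac < 1.0:
            raise ValueError("drop_frac must be in (0, 1)")
        if self.n_trees < 1 or self.cv_folds < 2 or self.tune_boot < 1:
            raise ValueError("n_trees >= 1, cv_folds >= 2, tune_boot >= 1 required")
        if not 0.0 < self.tune_train_frac < 1.0:
            raise ValueError("tune_train_frac must be in (0, 1)")
        if self.mtry_grid is not None and len(self.mtry_grid) == 0:
            raise ValueError("mtry_grid must be non-empty when given")
        if len(self.nodesize_grid) == 0:
            raise ValueError("nodesize_grid must be non-empty")

    def replace(self, **kw) -> "ForestConfig":
        return dataclasses.replace(self, **kw)

    def default_mtry_grid(self, p: int) -> tuple[int, ...]:
        cand = {1, int(np.ceil(np.sqrt(p))), int(np.ceil(p / 3)), int(np.ceil(p / 2)), p}
        return tuple(sorted(c for c in cand if 1 <= c <= p))


@dataclass
class EliminationCurve:
    """Cross-validated MSE as the feature set shrinks."""

    sizes: list[int]
    cv_mse: list[float]
    chosen_size: int
    chosen_features: list[str]
    feature_sets: list[list[str]] = field(default_factory=list, repr=False)

    def plot(self, ax=None):
        """MSE-vs-size curve with the chosen size marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.sizes, self.cv_mse, marker="o")
        ax.axvline(self.chosen_size, linestyle="--", color="grey")
        ax.set_xlabel("number of features")
        ax.set_ylabel("10-fold CV MSE")
        ax.invert_xaxis()
        return ax


@dataclass(frozen=True)
class RiskCall:
    score: float
    risk: str  # "low" | "high"


def classify_risk(score: float) -> RiskCall:
    """Dichotomise a classifier score at 0.5 (strictly greater -> high)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must be in [0, 1], got {score}")
    return RiskCall(score=float(score), risk="high" if score > 0.5 else "low")


def risk_calls(scores) -> pd.Series:
    """Vectorised risk dichotomisation; preserves the index of a Series."""
    s = pd.Series(scores)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores must be in [0, 1]")
    return pd.Series(np.where(s > 0.5, "high", "low"), index=s.index, name="risk")


# ---------------------------------------------------------------------------
# random-forest building blocks


def _forest(n_trees: int, mtry, nodesize: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=nodesize,
        random_state=seed,
        n_jobs=1,
    )


def _cv_mse(X, y, n_trees: int, cv_folds: int, seed: int) -> float:
    """Out-of-fold Brier score of the forest's case probability."""
    folds = min(cv_folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    err = np.empty(len(y))
    for i, (tr, te) in enumerate(skf.split(X, y)):
        f = _forest(n_trees, "sqrt", 1, seed + i + 1)
        f.fit(X[tr], y[tr])
        err[te] = (f.predict_proba(X[te])[:, 1] - y[te]) ** 2
    return float(err.mean())


def backward_eliminate(
    expr: pd.DataFrame,
    is_case,
    candidates: list[str],
    cfg: ForestConfig,
) -> EliminationCurve:
    """Gini-ranked backward elimination with the MSE-knee stopping rule.

    Starting from ``candidates``, repeatedly fit a forest, record the k-fold
    cross-validated MSE of the case-probability predictions, and drop the
    ``drop_frac`` of features with the lowest mean-decrease-Gini importance
    (at least one per round) until one feature remains. The chosen size is
    the curve's argmin; ties resolve to the smaller set.
    """
    candidates = list(candidates)
    if len(candidates) == 0:
        raise ValueError("no candidate features to eliminate from")
    is_case = np.asarray(is_case, dtype=bool).astype(int)
    sizes: list[int] = []
    mses: list[float] = []
    sets: list[list[str]] = []
    current = candidates
    rnd = 0
    while True:
        X = expr.loc[current].to_numpy(dtype=float).T
        seed = child_seed(cfg.seed, "elim", rnd)
        sizes.append(len(current))
        mses.append(_cv_mse(X, is_case, cfg.n_trees, cfg.cv_folds, seed))
        sets.append(list(current))
        if len(current) == 1:
            break
        f = _forest(cfg.n_trees, "sqrt", 1, seed)
        f.fit(X, is_case)
        imp = f.feature_importances_
        n_drop = max(1, int(np.floor(cfg.drop_frac * len(current))))
        order = np.argsort(imp, kind="stable")  # lowest importance first
        drop = set(order[:n_drop])
        current = [f_ for i, f_ in enumerate(current) if i not in drop]
        rnd += 1
    arr = np.asarray(mses)
    # sizes are strictly decreasing, so the last argmin is the smallest size
    best = int(np.flatnonzero(arr == arr.min()).max())
    return EliminationCurve(
        sizes=sizes,
        cv_mse=mses,
        chosen_size=sizes[best],
        chosen_features=sets[best],
        feature_sets=sets,
    )


def tune_forest(
    expr: pd.DataFrame,
    is_case,
    features: list[str],
    cfg: ForestConfig,
) -> tuple[int, int]:
    """Accuracy-optimising grid search over (mtry, nodesize).

    Each grid cell is scored by repeatedly (``tune_boot`` times) splitting
    the training samples into a ``tune_train_frac`` fitting part and a
    held-out part, fitting a forest and measuring held-out accuracy at the
    0.5 score threshold; the same splits are reused across cells. Ties break
    to the smaller nodesize, then the smaller mtry.
    """
    features = list(features)
    if len(features) == 0:
        raise ValueError("no features to tune on")
    p = len(features)
    grid_m = cfg.mtry_grid if cfg.mtry_grid is not None else cfg.default_mtry_grid(p)
    cells = []
    for m in grid_m:
        if m > p:
            warnings.warn(f"mtry={m} exceeds {p} features; cell skipped", stacklevel=2)
            continue
        for ns in cfg.nodesize_grid:
            cells.append((int(m), int(ns)))
    if not cells:
        raise ValueError("all grid cells skipped (every mtry exceeds the feature count)")

    is_case = np.asarray(is_case, dtype=bool).astype(int)
    X_all = expr.loc[features].to_numpy(dtype=float).T
    n = len(is_case)
    idx_case = np.flatnonzero(is_case == 1)
    idx_ctrl = np.flatnonzero(is_case == 0)
    if len(idx_case) < 3 or len(idx_ctrl) < 3:
        raise ValueError("too few samples per class to tune by resampling")

    acc = np.zeros(len(cells))
    for t in range(cfg.tune_boot):
        rng = substream(cfg.seed, "tune", t)
        tr = np.concatenate(
            [
                rng.choice(idx_case, size=max(2, round(cfg.tune_train_frac * len(idx_case))), replace=False),
                rng.choice(idx_ctrl, size=max(2, round(cfg.tune_train_frac * len(idx_ctrl))), replace=False),
            ]
        )
        te = np.setdiff1d(np.arange(n), tr)
        seed = child_seed(cfg.seed, "tunefit", t)
        for j, (m, ns) in enumerate(cells):
            f = _forest(cfg.n_trees, m, ns, seed)
            f.fit(X_all[tr], is_case[tr])
            pred = (f.predict_proba(X_all[te])[:, 1] > 0.5).astype(int)
            acc[j] += float((pred == is_case[te]).mean())
    acc /= cfg.tune_boot
    # argmax accuracy; ties -> smaller nodesize then smaller mtry
    order = sorted(range(len(cells)), key=lambda j: (-acc[j], cells[j][1], cells[j][0]))
    return cells[order[0]]


# ---------------------------------------------------------------------------
# genomic classifier (GC)


class GenomicClassifier:
    """Random-forest genomic classifier model.

    Parameters
    ----------
    expr : DataFrame
        Training expression (features x samples), already preprocessed.
    is_case : array-like of bool
        Case labels for the training samples (columns of ``expr``).
    candidates : list of str, optional
        Feature ids to build from (default: all rows of ``expr``) — normally
        the output of stability selection.
    config : ForestConfig
    """

    def __init__(self, expr, is_case, candidates=None, config: ForestConfig | None = None):
        self.expr = expr
        self.is_case = np.asarray(is_case, dtype=bool)
        if self.is_case.sum() == 0 or (~self.is_case).sum() == 0:
            raise ValueError("training data must contain both cases and controls")
        self.candidates = list(candidates) if candidates is not None else list(expr.index)
        self.config = config if config is not None else ForestConfig()

    def fit(self, eliminate: bool = True, tune: bool = True) -> "GenomicClassifierResults":
        """Run elimination and tuning (optionally) and fit the final forest."""
        cfg = self.config
        curve = None
        features = self.candidates
        if eliminate and len(features) >= 2:
            curve = backward_eliminate(self.expr, self.is_case, features, cfg)
            features = curve.chosen_features
        if tune:
            mtry, nodesize = tune_forest(self.expr, self.is_case, features, cfg)
        else:
            mtry, nodesize = min(len(features), max(1, int(np.ceil(np.sqrt(len(features)))))), 1
        return train_gc(
            self.expr, self.is_case, features, mtry, nodesize, cfg, elimination=curve
        )


def train_gc(
    expr: pd.DataFrame,
    is_case,
    features: list[str],
    mtry: int,
    nodesize: int,
    cfg: ForestConfig,
    elimination: EliminationCurve | None = None,
) -> "GenomicClassifierResults":
    """Fit the final probability forest on the full training set."""
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.all() or not is_case.any():
        raise ValueError("need both classes to fit the genomic classifier")
    features = list(features)
    X = expr.loc[features].to_numpy(dtype=float).T
    forest = _forest(cfg.n_trees, mtry, nodesize, child_seed(cfg.seed, "final"))
    forest.fit(X, is_case.astype(int))
    return GenomicClassifierResults(
        features=features,
        mtry=int(mtry),
        nodesize=int(nodesize),
        config=cfg,
        forest=forest,
        elimination=elimination,
        train_sample_ids=list(expr.columns),
    )


class GenomicClassifierResults:
    """Fitted genomic classifier: scores samples on [0, 1]."""

    kind = "GC"

    def __init__(self, features, mtry, nodesize, config, forest, elimination=None,
                 train_sample_ids=None):
        self.features = list(features)
        self.mtry = mtry
        self.nodesize = nodesize
        self.config = config
        self.forest = forest
        self.elimination = elimination
        self.train_sample_ids = train_sample_ids or []

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        """GC score (forest case-probability) per sample column of ``expr``."""
        missing = [f for f in self.features if f not in expr.index]
        if missing:
            raise KeyError(f"expression matrix lacks classifier features: {missing[:5]}")
        X = expr.loc[self.features].to_numpy(dtype=float).T
        scores = self.forest.predict_proba(X)[:, 1]
        return pd.Series(scores, index=expr.columns, name="gc_score")

    def predict_risk(self, expr: pd.DataFrame) -> pd.DataFrame:
        s = self.predict(expr)
        return pd.DataFrame({"score": s, "risk": risk_calls(s)})

    def importances(self) -> pd.Series:
        return pd.Series(
            self.forest.feature_importances_, index=self.features, name="gini_importance"
        ).sort_values(ascending=False)

    def summary(self) -> str:
        lines = [
            "Genomic classifier (random forest)",
            "=" * 44,
            f"markers:        {len(self.features)}",
            f"trees:          {self.forest.n_estimators}",
            f"mtry:           {self.mtry}",
            f"nodesize:       {self.nodesize}",
        ]
        if self.elimination is not None:
            lines.append(
                f"elimination:    {self.elimination.sizes[0]} -> "
                f"{self.elimination.chosen_size} features "
                f"(CV MSE {min(self.elimination.cv_mse):.4f})"
            )
        lines.append("-" * 44)
        lines.append("top markers by Gini importance:")
        for fid, v in self.importances().head(10).items():
            lines.append(f"  {fid:<20s} {v:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Write a self-describing JSON next to a binary ensemble bundle."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": self.kind,
            "features": self.features,
            "mtry": self.mtry,
            "nodesize": self.nodesize,
            "n_trees": self.forest.n_estimators,
            "config": dataclasses.asdict(self.config),
        }
        (path / "model.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self.forest, path / "forest.joblib")

    @classmethod
    def load(cls, path) -> "GenomicClassifierResults":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        cfg_d = meta["config"]
        for key in ("mtry_grid", "nodesize_grid"):
            if cfg_d.get(key) is not None:
                cfg_d[key] = tuple(cfg_d[key])
        cfg = ForestConfig(**cfg_d)
        forest = joblib.load(path / "forest.joblib")
        return cls(
            features=meta["features"],
            mtry=meta["mtry"],
            nodesize=meta["nodesize"],
            config=cfg,
            forest=forest,
        )


# ---------------------------------------------------------------------------
# clinical classifier (CC)

CLINICAL_COVARIATES = ["gs_high", "log2_ppsa", "ppsa_missing", "svi", "sm_pos", "ece", "node_pos"]


def encode_clinical(annot: pd.DataFrame, ppsa_median: float | None = None):
    """Design matrix for the clinical model.

    Gleason is dichotomised at >= 8; pre-operative PSA is log2-transformed
    with missing values median-imputed (median from the training set) and a
    missingness indicator added. Returns (X, median_used).
    """
    ppsa = annot["ppsa"].astype(float)
    if ppsa_median is None:
        ppsa_median = float(ppsa.median())
    missing = ppsa.isna()
    ppsa_f = ppsa.fillna(ppsa_median)
    X = pd.DataFrame(
        {
            "gs_high": (annot["gleason"] >= 8).astype(float),
            "log2_ppsa": np.log2(ppsa_f),
            "ppsa_missing": missing.astype(float),
            "svi": annot["svi"].astype(float),
            "sm_pos": annot["sm_pos"].astype(float),
            "ece": annot["ece"].astype(float),
            "node_pos": annot["node_pos"].astype(float),
        },
        index=annot.index,
    )
    return X, ppsa_median


def _fit_logit(X: pd.DataFrame, y: np.ndarray, covariate_hint: str = ""):
    """Logit MLE with constant-column pruning and a clear separation error."""
    keep = [c for c in X.columns if X[c].nunique() > 1]
    yb = np.asarray(y, dtype=bool)
    for c in keep:
        col = X[c].to_numpy()
        if set(np.unique(col)) <= {0.0, 1.0}:
            cb = col.astype(bool)
            if (cb == yb).all() or (cb == ~yb).all():
                raise ValueError(
                    f"complete separation: covariate {c!r} determines the outcome"
                )
    Xk = sm.add_constant(X[keep], has_constant="add")
    model = sm.Logit(y.astype(float), Xk)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True):
                    raise RuntimeError("newton did not converge")
            except Exception:
                # singular Hessian along the Newton path; quasi-Newton is
                # hardier, and true separation is caught by the checks below
                res = model.fit(disp=0, method="bfgs", maxiter=1000)
    except Exception as exc:  # PerfectSeparationError and kin
        offenders = []
        for c in keep:
            col = X[c]
            if col.nunique() == 2:
                tab = pd.crosstab(col, y)
                if (tab == 0).any().any():
                    offenders.append(c)
        raise ValueError(
            "logistic fit failed (likely complete separation"
            + (f" in {offenders}" if offenders else "")
            + f"){': ' + covariate_hint if covariate_hint else ''}"
        ) from exc
    if not np.isfinite(res.params).all() or np.abs(res.params).max() > 30:
        offenders = [c for c in keep if np.abs(res.params.get(c, 0.0)) > 30]
        raise ValueError(f"logistic fit diverged (separation?) in {offenders or keep}")
    return res, keep


class ClinicalClassifier:
    """Logistic clinical-only classifier model (training split only)."""

    def __init__(self, annot: pd.DataFrame):
        self.annot = annot
        self.is_case = annot["is_case"].to_numpy(dtype=bool)

    def fit(self) -> "ClinicalClassifierResults":
        X, med = encode_clinical(self.annot)
        res, keep = _fit_logit(X, self.is_case, "clinical covariates")
        return ClinicalClassifierResults(res, keep, med)


class ClinicalClassifierResults:
    kind = "CC"

    def __init__(self, sm_results, covariates, ppsa_median):
        self.sm_results = sm_results
        self.covariates = list(covariates)
        self.ppsa_median = ppsa_median

    @property
    def params(self) -> pd.Series:
        return self.sm_results.params

    def odds_ratios(self) -> pd.DataFrame:
        """Per-covariate OR with Wald 95% CI and p-value."""
        res = self.sm_results
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

    def predict(self, annot: pd.DataFrame) -> pd.Series:
        X, _ = encode_clinical(annot, ppsa_median=self.ppsa_median)
        Xk = sm.add_constant(X[self.covariates], has_constant="add")
        # align column order with the fit
        Xk = Xk[self.sm_results.params.index]
        return pd.Series(
            self.sm_results.predict(Xk), index=annot.index, name="cc_score"
        )

    def summary(self) -> str:
        return str(self.sm_results.summary())

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        payload = {
            "kind": self.kind,
            "covariates": self.covariates,
            "params": {k: float(v) for k, v in self.sm_results.params.items()},
            "ppsa_median": self.ppsa_median,
        }
        (path / "model.json").write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# integrated genomic-clinical classifier (GCC)


class _RidgeLogitResults:
    """Minimal stand-in for a statsmodels Logit result, produced by a weakly
    L2-penalised fit when the unpenalised likelihood has no maximum (training
    scores of a strong classifier often separate the classes perfectly)."""

    def __init__(self, params: pd.Series):
        self.params = params

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = X.to_numpy(dtype=float) @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        return "ridge-penalised logistic fit\n" + self.params.to_string()


def _fit_ridge_logit(X: pd.DataFrame, y: np.ndarray, alpha: float = 1.0):
    from sklearn.linear_model import LogisticRegression

    m = LogisticRegression(C=1.0 / alpha, max_iter=1000)
    m.fit(X.to_numpy(dtype=float), y.astype(int))
    params = pd.Series(
        np.r_[m.intercept_, m.coef_.ravel()], index=["const", *X.columns]
    )
    return _RidgeLogitResults(params)


class IntegratedClassifier:
    """Logistic combination of the GC and CC scores (training split).

    If the scores separate the classes completely — common for in-sample
    forest scores — the maximum-likelihood fit has no finite optimum and a
    lightly ridge-penalised logistic fit is used instead (warned)."""

    def __init__(self, gc_scores, cc_scores, is_case):
        self.gc = pd.Series(gc_scores)
        self.cc = pd.Series(cc_scores)
        self.is_case = np.asarray(is_case, dtype=bool)

    def fit(self) -> "IntegratedClassifierResults":
        X = pd.DataFrame({"gc": self.gc.to_numpy(), "cc": self.cc.to_numpy()},
                         index=self.gc.index)
        dropped = None
        corr = np.corrcoef(X["gc"], X["cc"])[0, 1] if X["cc"].nunique() > 1 else np.nan
        if X["cc"].nunique() <= 1 or (np.isfinite(corr) and abs(corr) > 0.999):
            warnings.warn(
                "CC scores carry no independent information; fitting on GC alone",
                stacklevel=2,
            )
            dropped = "cc"
            X = X[["gc"]]
        try:
            res, keep = _fit_logit(X, self.is_case, "classifier scores")
        except ValueError:
            warnings.warn(
                "classifier scores separate the classes; using a ridge-penalised fit",
                stacklevel=2,
            )
            res, keep = _fit_ridge_logit(X, self.is_case), list(X.columns)
        return IntegratedClassifierResults(res, keep, dropped=dropped)


class IntegratedClassifierResults:
    kind = "GCC"

    def __init__(self, sm_results, covariates, dropped=None):
        self.sm_results = sm_results
        self.covariates = list(covariates)
        self.dropped = dropped

    def predict(self, gc_scores, cc_scores) -> pd.Series:
        gc = pd.Series(gc_scores)
        X = pd.DataFrame({"gc": gc.to_numpy(), "cc": pd.Series(cc_scores).to_numpy()},
                         index=gc.index)
        Xk = sm.add_constant(X[self.covariates], has_constant="add")
        Xk = Xk[self.sm_results.params.index]
        return pd.Series(self.sm_results.predict(Xk), index=gc.index, name="gcc_score")

    def summary(self) -> str:
        return str(self.sm_results.summary())
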