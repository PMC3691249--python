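"""Two-stage feature selection: t-filter then bootstrapped elastic-net
stability selection.

Stage 1 reduces the feature space with an unadjusted per-feature two-sample
t-test (Welch by default) of cases vs controls on the training samples.

Stage 2 stabilises the surviving set: the case/control labels are modelled by
elastic-net-penalised logistic regression (mixing parameter alpha, default
0.5) on bootstrap resamples of the training samples, the penalty strength
being chosen by internal cross-validation within each resample; the number of
resamples in which each feature receives a nonzero coefficient is tallied,
and features selected in at least ``tally_threshold`` of the resamples
(default 25%) survive.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._rng import child_seed, substream

__all__ = ["SelectionConfig", "StabilityResult", "t_filter", "stability_select"]


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the selection stages.

    alpha is the elastic-net mixing parameter (1 = lasso, 0 = ridge);
    penalty strength is tuned per bootstrap resample by ``cv_folds``-fold
    cross-validated log-loss over ``n_penalty`` log-spaced strengths, or once
    globally when ``tuning='global'``.
    """

    t_p_threshold: float = 0.01
    alpha: float = 0.5
    n_boot: int = 1000
    tally_threshold: float = 0.25
    equal_var: bool = False
    tuning: str = "per_resample"  # or "global"
    cv_folds: int = 3
    n_penalty: int = 6
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.t_p_threshold <= 1.0:
            raise ValueError("t_p_threshold must be in (0, 1]")
        if not 0.0 < self.tally_threshold <= 1.0:
            raise ValueError("tally_threshold must be in (0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.tuning not in ("per_resample", "global"):
            raise ValueError("tuning must be 'per_resample' or 'global'")

    def replace(self, **kw) -> "SelectionConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class StabilityResult:
    """Bootstrap selection tallies and the surviving feature set."""

    tally: pd.Series  # per-feature count of resamples with nonzero coefficient
    n_boot: int
    selected: list[str]
    t_pass: list[str] = field(default_factory=list)
    n_skipped: int = 0

    @property
    def fraction(self) -> pd.Series:
        return self.tally / self.n_boot

    def table(self) -> pd.DataFrame:
        """Tally table (feature_id, tally, fraction, selected flag)."""
        return pd.DataFrame(
            {
                "tally": self.tally,
                "fraction": self.fraction,
                "selected": self.tally.index.isin(self.selected),
            }
        ).sort_values("tally", ascending=False)


def t_filter(
    expr: pd.DataFrame,
    is_case,
    p_threshold: float = 0.01,
    equal_var: bool = False,
) -> list[str]:
    """Features whose two-sided two-sample t-test p-value is < p_threshold.

    No multiplicity adjustment — this is a complexity-reduction filter, not an
    inference. Features with undefined t statistics (zero variance in both
    groups) are excluded with a warning.
    """
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("both classes need >= 2 samples for a t-test")
    X = expr.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(X[:, is_case], X[:, ~is_case], axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue)
    bad = ~np.isfinite(p)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} feature(s) with undefined t statistic excluded",
            stacklevel=2,
        )
    keep = np.isfinite(p) & (p < p_threshold)
    return list(expr.index[keep])


def _penalty_grid(n: int) -> np.ndarray:
    # C = 1 / (n_samples * lambda) in sklearn terms; this range brackets the
    # useful part of the path for standardized expression data
    return np.logspace(-2.0, 1.0, n)


def _fit_enet(X, y, C: float, alpha: float, max_iter: int) -> LogisticRegression:
    model = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,  # elastic-net mixing; 1 = lasso
        C=C,
        max_iter=max_iter,
        tol=1e-3,
        random_state=0,  # saga shuffles samples; pin for reproducibility
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence handled by caller
        model.fit(X, y)
    return model


def _cv_choose_C(X, y, cfg: SelectionConfig, seed: int) -> float:
    """Pick the penalty strength minimising cross-validated log-loss."""
    grid = _penalty_grid(cfg.n_penalty)
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed)
    losses = np.zeros(len(grid))
    eps = 1e-12
    for train, test in skf.split(X, y):
        for j, C in enumerate(grid):
            m = _fit_enet(X[train], y[train], C, cfg.alpha, cfg.max_iter)
            p = np.clip(m.predict_proba(X[test])[:, 1], eps, 1 - eps)
            losses[j] += -np.mean(y[test] * np.log(p) + (1 - y[test]) * np.log(1 - p))
    return float(grid[int(np.argmin(losses))])


def _stratified_resample(rng: np.random.Generator, is_case: np.ndarray) -> np.ndarray:
    idx_case = np.flatnonzero(is_case)
    idx_ctrl = np.flatnonzero(~is_case)
    take = np.concatenate(
        [
            rng.choice(idx_case, size=len(idx_case), replace=True),
            rng.choice(idx_ctrl, size=len(idx_ctrl), replace=True),
        ]
    )
    return take


def stability_select(
    expr: pd.DataFrame,
    is_case,
    cfg: SelectionConfig,
) -> StabilityResult:
    """Bootstrap elastic-net stability selection over an (already t-filtered)
    feature set.

    For each of ``cfg.n_boot`` class-stratified bootstrap resamples (size n,
    with replacement, seeded deterministically from ``cfg.seed`` and the
    round number), an elastic-net logistic regression of case status on all
    candidate features is fitted — features standardized to unit variance —
    and every feature with a nonzero coefficient has its tally incremented.
    Features with tally / n_boot >= ``cfg.tally_threshold`` are selected.
    Rounds whose solver fails are skipped, with a warning if more than 1% of
    rounds are lost.
    """
    is_case = np.asarray(is_case, dtype=bool)
    X_all = expr.to_numpy(dtype=float).T  # samples x features
    feature_ids = list(expr.index)
    tally = np.zeros(len(feature_ids), dtype=int)

    global_C = None
    if cfg.tuning == "global":
        mu, sd = X_all.mean(axis=0), X_all.std(axis=0)
        sd[sd == 0] = 1.0
        global_C = _cv_choose_C(
            (X_all - mu) / sd, is_case.astype(int), cfg, child_seed(cfg.seed, "globalcv")
        )

    n_skipped = 0
    for b in range(cfg.n_boot):
        rng = substream(cfg.seed, "boot", b)
        take = _stratified_resample(rng, is_case)
        X = X_all[take]
        y = is_case[take].astype(int)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
        try:
            C = global_C if global_C is not None else _cv_choose_C(
                X, y, cfg, child_seed(cfg.seed, "cv", b)
            )
            model = _fit_enet(X, y, C, cfg.alpha, cfg.max_iter)
        except Exception:  # solver failure: skip the round
            n_skipped += 1
            continue
        tally += (model.coef_.ravel() != 0.0).astype(int)

    if n_skipped > 0.01 * cfg.n_boot:
        warnings.warn(
            f"{n_skipped}/{cfg.n_boot} bootstrap rounds skipped (solver failures)",
            stacklevel=2,
        )
    n_eff = cfg.n_boot - n_skipped
    tally_s = pd.Series(tally, index=feature_ids, name="tally")
    selected = list(tally_s.index[tally_s / max(n_eff, 1) >= cfg.tally_threshold])
    return StabilityResult(
        tally=tally_s,
        n_boot=n_eff,
        selected=selected,
        t_pass=feature_ids,
        n_skipped=n_skipped,
    )
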