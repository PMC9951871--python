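"""Data-scaling power-law fits and Wilcoxon-based strategy ranking.

Downstream segmentation accuracy as a function of the amount of pretraining
data follows a saturating power law ``y = a * x**k + c`` (x in percent of
the standard pretraining set, with x = 0 the fully-supervised baseline;
y the mean test Dice).  The fit is nonlinear least squares with multiple
``k`` starts, reported with the Residual Standard Error
``S = sqrt(sum((y - yhat)**2) / (n - 2))``.

Pretraining strategies are compared against the supervised baseline with
one-sided Wilcoxon signed-rank tests on paired class-averaged Dice scores
pooled across label-limited regimes; per dataset the strategies are ranked
by ascending p-value and the strategy appearing in the top three for both
datasets is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ScalingFit",
    "PowerLawRegressor",
    "fit_power_law",
    "wilcoxon_one_sided",
    "rank_strategies",
    "RankingResult",
]


# ---------------------------------------------------------------------------
# power-law scaling fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingFit:
    """Fitted power-law parameters and goodness of fit."""

    a: float
    k: float
    c: float
    s: float  # residual standard error, Dice units
    points: tuple[tuple[float, float], ...]

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.a * np.power(x, self.k, where=x > 0, out=np.zeros_like(x)) + self.c


class PowerLawRegressor(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of ``y = a * x**k + c`` with ``k > 0``.

    Three-parameter power laws fitted to a handful of points are sensitive to
    initialization, so the fit is restarted from several exponents
    (``k_starts``) and the best solution kept.  ``k`` is constrained positive
    so that x = 0 cleanly maps to the offset ``c`` (the supervised baseline).

    Fitted attributes: ``a_``, ``k_``, ``c_`` and the residual standard
    error ``s_`` computed with the ``n - 2`` denominator.
    """

    def __init__(self, k_starts: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 1.0),
                 k_max: float = 5.0):
        self.k_starts = k_starts
        self.k_max = k_max

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if np.unique(x).size < 4:
            raise ValueError("power-law fit needs >= 4 distinct x values")
        if np.any(x < 0):
            raise ValueError("x values must be >= 0")

        def model(theta, xv):
            a, k, c = theta
            return a * np.power(xv, k, where=xv > 0, out=np.zeros_like(xv)) + c

        def resid(theta):
            return model(theta, x) - y

        c0 = y[np.argmin(x)]
        scale = y.max() - y.min() or 1.0
        best = None
        for k0 in self.k_starts:
            with np.errstate(all="ignore"):
                xk = np.power(x, k0, where=x > 0, out=np.zeros_like(x))
                denom = xk.max() or 1.0
                a0 = (y[np.argmax(x)] - c0) / denom
                try:
                    sol = least_squares(
                        resid, x0=[a0 if np.isfinite(a0) else scale, k0, c0],
                        bounds=([-np.inf, 1e-8, -np.inf], [np.inf, self.k_max, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14,
                    )
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None or not best.success and not np.isfinite(best.cost):
            raise RuntimeError("power-law fit failed to converge from every start")
        self.a_, self.k_, self.c_ = (float(v) for v in best.x)
        res = resid(best.x)
        n = x.size
        self.s_ = float(np.sqrt((res**2).sum() / (n - 2)))
        self.n_points_ = n
        self.points_ = tuple(zip(x.tolist(), y.tolist()))
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return self.a_ * np.power(x, self.k_, where=x > 0, out=np.zeros_like(x)) + self.c_

    def to_scaling_fit(self) -> ScalingFit:
        return ScalingFit(self.a_, self.k_, self.c_, self.s_, self.points_)


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> ScalingFit:
    """Fit ``y = a * x**k + c`` (k > 0) by multi-start nonlinear least squares
    and report the residual standard error with the ``n - 2`` denominator."""
    return PowerLawRegressor().fit(x, y).to_scaling_fit()


# ---------------------------------------------------------------------------
# one-sided Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _signed_rank_stat(diff: np.ndarray):
    ranks = rankdata(np.abs(diff))  # midranks for ties
    w_plus = float(ranks[diff > 0].sum())
    return w_plus, ranks


def _exact_tail_p(ranks: np.ndarray, w_obs: float, upper: bool) -> float:
    """Exact null tail probability by enumerating all 2^n sign assignments
    (valid with midrank ties since enumeration uses the observed ranks)."""
    n = len(ranks)
    totals = np.zeros(1)
    for r in ranks:  # dynamic enumeration of all achievable W+ sums
        totals = np.concatenate([totals, totals + r])
    if upper:
        return float((totals >= w_obs - 1e-12).mean())
    return float((totals <= w_obs + 1e-12).mean())


def wilcoxon_one_sided(
    a: Sequence[float],
    b: Sequence[float],
    alternative: Literal["greater", "less"] = "greater",
    exact_max_n: int = 12,
) -> float:
    """One-sided Wilcoxon signed-rank test on paired samples.

    Tests whether ``a`` tends to exceed ``b`` (``alternative='greater'``) via
    the signed-rank statistic of the differences ``a - b``.  Zero differences
    are dropped; ties receive midranks.  The null distribution is enumerated
    exactly for n <= ``exact_max_n`` remaining pairs and approximated by a
    tie-corrected normal otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        raise ValueError("all paired differences are zero; test is degenerate")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero paired differences, got {n}")
    w_plus, ranks = _signed_rank_stat(diff)
    if n <= exact_max_n:
        return _exact_tail_p(ranks, w_plus, upper=(alternative == "greater"))
    mu = n * (n + 1) / 4
    # tie correction to the null variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24 - tie_term)
    z = (w_plus - mu) / sigma
    if alternative == "greater":
        return float(norm.sf(z))
    return float(norm.cdf(z))


# ---------------------------------------------------------------------------
# strategy ranking
# ---------------------------------------------------------------------------

@dataclass
class RankingResult:
    """Per-dataset strategy rankings and the consensus selection."""

    rankings: dict[str, pd.DataFrame]  # dataset -> (strategy, p_value, rank)
    selected: str | None  # strategy label in every dataset's top 3, or None
    top3: dict[str, tuple[str, ...]]

    @property
    def has_consensus(self) -> bool:
        return self.selected is not None


def rank_strategies(scores: pd.DataFrame, top_k: int = 3) -> RankingResult:
    """Rank pretraining strategies by Wilcoxon p-value per dataset and pick
    the consensus strategy.

    ``scores`` is a long table with columns ``strategy, dataset, image_id,
    regime, dice_ssl, dice_supervised`` holding paired class-averaged Dice
    scores.  Per (strategy, dataset) the scores are pooled across regimes and
    tested one-sided for SSL > supervised; strategies are sorted by ascending
    p-value per dataset.  The selected strategy is the first one (by mean
    rank) appearing in the top ``top_k`` of every dataset; ``selected`` is
    None when the top sets are disjoint.
    """
    required = {"strategy", "dataset", "image_id", "regime", "dice_ssl", "dice_supervised"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"scores table is missing columns {sorted(missing)}")
    rankings = {}
    for dataset, group in scores.groupby("dataset"):
        rows = []
        for strategy, g in group.groupby("strategy"):
            p = wilcoxon_one_sided(g["dice_ssl"].to_numpy(),
                                   g["dice_supervised"].to_numpy(), "greater")
            rows.append({"strategy": strategy, "p_value": p})
        df = pd.DataFrame(rows).sort_values(
            ["p_value", "strategy"], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        rankings[dataset] = df
    top3 = {d: tuple(df["strategy"].head(top_k)) for d, df in rankings.items()}
    common = set.intersection(*(set(t) for t in top3.values())) if top3 else set()
    selected = None
    if common:
        # break ties by the best (lowest) mean rank across datasets
        mean_rank = {
            s: np.mean([
                float(df.loc[df["strategy"] == s, "rank"].iloc[0])
                for df in rankings.values()
            ])
            for s in common
        }
        selected = min(sorted(common), key=lambda s: mean_rank[s])
    return RankingResult(rankings, selected, top3)
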