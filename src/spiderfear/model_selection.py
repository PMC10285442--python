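"""AIC-based linear-model reduction for the SFI regression.

The study question is how much of the Spider Fear Index is explained by the
subjectively measured fear variables (BAT, questionnaires, per-category fear
scores, group, age).  Models are ordinary least squares with an intercept;
the Gaussian-likelihood AIC is

    AIC = n * ln(RSS / n) + 2 * (k + 1)

with k fitted coefficients (the +1 counts the error variance; additive
constants cancel in comparisons).  Backward stepwise elimination is the
default strategy; exhaustive search over all subsets is available for up to
12 candidates.  Per-term F tests of the selected model are partial
(drop-one) F statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin


@dataclass
class SelectionResult:
    selected_terms: tuple[str, ...]
    aic: float
    r_squared: float
    term_tests: pd.DataFrame  # term, F, p
    full_aic: float

    def __post_init__(self) -> None:
        assert self.aic <= self.full_aic + 1e-9


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * (k + 1)


class StepwiseAIC(BaseEstimator, RegressorMixin):
    """AIC-guided linear-model reduction (sklearn estimator protocol).

    Parameters
    ----------
    strategy : {"backward", "exhaustive"}
        Backward stepwise elimination (default) or exhaustive subset search
        (raises above 12 candidates).
    """

    def __init__(self, strategy: str = "backward"):
        self.strategy = strategy

    def fit(self, X, y) -> "StepwiseAIC":
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xm = X.to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xm.shape[1])]
        y = np.asarray(y, dtype=float)
        n, p = Xm.shape
        if n <= p + 1:
            raise ValueError("need n > number of candidate predictors + 1")
        ones = np.ones((n, 1))

        def design(sel: tuple[int, ...]) -> np.ndarray:
            return np.hstack([ones, Xm[:, list(sel)]]) if sel else ones

        # floor the RSS at numerical-zero relative to the total SS, so exact
        # fits compare by parsimony alone rather than by log of rounding error
        tss0 = float(np.sum((y - y.mean()) ** 2))
        rss_floor = 1e-12 * max(tss0, 1e-300)

        def aic_of(sel: tuple[int, ...]) -> float:
            return _aic(max(_ols_rss(design(sel), y), rss_floor), n, 1 + len(sel))

        full = tuple(range(p))
        full_aic = aic_of(full)
        if self.strategy == "backward":
            current, cur_aic = full, full_aic
            improved = True
            while improved and current:
                improved = False
                best_drop, best_aic = None, cur_aic
                for j in current:
                    cand = tuple(i for i in current if i != j)
                    a = aic_of(cand)
                    if a < best_aic - 1e-12:
                        best_drop, best_aic = cand, a
                if best_drop is not None:
                    current, cur_aic = best_drop, best_aic
                    improved = True
        elif self.strategy == "exhaustive":
            if p > 12:
                raise ValueError("exhaustive search limited to 12 candidates")
            current, cur_aic = (), aic_of(())
            for r in range(1, p + 1):
                for sel in combinations(range(p), r):
                    a = aic_of(sel)
                    if a < cur_aic - 1e-12:
                        current, cur_aic = sel, a
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")

        Xs = design(current)
        coef, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        rss = _ols_rss(Xs, y)
        tss = float(np.sum((y - y.mean()) ** 2))
        df_res = n - Xs.shape[1]
        rows = []
        for pos, j in enumerate(current):
            reduced = tuple(i for i in current if i != j)
            rss_red = _ols_rss(design(reduced), y)
            f = (rss_red - rss) / (rss / df_res) if rss > 0 else np.inf
            pval = float(stats.f.sf(f, 1, df_res)) if np.isfinite(f) else 0.0
            rows.append({"term": names[j], "F": float(f), "p": pval})
        self.feature_names_in_ = np.array(names)
        self.selected_terms_ = tuple(names[j] for j in current)
        self.selected_idx_ = current
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        self.aic_ = float(cur_aic)
        self.full_aic_ = float(full_aic)
        self.r_squared_ = 1.0 - rss / tss if tss > 0 else 1.0
        self.term_tests_ = pd.DataFrame(rows, columns=["term", "F", "p"])
        return self

    def predict(self, X) -> np.ndarray:
        Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return self.intercept_ + Xm[:, list(self.selected_idx_)] @ self.coef_

    def result(self) -> SelectionResult:
        return SelectionResult(selected_terms=self.selected_terms_, aic=self.aic_,
                               r_squared=self.r_squared_, term_tests=self.term_tests_,
                               full_aic=self.full_aic_)


def lm_aic_select(response, candidate_predictors, strategy: str = "backward") -> SelectionResult:
    """Reduce a linear model of ``response`` on the candidates by AIC."""
    return StepwiseAIC(strategy=strategy).fit(candidate_predictors, response).result()
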