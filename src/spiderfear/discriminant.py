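"""Two-group discriminant function analysis.

Linear discriminant classification with pooled within-group covariance
(sklearn's LinearDiscriminantAnalysis under the hood), reported the way
phobia studies report DFA: a resubstitution confusion matrix with per-group
percent correct, plus per-variable one-way ANOVA F statistics ranking each
variable's univariate discriminating power.  Leave-one-out cross-validated
assignment is available as an option; resubstitution (apparent accuracy) is
the default reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


@dataclass
class ConfusionMatrix:
    counts: pd.DataFrame  # true group x predicted group
    percent_correct: dict  # per-group and "total"

    def __post_init__(self) -> None:
        for v in self.percent_correct.values():
            assert -1e-9 <= v <= 100 + 1e-9


def onewayF(x: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F (between/within) for one variable across groups."""
    groups = [np.asarray(x)[labels == g] for g in np.unique(labels)]
    grand = np.concatenate(groups).mean()
    df_b = len(groups) - 1
    df_w = sum(len(g) for g in groups) - len(groups)
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    if ss_w == 0:
        return np.inf, 0.0
    f = (ss_b / df_b) / (ss_w / df_w)
    return float(f), float(stats.f.sf(f, df_b, df_w))


class GroupDiscriminant(BaseEstimator, ClassifierMixin):
    """Two-class LDA with DFA-style reporting.

    Parameters
    ----------
    shrinkage : float or None
        Optional covariance regularization (sklearn 'lsqr' solver) used as a
        fallback when the pooled covariance is singular; None fits the plain
        pooled-covariance discriminant.
    """

    def __init__(self, shrinkage: float | None = None):
        self.shrinkage = shrinkage

    def fit(self, X, y) -> "GroupDiscriminant":
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            Xm = X.to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            self.feature_names_ = [f"x{j}" for j in range(Xm.shape[1])]
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("exactly two groups required")
        if counts.min() < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.shrinkage is None:
            lda = LinearDiscriminantAnalysis(solver="svd")
        else:
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=self.shrinkage)
        lda.fit(Xm, y)
        self.lda_ = lda
        self.classes_ = classes
        rows = [
            {"variable": name, **dict(zip(("F", "p"), onewayF(Xm[:, j], y)))}
            for j, name in enumerate(self.feature_names_)
        ]
        self.variable_F_ = (pd.DataFrame(rows)
                            .sort_values("F", ascending=False)
                            .reset_index(drop=True))
        self._X, self._y = Xm, y
        return self

    def predict(self, X) -> np.ndarray:
        Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return self.lda_.predict(Xm)

    def confusion(self, cross_validate: bool = False) -> ConfusionMatrix:
        """Assignment table; resubstitution by default, LOO optionally."""
        if cross_validate:
            from sklearn.model_selection import LeaveOneOut, cross_val_predict

            pred = cross_val_predict(self.lda_, self._X, self._y, cv=LeaveOneOut())
        else:
            pred = self.lda_.predict(self._X)
        classes = list(self.classes_)
        counts = pd.DataFrame(0, index=classes, columns=classes)
        for t, p in zip(self._y, pred):
            counts.loc[t, p] += 1
        pct = {g: 100.0 * counts.loc[g, g] / counts.loc[g].sum() for g in classes}
        pct["total"] = 100.0 * np.trace(counts.to_numpy()) / len(self._y)
        return ConfusionMatrix(counts=counts, percent_correct=pct)


def lda_classify(features, labels, cross_validate: bool = False):
    """DFA convenience wrapper: (ConfusionMatrix, per-variable F table)."""
    model = GroupDiscriminant().fit(features, labels)
    return model.confusion(cross_validate=cross_validate), model.variable_F_
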