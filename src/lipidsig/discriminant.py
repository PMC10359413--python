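"""Supervised linear discriminant analysis of FA profiles.

Canonical discriminant functions are the eigenvectors of W^-1 B, where W
is the pooled within-groups covariance and B the between-groups scatter;
classes share W and carry equal prior probabilities, so a sample is
assigned to the nearest class centroid in discriminant space (Mahalanobis
distance under the within-groups metric).  With g classes and p
variables there are min(g-1, p) functions; their eigenvalues partition
the between-group variance, reported as percentages summing to 100.

When p >= n (44 variables, 16 samples) W is singular; by default it is
ridge-regularised with lambda = reg * trace(W)/p, reported in the result.
Resubstitution and leave-one-out classification measure (optimistic and
honest) predictive accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = ["LDAResult", "fit_lda", "loo_accuracy"]


class LDAError(ValueError):
    pass


@dataclass
class LDAResult:
    eigenvalues: np.ndarray  # one per discriminant function, descending
    pct_variance: np.ndarray  # percentages, sum to 100
    scores: pd.DataFrame  # samples x functions
    coefficients: pd.DataFrame  # variables x functions (raw discriminant)
    structure: pd.DataFrame  # pooled within-group variable-score correlations
    class_means: pd.DataFrame  # class x functions centroids
    predictions: pd.Series  # resubstitution labels
    classification_table: pd.DataFrame  # true x predicted counts
    priors: pd.Series
    regularization: float  # ridge added to the pooled covariance diagonal
    true_labels: pd.Series = None  # type: ignore[assignment]

    @property
    def n_functions(self) -> int:
        return len(self.eigenvalues)

    @property
    def resubstitution_accuracy(self) -> float:
        return float(
            (self.predictions.to_numpy() == self.true_labels.to_numpy()).mean()
        )


def _scatter(X: np.ndarray, y: np.ndarray, classes: np.ndarray):
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for c in classes:
        Xi = X[y == c]
        mu = Xi.mean(axis=0)
        d = Xi - mu
        W += d.T @ d
        B += len(Xi) * np.outer(mu - grand, mu - grand)
    W /= n - len(classes)  # pooled within-groups covariance
    return W, B


def fit_lda(
    X: pd.DataFrame,
    labels: pd.Series,
    reg: float = 1e-6,
    prune: bool = False,
) -> LDAResult:
    """Fit canonical LDA with equal priors and the within-groups covariance.

    Parameters
    ----------
    X : DataFrame
        Samples x variables (raw mol-% by default in this pipeline).
    labels : Series
        Class label per sample (e.g. diagnosis, or diagnosis x tissue).
    reg : float
        Ridge factor; lambda = reg * trace(W)/p is added to W's diagonal
        whenever W is singular (set ``reg=0`` to disable, in which case a
        singular W is rejected naming the collinear variables).
    prune : bool
        Drop exactly collinear/constant variables before fitting instead
        of relying on the ridge.
    """
    X = pd.DataFrame(X)
    labels = pd.Series(labels).reindex(X.index)
    classes = np.array(sorted(labels.unique()))
    if len(classes) < 2:
        raise LDAError("need at least 2 classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise LDAError(f"every class needs >= 2 samples: {dict(counts)}")
    if prune:
        keep = _prune_collinear(X.to_numpy(float))
        X = X.iloc[:, keep]
    Xa = X.to_numpy(float)
    y = labels.to_numpy()
    n, p = Xa.shape
    W, B = _scatter(Xa, y, classes)
    lam = 0.0
    rank = np.linalg.matrix_rank(W)
    if rank < p:
        if reg <= 0:
            bad = _collinear_variables(Xa, y, classes, X.columns)
            raise LDAError(
                "singular pooled within-groups covariance; collinear or "
                f"constant variables: {bad}"
            )
        lam = reg * np.trace(W) / p
        W = W + lam * np.eye(p)
    m = min(len(classes) - 1, p)
    evals, evecs = linalg.eigh(B, W)  # generalized symmetric problem
    order = np.argsort(evals)[::-1][:m]
    evals = np.clip(evals[order], 0.0, None)
    V = evecs[:, order]  # W-orthonormal: V.T @ W @ V = I
    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.full(m, 100.0 / m)
    func_names = [f"function_{i + 1}" for i in range(m)]
    scores = pd.DataFrame((Xa - Xa.mean(axis=0)) @ V, index=X.index,
                          columns=func_names)
    # orient: first (alphabetical) class has negative mean on each function
    first = classes[0]
    sign = np.where(scores[labels == first].mean(axis=0).to_numpy() > 0, -1.0, 1.0)
    V = V * sign
    scores = scores * sign
    class_means = scores.groupby(labels).mean()
    # structure coefficients: pooled within-group correlation of each
    # variable with each function score
    Sw_full, _ = _scatter(np.hstack([Xa, scores.to_numpy()]), y, classes)
    cov_xs = Sw_full[:p, p:]
    sx = np.sqrt(np.diag(Sw_full)[:p])
    ss = np.sqrt(np.diag(Sw_full)[p:])
    with np.errstate(divide="ignore", invalid="ignore"):
        structure = cov_xs / np.outer(sx, ss)
    preds = _classify(scores.to_numpy(), class_means.to_numpy(),
                      class_means.index.to_numpy())
    predictions = pd.Series(preds, index=X.index, name="predicted")
    table = pd.crosstab(labels.rename("true"), predictions)
    res = LDAResult(
        eigenvalues=evals,
        pct_variance=pct,
        scores=scores,
        coefficients=pd.DataFrame(V, index=X.columns, columns=func_names),
        structure=pd.DataFrame(structure, index=X.columns, columns=func_names),
        class_means=class_means,
        predictions=predictions,
        classification_table=table,
        priors=pd.Series(1.0 / len(classes), index=classes, name="prior"),
        regularization=lam,
        true_labels=labels.rename("true"),
    )
    return res


def _classify(scores, centroids, class_names):
    # scores are whitened w.r.t. the within-groups covariance, so nearest
    # centroid in discriminant space == smallest Mahalanobis distance;
    # equal priors add no offset.  Ties go to the alphabetically first class.
    d2 = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return class_names[np.argmin(d2, axis=1)]


def _prune_collinear(X: np.ndarray, tol: float = 1e-10) -> list[int]:
    """Greedy QR-based selection of a full-rank variable subset."""
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j] - X[:, j].mean()
        if basis.shape[1]:
            col = col - basis @ (basis.T @ col)
        nrm = np.linalg.norm(col)
        if nrm > tol * max(1.0, np.linalg.norm(X[:, j])):
            keep.append(j)
            basis = np.hstack([basis, (col / nrm)[:, None]])
    return keep


def _collinear_variables(X, y, classes, columns) -> list[str]:
    keep = _prune_collinear(X)
    return [c for i, c in enumerate(columns) if i not in keep]


def loo_accuracy(
    X: pd.DataFrame, labels: pd.Series, reg: float = 1e-6
) -> float:
    """Leave-one-out classification accuracy of the discriminant rule.

    The model (including regularisation) is refitted without each sample
    in turn and the held-out sample is classified from its score.
    """
    X = pd.DataFrame(X)
    labels = pd.Series(labels).reindex(X.index)
    correct = 0
    for s in X.index:
        rest = X.index != s
        fit = fit_lda(X.loc[rest], labels.loc[rest], reg=reg)
        V = fit.coefficients.to_numpy()
        center = X.loc[rest].to_numpy(float).mean(axis=0)
        score = (X.loc[s].to_numpy(float) - center) @ V
        pred = _classify(score[None, :], fit.class_means.to_numpy(),
                         fit.class_means.index.to_numpy())[0]
        correct += pred == labels.loc[s]
    return correct / len(X.index)
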