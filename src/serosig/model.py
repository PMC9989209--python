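"""All-in multiple logistic regression and classification metrics.

The signature classifier is an unpenalized logistic regression over the
selected, Z-transformed markers ("all in": every selected feature enters the
model).  Fitting is maximum likelihood by iteratively reweighted least
squares (Newton) with step halving, so the log-likelihood is non-decreasing
across iterations.  Complete separation — where the likelihood has no finite
maximizer and coefficients diverge — is detected and flagged rather than
silently returned as a converged fit.

Evaluation follows the diagnostic-study conventions: predicted probability
at or above the 0.5 critical value indicates ASD (the positive class), and
the AUC is the Mann-Whitney concordance probability with ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

_SEPARATION_COEF = 15.0  # |beta| beyond this on the z scale signals separation


@dataclass
class LogisticModel:
    """Fitted logistic formula p(x) = expit(beta0 + sum_m beta_m z_m)."""

    intercept: float
    coefficients: np.ndarray
    marker_ids: list[str]
    n_iter: int = 0
    converged: bool = True
    separated: bool = False
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        if len(self.coefficients) != len(self.marker_ids):
            raise ValueError("one coefficient per selected marker required")

    def equation(self, digits: int = 4) -> str:
        """Human-readable logistic equation on the z scale."""
        terms = "".join(
            f" {'+' if b >= 0 else '-'} {abs(b):.{digits}f}*z[{mid}]"
            for mid, b in zip(self.marker_ids, self.coefficients)
        )
        return f"logit(p) = {self.intercept:+.{digits}f}{terms}"


@dataclass
class Metrics:
    """Confusion counts and derived rates at a stated probability cutoff."""

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else float("nan")


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # ll = sum y*eta - log(1 + e^eta), stable for large |eta|
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    z_matrix: np.ndarray,
    labels: np.ndarray,
    marker_ids: list[str] | None = None,
    *,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticModel:
    """Maximum-likelihood logistic fit by IRLS with step halving.

    Converges when the maximum absolute score (gradient) drops below ``tol``
    or after ``max_iter`` Newton steps.  ``ridge`` adds an optional L2 penalty
    on the slopes (not the intercept) for separable folds; the default is the
    unpenalized fit.  On complete separation the coefficients at the
    iteration cap are returned with ``separated=True``.
    """
    x = np.asarray(z_matrix, float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit")
    n, p = x.shape
    if marker_ids is None:
        marker_ids = [f"x{j}" for j in range(p)]
    if n < p + 1:
        import warnings

        warnings.warn(
            f"fitting {p} coefficients on only {n} rows; estimates may be unstable",
            stacklevel=2,
        )
    design = np.column_stack([np.ones(n), x])
    penalty = np.zeros(p + 1)
    penalty[1:] = ridge
    beta = np.zeros(p + 1)
    converged = False
    n_iter = 0
    eta = design @ beta
    ll = _log_likelihood(eta, y) - 0.5 * np.sum(penalty * beta**2)
    for n_iter in range(1, max_iter + 1):
        prob = expit(eta)
        score = design.T @ (y - prob) - penalty * beta
        if np.max(np.abs(score)) < tol:
            converged = True
            n_iter -= 1
            break
        w = np.clip(prob * (1.0 - prob), 1e-12, None)
        hessian = (design * w[:, None]).T @ design + np.diag(penalty)
        try:
            step = np.linalg.solve(hessian, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hessian, score, rcond=None)[0]
        # halve until the (penalized) log-likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            eta_c = design @ candidate
            ll_c = _log_likelihood(eta_c, y) - 0.5 * np.sum(penalty * candidate**2)
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        beta, eta, ll = candidate, eta_c, ll_c
    separated = ridge == 0.0 and float(np.max(np.abs(beta))) > _SEPARATION_COEF
    return LogisticModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        marker_ids=list(marker_ids),
        n_iter=n_iter,
        converged=converged,
        separated=separated,
        ridge=ridge,
    )


def predict_prob(model: LogisticModel, z_matrix: np.ndarray) -> np.ndarray:
    """Predicted case probability per row; columns must match the model."""
    x = np.asarray(z_matrix, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] != len(model.marker_ids):
        raise ValueError(
            f"matrix has {x.shape[1]} markers, model expects {len(model.marker_ids)}"
        )
    return expit(model.intercept + x @ model.coefficients)


def classify(probs: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Label 1 (ASD) iff p >= cutoff: the 0.5 boundary itself is called ASD."""
    probs = np.asarray(probs, float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs >= cutoff).astype(int)


def confusion_metrics(
    predicted: np.ndarray, true: np.ndarray, cutoff: float = 0.5
) -> Metrics:
    """Confusion counts and rates with ASD (1) as the positive class."""
    pred = np.asarray(predicted, int)
    y = np.asarray(true, int)
    if len(pred) != len(y) or len(y) == 0:
        raise ValueError("need equal-length, nonempty label vectors")
    if set(np.unique(pred)) - {0, 1} or set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return Metrics(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        cutoff=cutoff,
    )


def roc_auc(scores: np.ndarray, true: np.ndarray) -> tuple[float, np.ndarray]:
    """Mann-Whitney AUC and the threshold-swept ROC point list.

    AUC = (number of (case, control) pairs where the case outscores the
    control, plus half the tied pairs) / (n_case * n_control).  ROC points
    are (fpr, tpr) at every distinct score threshold, from (0, 0) to (1, 1).
    """
    s = np.asarray(scores, float)
    y = np.asarray(true, int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    sorted_scores = s[order]
    sorted_y = y[order]
    tps = np.cumsum(sorted_y == 1)
    fps = np.cumsum(sorted_y == 0)
    # keep the last index of each distinct score (all rows at that threshold in)
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    points = np.column_stack(
        [np.r_[0.0, fps[distinct] / n_neg], np.r_[0.0, tps[distinct] / n_pos]]
    )
    return float(auc), points
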