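"""Univariate logistic regression, leave-one-out CV and ROC AUC.

The evaluation procedure for comparing risk metrics: each scalar metric
(B_net, a model's ΔAPD90, or hERG block) is fit one at a time in a
logistic regression ``logit P(risk) = a + b*x`` by maximum likelihood,
assessed by leave-one-out cross-validation — train on n−1 compounds,
predict the held-out one, so every compound serves in the test set —
and the out-of-sample predicted probabilities are summarised as a ROC
AUC with the midrank Mann–Whitney tie rule.

The fitter is written here rather than delegated so that its behaviour
under the small, often separable datasets of this field is explicit:
complete or quasi-complete separation is detected up front and handled
by an L2-penalised refit (λ = 1e-6) whose out-of-sample probability
ordering — the only thing AUC consumes — matches the limiting MLE.
Folds whose training labels are single-class fall back to the training
positive rate instead of being dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .errors import DegenerateLabelsError, DomainError

logger = logging.getLogger(__name__)

_TOL = 1e-8  # convergence tolerance on log-likelihood change
_MAX_ITER = 100
_RIDGE = 1e-6  # quadratic coefficient penalty used on separation


@dataclass(frozen=True)
class MetricVector:
    """One metric's values and binary labels over an ordered compound list."""

    compounds: tuple[str, ...]
    x: tuple[float, ...]
    y: tuple[int, ...]
    metric_name: str
    scheme_name: str
    dataset_name: str = "dataset"

    def __post_init__(self) -> None:
        if not len(self.compounds) == len(self.x) == len(self.y):
            raise DomainError("compounds, x and y must have equal lengths")
        if any(label not in (0, 1) for label in self.y):
            raise DomainError("labels must be binary")


@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    slope: float
    converged: bool
    penalised: bool


@dataclass
class EvaluationTable:
    """Grid of LOOCV ROC AUC cells: dataset rows by metric columns, one scheme."""

    scheme: str
    rows: list[str] = field(default_factory=list)
    columns: list[str] = field(default_factory=list)
    cells: dict[tuple[str, str], float | None] = field(default_factory=dict)
    n_compounds: dict[tuple[str, str], int] = field(default_factory=dict)
    n_positive: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_records(self) -> list[dict[str, object]]:
        return [
            {
                "dataset": dataset,
                "scheme": self.scheme,
                "metric": metric,
                "n_compounds": self.n_compounds[(dataset, metric)],
                "n_positive": self.n_positive[(dataset, metric)],
                "loocv_roc_auc": self.cells[(dataset, metric)],
            }
            for dataset in self.rows
            for metric in self.columns
            if (dataset, metric) in self.cells
        ]


def _validate_xy(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d arrays of equal length")
    if x.size < 2:
        raise DomainError("need at least two observations")
    if not np.all(np.isfinite(x)):
        raise DomainError("x contains non-finite values")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels contain a single class")


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    """Complete or quasi-complete separation of a univariate predictor.

    Either every positive x is >= every negative x or vice versa; in
    both cases the unpenalised MLE diverges.
    """
    pos, neg = x[y == 1], x[y == 0]
    return pos.min() >= neg.max() or pos.max() <= neg.min()


def _newton(x: np.ndarray, y: np.ndarray, ridge: float) -> tuple[float, float, bool]:
    """Newton–Raphson on the (optionally ridge-penalised) Bernoulli log-likelihood."""
    design = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    last_ll = -np.inf
    for _ in range(_MAX_ITER):
        eta = design @ beta
        p = expit(eta)
        # log-likelihood via logaddexp for numerical stability at large |eta|
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * ridge * beta @ beta)
        grad = design.T @ (y - p) - ridge * beta
        w = np.clip(p * (1.0 - p), 1e-12, None)
        hess = design.T @ (design * w[:, None]) + ridge * np.eye(2)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return float(beta[0]), float(beta[1]), False
        # halve the step until the objective does not decrease
        scale = 1.0
        while scale > 1e-8:
            trial = beta + scale * step
            eta_t = design @ trial
            ll_t = float(
                np.sum(y * eta_t - np.logaddexp(0.0, eta_t))
                - 0.5 * ridge * trial @ trial
            )
            if ll_t >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        if abs(ll - last_ll) < _TOL:
            return float(beta[0]), float(beta[1]), True
        last_ll = ll
    return float(beta[0]), float(beta[1]), False


def fit_logistic(x, y) -> LogisticFit:
    """Maximum-likelihood fit of ``logit p = intercept + slope * x``.

    On detected separation the fit is repeated with a small L2 penalty
    and flagged ``penalised``.  A constant predictor yields slope 0 and
    an intercept at the empirical log-odds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_xy(x, y)

    if np.ptp(x) == 0.0:
        rate = float(np.mean(y))
        return LogisticFit(float(np.log(rate / (1.0 - rate))), 0.0, True, False)

    if _is_separated(x, y):
        intercept, slope, converged = _newton(x, y, _RIDGE)
        logger.debug("separation detected; penalised refit (slope=%.3g)", slope)
        return LogisticFit(intercept, slope, converged, True)

    intercept, slope, converged = _newton(x, y, 0.0)
    if not converged or not np.isfinite([intercept, slope]).all():
        intercept, slope, converged = _newton(x, y, _RIDGE)
        return LogisticFit(intercept, slope, converged, True)
    return LogisticFit(intercept, slope, converged, False)


def predict_prob(fit: LogisticFit, x: float) -> float:
    """Inverse-logit of the linear predictor at ``x``."""
    if not np.isfinite(x):
        raise DomainError(f"x must be finite, got {x}")
    return float(expit(fit.intercept + fit.slope * x))


def loocv_probabilities(
    data: MetricVector, events: list[str] | None = None
) -> dict[str, float]:
    """Out-of-sample predicted probability for every compound.

    For each compound a logistic model is fit to the other n−1 and the
    held-out compound's risk probability predicted.  Folds whose
    training labels collapse to one class fall back to the training
    positive rate; no fold is ever dropped.  Per-fold anomalies are
    logged and, if ``events`` is given, appended to it.
    """
    x = np.asarray(data.x, dtype=float)
    y = np.asarray(data.y, dtype=float)
    if x.size < 3:
        raise DomainError("leave-one-out needs at least three compounds")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels contain a single class")

    probs: dict[str, float] = {}
    for i, compound in enumerate(data.compounds):
        mask = np.ones(x.size, dtype=bool)
        mask[i] = False
        x_train, y_train = x[mask], y[mask]
        if len(np.unique(y_train)) < 2:
            prob = float(np.mean(y_train))
            message = f"fold {compound}: single-class training labels, using positive rate"
            logger.debug(message)
            if events is not None:
                events.append(message)
        else:
            fit = fit_logistic(x_train, y_train)
            if fit.penalised and events is not None:
                events.append(f"fold {compound}: separation, penalised fit")
            prob = predict_prob(fit, float(x[i]))
        probs[compound] = prob
    return probs


def roc_auc(scores: dict[str, float], y: dict[str, int]) -> float:
    """Mann–Whitney AUC of ``scores`` against binary labels, ties counted half.

    Equals (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg),
    computed via midranks.
    """
    compounds = list(scores)
    s = np.array([scores[c] for c in compounds], dtype=float)
    labels = np.array([y[c] for c in compounds], dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("AUC needs both classes")
    ranks = rankdata(s)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def loocv_auc(data: MetricVector, events: list[str] | None = None) -> float:
    """LOOCV ROC AUC of one metric: the cell value of the evaluation tables."""
    probs = loocv_probabilities(data, events=events)
    labels = dict(zip(data.compounds, data.y))
    return roc_auc(probs, labels)


def evaluate(metric_vectors: list[MetricVector]) -> EvaluationTable:
    """LOOCV ROC AUC for every metric vector, arranged dataset x metric.

    A cell whose labels are degenerate is recorded as unavailable
    (None) rather than aborting the rest of the table.  All vectors
    must share one classification scheme.
    """
    if not metric_vectors:
        raise DomainError("no metric vectors supplied")
    schemes = {mv.scheme_name for mv in metric_vectors}
    if len(schemes) > 1:
        raise DomainError(f"mixed schemes in one table: {sorted(schemes)}")

    table = EvaluationTable(scheme=schemes.pop())
    for mv in metric_vectors:
        if mv.dataset_name not in table.rows:
            table.rows.append(mv.dataset_name)
        if mv.metric_name not in table.columns:
            table.columns.append(mv.metric_name)
        key = (mv.dataset_name, mv.metric_name)
        table.n_compounds[key] = len(mv.compounds)
        table.n_positive[key] = int(sum(mv.y))
        try:
            events: list[str] = []
            table.cells[key] = loocv_auc(mv, events=events)
            if events:
                logger.info("%s/%s: %d fold events", mv.dataset_name, mv.metric_name,
                            len(events))
        except DegenerateLabelsError as err:
            logger.warning("%s/%s unavailable: %s", mv.dataset_name, mv.metric_name, err)
            table.cells[key] = None
    return table
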