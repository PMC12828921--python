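"""Post-hoc probability calibration and calibration diagnostics.

The calibration pipeline is temperature scaling (a single positive scalar T
dividing the logits) followed by beta-calibration, the three-parameter
monotone map ``m(p) = sigmoid(c + a ln p - b ln(1-p))`` with a, b >= 0.
Both maps are strictly monotone, so discrimination (AUC) is unchanged by
calibration.  Diagnostics: expected calibration error over equal-count
(decile) bins, the calibration slope (logistic coefficient of logit(p)),
and reliability tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit as _logit_fn

log = logging.getLogger(__name__)

EPS = 1e-7


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationParams:
    """Fitted temperature and beta-calibration parameters for one label."""

    temperature: float = 1.0
    a: float = 1.0
    b: float = 1.0
    c: float = 0.0

    def validate(self) -> None:
        if self.temperature <= 0:
            raise CalibrationError("temperature must be > 0")
        if self.a < 0 or self.b < 0:
            raise CalibrationError("beta parameters a, b must be >= 0")


def _nll(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, EPS, 1 - EPS)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def fit_temperature(logits: np.ndarray, labels: np.ndarray) -> float:
    """Temperature minimising the NLL of sigmoid(logit / T).

    1-D bounded search on [0.05, 20]; dividing by a positive T preserves the
    rank order of probabilities.
    """
    logits = np.asarray(logits, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if labels.min() == labels.max():
        raise CalibrationError("temperature scaling needs both classes present")
    res = minimize_scalar(
        lambda t: _nll(expit(logits / t), labels),
        bounds=(0.05, 20.0),
        method="bounded",
        options={"xatol": 1e-5},
    )
    return float(res.x)


def fit_beta_calibration(probs: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Fit (a, b, c) of m(p) = sigmoid(c + a ln p - b ln(1-p)) by maximum
    likelihood with a, b constrained non-negative.

    Degenerate inputs (all probabilities equal) return the identity map
    (1, 1, 0) with a warning.
    """
    p = np.clip(np.asarray(probs, dtype=float).ravel(), EPS, 1 - EPS)
    y = np.asarray(labels, dtype=float).ravel()
    if y.min() == y.max():
        raise CalibrationError("beta calibration needs both classes present")
    if np.ptp(p) < 1e-12:
        log.warning("degenerate probabilities: beta calibration returns identity")
        return 1.0, 1.0, 0.0
    f1 = np.log(p)
    f2 = -np.log(1.0 - p)
    n = len(y)

    def nll(theta):
        a, b, c = theta
        z = c + a * f1 + b * f2
        # log-likelihood of logistic model with features (ln p, -ln(1-p))
        return float(np.mean(np.logaddexp(0.0, z) - y * z))

    def grad(theta):
        a, b, c = theta
        z = c + a * f1 + b * f2
        r = expit(z) - y
        return np.array([(r * f1).mean(), (r * f2).mean(), r.mean()])

    res = minimize(
        nll,
        x0=np.array([1.0, 1.0, 0.0]),
        jac=grad,
        method="L-BFGS-B",
        bounds=[(0.0, None), (0.0, None), (None, None)],
    )
    a, b, c = res.x
    return float(a), float(b), float(c)


def fit_calibration(logits: np.ndarray, labels: np.ndarray) -> CalibrationParams:
    """Temperature first, then beta-calibration on its output."""
    T = fit_temperature(logits, labels)
    p = expit(np.asarray(logits, dtype=float) / T)
    a, b, c = fit_beta_calibration(p, labels)
    return CalibrationParams(temperature=T, a=a, b=b, c=c)


def apply_calibration(logits: np.ndarray, params: CalibrationParams) -> np.ndarray:
    """Map raw logits to calibrated probabilities (monotone)."""
    params.validate()
    p = np.clip(expit(np.asarray(logits, dtype=float) / params.temperature), EPS, 1 - EPS)
    z = params.c + params.a * np.log(p) - params.b * np.log(1.0 - p)
    return expit(z)


def _equal_count_edges(probs: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.quantile(probs, qs)
    edges[0] = -np.inf
    edges[-1] = np.inf
    return edges


def ece(probs: np.ndarray, labels: np.ndarray, n_bins: int = 10) -> float:
    """Expected calibration error over equal-count (decile) bins.

    ECE = sum_b (n_b / n) * |mean predicted_b - observed rate_b|, in [0, 1].
    """
    p = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if len(p) < n_bins:
        raise ValueError(f"need at least {n_bins} points for {n_bins} bins")
    edges = _equal_count_edges(p, n_bins)
    idx = np.searchsorted(edges, p, side="right") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    total = 0.0
    n = len(p)
    for b in range(n_bins):
        in_bin = idx == b
        nb = int(in_bin.sum())
        if nb == 0:
            continue
        total += (nb / n) * abs(p[in_bin].mean() - y[in_bin].mean())
    return float(total)


def reliability_table(
    probs: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Per-decile mean predicted probability, observed rate and count."""
    p = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    edges = _equal_count_edges(p, n_bins)
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        in_bin = idx == b
        nb = int(in_bin.sum())
        rows.append(
            {
                "bin": b,
                "count": nb,
                "mean_predicted": float(p[in_bin].mean()) if nb else np.nan,
                "observed_rate": float(y[in_bin].mean()) if nb else np.nan,
            }
        )
    return pd.DataFrame(rows)


def calibration_slope(probs: np.ndarray, labels: np.ndarray) -> float:
    """Coefficient of logit(p) in a logistic regression of y on logit(p).

    Perfect calibration gives slope 1; overconfident probabilities give
    slope < 1.  Complete separation is reported as +inf.
    """
    p = np.clip(np.asarray(probs, dtype=float).ravel(), EPS, 1 - EPS)
    y = np.asarray(labels, dtype=float).ravel()
    if y.min() == y.max():
        raise CalibrationError("calibration slope needs both classes present")
    if p[y == 1].min() > p[y == 0].max():
        # complete separation: the MLE slope diverges
        return float("inf")
    X = sm.add_constant(_logit_fn(p))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        slope = float(fit.params[1])
    except Exception:
        return float("inf")
    if not np.isfinite(slope) or abs(slope) > 1e3:
        # quasi-separation: the MLE diverges
        return float("inf")
    return slope
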