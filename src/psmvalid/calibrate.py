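"""Logistic calibration of classifier margins into probabilities.

The ADTree margin is a confidence score, not a probability.  Fitting a
sigmoid ``p(+ | m) = 1 / (1 + exp(-(A m + B)))`` to held-out (margin,
label) pairs by maximum likelihood gives a strictly monotone, one-to-one
mapping from scores to probability estimates, so ranking metrics (AUC) are
unchanged while the absolute scale becomes interpretable.  This is the
Platt-scaling family; by default plain {0,1} targets are used, with
Platt's smoothed targets available as an option.  Margins should come from
data not used to train the tree — training-set margins are optimistically
large and would skew the slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special


@dataclass(frozen=True)
class CalibrationModel:
    """Sigmoid parameters: probability(m) = sigmoid(slope * m + intercept)."""
    slope: float
    intercept: float


def _nll_and_grad(theta: np.ndarray, m: np.ndarray, t: np.ndarray):
    a, b = theta
    z = a * m + b
    # mean of t*softplus(-z) + (1-t)*softplus(z), numerically stable
    nll = np.mean(t * np.logaddexp(0.0, -z) + (1.0 - t) * np.logaddexp(0.0, z))
    p = special.expit(z)
    resid = p - t
    grad = np.array([np.mean(resid * m), np.mean(resid)])
    return nll, grad


def fit_calibration(margins, labels, platt_targets: bool = False,
                    max_iter: int = 10_000, gtol: float = 1e-10) -> CalibrationModel:
    """Maximum-likelihood fit of the calibration sigmoid.

    ``platt_targets`` replaces the {0,1} targets with Platt's smoothed
    values (N+ + 1)/(N+ + 2) and 1/(N- + 2), which regularize the fit on
    small or separable samples.  On perfectly separated margins the plain
    MLE slope grows until the iteration cap; no divergence occurs.
    """
    m = np.asarray(margins, dtype=float)
    y = np.asarray(labels, dtype=float)
    if m.shape != y.shape or m.ndim != 1:
        raise ValueError("margins and labels must be equal-length 1-D vectors")
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite margins")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("calibration requires both classes")

    if platt_targets:
        t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    else:
        t = y

    # start at the no-signal solution: A = 0, B = logit(positive fraction)
    b0 = math.log((n_pos + 1.0) / (n_neg + 1.0))
    res = optimize.minimize(
        _nll_and_grad, x0=np.array([0.0, b0]), args=(m, t),
        jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-15})
    a, b = res.x
    return CalibrationModel(slope=float(a), intercept=float(b))


def calibrate(model: CalibrationModel, margins):
    """Map margin score(s) to probabilities in (0, 1).

    Strictly increasing in the margin whenever the slope is positive.
    Accepts a scalar or an array; raises on non-finite margins.
    """
    m = np.asarray(margins, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite margin")
    p = special.expit(model.slope * m + model.intercept)
    if np.ndim(margins) == 0:
        return float(p)
    return p
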