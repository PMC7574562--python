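"""Small ridge-stabilised logistic fits shared by karyotyping and DMR scoring.

Perfect separation is the expected regime for Z-score karyotyping, so the
fits carry an L2 penalty on the coefficients of standardised predictors
(intercept unpenalised). With the default tiny penalty the fit is
numerically the maximum-likelihood solution whenever one exists.
"""

from __future__ import annotations

import numpy as np

_ETA_CLIP = 30.0


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))


def ridge_logistic_fit(
    x: np.ndarray,
    y: np.ndarray,
    penalty: float = 1e-4,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> dict:
    """Penalised logistic regression via iteratively reweighted least squares.

    Predictors are standardised internally (zero mean, unit SD over the
    training rows); the L2 penalty applies to the standardised coefficients,
    never the intercept. Returns a dict with the fit on the standardised
    scale plus the scaling needed to predict new rows.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and np.asarray(y).size == x.shape[1]:
        x = x.T
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = np.column_stack([np.ones(n), (x - mean) / sd])
    beta = np.zeros(p + 1)
    pen = np.diag([0.0] + [2.0 * penalty] * p)
    ll = -np.inf
    for _ in range(max_iter):
        eta = xs @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        grad = xs.T @ (y - mu) - pen @ beta
        hess = (xs * w[:, None]).T @ xs + pen
        try:
            beta = beta + np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            beta = beta + np.linalg.lstsq(hess, grad, rcond=None)[0]
        eta = np.clip(xs @ beta, -_ETA_CLIP, _ETA_CLIP)
        new_ll = float(
            np.sum(y * eta - np.log1p(np.exp(eta))) - 0.5 * beta @ pen @ beta
        )
        if abs(new_ll - ll) < tol * (abs(new_ll) + 1.0):
            ll = new_ll
            break
        ll = new_ll
    return {"beta": beta, "mean": mean, "sd": sd, "loglik": ll}


def ridge_logistic_predict(model: dict, x: np.ndarray) -> np.ndarray:
    """Predicted probabilities for new rows under a `ridge_logistic_fit`."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model["mean"].size:
        x = x.reshape(-1, model["mean"].size)
    xs = np.column_stack(
        [np.ones(x.shape[0]), (x - model["mean"]) / model["sd"]]
    )
    return _sigmoid(xs @ model["beta"])
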