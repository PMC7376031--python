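"""Single-hidden-layer feed-forward network trained by L-BFGS.

Tanh hidden units, linear outputs, squared-error loss summed over output
columns, L2 weight decay on the connection weights. Output weights start at
zero so the network treats every response column symmetrically: permuting
response columns permutes fitted outputs identically.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def _unpack(theta, p, h, m):
    i = 0
    W1 = theta[i:i + p * h].reshape(p, h); i += p * h
    b1 = theta[i:i + h]; i += h
    W2 = theta[i:i + h * m].reshape(h, m); i += h * m
    b2 = theta[i:i + m]
    return W1, b1, W2, b2


def _loss_grad(theta, X, Y, decay, p, h, m):
    W1, b1, W2, b2 = _unpack(theta, p, h, m)
    n = X.shape[0]
    A = np.tanh(X @ W1 + b1)          # (n, h)
    F = A @ W2 + b2                   # (n, m)
    R = F - Y
    loss = (R * R).sum() / n + decay * ((W1 * W1).sum() + (W2 * W2).sum())
    G = 2.0 * R / n                   # dloss/dF
    gW2 = A.T @ G + 2.0 * decay * W2
    gb2 = G.sum(axis=0)
    dA = (G @ W2.T) * (1.0 - A * A)
    gW1 = X.T @ dA + 2.0 * decay * W1
    gb1 = dA.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return loss, grad


class TinyMLP:
    """One-hidden-layer regression network with multi-output support.

    Parameters
    ----------
    hidden : int
        Number of tanh hidden units.
    decay : float
        L2 penalty on connection weights (not biases).
    max_iter : int
        L-BFGS iteration cap per restart.
    n_restarts : int
        Random restarts; the solution with the lowest training loss wins.
    seed : int
        Base seed; restart r initializes hidden weights from seed + r.
    """

    def __init__(self, hidden=8, decay=0.01, max_iter=500, n_restarts=5, seed=0):
        self.hidden = hidden
        self.decay = decay
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.seed = seed
        self.converged_ = None
        self.loss_ = None

    def fit(self, X, Y):
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        single = Y.ndim == 1
        if single:
            Y = Y[:, None]
        p, h, m = X.shape[1], self.hidden, Y.shape[1]
        best = None
        for r in range(self.n_restarts):
            rng = np.random.default_rng(self.seed + r)
            W1 = rng.normal(0.0, 1.0 / np.sqrt(max(p, 1)), size=(p, h))
            b1 = rng.normal(0.0, 0.1, size=h)
            # zero output weights: response columns are interchangeable
            theta0 = np.concatenate([W1.ravel(), b1, np.zeros(h * m + m)])
            res = minimize(_loss_grad, theta0, args=(X, Y, self.decay, p, h, m),
                           jac=True, method="L-BFGS-B",
                           options={"maxiter": self.max_iter})
            if best is None or res.fun < best.fun:
                best = res
        self._params = _unpack(best.x, p, h, m)
        self._shape = (p, h, m)
        self._single = single
        self.loss_ = float(best.fun)
        self.converged_ = bool(best.success)
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        W1, b1, W2, b2 = self._params
        F = np.tanh(X @ W1 + b1) @ W2 + b2
        return F[:, 0] if self._single else F
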