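"""Univariate-response partial least squares (NIPALS PLS1) and its
discriminant-analysis wrapper.

The class membership response y holds 0 (normal cartilage) or 1 (damaged
cartilage).  X and y are mean-centred on the training rows; no channel-wise
autoscaling is applied (SNV and Frobenius block scaling already handle
scale, and autoscaling would fight derivative preprocessing).  For each
latent variable a:

    w_a = X'y / ||X'y||        (weights)
    t_a = X w_a                (scores)
    p_a = X't_a / (t_a't_a)    (x-loadings)
    q_a = y't_a / (t_a't_a)    (y-loading)
    X  <- X - t_a p_a'         (deflation; y is not deflated for PLS1)

Regression coefficients for the first a components follow the standard
identity b_a = W_a (P_a' W_a)^{-1} q_a, so one fit yields the whole nested
sequence of models a = 1..A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PLSModel", "fit_pls", "predict", "classify", "confusion_stats"]


def _check_class_vector(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    vals = set(np.unique(y).tolist())
    if not vals <= {0, 1}:
        raise ValueError(f"class vector must contain only 0/1, got {sorted(vals)}")
    return y.astype(float)


@dataclass
class PLSModel:
    """Fitted NIPALS decomposition with the full nested LV sequence."""

    n_lv: int
    x_mean: np.ndarray          # (channels,)
    y_mean: float
    W: np.ndarray               # (channels, A) unit-norm weight vectors
    T: np.ndarray               # (samples, A) scores of the training rows
    P: np.ndarray               # (channels, A) x-loadings
    q: np.ndarray               # (A,) y-loadings
    row_keys: list | None = None

    def coefficients(self, a: int | None = None) -> np.ndarray:
        """Regression coefficients of the a-component model (default: all)."""
        a = self.n_lv if a is None else a
        if not 1 <= a <= self.n_lv:
            raise ValueError(f"a must be in 1..{self.n_lv}, got {a}")
        Wa, Pa, qa = self.W[:, :a], self.P[:, :a], self.q[:a]
        return Wa @ np.linalg.solve(Pa.T @ Wa, qa)

    @property
    def b(self) -> np.ndarray:
        return self.coefficients()

    def predict(self, Xnew: np.ndarray, a: int | None = None) -> np.ndarray:
        return predict(self, Xnew, a=a)

    def scores(self, Xnew: np.ndarray) -> np.ndarray:
        """Project new rows onto the latent space: t = Xc W (P'W)^{-1}."""
        Xc = np.atleast_2d(np.asarray(Xnew, float)) - self.x_mean
        return Xc @ self.W @ np.linalg.inv(self.P.T @ self.W)


def fit_pls(X: np.ndarray, y: np.ndarray, A: int, row_keys: list | None = None) -> PLSModel:
    """Fit a PLS1 model with A latent variables.

    Raises if A exceeds min(n_samples - 1, n_channels), if y is single-class,
    or if X has no variance left to extract a component from.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = _check_class_vector(y)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("X row count and y length differ")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present for fitting")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if A < 1 or A > min(n - 1, p):
        raise ValueError(f"A must be in 1..{min(n - 1, p)}, got {A}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yc = y - y_mean
    if not np.any(Xd):
        raise ValueError("X has zero variance after centering")

    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    for a in range(A):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14 * max(1.0, np.abs(Xd).max()):
            raise ValueError(
                f"no covariance left to extract component {a + 1}; reduce A"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            raise ValueError(f"degenerate score vector at component {a + 1}")
        pvec = Xd.T @ t / tt
        W[:, a], T[:, a], P[:, a] = w, t, pvec
        q[a] = float(yc @ t) / tt
        Xd = Xd - np.outer(t, pvec)

    return PLSModel(n_lv=A, x_mean=x_mean, y_mean=y_mean, W=W, T=T, P=P, q=q,
                    row_keys=list(row_keys) if row_keys is not None else None)


def predict(model: PLSModel, Xnew: np.ndarray, a: int | None = None) -> np.ndarray:
    """Continuous class scores: y_mean + (Xnew - x_mean) b."""
    Xnew = np.atleast_2d(np.asarray(Xnew, float))
    if Xnew.shape[1] != model.x_mean.size:
        raise ValueError(
            f"channel mismatch: model has {model.x_mean.size}, input {Xnew.shape[1]}"
        )
    return model.y_mean + (Xnew - model.x_mean) @ model.coefficients(a)


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard 0/1 call: 1 iff score > threshold (ties go to 0)."""
    scores = np.asarray(scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    return (scores > threshold).astype(int)


def confusion_stats(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Sensitivity / specificity / accuracy and the 2x2 counts.

    Sensitivity is the fraction of damaged (1) samples called damaged,
    specificity the fraction of healthy (0) called healthy.  Fractions are
    kept unrounded; percentage rounding happens only at report time.
    """
    pred = np.asarray(pred, int)
    truth = np.asarray(truth, int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth length mismatch")
    _check_class_vector(truth)
    n1 = int((truth == 1).sum())
    n0 = int((truth == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("truth must contain both classes")
    tp = int(((pred == 1) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    sens = tp / n1
    spec = tn / n0
    acc = (tp + tn) / (n1 + n0)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "counts": {"tp": tp, "fn": n1 - tp, "tn": tn, "fp": n0 - tn,
                   "n_damaged": n1, "n_healthy": n0},
    }
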