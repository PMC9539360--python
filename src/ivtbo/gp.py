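"""Gaussian-process surrogate for IVT yield: ARD Matérn 5/2, constant mean.

The surrogate models measured mRNA yield (g/L) as a GP over the encoded unit
cube.  The kernel is the Matérn 5/2 with automatic relevance determination,

    k(x, x') = sigma_f^2 (1 + sqrt(5) r + 5/3 r^2) exp(-sqrt(5) r),
    r^2 = sum_d (x_d - x'_d)^2 / l_d^2,

with a per-coordinate length scale l_d (one per numeric parameter and per
categorical level), a covariance amplitude sigma_f^2, an observation noise
variance sigma_n^2, and a learned constant mean c in yield units.  Sample
paths are twice differentiable — rough enough for a reaction response surface
without the unrealistic smoothness of the squared exponential.

Hyperparameters are point estimates: the log marginal likelihood is maximized
by L-BFGS in log-space from multiple seeded restarts.  Targets stay in raw
g/L (no standardization) so the acquisition function and all reports remain
in measurement units.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize

__all__ = [
    "GPHyperparams",
    "GPModel",
    "matern52",
    "matern52_gram",
    "fit",
    "predict",
    "log_marginal_likelihood",
]

SQRT5 = np.sqrt(5.0)
JITTER_REL = 1e-8  # added to the Gram diagonal, relative to sigma_f^2
NOISE_FLOOR = 1e-6  # absolute lower bound on sigma_n^2


@dataclass(frozen=True)
class GPHyperparams:
    """ARD Matérn 5/2 hyperparameters; scales strictly positive."""

    length_scales: np.ndarray  # l_d > 0, one per encoded dimension
    signal_var: float  # sigma_f^2 > 0, (g/L)^2
    noise_var: float  # sigma_n^2 >= NOISE_FLOOR, (g/L)^2
    mean: float  # constant prior mean c, g/L

    def __post_init__(self) -> None:
        ls = np.atleast_1d(np.asarray(self.length_scales, dtype=float))
        object.__setattr__(self, "length_scales", ls)
        if np.any(ls <= 0):
            raise ValueError("length scales must be strictly positive")
        if self.signal_var <= 0:
            raise ValueError("signal variance must be strictly positive")
        if self.noise_var < 0:
            raise ValueError("noise variance must be non-negative")

    @property
    def prior_sd(self) -> float:
        return float(np.sqrt(self.signal_var + self.noise_var))


def _scaled_sqdists(X: np.ndarray, X2: np.ndarray, ls: np.ndarray) -> np.ndarray:
    A = X / ls
    B = X2 / ls
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.maximum(d2, 0.0)


def _matern52_of_r(r: np.ndarray, signal_var: float) -> np.ndarray:
    return signal_var * (1.0 + SQRT5 * r + (5.0 / 3.0) * r**2) * np.exp(-SQRT5 * r)


def matern52(x: np.ndarray, x2: np.ndarray, h: GPHyperparams) -> float:
    """Kernel value between two encoded points."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    if x.shape != x2.shape:
        raise ValueError("points must have equal dimension")
    r = float(np.sqrt(np.sum(((x - x2) / h.length_scales) ** 2)))
    return float(_matern52_of_r(np.array(r), h.signal_var))


def matern52_gram(X: np.ndarray, X2: np.ndarray, h: GPHyperparams) -> np.ndarray:
    """Cross-covariance matrix between two sets of encoded points."""
    r = np.sqrt(_scaled_sqdists(np.atleast_2d(X), np.atleast_2d(X2), h.length_scales))
    return _matern52_of_r(r, h.signal_var)


@dataclass(frozen=True)
class GPModel:
    """Fitted GP: training data, hyperparameters, cached Cholesky solve."""

    X: np.ndarray
    y: np.ndarray
    hyper: GPHyperparams
    _chol: np.ndarray  # lower Cholesky factor of K + sigma_n^2 I (+ jitter)
    _alpha: np.ndarray  # (K + sigma_n^2 I)^-1 (y - c)

    @property
    def n(self) -> int:
        return len(self.y)

    def to_json(self) -> str:
        """Checkpoint: hyperparameters plus training data and its digest."""
        digest = hashlib.sha256(
            self.X.tobytes() + self.y.tobytes()
        ).hexdigest()
        return json.dumps(
            {
                "length_scales": self.hyper.length_scales.tolist(),
                "signal_var": self.hyper.signal_var,
                "noise_var": self.hyper.noise_var,
                "mean": self.hyper.mean,
                "X": self.X.tolist(),
                "y": self.y.tolist(),
                "digest": digest,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GPModel":
        d = json.loads(text)
        h = GPHyperparams(
            np.array(d["length_scales"]), d["signal_var"], d["noise_var"], d["mean"]
        )
        return _build_model(np.array(d["X"]), np.array(d["y"]), h)


def _build_model(X: np.ndarray, y: np.ndarray, h: GPHyperparams) -> GPModel:
    K = matern52_gram(X, X, h)
    Kn = K + (h.noise_var + JITTER_REL * h.signal_var) * np.eye(len(y))
    try:
        L = np.linalg.cholesky(Kn)
    except np.linalg.LinAlgError as e:  # pragma: no cover - pathological data
        raise np.linalg.LinAlgError(
            "Gram matrix singular after jitter; increase the noise floor"
        ) from e
    alpha = cho_solve((L, True), y - h.mean)
    return GPModel(X=X, y=y, hyper=h, _chol=L, _alpha=alpha)


def log_marginal_likelihood(
    X: np.ndarray, y: np.ndarray, h: GPHyperparams
) -> float:
    """Exact Gaussian log marginal likelihood of y under the GP prior."""
    m = _build_model(np.asarray(X, dtype=float), np.asarray(y, dtype=float), h)
    r = m.y - h.mean
    return float(
        -0.5 * r @ m._alpha
        - np.sum(np.log(np.diag(m._chol)))
        - 0.5 * len(y) * np.log(2.0 * np.pi)
    )


def _lml_and_grad(theta: np.ndarray, D2: np.ndarray, y: np.ndarray):
    """Negative LML and gradient wrt [log l_d, log sigma_f^2, log sigma_n^2, c].

    ``D2`` is the precomputed (n, n, d) tensor of squared coordinate
    differences of the training inputs.
    """
    d = D2.shape[2]
    ls = np.exp(theta[:d])
    sf2 = np.exp(theta[d])
    sn2 = np.exp(theta[d + 1]) + NOISE_FLOOR
    c = theta[d + 2]
    n = len(y)

    r2 = D2.reshape(n * n, d) @ (1.0 / ls**2)
    r2 = r2.reshape(n, n)
    r = np.sqrt(np.maximum(r2, 0.0))
    E = np.exp(-SQRT5 * r)
    K = sf2 * (1.0 + SQRT5 * r + (5.0 / 3.0) * r2) * E
    Kn = K + (sn2 + JITTER_REL * sf2) * np.eye(n)
    try:
        L = np.linalg.cholesky(Kn)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    resid = y - c
    alpha = cho_solve((L, True), resid)
    lml = (
        -0.5 * resid @ alpha
        - np.sum(np.log(np.diag(L)))
        - 0.5 * n * np.log(2.0 * np.pi)
    )

    Kinv = cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv  # dLML/dtheta_k = 0.5 tr(W dK/dtheta_k)
    grad = np.zeros_like(theta)
    # d/dr of the Matern part is -(5/3) r (1 + sqrt5 r) e^{-sqrt5 r}; combined
    # with dr/dlog l_d = -D2_d / (l_d^2 r) the r factors cancel.
    C = sf2 * (5.0 / 3.0) * (1.0 + SQRT5 * r) * E
    WC = (W * C).reshape(n * n)
    grad[:d] = 0.5 * (WC @ D2.reshape(n * n, d)) / ls**2
    grad[d] = 0.5 * np.sum(W * (K + JITTER_REL * sf2 * np.eye(n)))
    grad[d + 1] = 0.5 * np.trace(W) * (sn2 - NOISE_FLOOR)
    grad[d + 2] = np.sum(alpha)
    return -lml, -grad


def fit(
    X: np.ndarray,
    y: np.ndarray,
    restarts: int = 8,
    seed: int = 0,
    max_iter: int = 100,
    noise_floor_var: float | None = None,
) -> GPModel:
    """Fit hyperparameters by multi-start L-BFGS on the log marginal likelihood.

    Restart points are drawn from a prior box l_d in [0.05, 5],
    sigma_f^2 in [0.1, 10] x var(y), sigma_n^2 in [1e-4, 1] x var(y); one
    additional deterministic start uses unit length scales.  Deterministic
    under ``seed``.

    ``noise_floor_var`` imposes a lower bound (in (g/L)^2) on the fitted
    observation-noise variance.  With one measurement per condition the
    marginal likelihood is happy to drive sigma_n^2 to zero and interpolate
    replicate noise as structure; when the assay's replicate variability is
    known (for IVT yields, replicate SDs of a few tenths of a g/L), flooring
    sigma_n^2 at it keeps the surrogate honestly uncertain.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 2:
        raise ValueError("need at least 2 observations to fit the surrogate")
    if X.shape[0] != len(y):
        raise ValueError("X and y lengths differ")
    n, d = X.shape
    rng = np.random.default_rng(seed)
    v = max(float(np.var(y)), 1e-6)
    ybar = float(np.mean(y))
    nf = 0.0 if noise_floor_var is None else float(noise_floor_var)

    starts = [
        np.concatenate(
            [np.zeros(d), [np.log(v), np.log(max(0.01 * v, nf))], [ybar]]
        )
    ]
    for _ in range(max(0, restarts - 1)):
        ls = np.exp(rng.uniform(np.log(0.05), np.log(5.0), size=d))
        sf2 = np.exp(rng.uniform(np.log(0.1 * v), np.log(10.0 * v)))
        sn2 = np.exp(
            rng.uniform(np.log(max(1e-4 * v, nf)), np.log(max(v, 2 * nf)))
        )
        starts.append(
            np.concatenate([np.log(ls), [np.log(sf2), np.log(sn2)], [ybar]])
        )

    lo_y, hi_y = np.min(y) - 10 * (np.ptp(y) + 1.0), np.max(y) + 10 * (np.ptp(y) + 1.0)
    sn2_lo = max(1e-9 * v, nf)
    bounds = (
        [(np.log(1e-3), np.log(1e3))] * d
        + [(np.log(1e-8 * v), np.log(1e4 * v))]
        + [(np.log(sn2_lo), np.log(max(1e2 * v, 2 * sn2_lo)))]
        + [(lo_y, hi_y)]
    )

    D2 = (X[:, None, :] - X[None, :, :]) ** 2  # shared across restarts
    best_val, best_theta = np.inf, starts[0]
    for th0 in starts:
        res = minimize(
            _lml_and_grad,
            th0,
            args=(D2, y),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter},
        )
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, best_theta = res.fun, res.x

    ls = np.exp(best_theta[:d])
    h = GPHyperparams(
        length_scales=ls,
        signal_var=float(np.exp(best_theta[d])),
        noise_var=float(np.exp(best_theta[d + 1]) + NOISE_FLOOR),
        mean=float(best_theta[d + 2]),
    )
    return _build_model(X, y, h)


def predict(m: GPModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and sd (g/L) at one or more encoded points.

    The sd is that of the latent function (no observation noise); callers
    wanting the predictive sd of a replicate measurement should add noise_var.
    With no training data the prior (c, sqrt(sigma_f^2 + sigma_n^2)) is
    returned.
    """
    Xq = np.atleast_2d(np.asarray(X, dtype=float))
    single = np.asarray(X).ndim == 1
    if Xq.shape[1] != m.X.shape[1] and m.n > 0:
        raise ValueError(
            f"query dimension {Xq.shape[1]} != training dimension {m.X.shape[1]}"
        )
    h = m.hyper
    if m.n == 0:
        mu = np.full(len(Xq), h.mean)
        sd = np.full(len(Xq), h.prior_sd)
    else:
        Ks = matern52_gram(Xq, m.X, h)
        mu = h.mean + Ks @ m._alpha
        V = solve_triangular(m._chol, Ks.T, lower=True)
        var = h.signal_var - np.sum(V**2, axis=0)
        sd = np.sqrt(np.maximum(var, 0.0))
    if single:
        return float(mu[0]), float(sd[0])
    return mu, sd


def empty_model(h: GPHyperparams, dim: int) -> GPModel:
    """A prior-only model (no observations), for prediction before any data."""
    return GPModel(
        X=np.zeros((0, dim)),
        y=np.zeros(0),
        hyper=h,
        _chol=np.zeros((0, 0)),
        _alpha=np.zeros(0),
    )
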