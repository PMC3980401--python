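"""Gaussian-process multi-instance learning with a soft-max bag likelihood.

Each instance x carries a latent score f(x) with a zero-mean GP prior
(RBF kernel); g(x) = logistic(f(x)) is the probability that the instance is
positive.  Under the standard MIL assumption a bag is positive when its best
instance is, so the bag-level probability is the soft maximum

    s(B) = (1/alpha) * log( (1/|B|) * sum_j exp(alpha * g(x_j)) )

clipped to [0, 1]; as alpha -> infinity this approaches max_j g(x_j).  Bags
enter a Bernoulli likelihood (positive bags contribute log s, negative bags
log(1 - s)); the posterior over latents is approximated by a Laplace
expansion around the Newton-ascent mode, and the predictive bag probability
pushes the GP conditional of the test bag's top instance through the soft-max
by Gauss-Hermite quadrature.  The binary decision is b = 1 iff r > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.spatial.distance import cdist, pdist
from scipy.special import expit, logsumexp

from .mil_core import Bag, Standardizer

__all__ = [
    "GPMILModel",
    "TermPrediction",
    "bag_likelihood",
    "joint_log_likelihood",
    "fit_gpmil",
    "predict_gpmil",
]

_EPS = 1e-9
_N_GH = 32


@dataclass(frozen=True)
class TermPrediction:
    """One image's annotation decision for one term."""

    image_id: str
    probability: float
    binary: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if self.binary != int(self.probability > 0.5):
            raise ValueError("binary decision must equal sign(r - 0.5)")


def bag_likelihood(g_values: np.ndarray, alpha: float) -> float:
    """Soft-max bag probability from per-instance scores g in (0, 1)."""
    g = np.asarray(g_values, dtype=float)
    if g.size == 0:
        raise ValueError("empty bag")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    s = (logsumexp(alpha * g) - np.log(g.size)) / alpha
    return float(np.clip(s, 0.0, 1.0))


def joint_log_likelihood(bag_indices: list[np.ndarray], labels: np.ndarray,
                         latent_f: np.ndarray, alpha: float) -> float:
    """Log of the product of Bernoulli bag likelihoods over a dataset."""
    total = 0.0
    for idx, t in zip(bag_indices, labels):
        g = expit(latent_f[idx])
        s = np.clip(bag_likelihood(g, alpha), _EPS, 1.0 - _EPS)
        total += np.log(s) if t == 1 else np.log(1.0 - s)
    return float(total)


def _bag_grad_hess(f_b: np.ndarray, t: int, alpha: float):
    """Gradient and Hessian of one bag's log-likelihood w.r.t. its latents."""
    g = expit(f_b)
    u = g * (1.0 - g)                      # dg/df
    du = u * (1.0 - 2.0 * g)               # d2g/df2
    z = alpha * g
    w = np.exp(z - z.max())
    w /= w.sum()                           # softmax weights = ds/dg
    s_raw = (logsumexp(z) - np.log(g.size)) / alpha
    s = float(np.clip(s_raw, _EPS, 1.0 - _EPS))
    if t == 1:
        dl_ds, d2l_ds2 = 1.0 / s, -1.0 / s ** 2
    else:
        dl_ds, d2l_ds2 = -1.0 / (1.0 - s), -1.0 / (1.0 - s) ** 2
    ds_df = w * u
    # d2s/df2 = u_j u_l * alpha (diag(w) - w w^T) + diag(w * du)
    h_s = alpha * (np.diag(w) - np.outer(w, w)) * np.outer(u, u) + np.diag(w * du)
    grad = dl_ds * ds_df
    hess = d2l_ds2 * np.outer(ds_df, ds_df) + dl_ds * h_s
    return grad, hess


def _likelihood_grad_hess(bag_indices, labels, f, alpha):
    n = f.size
    grad = np.zeros(n)
    hess = np.zeros((n, n))
    for idx, t in zip(bag_indices, labels):
        g_b, h_b = _bag_grad_hess(f[idx], int(t), alpha)
        grad[idx] += g_b
        hess[np.ix_(idx, idx)] += h_b
    return grad, hess


def _rbf_kernel(xa: np.ndarray, xb: np.ndarray, lengthscale: float,
                variance: float) -> np.ndarray:
    d2 = cdist(xa, xb, metric="sqeuclidean")
    return variance * np.exp(-d2 / (2.0 * lengthscale ** 2))


@dataclass
class GPMILModel:
    """Laplace-approximate GPMIL posterior for one annotation term."""

    term: str
    X: np.ndarray                      # stacked training instances
    bag_indices: list[np.ndarray]
    bag_ids: list[str]
    labels: np.ndarray
    lengthscale: float
    variance: float
    alpha: float
    jitter: float
    f_hat: np.ndarray = field(repr=False)
    K: np.ndarray = field(repr=False)
    alpha_vec: np.ndarray = field(repr=False)   # K^{-1} f_hat
    B: np.ndarray = field(repr=False)           # K^{-1} - K^{-1} Sigma K^{-1}
    standardizer: Standardizer | None = None
    converged: bool = True


def fit_gpmil(bags: list[Bag], labels, lengthscale: float | None = None,
              variance: float = 1.0, alpha: float = 10.0, jitter: float = 1e-6,
              max_newton: int = 100, tol: float = 1e-5, term: str = "term",
              standardize: bool = False) -> GPMILModel:
    """Find the Laplace posterior mode of the latent instance scores.

    Damped Newton ascent on log p(T|G) - (1/2) f^T K^{-1} f; the RBF
    lengthscale defaults to the median pairwise instance distance (median
    heuristic).  Deterministic: no randomness enters the fit.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("training set must contain both classes")
    std = None
    if standardize:
        std = Standardizer().fit(bags)
        bags = std.transform_all(bags)
    X = np.vstack([b.instances for b in bags])
    bag_indices, start = [], 0
    for b in bags:
        bag_indices.append(np.arange(start, start + b.n_instances))
        start += b.n_instances
    n = X.shape[0]
    if lengthscale is None:
        d = pdist(X)
        d = d[d > 0]
        lengthscale = float(np.median(d)) if d.size else 1.0
    K = _rbf_kernel(X, X, lengthscale, variance) + jitter * np.eye(n)

    # Optimize in dual coordinates f = K a so the ill-conditioned K is never
    # inverted: Psi(a) = log p(T | K a) - (1/2) a^T K a, Newton direction
    # delta = (I + W K)^{-1} (grad_L - a) with W = -Hess_L.  The sharp
    # soft-max surface is multimodal, so the target alpha is reached by
    # continuation: each fit warm-starts from the mode at a smoother alpha.
    a = np.zeros(n)
    eye = np.eye(n)
    anneal = [al for al in (2.0, 5.0, 10.0, 20.0) if al < alpha] + [alpha]
    for al in anneal:
        a = _newton_ascent(a, K, bag_indices, labels, al, eye, max_newton, tol)
    f = K @ a
    converged = np.linalg.norm(
        _likelihood_grad_hess(bag_indices, labels, f, alpha)[0] - a,
        np.inf) < 10 * tol
    if not converged:
        warnings.warn(
            f"GPMIL Newton ascent stopped before reaching gradient tolerance {tol}",
            stacklevel=2)

    _, hess_l = _likelihood_grad_hess(bag_indices, labels, f, alpha)
    W = -hess_l
    # Predictive-variance correction B = (K + W^{-1})^{-1} = W (I + K W)^{-1};
    # W can be indefinite under the soft-max likelihood, so regularize the
    # solve if needed and symmetrize.
    M = eye + K @ W
    try:
        B = np.linalg.solve(M.T, W.T).T
    except np.linalg.LinAlgError:
        B = np.linalg.solve(M.T + 1e-8 * eye, W.T).T
    B = 0.5 * (B + B.T)
    return GPMILModel(term=term, X=X, bag_indices=bag_indices,
                      bag_ids=[b.image_id for b in bags], labels=labels,
                      lengthscale=lengthscale, variance=variance, alpha=alpha,
                      jitter=jitter, f_hat=f, K=K, alpha_vec=a, B=B,
                      standardizer=std, converged=converged)


def _newton_ascent(a, K, bag_indices, labels, alpha, eye, max_newton, tol):
    def objective(a_vec, f_vec):
        return (joint_log_likelihood(bag_indices, labels, f_vec, alpha)
                - 0.5 * a_vec @ f_vec)

    f = K @ a
    obj = objective(a, f)
    for it in range(max_newton):
        grad_l, hess_l = _likelihood_grad_hess(bag_indices, labels, f, alpha)
        grad = grad_l - a                  # gradient of Psi w.r.t. f at the mode
        if np.linalg.norm(grad, np.inf) < tol:
            break
        W = -hess_l
        step = None
        lam = 0.0
        for _ in range(8):
            try:
                step = np.linalg.solve(eye + (W + lam * eye) @ K, grad)
                if np.isfinite(step).all():
                    break
            except np.linalg.LinAlgError:
                pass
            lam = 10 * max(lam, 1e-6)
            step = None
        improved = False
        # Newton direction first; near the symmetric start f = 0 the soft-max
        # surface is a saddle and the Newton step can point downhill, so fall
        # back to the (always ascending) gradient direction in a-space.
        directions = [step, grad] if step is not None else [grad]
        for direction in directions:
            t_ls = 1.0
            for _ in range(30):
                a_new = a + t_ls * direction
                f_new = K @ a_new
                obj_new = objective(a_new, f_new)
                if np.isfinite(obj_new) and obj_new > obj + 1e-12:
                    a, f, obj, improved = a_new, f_new, obj_new, True
                    break
                t_ls *= 0.5
            if improved:
                break
        if not improved:
            break
        if not np.isfinite(f).all():
            raise ArithmeticError(
                f"Newton ascent diverged at iteration {it}: non-finite latents")
    return a


def predict_gpmil(model: GPMILModel, test: Bag,
                  n_quad: int = _N_GH) -> TermPrediction:
    """Predictive annotation probability for a test bag.

    The GP conditional gives each test instance's latent mean and variance;
    the instance with the highest mean score is integrated through the bag
    soft-max with Gauss-Hermite quadrature (the remaining instances are held
    at their posterior-mean scores).
    """
    bag = model.standardizer.transform(test) if model.standardizer else test
    if bag.dim != model.X.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: model {model.X.shape[1]}, bag {bag.dim}")
    K_star = _rbf_kernel(model.X, bag.instances, model.lengthscale, model.variance)
    mean = K_star.T @ model.alpha_vec
    var = (model.variance + model.jitter
           - np.einsum("ij,ik,kj->j", K_star, model.B, K_star))
    var = np.clip(var, 1e-10, None)
    g_mean = expit(mean)
    top = int(np.argmax(g_mean))
    nodes, weights = hermegauss(n_quad)    # integrates against N(0,1)
    weights = weights / np.sqrt(2.0 * np.pi)
    r = 0.0
    g_vec = g_mean.copy()
    for z, w in zip(nodes, weights):
        g_vec[top] = expit(mean[top] + np.sqrt(var[top]) * z)
        r += w * bag_likelihood(g_vec, model.alpha)
    r = float(np.clip(r, 0.0, 1.0))
    return TermPrediction(image_id=test.image_id, probability=r,
                          binary=int(r > 0.5))
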