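"""Gaussian-mixture clustering of projection patterns.

Axons of one source region are clustered on their projection feature vector
(per-region path lengths or terminal counts) under a mixture of C Gaussians
with weights p_k, means μ_k and covariances Σ_k, fitted by
Expectation-Maximization and selected by the Bayesian Information Criterion.

The posterior cluster membership of an axon with feature f is

    P(c | f) = p_c N(f; μ_c, Σ_c) / Σ_k p_k N(f; μ_k, Σ_k),

all densities evaluated in log space with log-sum-exp stabilization.  The
default covariance is *spherical* (one scalar variance per cluster), which
is what BIC selects on projection-length data; diagonal and full covariances
are available.

BIC is computed as ``κ·ln(n) − 2·l(θ)`` with κ the free-parameter count, so
*lower is better* and model selection uses argmin.  (The equivalent
"maximize −BIC" convention differs only in sign.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GMMModel",
    "gaussian_density",
    "gaussian_log_density",
    "posterior",
    "fit_em",
    "bic",
    "select_model",
    "sample_virtual_axons",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _component_log_density(
    X: np.ndarray, mean: np.ndarray, cov, covariance_type: str
) -> np.ndarray:
    """Log multivariate-normal density of rows of X (shape (n, d))."""
    X = np.atleast_2d(np.asarray(X, float))
    mean = np.asarray(mean, float)
    d = X.shape[1]
    diff = X - mean
    if covariance_type == "spherical":
        var = float(cov)
        if var <= 0:
            raise ValueError("singular (non-positive) spherical variance")
        return -0.5 * (d * (_LOG2PI + np.log(var)) + (diff ** 2).sum(axis=1) / var)
    if covariance_type == "diag":
        var = np.asarray(cov, float)
        if np.any(var <= 0):
            raise ValueError("singular diagonal covariance")
        return -0.5 * (
            (_LOG2PI + np.log(var)).sum() + ((diff ** 2) / var).sum(axis=1)
        )
    if covariance_type == "full":
        cov = np.asarray(cov, float)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise ValueError("singular full covariance")
        sol = np.linalg.solve(cov, diff.T).T
        maha = (diff * sol).sum(axis=1)
        return -0.5 * (d * _LOG2PI + logdet + maha)
    raise ValueError(f"unknown covariance_type {covariance_type!r}")


def gaussian_log_density(f, mean, cov, covariance_type: str = "spherical") -> float:
    """Log density of the multivariate normal N(mean, cov) at ``f``."""
    return float(_component_log_density(np.atleast_2d(f), mean, cov, covariance_type)[0])


def gaussian_density(f, mean, cov, covariance_type: str = "spherical") -> float:
    """Multivariate normal density at ``f`` (evaluated in log space)."""
    return float(np.exp(gaussian_log_density(f, mean, cov, covariance_type)))


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class GMMModel:
    """Fitted per-source-region Gaussian mixture.

    ``covariances`` is shaped per ``covariance_type``: (C,) scalar variances
    for spherical, (C, B) for diag, (C, B, B) for full.
    ``observed_masks[c, j]`` records whether region j was targeted by any
    training member of cluster c; virtual-axon sampling zeroes unobserved
    regions.
    """

    source_region: str
    region_vocab: list[str]
    C: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    covariance_type: str = "spherical"
    observed_masks: np.ndarray | None = None
    log_likelihood: float = float("nan")
    bic: float = float("nan")
    seed: int | None = None
    n_iter: int = 0
    bic_trace: dict[int, float] = field(default_factory=dict)
    ll_trace: list[float] = field(default_factory=list)  # winning EM run

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.atleast_2d(np.asarray(self.means, float))
        self.covariances = np.asarray(self.covariances, float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("negative mixture weight")

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def component_log_densities(self, X: np.ndarray) -> np.ndarray:
        """(n, C) matrix of per-component log densities."""
        X = np.atleast_2d(np.asarray(X, float))
        out = np.empty((X.shape[0], self.C))
        for k in range(self.C):
            out[:, k] = _component_log_density(
                X, self.means[k], self.covariances[k], self.covariance_type
            )
        return out

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """(n, C) posterior membership probabilities, rows summing to 1."""
        logw = np.log(np.clip(self.weights, 1e-300, None))
        lg = self.component_log_densities(X) + logw
        lg -= logsumexp(lg, axis=1, keepdims=True)
        return np.exp(lg)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.posterior(X), axis=1)

    def score(self, X: np.ndarray) -> float:
        """Total log-likelihood of the data under the mixture."""
        logw = np.log(np.clip(self.weights, 1e-300, None))
        return float(logsumexp(self.component_log_densities(X) + logw, axis=1).sum())

    def n_free_parameters(self) -> int:
        C, B = self.C, self.n_features
        kappa = (C - 1) + C * B
        if self.covariance_type == "spherical":
            kappa += C
        elif self.covariance_type == "diag":
            kappa += C * B
        else:
            kappa += C * B * (B + 1) // 2
        return kappa

    def sample(self, n: int, rng: np.random.Generator | int):
        return sample_virtual_axons(self, n, rng)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "source_region": self.source_region,
            "region_vocab": self.region_vocab,
            "C": self.C,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "covariance_type": self.covariance_type,
            "observed_masks": None
            if self.observed_masks is None
            else self.observed_masks.astype(int).tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "bic_trace": {str(k): v for k, v in self.bic_trace.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GMMModel":
        with open(path) as fh:
            doc = json.load(fh)
        masks = doc.pop("observed_masks")
        trace = {int(k): v for k, v in doc.pop("bic_trace", {}).items()}
        model = cls(
            observed_masks=None if masks is None else np.asarray(masks, bool),
            bic_trace=trace,
            **{
                k: (np.asarray(v) if k in ("weights", "means", "covariances") else v)
                for k, v in doc.items()
            },
        )
        return model


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _init_means_kmeanspp(X: np.ndarray, C: int, rng: np.random.Generator,
                         lloyd_iter: int = 20) -> np.ndarray:
    """Distance-weighted (k-means++) seeding refined by Lloyd iterations.

    The refinement starts EM from a balanced hard partition, which keeps it
    out of the classical singular maximizers (a component collapsing onto a
    single point with vanishing variance).
    """
    n = X.shape[0]
    means = [X[rng.integers(n)]]
    for _ in range(1, C):
        d2 = np.min(
            ((X[:, None, :] - np.asarray(means)[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        total = d2.sum()
        if total <= 0:
            means.append(X[rng.integers(n)])
        else:
            means.append(X[rng.choice(n, p=d2 / total)])
    means = np.asarray(means, dtype=float)
    labels = None
    for _ in range(lloyd_iter):
        d2 = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(C):
            members = X[labels == k]
            if members.shape[0]:
                means[k] = members.mean(axis=0)
    return means


def _m_step(X, resp, covariance_type, var_floor):
    n, d = X.shape
    nk = resp.sum(axis=0)
    nk = np.clip(nk, 1e-12, None)
    weights = nk / nk.sum()
    means = (resp.T @ X) / nk[:, None]
    C = resp.shape[1]
    if covariance_type == "spherical":
        covs = np.empty(C)
        for k in range(C):
            diff2 = ((X - means[k]) ** 2).sum(axis=1)
            covs[k] = max((resp[:, k] @ diff2) / (nk[k] * d), var_floor)
    elif covariance_type == "diag":
        covs = np.empty((C, d))
        for k in range(C):
            diff2 = (X - means[k]) ** 2
            covs[k] = np.maximum((resp[:, k][:, None] * diff2).sum(axis=0) / nk[k],
                                 var_floor)
    else:
        covs = np.empty((C, d, d))
        for k in range(C):
            diff = X - means[k]
            covs[k] = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            covs[k] += var_floor * np.eye(d)
    return weights, means, covs


def fit_em(
    data: np.ndarray,
    C: int,
    covariance_type: str = "spherical",
    rng: np.random.Generator | int | None = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    source_region: str = "",
    region_vocab: list[str] | None = None,
) -> GMMModel:
    """Fit a C-component mixture by EM; best of ``n_init`` seedings kept.

    The E-step computes posteriors, the M-step the weighted maximum
    likelihood estimates of weights, means and covariances (variances are
    floored at ``1e-6`` times the data scale).  The log-likelihood is
    non-decreasing across iterations up to ``tol``; a component that empties
    is re-seeded from the data point with the lowest maximum posterior.
    """
    X = np.atleast_2d(np.asarray(data, float))
    n, d = X.shape
    if C > n:
        raise ValueError(f"cannot fit C={C} clusters to n={n} points")
    if C < 1:
        raise ValueError("C must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    scale2 = float(np.mean(np.var(X, axis=0)))
    var_floor = max(1e-6 * scale2, 1e-12)

    best: tuple[float, tuple] | None = None
    for _ in range(max(1, n_init)):
        means = _init_means_kmeanspp(X, C, rng)
        # hard-assignment bootstrap of responsibilities
        d2 = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        resp = np.zeros((n, C))
        resp[np.arange(n), np.argmin(d2, axis=1)] = 1.0
        weights, means, covs = _m_step(X, resp, covariance_type, var_floor)
        model = GMMModel(source_region, region_vocab or [], C, weights, means, covs,
                         covariance_type)
        prev_ll = -np.inf
        n_iter = 0
        lls: list[float] = []
        for n_iter in range(1, max_iter + 1):
            resp = model.posterior(X)
            nk = resp.sum(axis=0)
            empty = np.flatnonzero(nk < 1e-6)
            if empty.size:
                worst = int(np.argmin(resp.max(axis=1)))
                for k in empty:
                    model.means[k] = X[worst]
                    if covariance_type == "spherical":
                        model.covariances[k] = max(scale2, var_floor)
                    elif covariance_type == "diag":
                        model.covariances[k] = np.maximum(np.var(X, axis=0), var_floor)
                    else:
                        model.covariances[k] = np.diag(
                            np.maximum(np.var(X, axis=0), var_floor))
                    model.weights[k] = 1.0 / n
                model.weights /= model.weights.sum()
                resp = model.posterior(X)
            weights, means, covs = _m_step(X, resp, covariance_type, var_floor)
            model.weights, model.means, model.covariances = weights, means, covs
            ll = model.score(X)
            lls.append(ll)
            if ll - prev_ll < tol * max(1.0, abs(ll)) and n_iter > 1:
                prev_ll = ll
                break
            prev_ll = ll
        ll = model.score(X)
        if best is None or ll > best[0]:
            best = (ll, (model.weights.copy(), model.means.copy(),
                         model.covariances.copy(), n_iter, lls))

    ll, (weights, means, covs, n_iter, lls) = best
    model = GMMModel(
        source_region=source_region,
        region_vocab=region_vocab or [],
        C=C,
        weights=weights,
        means=means,
        covariances=covs,
        covariance_type=covariance_type,
        log_likelihood=ll,
        n_iter=n_iter,
        ll_trace=lls,
    )
    # per-cluster observed-region masks from the hard assignment
    labels = model.predict(X)
    masks = np.zeros((C, d), dtype=bool)
    for k in range(C):
        members = X[labels == k]
        if members.shape[0]:
            masks[k] = (members > 0).any(axis=0)
        else:
            masks[k] = model.means[k] > 1e-12
    model.observed_masks = masks
    model.bic = bic(model, X)
    return model


def posterior(model: GMMModel, f: np.ndarray) -> np.ndarray:
    """Posterior cluster probabilities P(c | f) for a single feature vector."""
    return model.posterior(np.atleast_2d(f))[0]


def bic(model: GMMModel, data: np.ndarray) -> float:
    """κ·ln(n) − 2·l(θ); lower is better (selection uses argmin)."""
    X = np.atleast_2d(np.asarray(data, float))
    n = X.shape[0]
    return float(model.n_free_parameters() * np.log(n) - 2.0 * model.score(X))


def select_model(
    data: np.ndarray,
    c_range: tuple[int, int] | None = None,
    imposed_c: int | None = None,
    rng: np.random.Generator | int | None = 0,
    covariance_type: str = "spherical",
    source_region: str = "",
    region_vocab: list[str] | None = None,
    **fit_kwargs,
) -> GMMModel:
    """Fit over a range of cluster counts and keep the best-BIC model.

    The default range is ``ceil(N/2)..N`` for N axons (degenerate N collapse
    to {1} / {1, 2}); an ``imposed_c`` overrides the search entirely.  The
    returned model carries the full BIC trace in ``model.bic_trace``.
    """
    X = np.atleast_2d(np.asarray(data, float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("no data to cluster")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if imposed_c is not None:
        candidates = [int(imposed_c)]
    else:
        if c_range is None:
            lo = max(1, int(np.ceil(n / 2)))
            hi = n
        else:
            lo, hi = c_range
        lo = max(1, min(lo, n))
        hi = max(lo, min(hi, n))
        candidates = list(range(lo, hi + 1))

    trace: dict[int, float] = {}
    best_model: GMMModel | None = None
    for c in candidates:
        model = fit_em(
            X, c, covariance_type=covariance_type, rng=rng,
            source_region=source_region, region_vocab=region_vocab, **fit_kwargs,
        )
        trace[c] = model.bic
        if best_model is None or model.bic < best_model.bic:
            best_model = model
    assert best_model is not None
    best_model.bic_trace = trace
    return best_model


def sample_virtual_axons(
    model: GMMModel, n: int, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n virtual projection vectors from the mixture.

    For each sample a cluster c is chosen with probability p_c and a vector
    drawn from N(μ_c, Σ_c).  Post-processing clips negatives to 0 and zeroes
    entries in regions never observed in that cluster's training members.

    Returns (samples (n, B), cluster labels (n,)).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    B = model.n_features
    labels = rng.choice(model.C, size=n, p=model.weights)
    out = np.empty((n, B))
    for i, c in enumerate(labels):
        if model.covariance_type == "spherical":
            x = rng.normal(model.means[c], np.sqrt(model.covariances[c]), size=B)
        elif model.covariance_type == "diag":
            x = rng.normal(model.means[c], np.sqrt(model.covariances[c]))
        else:
            x = rng.multivariate_normal(model.means[c], model.covariances[c])
        x = np.clip(x, 0.0, None)
        if model.observed_masks is not None:
            x = np.where(model.observed_masks[c], x, 0.0)
        out[i] = x
    return out, labels
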