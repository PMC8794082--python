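"""Noise-augmented von Mises-Fisher mixture fitting by EM.

The model places K vMF components on the unit sphere plus one fixed "noise"
component: a vMF with concentration near zero (effectively uniform) whose
mean is pinned to the global sample mean direction.  Observations that fit
none of the K directional clusters accumulate in the noise component, which
makes the identified clusters robust to outliers.  Only the noise mixing
proportion is updated during fitting; its mean and concentration are not.

Fitting alternates the standard E step (posterior membership probabilities,
the responsibilities gamma_jk) with an M step that uses the weighted mean
direction for mu_k, the Banerjee et al. closed-form approximation for
kappa_k, and responsibility averages for the mixing proportions.  The
number of clusters is chosen by minimising the BIC

    phi_m(K) = -2 * l_K(theta_hat) + ((m + 2) * K + m) * log(n)

over successive K, stopping once the criterion deteriorates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.special import logsumexp

from .io import DirectionalDataset
from .vmf import KAPPA_CAP, VMFParams, estimate_kappa, invert_bessel_ratio, log_norm_const

__all__ = [
    "MixtureModel",
    "Responsibilities",
    "FitResult",
    "ClusterAssignment",
    "NOISE_LABEL",
    "spherical_kmeans",
    "initialize",
    "e_step",
    "m_step",
    "log_likelihood",
    "fit_fixed_k",
    "select_k",
    "assign",
]

#: Label used for the noise component in hard assignments.
NOISE_LABEL = "noise"

#: Fixed concentration of the noise component: close enough to zero that its
#: density is effectively uniform on the sphere.
NOISE_KAPPA = 1e-4

_R_BAR_CLIP = 1.0 - 1e-12


class EmptyComponentError(RuntimeError):
    """A non-noise component lost all responsibility mass during EM."""


@dataclass
class MixtureModel:
    """K fitted vMF components plus the fixed noise component.

    ``pi`` holds the K+1 mixing proportions; index K (last) is the noise
    component with mean ``noise_mu`` (the global sample mean direction,
    arbitrary since the component is near-uniform) and tiny fixed
    concentration ``noise_kappa``.
    """

    components: list[VMFParams]
    noise_mu: np.ndarray
    pi: np.ndarray
    noise_kappa: float = NOISE_KAPPA

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.noise_mu = np.asarray(self.noise_mu, dtype=float)
        if self.pi.shape != (self.K + 1,):
            raise ValueError("pi must have K+1 entries")
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("mixing proportions must be non-negative and sum to 1")

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def m(self) -> int:
        return self.components[0].dim if self.components else self.noise_mu.size

    def all_components(self) -> list[VMFParams]:
        noise = VMFParams(mu=self.noise_mu, kappa=self.noise_kappa)
        return [*self.components, noise]

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "mu": [c.mu.tolist() for c in self.components],
            "kappa": [c.kappa for c in self.components],
            "noise_mu": self.noise_mu.tolist(),
            "noise_kappa": self.noise_kappa,
            "pi": self.pi.tolist(),
        }


@dataclass
class Responsibilities:
    """Posterior membership probabilities gamma, shape (n, K+1); noise last."""

    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if np.any(self.gamma < -1e-12) or np.any(self.gamma > 1 + 1e-12):
            raise ValueError("responsibilities must lie in [0, 1]")
        if np.max(np.abs(self.gamma.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("responsibility rows must sum to 1")

    @property
    def n(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_components(self) -> int:
        return self.gamma.shape[1]


@dataclass
class FitResult:
    """A converged (or best-effort) mixture fit for one value of K."""

    model: MixtureModel
    resp: Responsibilities
    loglik_trace: list[float]
    bic: float
    n_iter: int
    converged: bool
    n_restarts_used: int
    seed: int | None

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def save_params(self, path: str | Path) -> None:
        payload = {
            "model": self.model.to_dict(),
            "loglik": self.loglik,
            "bic": self.bic,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class ClusterAssignment:
    """Hard or thresholded cluster labels plus the full membership matrix.

    ``hard_labels`` uses 1-based cluster indices as strings ("1".."K"),
    ``"noise"`` for the noise component, and ``"unassigned"`` under
    threshold mode when no membership probability reaches the threshold.
    """

    hard_labels: list[str]
    membership_probs: np.ndarray
    soft_threshold: float | None = None
    soft_labels: list[list[str]] | None = None


def _mean_direction(x: np.ndarray) -> np.ndarray:
    s = x.sum(axis=0)
    norm = np.linalg.norm(s)
    if norm < 1e-300:
        # perfectly balanced antipodal data: fall back to the first point
        return x[0].copy()
    return s / norm


# ---------------------------------------------------------------------------
# Initialisation: spherical k-means
# ---------------------------------------------------------------------------

def spherical_kmeans(
    x: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int = 100,
) -> np.ndarray:
    """Cosine-similarity k-means on unit vectors; returns 0-based labels.

    Centroids start as K distinct observation rows chosen at random, are
    updated to the unit-normalised mean of their members, and assignment
    maximises the dot product.  Emptied centroids are re-seeded to a random
    observation.
    """
    n = x.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of observations n={n}")
    centroids = x[rng.choice(n, size=K, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        new_labels = np.argmax(x @ centroids.T, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(K):
            members = x[labels == k]
            if members.shape[0] == 0:
                centroids[k] = x[rng.integers(n)]
                continue
            s = members.sum(axis=0)
            norm = np.linalg.norm(s)
            centroids[k] = s / norm if norm > 1e-300 else members[0]
    return labels


def initialize(
    data: DirectionalDataset,
    K: int,
    noise_prop0: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> Responsibilities:
    """Initial responsibilities from a spherical k-means partition.

    The cluster that k-means assigns observation i to receives
    1 - noise_prop0; the noise column receives noise_prop0; all other
    columns 0.  EM then starts at the M step.
    """
    if not 0.0 < noise_prop0 < 1.0:
        raise ValueError("noise_prop0 must lie in (0, 1)")
    rng = np.random.default_rng(rng)
    labels = spherical_kmeans(data.x, K, rng)
    gamma = np.zeros((data.n, K + 1))
    gamma[np.arange(data.n), labels] = 1.0 - noise_prop0
    gamma[:, K] = noise_prop0
    return Responsibilities(gamma=gamma)


# ---------------------------------------------------------------------------
# E and M steps
# ---------------------------------------------------------------------------

def _log_joint(data: DirectionalDataset, model: MixtureModel) -> np.ndarray:
    """(n, K+1) matrix of log(pi_k) + log f(x_j | mu_k, kappa_k)."""
    comps = model.all_components()
    out = np.empty((data.n, len(comps)))
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
    for k, c in enumerate(comps):
        out[:, k] = log_pi[k] + log_norm_const(c.dim, c.kappa) + c.kappa * (data.x @ c.mu)
    return out


def e_step(data: DirectionalDataset, model: MixtureModel) -> Responsibilities:
    """Posterior responsibilities gamma_jk, computed in log space."""
    lj = _log_joint(data, model)
    gamma = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
    return Responsibilities(gamma=gamma)


def log_likelihood(data: DirectionalDataset, model: MixtureModel) -> float:
    """Observed-data log-likelihood l_K(theta) of the mixture."""
    return float(logsumexp(_log_joint(data, model), axis=1).sum())


def m_step(
    data: DirectionalDataset,
    resp: Responsibilities,
    noise_mu: np.ndarray | None = None,
    noise_kappa: float = NOISE_KAPPA,
    kappa_cap: float = KAPPA_CAP,
    kappa_method: Literal["approx", "exact"] = "approx",
) -> MixtureModel:
    """Update component parameters from responsibilities.

    For each non-noise component k: mu_k is the normalised weighted sum of
    observations, kappa_k the Banerjee approximation evaluated at the mean
    resultant length r_bar_k; mixing proportions are responsibility means.
    The noise component's mu and kappa are never updated.

    ``kappa_method="exact"`` replaces the closed-form kappa approximation
    with root-finding inversion of the Bessel ratio.  The approximation is
    the default; note it makes the M step inexact, so the EM log-likelihood
    can occasionally dip by an amount of the order of the approximation
    error, whereas the exact update is strictly ascending.
    """
    gamma = resp.gamma
    K = resp.n_components - 1
    n = data.n
    if noise_mu is None:
        noise_mu = _mean_direction(data.x)

    weights = gamma.sum(axis=0)
    if np.any(weights[:K] < 1e-8 * n):
        k_bad = int(np.argmin(weights[:K]))
        raise EmptyComponentError(f"component {k_bad} has vanishing responsibility mass")

    components = []
    for k in range(K):
        s = gamma[:, k] @ data.x
        s_norm = np.linalg.norm(s)
        if s_norm < 1e-300:
            raise EmptyComponentError(f"component {k} has zero resultant vector")
        mu = s / s_norm
        r_bar = min(s_norm / weights[k], _R_BAR_CLIP)
        if kappa_method == "exact":
            kappa = invert_bessel_ratio(r_bar, data.m, kappa_cap=kappa_cap)
        else:
            kappa = estimate_kappa(r_bar, data.m, kappa_cap=kappa_cap)
        components.append(VMFParams(mu=mu, kappa=kappa, kappa_cap=kappa_cap))

    return MixtureModel(
        components=components,
        noise_mu=noise_mu,
        pi=weights / n,
        noise_kappa=noise_kappa,
    )


# ---------------------------------------------------------------------------
# Full fitting loop
# ---------------------------------------------------------------------------

def _run_em(
    data: DirectionalDataset,
    gamma0: Responsibilities,
    noise_mu: np.ndarray,
    tol: float,
    max_iter: int,
    noise_kappa: float,
    kappa_cap: float,
    kappa_method: str,
) -> tuple[MixtureModel, Responsibilities, list[float], int, bool]:
    resp = gamma0
    trace: list[float] = []
    converged = False
    model = m_step(data, resp, noise_mu=noise_mu, noise_kappa=noise_kappa,
                   kappa_cap=kappa_cap, kappa_method=kappa_method)
    for it in range(1, max_iter + 1):
        resp = e_step(data, model)
        ll = log_likelihood(data, model)
        trace.append(ll)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        model = m_step(data, resp, noise_mu=noise_mu, noise_kappa=noise_kappa,
                       kappa_cap=kappa_cap, kappa_method=kappa_method)
    return model, resp, trace, len(trace), converged


def _bic(loglik: float, K: int, m: int, n: int) -> float:
    r = (m + 2) * K + m
    return -2.0 * loglik + r * np.log(n)


def fit_fixed_k(
    data: DirectionalDataset,
    K: int,
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 500,
    noise_prop0: float = 0.05,
    noise_kappa: float = NOISE_KAPPA,
    kappa_cap: float = KAPPA_CAP,
    kappa_method: Literal["approx", "exact"] = "approx",
    seed: int | None = None,
) -> FitResult:
    """Fit the (K+1)-component mixture, keeping the best of ``n_restarts`` runs.

    Each restart initialises via spherical k-means with its own derived seed
    and iterates EM until the change in log-likelihood falls below ``tol``.
    The restart attaining the greatest final log-likelihood wins.  A restart
    whose EM empties a component is abandoned and re-initialised (up to 3
    extra attempts).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    noise_mu = _mean_direction(data.x)
    ss = np.random.SeedSequence(seed)
    restart_seeds = ss.spawn(n_restarts)

    best: FitResult | None = None
    used = 0
    for r_seed in restart_seeds:
        used += 1
        outcome = None
        for attempt_seed in [r_seed, *r_seed.spawn(3)]:
            rng = np.random.default_rng(attempt_seed)
            gamma0 = initialize(data, K, noise_prop0=noise_prop0, rng=rng)
            try:
                outcome = _run_em(
                    data, gamma0, noise_mu, tol, max_iter, noise_kappa, kappa_cap,
                    kappa_method,
                )
                break
            except EmptyComponentError:
                continue
        if outcome is None:
            continue
        model, resp, trace, n_iter, converged = outcome
        result = FitResult(
            model=model,
            resp=resp,
            loglik_trace=trace,
            bic=_bic(trace[-1], K, data.m, data.n),
            n_iter=n_iter,
            converged=converged,
            n_restarts_used=used,
            seed=seed,
        )
        if best is None or result.loglik > best.loglik:
            best = result
    if best is None:
        raise EmptyComponentError(
            f"all restarts collapsed for K={K}; data may not support this many clusters"
        )
    if not best.converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations for K={K}", RuntimeWarning
        )
    return best


def select_k(
    data: DirectionalDataset,
    k_min: int = 1,
    k_max_cap: int = 10,
    patience: int = 2,
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 500,
    noise_prop0: float = 0.05,
    noise_kappa: float = NOISE_KAPPA,
    kappa_cap: float = KAPPA_CAP,
    kappa_method: Literal["approx", "exact"] = "approx",
    seed: int | None = None,
) -> FitResult:
    """Choose the number of clusters by BIC.

    Fits K = k_min, k_min+1, ... and computes phi_m(K).  Stops after
    ``patience`` consecutive K whose criterion exceeds the running minimum
    (or at ``k_max_cap``), then returns the fit minimising phi_m(K).  The
    default patience of 2 keeps searching past a single bad local optimum,
    which materially improves selection when one true cluster is small;
    patience=1 stops at the first deterioration.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    ss = np.random.SeedSequence(seed)
    best: FitResult | None = None
    n_worse = 0
    for K, k_seed in zip(
        range(k_min, k_max_cap + 1), ss.spawn(k_max_cap - k_min + 1)
    ):
        try:
            result = fit_fixed_k(
                data,
                K,
                n_restarts=n_restarts,
                tol=tol,
                max_iter=max_iter,
                noise_prop0=noise_prop0,
                noise_kappa=noise_kappa,
                kappa_cap=kappa_cap,
                kappa_method=kappa_method,
                seed=int(k_seed.generate_state(1)[0] % (2**31)),
            )
        except EmptyComponentError:
            break  # data cannot support K components; larger K will not help
        if best is None or result.bic < best.bic:
            best = result
            n_worse = 0
        else:
            n_worse += 1
            if n_worse >= patience:
                break
    assert best is not None
    return best


def assign(
    result: FitResult,
    mode: Literal["hard", "threshold", "soft"] = "hard",
    threshold: float | None = None,
) -> ClusterAssignment:
    """Turn responsibilities into cluster labels.

    hard: argmax membership (ties -> lowest index).  threshold: argmax only
    if its probability reaches ``threshold``, else "unassigned".  soft: all
    clusters with probability >= ``threshold`` (possibly several, possibly
    none).
    """
    gamma = result.resp.gamma
    K = result.model.K

    def _label(k: int) -> str:
        return NOISE_LABEL if k == K else str(k + 1)

    if mode not in ("hard", "threshold", "soft"):
        raise ValueError(f"unknown assignment mode: {mode!r}")
    if mode != "hard":
        if threshold is None or not 0.0 < threshold <= 1.0:
            raise ValueError("threshold in (0, 1] is required for threshold/soft modes")

    argmax = np.argmax(gamma, axis=1)  # np.argmax breaks ties at lowest index
    hard = [_label(k) for k in argmax]

    if mode == "hard":
        return ClusterAssignment(hard_labels=hard, membership_probs=gamma)
    if mode == "threshold":
        labels = [
            h if gamma[j, argmax[j]] >= threshold else "unassigned"
            for j, h in enumerate(hard)
        ]
        return ClusterAssignment(
            hard_labels=labels, membership_probs=gamma, soft_threshold=threshold
        )
    soft = [[_label(k) for k in range(K + 1) if gamma[j, k] >= threshold] for j in range(gamma.shape[0])]
    return ClusterAssignment(
        hard_labels=hard,
        membership_probs=gamma,
        soft_threshold=threshold,
        soft_labels=soft,
    )
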