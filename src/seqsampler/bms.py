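"""Random-effects Bayesian model selection over per-participant log evidence.

Participants are assumed to be drawn from a population in which each model
has an unknown frequency; the posterior over frequencies is a Dirichlet
estimated by the standard variational fixed point (responsibilities
``u_nk ∝ exp(log_evidence_nk + ψ(α_k) − ψ(Σα))``, then ``α = α0 + Σ_n u_nk``).
Exceedance probability (XP) is the posterior probability that a model is the
most frequent; the Bayes omnibus risk (BOR) is the posterior probability of
the null hypothesis that all models are equally frequent, from the free
energies of the null and the random-effects alternative; the protected
exceedance probability blends the two:

    PXP_k = (1 − BOR) · XP_k + BOR / K
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, digamma, gammaln, logsumexp


class BMSConvergenceError(RuntimeError):
    pass


@dataclass
class BMSResult:
    alpha: np.ndarray            # Dirichlet concentration per model
    freq_mean: np.ndarray        # expected model frequencies
    freq_sd: np.ndarray
    responsibilities: np.ndarray  # participants × models
    xp: np.ndarray | None = None
    bor: float | None = None
    pxp: np.ndarray | None = None
    n_iterations: int = 0

    def to_dict(self) -> dict:
        out = dict(
            alpha=self.alpha.tolist(),
            freq_mean=self.freq_mean.tolist(),
            freq_sd=self.freq_sd.tolist(),
            n_iterations=self.n_iterations,
        )
        if self.xp is not None:
            out["xp"] = self.xp.tolist()
        if self.bor is not None:
            out["bor"] = self.bor
        if self.pxp is not None:
            out["pxp"] = self.pxp.tolist()
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _check_evidence(log_evidence: np.ndarray) -> np.ndarray:
    L = np.asarray(log_evidence, float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("log_evidence must be (participants × ≥2 models)")
    if not np.all(np.isfinite(L)):
        raise ValueError("log_evidence must be finite")
    return L


def vb_dirichlet(
    log_evidence,
    alpha0: float | np.ndarray = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Variational Dirichlet posterior over model frequencies."""
    L = _check_evidence(log_evidence)
    n, K = L.shape
    a0 = np.broadcast_to(np.asarray(alpha0, float), (K,)).copy()
    if np.any(a0 <= 0):
        raise ValueError("alpha0 must be positive")
    alpha = a0.copy() + n / K
    for it in range(1, max_iter + 1):
        logu = L + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = a0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise BMSConvergenceError(
            f"no convergence after {max_iter} iterations (α = {alpha})"
        )
    s = alpha.sum()
    mean = alpha / s
    sd = np.sqrt(alpha * (s - alpha) / (s * s * (s + 1.0)))
    return BMSResult(
        alpha=alpha, freq_mean=mean, freq_sd=sd,
        responsibilities=u, n_iterations=it,
    )


def exceedance(
    alpha,
    n_samples: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Monte-Carlo P(frequency_k is the largest) under Dirichlet(alpha)."""
    alpha = np.asarray(alpha, float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    return np.bincount(winners, minlength=alpha.size) / n_samples


def exceedance_2model_exact(alpha) -> np.ndarray:
    """Closed form for K=2: XP₁ = P(f₁ > 1/2) from the Beta CDF."""
    alpha = np.asarray(alpha, float)
    if alpha.size != 2:
        raise ValueError("exact form only for two models")
    xp1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
    return np.array([xp1, 1.0 - xp1])


def _free_energy_alternative(L, alpha, u, a0) -> float:
    """Variational bound of the random-effects (Dirichlet) model."""
    dg = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_u = -np.sum(np.where(u > 0, u * np.log(u), 0.0))
    e_lik = float(np.sum(u * (L + dg)))
    e_prior = (
        gammaln(a0.sum()) - gammaln(a0).sum()
        + float(np.sum((a0 - 1.0) * dg))
    )
    ent_q = (
        gammaln(alpha.sum()) - gammaln(alpha).sum()
        + float(np.sum((alpha - 1.0) * dg))
    )
    return e_lik + ent_u + e_prior - ent_q


def _log_evidence_null(L) -> float:
    """Exact log evidence of the null: every participant uses each model
    with fixed probability 1/K."""
    n, K = L.shape
    return float(np.sum(logsumexp(L, axis=1) - np.log(K)))


def bayes_omnibus_risk(log_evidence, result: BMSResult, alpha0=1.0) -> float:
    """Posterior probability that model frequencies are all equal (the null)
    rather than heterogeneous, from the two free energies."""
    L = _check_evidence(log_evidence)
    K = L.shape[1]
    a0 = np.broadcast_to(np.asarray(alpha0, float), (K,)).copy()
    f1 = _free_energy_alternative(L, result.alpha, result.responsibilities, a0)
    f0 = _log_evidence_null(L)
    return float(1.0 / (1.0 + np.exp(f1 - f0)))


def protected_exceedance(
    log_evidence,
    alpha0: float | np.ndarray = 1.0,
    n_samples: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> BMSResult:
    """Full BMS: Dirichlet posterior, XP, BOR and PXP."""
    L = _check_evidence(log_evidence)
    res = vb_dirichlet(L, alpha0)
    res.xp = exceedance(res.alpha, n_samples, rng)
    res.bor = bayes_omnibus_risk(L, res, alpha0)
    K = L.shape[1]
    res.pxp = (1.0 - res.bor) * res.xp + res.bor / K
    return res


def prevalence_comparison(
    alpha_a,
    alpha_b,
    model: int = 0,
    n_samples: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte-Carlo P(frequency of ``model`` is higher in cohort A than B),
    sampling the two Dirichlet posteriors independently."""
    alpha_a = np.asarray(alpha_a, float)
    alpha_b = np.asarray(alpha_b, float)
    if alpha_a.shape != alpha_b.shape:
        raise ValueError("posteriors must come from the same model set")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fa = rng.dirichlet(alpha_a, size=n_samples)[:, model]
    fb = rng.dirichlet(alpha_b, size=n_samples)[:, model]
    return float(np.mean(fa > fb))
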