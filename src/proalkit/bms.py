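"""Random-effects Bayesian model selection (RFX-BMS).

Given a subjects x models matrix of log model evidences, a Dirichlet model
over population model frequencies is fitted by variational Bayes.  Outputs
are the Dirichlet concentrations, expected frequencies r, per-subject model
attributions g, exceedance probabilities (Monte-Carlo under the Dirichlet
posterior), the Bayesian omnibus risk — the posterior probability that all
models are equally frequent — and the protected exceedance probabilities
that shrink the exceedance probabilities toward 1/K by that risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp


class BMSConvergenceError(RuntimeError):
    def __init__(self, msg, trace):
        super().__init__(msg)
        self.trace = trace


@dataclass
class BMSResult:
    model_labels: list[str]
    alpha: np.ndarray     # Dirichlet concentrations
    r: np.ndarray         # expected model frequencies
    g: np.ndarray         # subjects x models posterior attributions
    ep: np.ndarray        # exceedance probabilities
    bor: float            # Bayesian omnibus risk
    pxp: np.ndarray       # protected exceedance probabilities
    F1: float             # free energy of the random-effects model
    F0: float             # free energy of the equal-frequency null

    def to_record(self) -> dict:
        return {
            "models": self.model_labels,
            "alpha": self.alpha.tolist(),
            "frequencies": self.r.tolist(),
            "exceedance_prob": self.ep.tolist(),
            "protected_exceedance_prob": self.pxp.tolist(),
            "bayesian_omnibus_risk": self.bor,
            "free_energy": self.F1,
            "null_free_energy": self.F0,
        }


def _validate_L(L: np.ndarray) -> np.ndarray:
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] < 1 or L.shape[1] < 2:
        raise ValueError("need a subjects x models matrix with >= 2 models")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    return L


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL(Dir(alpha) || Dir(alpha0)), closed form."""
    a_sum = alpha.sum()
    return float(gammaln(a_sum) - gammaln(alpha).sum()
                 - gammaln(alpha0.sum()) + gammaln(alpha0).sum()
                 + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(a_sum))))


def rfx_bms_vb(L: np.ndarray, alpha0: np.ndarray | float = 1.0,
               tol: float = 1e-6, max_iter: int = 10_000
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Variational fixed point of the Dirichlet random-effects model.

    Iterates g_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα)); α = α0 + Σ_n g_n until the
    concentration change falls below ``tol``.  Returns (alpha, r, g, F1)
    where F1 is the variational free energy (evidence lower bound) of the
    random-effects model.
    """
    L = _validate_L(L)
    n, K = L.shape
    alpha0 = np.full(K, float(alpha0)) if np.isscalar(alpha0) \
        else np.asarray(alpha0, dtype=float)
    if np.any(alpha0 <= 0):
        raise ValueError("alpha0 must be positive")
    alpha = alpha0.copy()
    trace = []
    for _ in range(max_iter):
        w = L + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        delta = np.max(np.abs(alpha_new - alpha))
        trace.append(delta)
        alpha = alpha_new
        if delta < tol:
            break
    else:
        raise BMSConvergenceError(
            f"RFX-BMS did not converge in {max_iter} iterations", trace)
    r = alpha / alpha.sum()
    w = L + digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(g > 0, g * np.log(g), 0.0)
    F1 = float(np.sum(g * w) - np.sum(ent) - _dirichlet_kl(alpha, alpha0))
    return alpha, r, g, F1


def exceedance_probabilities(alpha: np.ndarray, n_samples: int = 100_000,
                             seed: int = 0) -> np.ndarray:
    """Monte-Carlo P(r_k > r_j for all j) under Dirichlet(alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    # break exact ties uniformly (measure zero for continuous draws)
    jitter = rng.random(draws.shape) * 1e-12
    winners = np.argmax(draws + jitter, axis=1)
    counts = np.bincount(winners, minlength=len(alpha))
    return counts / n_samples


def omnibus_risk_and_pxp(L: np.ndarray, ep: np.ndarray, F1: float
                         ) -> tuple[float, np.ndarray]:
    """Bayesian omnibus risk and protected exceedance probabilities.

    The null model fixes all frequencies at 1/K, with free energy
    F0 = Σ_n [logsumexp_k L_nk − log K]; bor = 1/(1+exp(F1−F0)) and
    pxp_k = ep_k (1−bor) + bor/K.
    """
    L = _validate_L(L)
    K = L.shape[1]
    F0 = float(np.sum(logsumexp(L, axis=1) - math.log(K)))
    x = F1 - F0
    bor = 1.0 / (1.0 + math.exp(x)) if x < 700 else 0.0
    pxp = np.asarray(ep) * (1.0 - bor) + bor / K
    return bor, pxp


def run_bms(L: np.ndarray, model_labels=None, alpha0: float = 1.0,
            tol: float = 1e-6, max_iter: int = 10_000,
            n_samples: int = 100_000, seed: int = 0) -> BMSResult:
    """Full RFX-BMS pipeline on a log-evidence matrix."""
    L = _validate_L(L)
    K = L.shape[1]
    if model_labels is None:
        model_labels = [f"m{k}" for k in range(K)]
    alpha, r, g, F1 = rfx_bms_vb(L, alpha0=alpha0, tol=tol, max_iter=max_iter)
    ep = exceedance_probabilities(alpha, n_samples=n_samples, seed=seed)
    bor, pxp = omnibus_risk_and_pxp(L, ep, F1)
    return BMSResult(model_labels=list(model_labels), alpha=alpha, r=r, g=g,
                     ep=ep, bor=bor, pxp=pxp, F1=F1,
                     F0=float(np.sum(logsumexp(L, axis=1) - math.log(K))))


def evidence_matrix_from_table(table, model_order=None):
    """Pivot the flat fit table (subject_id, model, lme) into (L, labels)."""
    pivot = table.pivot(index="subject_id", columns="model", values="lme")
    if model_order is not None:
        pivot = pivot[list(model_order)]
    if pivot.isna().any().any():
        raise ValueError("missing log evidences for some subject x model")
    return pivot.to_numpy(), list(pivot.columns)
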