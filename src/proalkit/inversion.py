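"""MAP inversion of the learning models and Laplace model evidence.

Each model's free parameters are estimated in an unconstrained *estimation
space* (identity for omega2/omega3, log for zeta and mu_meta, logit for the
RW learning rate) under independent Gaussian priors.  The objective is the
negative log joint, minimized by multi-start quasi-Newton optimization; the
log model evidence is the Laplace approximation

    lme = -nlj(theta_hat) + (d/2) log(2 pi) - 1/2 log det H

with H the numerical Hessian of the negative log joint at the optimum.  The
same estimation-space convention is used for fitting and for the evidence,
so evidences are comparable across models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import models as M
from .task import TaskSchedule, TrialRecord

_BIG = 1e12  # objective value assigned to inadmissible parameter regimes


class FitError(RuntimeError):
    """All optimization restarts failed."""


# ---------------------------------------------------------------------------
# parameter transforms and priors

def _identity(x):
    return x


def _logit(p):
    return math.log(p) - math.log1p(-p)


_TRANSFORMS: dict[str, tuple[Callable, Callable]] = {
    # name -> (native -> estimation, estimation -> native)
    "identity": (_identity, _identity),
    "log": (math.log, math.exp),
    "logit": (_logit, M.sigmoid),
}


@dataclass(frozen=True)
class FreeParam:
    name: str
    transform: str  # key into _TRANSFORMS
    prior_mean: float  # in estimation space
    prior_var: float

    def to_native(self, est: float) -> float:
        return _TRANSFORMS[self.transform][1](est)

    def to_est(self, native: float) -> float:
        return _TRANSFORMS[self.transform][0](native)


@dataclass(frozen=True)
class PriorSpec:
    """Free parameters (with estimation-space Gaussian priors) and fixed
    parameters of one model."""

    model_id: str
    free: tuple[FreeParam, ...]
    fixed: dict

    @property
    def d(self) -> int:
        return len(self.free)

    def native_params(self, theta_est: np.ndarray):
        kwargs = dict(self.fixed)
        for fp, v in zip(self.free, theta_est):
            kwargs[fp.name] = fp.to_native(float(v))
        if self.model_id == M.HGF:
            return M.HGFParams(**kwargs)
        if self.model_id == M.RW:
            return M.RWParams(**kwargs)
        if self.model_id == M.SK1:
            return M.SK1Params(**kwargs)
        raise ValueError(f"unknown model {self.model_id!r}")

    def est_from_native(self, params) -> np.ndarray:
        return np.array([fp.to_est(getattr(params, fp.name)) for fp in self.free])


def default_priors(model_id: str, kappa: float = 1.0) -> PriorSpec:
    """Toolbox-convention priors; fully overridable by constructing PriorSpec
    directly."""
    ln = math.log
    if model_id == M.HGF:
        return PriorSpec(M.HGF, (
            FreeParam("omega2", "identity", -3.0, 16.0),
            FreeParam("omega3", "identity", -6.0, 16.0),
            FreeParam("zeta", "log", ln(48.0), 1.0),
        ), {"kappa": kappa, "mu2_0": 0.0, "sigma2_0": 0.1,
            "mu3_0": 1.0, "sigma3_0": 1.0})
    if model_id == M.RW:
        return PriorSpec(M.RW, (
            FreeParam("alpha", "logit", _logit(0.3), 1.0),
            FreeParam("zeta", "log", ln(48.0), 1.0),
        ), {"v0": 0.5})
    if model_id == M.SK1:
        return PriorSpec(M.SK1, (
            FreeParam("mu_meta", "log", ln(0.05), 1.0),
            FreeParam("zeta", "log", ln(48.0), 1.0),
        ), {"beta0": ln(0.1), "v0": 0.5})
    raise ValueError(f"unknown model {model_id!r}")


# ---------------------------------------------------------------------------
# objective

def neg_log_joint(theta_est: np.ndarray, inputs: Sequence[int],
                  responses: Sequence[int | None], priors: PriorSpec) -> float:
    """Negative log joint: -log-likelihood - log-prior, in estimation space.

    Inadmissible parameter regimes (filter precision failures, overflow) map
    to a large finite value so optimizers can retreat from them.
    """
    try:
        params = priors.native_params(np.asarray(theta_est, dtype=float))
        traj = M.run_filter(priors.model_id, params, inputs)
        ll = M.response_loglik(traj, responses, params.zeta)
    except (M.InvalidParameterRegimeError, ValueError, OverflowError):
        return _BIG
    if not math.isfinite(ll):
        return _BIG
    lp = 0.0
    for fp, v in zip(priors.free, theta_est):
        lp += -0.5 * math.log(2 * math.pi * fp.prior_var) \
              - 0.5 * (float(v) - fp.prior_mean) ** 2 / fp.prior_var
    return -(ll + lp)


# ---------------------------------------------------------------------------
# Laplace evidence

def numerical_hessian(fun: Callable[[np.ndarray], float], x: np.ndarray,
                      step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    d = len(x)
    H = np.empty((d, d))
    f0 = fun(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / step ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (fun(x + ei + ej) - fun(x + ei - ej)
                                 - fun(x - ei + ej) + fun(x - ei - ej)) \
                / (4 * step ** 2)
    return H


def laplace_log_evidence(fun: Callable[[np.ndarray], float],
                         theta_hat: np.ndarray,
                         step: float = 1e-4) -> tuple[float, float]:
    """Laplace approximation of the log marginal likelihood.

    ``fun`` is the negative log joint; returns ``(lme, hessian_logdet)``.
    With zero free parameters the evidence is the joint itself.  Raises
    ``np.linalg.LinAlgError`` if the Hessian is not positive definite.
    """
    theta_hat = np.atleast_1d(np.asarray(theta_hat, dtype=float))
    d = len(theta_hat)
    if d == 0:
        return -fun(theta_hat), 0.0
    H = numerical_hessian(fun, theta_hat, step)
    np.linalg.cholesky(H)  # raises if not positive definite
    sign, logdet = np.linalg.slogdet(H)
    return (-fun(theta_hat) + 0.5 * d * math.log(2 * math.pi)
            - 0.5 * logdet), logdet


# ---------------------------------------------------------------------------
# MAP fitting

@dataclass
class FitResult:
    model_id: str
    params_est: dict[str, float]
    params_native: dict[str, float]  # free + fixed, native space
    nlj: float
    hessian_logdet: float | None
    lme: float | None
    n_restarts: int
    converged: bool
    seed: int

    def to_record(self) -> dict:
        return {
            "model": self.model_id,
            "params_est": self.params_est,
            "params": self.params_native,
            "neg_log_joint": self.nlj,
            "hessian_logdet": self.hessian_logdet,
            "lme": self.lme,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "seed": self.seed,
        }


def fit_map(inputs: Sequence[int], responses: Sequence[int | None],
            priors: PriorSpec, n_restarts: int = 8, seed: int = 0,
            tol: float = 1e-6) -> FitResult:
    """MAP estimate by the best of ``n_restarts`` quasi-Newton minimizations
    of the negative log joint from prior-dispersed starts.

    The first start is the prior mean; the rest are prior mean plus a
    standard-normal draw scaled by the prior SD.  Deterministic given seed.
    """
    if not any(y is not None for y in responses):
        raise ValueError("need at least one non-missing response")
    rng = np.random.default_rng(seed)
    mean = np.array([fp.prior_mean for fp in priors.free])
    sd = np.array([math.sqrt(fp.prior_var) for fp in priors.free])

    def obj(theta):
        return neg_log_joint(theta, inputs, responses, priors)

    best = None
    failures = []
    for r in range(max(1, n_restarts)):
        x0 = mean if r == 0 else mean + sd * rng.standard_normal(len(mean))
        if obj(x0) >= _BIG:
            x0 = mean
        try:
            res = optimize.minimize(obj, x0, method="L-BFGS-B",
                                    options={"ftol": tol, "maxiter": 500})
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if not math.isfinite(res.fun) or res.fun >= _BIG:
            failures.append("objective not finite at optimum")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all {n_restarts} restarts failed: {failures}")

    theta = best.x
    params = priors.native_params(theta)
    try:
        lme, hld = laplace_log_evidence(obj, theta)
        if not math.isfinite(lme):
            lme, hld = None, None
    except np.linalg.LinAlgError:
        lme, hld = None, None
    native = {fp.name: fp.to_native(float(t))
              for fp, t in zip(priors.free, theta)}
    native.update(priors.fixed)
    return FitResult(
        model_id=priors.model_id,
        params_est={fp.name: float(t) for fp, t in zip(priors.free, theta)},
        params_native=native,
        nlj=float(best.fun),
        hessian_logdet=hld,
        lme=lme,
        n_restarts=n_restarts,
        converged=bool(lme is not None),
        seed=seed,
    )


def fit_trials(trials: Sequence[TrialRecord], priors: PriorSpec,
               n_restarts: int = 8, seed: int = 0) -> FitResult:
    """Convenience wrapper: recode trial records and fit."""
    inputs = [t.u for t in trials]
    responses = M.responses_as_match(trials)
    return fit_map(inputs, responses, priors, n_restarts=n_restarts, seed=seed)


# ---------------------------------------------------------------------------
# parameter recovery

@dataclass
class RecoveryReport:
    """Original vs mean-recovered parameter values across subjects."""

    param_names: list[str]
    original: pd.DataFrame          # subjects x params
    mean_recovered: pd.DataFrame    # subjects x params
    correlations: dict[str, float]  # per-parameter Pearson r
    n_excluded: int = 0


def recover_parameters(true_params: Sequence, model_id: str,
                       schedule: TaskSchedule, n_sims: int = 10,
                       seed: int = 0, priors: PriorSpec | None = None,
                       n_restarts: int = 4) -> RecoveryReport:
    """Simulate ``n_sims`` sessions per parameter set, refit each, and
    correlate original with mean-recovered values across subjects.

    Subjects whose refits all fail are excluded and counted."""
    if len(true_params) < 5:
        raise ValueError("need at least 5 parameter sets")
    if priors is None:
        priors = default_priors(model_id)
    names = [fp.name for fp in priors.free]
    ss = np.random.SeedSequence(seed)
    orig_rows, rec_rows = [], []
    n_excluded = 0
    for i, p in enumerate(true_params):
        child = ss.spawn(1)[0]
        sim_seeds = child.generate_state(2 * n_sims) % (2 ** 31)
        recovered = []
        for s in range(n_sims):
            trials, _ = M.simulate_agent(model_id, p, schedule,
                                         rng_seed=int(sim_seeds[2 * s]))
            try:
                fit = fit_trials(trials, priors, n_restarts=n_restarts,
                                 seed=int(sim_seeds[2 * s + 1]))
            except FitError:
                continue
            recovered.append([fit.params_est[n] for n in names])
        if not recovered:
            n_excluded += 1
            continue
        orig_rows.append([priors.free[j].to_est(getattr(p, n))
                          for j, n in enumerate(names)])
        rec_rows.append(np.mean(recovered, axis=0))
    original = pd.DataFrame(orig_rows, columns=names)
    mean_rec = pd.DataFrame(rec_rows, columns=names)
    corrs = {}
    for n in names:
        if original[n].nunique() <= 1 or mean_rec[n].nunique() <= 1:
            corrs[n] = float("nan")
        else:
            corrs[n] = float(stats.pearsonr(original[n], mean_rec[n])[0])
    return RecoveryReport(param_names=names, original=original,
                          mean_recovered=mean_rec, correlations=corrs,
                          n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# interchange

def fits_to_table(fits: dict[tuple[str, str], FitResult]) -> pd.DataFrame:
    """Flat summary table (subject, model, params..., lme) from a mapping
    keyed by (subject_id, model_id)."""
    rows = []
    for (subject, model), fit in fits.items():
        row = {"subject_id": subject, "model": model, "lme": fit.lme,
               "neg_log_joint": fit.nlj, "converged": fit.converged}
        for k, v in fit.params_native.items():
            row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_fit_records(fits: dict[tuple[str, str], FitResult], path) -> None:
    records = [{"subject_id": s, **f.to_record()} for (s, _), f in fits.items()]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
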