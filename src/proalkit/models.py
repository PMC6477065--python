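"""Trial-by-trial learning models: three-level binary HGF, Rescorla-Wagner,
Sutton K1, and the shared unit-square sigmoid response model.

All three perceptual models filter the same binary input sequence ``u``
(1 iff the reference cue-outcome association held on the trial) and produce
a per-trial predicted outcome probability ``muhat1``.  The response model maps
that prediction to a choice probability through

    p(y=1) = muhat1**zeta / (muhat1**zeta + (1 - muhat1)**zeta)

with ``zeta`` the inverse decision noise: zeta -> 0 gives random choice,
zeta -> inf a step function at 0.5.

The HGF tracks the association tendency ``x2`` (so muhat1 = s(mu2)) and its
log-volatility ``x3``; the tonic parameters ``omega2``/``omega3`` set the step
size of the Gaussian random walks at levels 2 and 3, and ``kappa`` couples
level 3 into the level-2 step size.  Filters are deterministic: identical
parameters and inputs give bitwise-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .task import TaskSchedule, TrialRecord, generate_trials

#: probability clip used in the response likelihood
EPS = 1e-4

HGF = "hgf"
RW = "rw"
SK1 = "sk1"
MODEL_IDS = (HGF, RW, SK1)


class InvalidParameterRegimeError(ValueError):
    """The filter hit a non-positive precision; parameter set inadmissible."""


@dataclass(frozen=True)
class HGFParams:
    omega2: float = -3.0
    omega3: float = -6.0
    kappa: float = 1.0
    zeta: float = 48.0
    mu2_0: float = 0.0
    sigma2_0: float = 0.1
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self):
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass(frozen=True)
class RWParams:
    alpha: float = 0.3
    v0: float = 0.5
    zeta: float = 48.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.v0 < 1:
            raise ValueError("v0 must lie in (0, 1)")
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")


ALPHA_CAP = 1.0


@dataclass(frozen=True)
class SK1Params:
    mu_meta: float = 0.05
    beta0: float = math.log(0.1)
    v0: float = 0.5
    zeta: float = 48.0

    def __post_init__(self):
        if self.mu_meta < 0:
            raise ValueError("mu_meta must be non-negative")
        if not 0 < self.v0 < 1:
            raise ValueError("v0 must lie in (0, 1)")
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if math.exp(self.beta0) > ALPHA_CAP:
            raise ValueError("exp(beta0) exceeds the learning-rate cap")


@dataclass
class BeliefTrajectory:
    """Per-trial belief tracks; HGF fills all fields, RW/SK1 the value and
    learning-rate tracks only."""

    muhat1: np.ndarray
    mu2: np.ndarray | None = None
    sigma2: np.ndarray | None = None
    mu3: np.ndarray | None = None
    sigma3: np.ndarray | None = None
    pihat2: np.ndarray | None = None
    pihat3: np.ndarray | None = None
    delta1: np.ndarray | None = None
    delta2: np.ndarray | None = None
    value: np.ndarray | None = None       # RW/SK1 posterior value v(k)
    learning_rate: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.muhat1)

    def to_frame(self) -> pd.DataFrame:
        cols = {"muhat1": self.muhat1}
        for name in ("mu2", "sigma2", "mu3", "sigma3", "pihat2", "pihat3",
                     "delta1", "delta2", "value", "learning_rate"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        df = pd.DataFrame(cols)
        df.insert(0, "trial", np.arange(1, len(self) + 1))
        return df


def sigmoid(x: float) -> float:
    """Logistic function 1/(1+exp(-x)), stable for large |x|."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def response_prob(muhat1: float, zeta: float) -> float:
    """Unit-square sigmoid choice probability p(y=1 | muhat1, zeta)."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if not 0 < muhat1 < 1:
        raise ValueError("muhat1 must lie in (0, 1)")
    # work in log space: p = 1 / (1 + ((1-m)/m)**zeta)
    logit = zeta * (math.log(muhat1) - math.log1p(-muhat1))
    return sigmoid(logit)


def hgf_filter(params: HGFParams, inputs: Sequence[int]) -> BeliefTrajectory:
    """Run the three-level binary HGF over a 0/1 input sequence.

    Per trial the filter predicts (muhat2 = previous mu2, muhat1 = s(muhat2)),
    forms precision-weighted prediction errors, and updates levels 2 and 3.
    Raises :class:`InvalidParameterRegimeError` if any updated precision is
    non-positive (the caller treats the parameter set as inadmissible).
    """
    n = len(inputs)
    om2, om3, ka = params.omega2, params.omega3, params.kappa
    mu2, s2 = params.mu2_0, params.sigma2_0
    mu3, s3 = params.mu3_0, params.sigma3_0
    exp_om3 = math.exp(min(om3, 700.0))

    out = {k: np.empty(n) for k in ("muhat1", "mu2", "sigma2", "mu3", "sigma3",
                                    "pihat2", "pihat3", "delta1", "delta2")}
    for k in range(n):
        u = float(inputs[k])
        muhat2, muhat3 = mu2, mu3
        muhat1 = sigmoid(muhat2)
        v2 = math.exp(min(ka * muhat3 + om2, 700.0))
        pihat2 = 1.0 / (s2 + v2)
        pihat3 = 1.0 / (s3 + exp_om3)
        if pihat2 <= 0 or pihat3 <= 0 or not math.isfinite(pihat2):
            raise InvalidParameterRegimeError("non-positive prediction precision")
        d1 = u - muhat1
        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        mu2 = muhat2 + d1 / pi2
        s2 = 1.0 / pi2
        w2 = v2 * pihat2
        d2 = (s2 + (mu2 - muhat2) ** 2) * pihat2 - 1.0
        pi3 = pihat3 + 0.5 * ka * ka * w2 * (w2 + (2.0 * w2 - 1.0) * d2)
        if pi3 <= 0 or not math.isfinite(pi3):
            raise InvalidParameterRegimeError("non-positive level-3 precision")
        mu3 = muhat3 + (ka / (2.0 * pi3)) * w2 * d2
        s3 = 1.0 / pi3
        out["muhat1"][k] = muhat1
        out["mu2"][k] = mu2
        out["sigma2"][k] = s2
        out["mu3"][k] = mu3
        out["sigma3"][k] = s3
        out["pihat2"][k] = pihat2
        out["pihat3"][k] = pihat3
        out["delta1"][k] = d1
        out["delta2"][k] = d2
    return BeliefTrajectory(**out)


def rw_filter(params: RWParams, inputs: Sequence[int]) -> BeliefTrajectory:
    """Rescorla-Wagner delta rule with fixed learning rate alpha."""
    n = len(inputs)
    v = params.v0
    a = params.alpha
    muhat1 = np.empty(n)
    value = np.empty(n)
    delta1 = np.empty(n)
    for k in range(n):
        vhat = v
        d = float(inputs[k]) - vhat
        v = vhat + a * d
        muhat1[k] = min(max(vhat, EPS), 1.0 - EPS)
        value[k] = v
        delta1[k] = d
    return BeliefTrajectory(muhat1=muhat1, value=value, delta1=delta1,
                            learning_rate=np.full(n, a))


def sk1_filter(params: SK1Params, inputs: Sequence[int]) -> BeliefTrajectory:
    """Sutton K1 gain adaptation: the log learning rate beta follows the
    correlation between the current prediction error and an eligibility
    trace h, so persistent errors raise the learning rate."""
    if params.mu_meta < 0:
        raise ValueError("mu_meta must be non-negative")
    n = len(inputs)
    v = params.v0
    beta = params.beta0
    h = 0.0
    mu = params.mu_meta
    muhat1 = np.empty(n)
    value = np.empty(n)
    delta1 = np.empty(n)
    lrate = np.empty(n)
    for k in range(n):
        vhat = v
        d = float(inputs[k]) - vhat
        beta = beta + mu * d * h
        a = min(math.exp(beta), ALPHA_CAP)
        v = vhat + a * d
        h = (h + a * d) * max(0.0, 1.0 - a)
        muhat1[k] = min(max(vhat, EPS), 1.0 - EPS)
        value[k] = v
        delta1[k] = d
        lrate[k] = a
    return BeliefTrajectory(muhat1=muhat1, value=value, delta1=delta1,
                            learning_rate=lrate)


def run_filter(model_id: str, params, inputs) -> BeliefTrajectory:
    if model_id == HGF:
        return hgf_filter(params, inputs)
    if model_id == RW:
        return rw_filter(params, inputs)
    if model_id == SK1:
        return sk1_filter(params, inputs)
    raise ValueError(f"unknown model {model_id!r}")


def response_loglik(trajectory: BeliefTrajectory,
                    responses: Sequence[int | None],
                    zeta: float) -> float:
    """Sum of log choice probabilities over non-missing trials.

    ``responses[k]`` is 1/0 for the two choice categories (1 = the response
    matching the reference association) or None for a missing trial; missing
    trials contribute zero but the beliefs were already updated by the input.
    ``muhat1`` is clipped to [EPS, 1-EPS] before the response model.
    """
    if len(trajectory) != len(responses):
        raise ValueError("trajectory and responses have different lengths")
    ll = 0.0
    for k, y in enumerate(responses):
        if y is None:
            continue
        m = min(max(float(trajectory.muhat1[k]), EPS), 1.0 - EPS)
        p1 = response_prob(m, zeta)
        p = p1 if y == 1 else 1.0 - p1
        ll += math.log(min(max(p, 1e-300), 1.0))
    return ll


def simulate_agent(model_id: str, params, schedule: TaskSchedule,
                   rng_seed: int) -> tuple[list[TrialRecord], BeliefTrajectory]:
    """Simulate one session: generate trials, filter the inputs, and sample
    responses Bernoulli(response_prob) per trial.  Deterministic given seed."""
    rng = np.random.default_rng(rng_seed)
    trials = generate_trials(schedule, rng_seed=int(rng.integers(2 ** 31)))
    inputs = [t.u for t in trials]
    traj = run_filter(model_id, params, inputs)
    draws = rng.random(len(trials))
    for k, t in enumerate(trials):
        m = min(max(float(traj.muhat1[k]), EPS), 1.0 - EPS)
        p1 = response_prob(m, params.zeta)
        y_match = int(draws[k] < p1)
        # y=1 means "the response consistent with the reference association";
        # translate back to a face given the cue
        if t.cue == "high_tone":
            t.response = "female" if y_match else "male"
        else:
            t.response = "male" if y_match else "female"
    return trials, traj


def responses_as_match(trials: Sequence[TrialRecord]) -> list[int | None]:
    """Recode face responses as match-indicator space (1 iff the response is
    the outcome predicted by the reference association given the cue)."""
    out: list[int | None] = []
    for t in trials:
        if t.response == "missing":
            out.append(None)
        elif t.cue == "high_tone":
            out.append(int(t.response == "female"))
        else:
            out.append(int(t.response == "male"))
    return out
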