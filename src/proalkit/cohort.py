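"""Synthetic cohort generator.

Produces per-subject questionnaire scores, learning-model parameters and
full trial-level behavior with the joint structure the analysis stage
assumes, so the whole pipeline is testable without any external data.

Subjects are drawn from a latent Gaussian copula: each variable is a
monotone transform of a standard-normal latent, and the latent correlation
for each configured pair is calibrated (Gauss-Hermite quadrature + root
finding) so the *output-scale* Pearson correlation hits its target despite
the non-linear marginals.  Raw verbal-abuse scores are modeled as
zero-inflated lognormal before integer clipping, reproducing their strong
positive skew; resilience and anxiety scales are approximately Gaussian
within range.  The emotion-coping subscale is generated structurally from
the simple regression model (transformed preschool score and omega2 plus
Gaussian noise), so the cohort carries the configured effect pattern.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats as sps

from . import __version__ as _pkg_version
from .models import HGFParams, simulate_agent
from .stats import tukey_ladder
from .task import TaskSchedule, canonical_schedule, trials_to_frame

# questionnaire structure constants
VAQ_N_ITEMS = 15
VAQ_ITEM_RANGE = (0, 8)
RAS_N_SUBSCALES = 3
RAS_ITEMS_PER_SUBSCALE = 4
RAS_N_ITEMS = RAS_N_SUBSCALES * RAS_ITEMS_PER_SUBSCALE
RAS_ITEM_RANGE = (1, 5)
STAI_N_ITEMS = 20
STAI_ITEM_RANGE = (1, 4)


@dataclass(frozen=True)
class ZeroInflatedLognormal:
    """Marginal for raw verbal-abuse period scores: a point mass at zero and
    a lognormal body, expressed as a monotone transform of a latent normal."""

    p_zero: float
    mu_log: float
    sigma_log: float

    def transform(self, z: np.ndarray) -> np.ndarray:
        u = sps.norm.cdf(z)
        x = np.zeros_like(z, dtype=float)
        pos = u > self.p_zero
        q = (u[pos] - self.p_zero) / (1.0 - self.p_zero)
        q = np.clip(q, 1e-12, 1 - 1e-12)
        x[pos] = np.exp(self.mu_log + self.sigma_log * sps.norm.ppf(q))
        hi = VAQ_N_ITEMS * VAQ_ITEM_RANGE[1]
        return np.clip(np.rint(x), 0, hi)


@dataclass(frozen=True)
class GaussianScale:
    """Gaussian marginal, optionally rounded to integers, clipped to range."""

    mean: float
    sd: float
    lo: float
    hi: float
    integer: bool = True

    def transform(self, z: np.ndarray) -> np.ndarray:
        x = self.mean + self.sd * np.asarray(z, dtype=float)
        if self.integer:
            x = np.rint(x)
        return np.clip(x, self.lo, self.hi)


@dataclass(frozen=True)
class LognormalScale:
    """Lognormal marginal matched to a target mean and SD (positive vars)."""

    mean: float
    sd: float

    def transform(self, z: np.ndarray) -> np.ndarray:
        cv2 = (self.sd / self.mean) ** 2
        s2 = math.log1p(cv2)
        m = math.log(self.mean) - 0.5 * s2
        return np.exp(m + math.sqrt(s2) * np.asarray(z, dtype=float))


@dataclass
class CohortConfig:
    """Defaults encode the study conditions: 36 subjects, the published
    questionnaire moments, the published correlation and regression effect
    structure."""

    n_subjects: int = 36
    seed: int = 0
    # marginals
    age: GaussianScale = field(default_factory=lambda: GaussianScale(
        23.42, 4.10, 18.0, 35.0, integer=False))
    p_male: float = 23 / 36
    vaq_preschool: ZeroInflatedLognormal = field(default_factory=lambda:
        ZeroInflatedLognormal(0.25, 1.35, 1.10))
    vaq_childhood: ZeroInflatedLognormal = field(default_factory=lambda:
        ZeroInflatedLognormal(0.15, 2.42, 1.00))
    vaq_adolescent: ZeroInflatedLognormal = field(default_factory=lambda:
        ZeroInflatedLognormal(0.12, 2.45, 0.85))
    ras_social: GaussianScale = field(default_factory=lambda: GaussianScale(
        17.06, 2.10, 13.0, 20.0))
    ras_situation: GaussianScale = field(default_factory=lambda: GaussianScale(
        16.36, 2.10, 10.0, 20.0))
    stai_s: GaussianScale = field(default_factory=lambda: GaussianScale(
        35.83, 9.19, 20.0, 80.0))
    stai_t: GaussianScale = field(default_factory=lambda: GaussianScale(
        36.00, 9.63, 20.0, 80.0))
    # upper clip keeps every agent in the filter's admissible regime (at
    # kappa=1 the level-3 precision can turn negative above roughly -1)
    omega2: GaussianScale = field(default_factory=lambda: GaussianScale(
        -5.46, 2.82, -12.0, -1.5, integer=False))
    omega3: GaussianScale = field(default_factory=lambda: GaussianScale(
        -6.06, 0.14, -7.0, -5.0, integer=False))
    zeta: LognormalScale = field(default_factory=lambda: LognormalScale(3.16, 1.94))
    # output-scale Pearson correlation targets for copula pairs
    correlation_targets: dict = field(default_factory=lambda: {
        ("omega2", "vaq_childhood"): -0.379,
        ("omega2", "vaq_adolescent"): -0.448,
    })
    # structural model for the emotion-coping subscale; the coefficients act
    # on the transformed-preschool scale defined by (vaqt_mean, vaqt_sd)
    simple_intercept: float = 15.072
    simple_beta_vaq_t: float = -0.891
    simple_beta_omega2: float = -0.282
    simple_resid_sd: float = 2.281
    vaqt_mean: float = 1.31
    vaqt_sd: float = 0.98

    def to_dict(self) -> dict:
        d = asdict(self)
        d["correlation_targets"] = {f"{a}|{b}": v for (a, b), v
                                    in self.correlation_targets.items()}
        return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    ct = {tuple(k.split("|")): v
          for k, v in d.pop("correlation_targets", {}).items()}
    kwargs = {}
    for name, cls in [("age", GaussianScale), ("vaq_preschool", ZeroInflatedLognormal),
                      ("vaq_childhood", ZeroInflatedLognormal),
                      ("vaq_adolescent", ZeroInflatedLognormal),
                      ("ras_social", GaussianScale), ("ras_situation", GaussianScale),
                      ("stai_s", GaussianScale), ("stai_t", GaussianScale),
                      ("omega2", GaussianScale), ("omega3", GaussianScale),
                      ("zeta", LognormalScale)]:
        if name in d and isinstance(d[name], dict):
            kwargs[name] = cls(**d.pop(name))
    kwargs.update(d)
    if ct:
        kwargs["correlation_targets"] = ct
    return CohortConfig(**kwargs)


# copula variable order (emotion coping is structural, not copula-drawn)
_COPULA_VARS = ("age", "gender", "vaq_preschool", "vaq_childhood",
                "vaq_adolescent", "ras_social", "ras_situation",
                "stai_s", "stai_t", "omega2", "omega3", "zeta")


def _marginal_fn(config: CohortConfig, var: str):
    if var == "gender":
        thr = sps.norm.ppf(config.p_male)
        return lambda z: (np.asarray(z) < thr).astype(float)  # 1 = male
    return getattr(config, var).transform


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(96)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()  # probabilists' weights


def _output_pearson(g1, g2, rho: float) -> float:
    """Pearson correlation of (g1(Z1), g2(Z2)) with latent corr rho, by
    Gauss-Hermite quadrature."""
    z = _GH_NODES
    w = _GH_WEIGHTS
    x1 = g1(z)
    m1 = float(w @ x1)
    v1 = float(w @ (x1 - m1) ** 2)
    x2m = g2(rho * z[:, None] + math.sqrt(max(1 - rho * rho, 0.0)) * z[None, :])
    m2 = float(w @ (g2(z)))
    v2 = float(w @ (g2(z) - m2) ** 2)
    e12 = float(w @ ((x1[:, None] - m1) * (x2m - m2) @ w))
    if v1 <= 0 or v2 <= 0:
        return 0.0
    return e12 / math.sqrt(v1 * v2)


def match_latent_rho(g1, g2, target: float) -> float:
    """Latent normal correlation whose output-scale Pearson equals target."""
    if target == 0.0:
        return 0.0
    f = lambda rho: _output_pearson(g1, g2, rho) - target
    lo, hi = (-0.999, 0.0) if target < 0 else (0.0, 0.999)
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(f"correlation target {target} unattainable for marginals")
    return float(optimize.brentq(f, lo, hi, xtol=1e-4))


def _nearest_pd(S: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipping repair to the nearest positive-definite
    correlation matrix (diagonal renormalized to 1)."""
    vals, vecs = np.linalg.eigh(S)
    if vals.min() > eps:
        return S
    vals = np.clip(vals, eps, None)
    A = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    if np.linalg.eigvalsh(A).min() <= 0:
        raise ValueError("correlation matrix not repairable")
    return A


def latent_correlation(config: CohortConfig) -> np.ndarray:
    k = len(_COPULA_VARS)
    S = np.eye(k)
    idx = {v: i for i, v in enumerate(_COPULA_VARS)}
    for (a, b), target in config.correlation_targets.items():
        if a not in idx or b not in idx:
            raise ValueError(f"unknown correlation pair ({a}, {b})")
        rho = match_latent_rho(_marginal_fn(config, a),
                               _marginal_fn(config, b), float(target))
        S[idx[a], idx[b]] = S[idx[b], idx[a]] = rho
    return _nearest_pd(S)


def generate_cohort(config: CohortConfig
                    ) -> tuple[pd.DataFrame, list[HGFParams]]:
    """Draw a cohort table and per-subject HGF agent parameters.

    Deterministic given ``config.seed``.  The transformed preschool score is
    produced by the same ladder-of-powers selection the analysis stage uses;
    the emotion-coping subscale is its configured linear function of that
    transform and omega2, plus Gaussian noise, rounded and clipped to scale.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    S = latent_correlation(config)
    Z = rng.multivariate_normal(np.zeros(len(_COPULA_VARS)), S, size=n,
                                method="cholesky")
    cols = {}
    for j, v in enumerate(_COPULA_VARS):
        cols[v] = _marginal_fn(config, v)(Z[:, j])
    df = pd.DataFrame(cols)
    df.insert(0, "subject_id", [f"s{i + 1:03d}" for i in range(n)])

    # ladder-of-powers transform of the raw preschool score, rescaled to the
    # configured moments so the structural coefficients act on their scale
    # (Pearson structure is invariant to the linear rescaling)
    vaq_t, lam, off = tukey_ladder(df["vaq_preschool"].to_numpy())
    sd = vaq_t.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate preschool scores: transform has no spread")
    df["vaq_preschool_t"] = (config.vaqt_mean
                             + config.vaqt_sd * (vaq_t - vaq_t.mean()) / sd)
    lin = (config.simple_intercept
           + config.simple_beta_vaq_t * df["vaq_preschool_t"]
           + config.simple_beta_omega2 * df["omega2"]
           + rng.normal(0.0, config.simple_resid_sd, size=n))
    lo = RAS_ITEMS_PER_SUBSCALE * RAS_ITEM_RANGE[0]
    hi = RAS_ITEMS_PER_SUBSCALE * RAS_ITEM_RANGE[1]
    df["ras_emotion"] = np.clip(np.rint(lin), lo, hi)
    df["ras_total"] = df["ras_emotion"] + df["ras_social"] + df["ras_situation"]

    order = ["subject_id", "age", "gender", "vaq_preschool", "vaq_childhood",
             "vaq_adolescent", "vaq_preschool_t", "ras_total", "ras_emotion",
             "ras_social", "ras_situation", "stai_s", "stai_t",
             "omega2", "omega3", "zeta"]
    df = df[order]
    agents = [HGFParams(omega2=float(r.omega2), omega3=float(r.omega3),
                        zeta=float(r.zeta))
              for r in df.itertuples(index=False)]
    return df, agents


def partition_total(total: int, n_items: int, lo: int, hi: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Random composition of an integer total into item scores in [lo, hi]."""
    total = int(total)
    if not n_items * lo <= total <= n_items * hi:
        raise ValueError(f"total {total} infeasible for {n_items} items in "
                         f"[{lo}, {hi}]")
    items = np.full(n_items, lo)
    for _ in range(total - n_items * lo):
        room = np.flatnonzero(items < hi)
        items[room[rng.integers(len(room))]] += 1
    return items


def item_scores(cohort: pd.DataFrame, seed: int = 0) -> dict[str, pd.DataFrame]:
    """Item-level questionnaire scores consistent with each subject's totals.

    Only the totals feed the analysis; items exist so the simulated
    instruments have the real ones' structure (15 verbal-abuse items per
    period, 3 x 4 resilience items, 20 anxiety items per form)."""
    rng = np.random.default_rng(seed)
    out = {}
    specs = [("vaq_preschool", VAQ_N_ITEMS, *VAQ_ITEM_RANGE),
             ("vaq_childhood", VAQ_N_ITEMS, *VAQ_ITEM_RANGE),
             ("vaq_adolescent", VAQ_N_ITEMS, *VAQ_ITEM_RANGE),
             ("ras_emotion", RAS_ITEMS_PER_SUBSCALE, *RAS_ITEM_RANGE),
             ("ras_social", RAS_ITEMS_PER_SUBSCALE, *RAS_ITEM_RANGE),
             ("ras_situation", RAS_ITEMS_PER_SUBSCALE, *RAS_ITEM_RANGE),
             ("stai_s", STAI_N_ITEMS, *STAI_ITEM_RANGE),
             ("stai_t", STAI_N_ITEMS, *STAI_ITEM_RANGE)]
    for col, n_items, lo, hi in specs:
        rows = [partition_total(int(t), n_items, lo, hi, rng)
                for t in cohort[col]]
        out[col] = pd.DataFrame(
            rows, columns=[f"{col}_item{i + 1}" for i in range(n_items)],
            index=cohort["subject_id"])
    return out


def generate_behavior(agents: list[HGFParams], schedule: TaskSchedule,
                      seed: int = 0, subject_ids=None) -> pd.DataFrame:
    """One simulated session per agent on the given schedule; returns the
    concatenated long-format trial table."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(agents)) % (2 ** 31)
    if subject_ids is None:
        subject_ids = [f"s{i + 1:03d}" for i in range(len(agents))]
    frames = []
    for sid, params, s in zip(subject_ids, agents, seeds):
        trials, _ = simulate_agent("hgf", params, schedule, rng_seed=int(s))
        frames.append(trials_to_frame(trials, sid))
    return pd.concat(frames, ignore_index=True)


def config_hash(config: CohortConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def end_to_end_dataset(config: CohortConfig, outdir) -> dict:
    """Write the full synthetic bundle (cohort, agents, behavior, manifest)
    and return the manifest.  Regenerating from the manifest reproduces the
    same files byte for byte."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, agents = generate_cohort(config)
    schedule = canonical_schedule()
    behavior = generate_behavior(agents, schedule, seed=config.seed,
                                 subject_ids=list(cohort["subject_id"]))
    try:
        cohort.to_csv(outdir / "cohort.csv", index=False)
        behavior.to_csv(outdir / "trials.csv", index=False)
    except OSError as exc:
        raise OSError(f"failed writing dataset under {outdir}: {exc}") from exc
    manifest = {
        "generator_version": _pkg_version,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "files": ["cohort.csv", "trials.csv"],
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def regenerate_from_manifest(manifest: dict, outdir) -> dict:
    return end_to_end_dataset(config_from_dict(manifest["config"]), outdir)
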