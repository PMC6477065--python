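"""Cohort-level statistics: summaries, power transform, correlations,
collinearity, the regression suite with leave-one-out cross-validation, and
a mixed graphical model over continuous and binary variables.

The regression suite mirrors a fixed family of ordinary-least-squares models
predicting resilience emotion-coping appraisal from transformed preschool
verbal-abuse scores and the tonic level-2 volatility parameter omega2:

    simple            y ~ vaq_preschool_t + omega2
    full              y ~ vaq_preschool_t + omega2 + vaq_preschool_t:omega2
    partial_omega2    y ~ omega2 + vaq_preschool_t:omega2
    partial_vaq       y ~ vaq_preschool_t + vaq_preschool_t:omega2
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import Lasso, LogisticRegression

UNDEFINED = float("nan")


# ---------------------------------------------------------------------------
# summaries

def summarize(table: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Per-variable mean, SD (n-1), median, min, max, adjusted Fisher-Pearson
    skewness and excess kurtosis.  Constant variables get NaN skew/kurtosis
    markers rather than an exception."""
    if variables is None:
        variables = [c for c in table.columns
                     if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for v in variables:
        x = table[v].dropna().to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError(f"need >= 3 observations for {v!r}")
        constant = np.ptp(x) == 0
        rows.append({
            "variable": v, "mean": x.mean(), "sd": x.std(ddof=1),
            "median": float(np.median(x)), "min": x.min(), "max": x.max(),
            "skewness": UNDEFINED if constant else float(sps.skew(x, bias=False)),
            "kurtosis": UNDEFINED if constant
            else float(sps.kurtosis(x, fisher=True, bias=False)),
        })
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# Tukey ladder of powers

LADDER = (-2.0, -1.0, -0.5, 0.0, 1 / 3, 0.5, 1.0, 2.0)


def _ladder_transform(x: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.log(x)
    if lam < 0:
        return -np.power(x, lam)  # negated to keep the transform increasing
    return np.power(x, lam)


def tukey_ladder(x) -> tuple[np.ndarray, float, float]:
    """Pick the ladder power minimizing |sample skewness| of the transform.

    A +1 offset is applied first when min(x) <= 0 so every rung is finite.
    Ties are broken toward the power closest to 1 (identity).  Returns
    ``(transformed, lambda, offset)``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("need >= 5 observations")
    offset = 1.0 if np.min(x) <= 0 else 0.0
    xo = x + offset
    best = None
    for lam in LADDER:
        t = _ladder_transform(xo, lam)
        if not np.all(np.isfinite(t)):
            continue
        s = abs(float(sps.skew(t, bias=False))) if np.ptp(t) > 0 else 0.0
        key = (round(s, 12), abs(lam - 1.0))
        if best is None or key < best[0]:
            best = (key, lam, t)
    _, lam, t = best
    return t, lam, offset


# ---------------------------------------------------------------------------
# correlations

def pearson_matrix(table: pd.DataFrame, variables=None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p (t reference, n-2 df) on complete
    cases per pair.  Zero-variance variables get NaN rows/columns."""
    if variables is None:
        variables = [c for c in table.columns
                     if pd.api.types.is_numeric_dtype(table[c])]
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        xi = table[variables[i]]
        for j in range(i, k):
            xj = table[variables[j]]
            ok = xi.notna() & xj.notna()
            if ok.sum() < 3:
                raise ValueError(
                    f"need >= 3 complete cases for {variables[i]}, {variables[j]}")
            a, b = xi[ok].to_numpy(float), xj[ok].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue  # undefined marker stays NaN
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
            else:
                rr, pp = sps.pearsonr(a, b)
                r[i, j] = r[j, i] = rr
                p[i, j] = p[j, i] = pp
    idx = pd.Index(variables)
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))


# ---------------------------------------------------------------------------
# collinearity

def vif(table: pd.DataFrame, predictors) -> pd.Series:
    """Variance inflation factor 1/(1-R^2_j) per predictor, R^2_j from the
    OLS of predictor j on the others (with intercept).  Exact collinearity
    gives inf rather than an exception."""
    X = table[list(predictors)].dropna().to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(predictors):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        Z = sm.add_constant(others)
        res = sm.OLS(y, Z).fit()
        r2 = res.rsquared
        out[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# regression suite

MODEL_FORMULAS = {
    "simple": ["vaq_preschool_t", "omega2"],
    "full": ["vaq_preschool_t", "omega2", "vaq_preschool_t:omega2"],
    "partial_omega2": ["omega2", "vaq_preschool_t:omega2"],
    "partial_vaq": ["vaq_preschool_t", "vaq_preschool_t:omega2"],
}


@dataclass
class RegressionReport:
    label: str
    terms: pd.DataFrame          # estimate, ci_low, ci_high per term
    adj_r2: float
    resid_se: float
    df_resid: int
    f_stat: float
    f_df: tuple[int, int]
    f_pvalue: float
    q2: float | None = None

    def __str__(self) -> str:
        lines = [f"[{self.label}]"]
        for name, row in self.terms.iterrows():
            lines.append(f"  {name}: {row.estimate:.3f} "
                         f"({row.ci_low:.3f}, {row.ci_high:.3f})")
        lines.append(f"  adjusted R^2 = {self.adj_r2:.3f}")
        lines.append(f"  residual SE = {self.resid_se:.3f} (df = {self.df_resid})")
        lines.append(f"  F({self.f_df[0]}, {self.f_df[1]}) = {self.f_stat:.3f}, "
                     f"p = {self.f_pvalue:.4f}")
        if self.q2 is not None:
            lines.append(f"  LOOCV Q^2 = {self.q2:.3f}")
        return "\n".join(lines)


def _design(table: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        else:
            cols.append(table[t].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def fit_ols(table: pd.DataFrame, outcome: str, terms: list[str],
            label: str = "model", with_q2: bool = False) -> RegressionReport:
    """OLS with intercept; t-based 95% CIs, adjusted R^2, residual SE and the
    overall F test.  Raises on rank deficiency, naming the aliased term."""
    data = table[[outcome] + sorted({c for t in terms for c in t.split(":")})]
    data = data.dropna()
    y = data[outcome].to_numpy(float)
    X = _design(data, terms)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("too few complete cases")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # identify an aliased column by testing rank growth
        rank = 1
        for j, t in enumerate(terms):
            newrank = np.linalg.matrix_rank(Xc[:, :j + 2])
            if newrank == rank:
                raise ValueError(f"rank-deficient design: term {t!r} is aliased")
            rank = newrank
        raise ValueError("rank-deficient design")
    res = sm.OLS(y, Xc).fit()
    ci = res.conf_int(alpha=0.05)
    names = ["const"] + terms
    report_terms = pd.DataFrame(
        {"estimate": res.params, "ci_low": ci[:, 0], "ci_high": ci[:, 1]},
        index=names)
    report = RegressionReport(
        label=label, terms=report_terms, adj_r2=float(res.rsquared_adj),
        resid_se=float(np.sqrt(res.mse_resid)), df_resid=int(res.df_resid),
        f_stat=float(res.fvalue), f_df=(int(res.df_model), int(res.df_resid)),
        f_pvalue=float(res.f_pvalue))
    if with_q2:
        report.q2 = loocv_q2(data, outcome, terms)
    return report


def fit_linear_models(table: pd.DataFrame, outcome: str = "ras_emotion",
                      with_q2: bool = True) -> dict[str, RegressionReport]:
    """The fixed four-model regression suite for one outcome."""
    return {label: fit_ols(table, outcome, terms, label=label, with_q2=with_q2)
            for label, terms in MODEL_FORMULAS.items()}


def loocv_q2(table: pd.DataFrame, outcome: str, terms: list[str]) -> float:
    """Leave-one-out cross-validated prediction score
    Q^2 = 1 - PRESS / total sum of squares, by explicit per-fold refits."""
    data = table[[outcome] + sorted({c for t in terms for c in t.split(":")})]
    data = data.dropna().reset_index(drop=True)
    y = data[outcome].to_numpy(float)
    X = sm.add_constant(_design(data, terms), has_constant="add")
    n, p = X.shape
    if n < p + 2:
        raise ValueError("too few observations for LOOCV")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        if np.linalg.matrix_rank(Xt) < p:
            raise ValueError(f"rank-deficient fold leaving out case {i}")
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        press += (y[i] - X[i] @ beta) ** 2
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


# ---------------------------------------------------------------------------
# simple-model coefficient recovery study

SIMPLE_MODEL_TRUTH = {
    "intercept": 15.072,
    "vaq_preschool_t": -0.891,
    "omega2": -0.282,
    "resid_sd": 2.281,
}

PREDICTOR_MOMENTS = {
    "vaq_preschool_t": (1.31, 0.98),
    "omega2": (-5.46, 2.82),
}


def simple_model_recovery_study(n_cohorts: int = 500, n: int = 36,
                                seed: int = 0,
                                truth: dict | None = None,
                                moments: dict | None = None) -> dict:
    """Repeatedly simulate cohorts from the simple regression model and
    refit it, returning the mean refitted coefficients and residual SE.

    Per cohort the two predictors are independent Gaussians with the
    configured moments; the outcome is the linear predictor plus Gaussian
    noise with the configured residual SD.
    """
    truth = dict(SIMPLE_MODEL_TRUTH if truth is None else truth)
    moments = dict(PREDICTOR_MOMENTS if moments is None else moments)
    rng = np.random.default_rng(seed)
    sums = {"intercept": 0.0, "vaq_preschool_t": 0.0, "omega2": 0.0,
            "resid_se": 0.0}
    for _ in range(n_cohorts):
        vaqt = rng.normal(*moments["vaq_preschool_t"], size=n)
        om2 = rng.normal(*moments["omega2"], size=n)
        y = (truth["intercept"] + truth["vaq_preschool_t"] * vaqt
             + truth["omega2"] * om2 + rng.normal(0.0, truth["resid_sd"], n))
        table = pd.DataFrame({"ras_emotion": y, "vaq_preschool_t": vaqt,
                              "omega2": om2})
        rep = fit_ols(table, "ras_emotion", ["vaq_preschool_t", "omega2"],
                      label="simple")
        sums["intercept"] += rep.terms.loc["const", "estimate"]
        sums["vaq_preschool_t"] += rep.terms.loc["vaq_preschool_t", "estimate"]
        sums["omega2"] += rep.terms.loc["omega2", "estimate"]
        sums["resid_se"] += rep.resid_se
    return {k: v / n_cohorts for k, v in sums.items()}


# ---------------------------------------------------------------------------
# mixed graphical model

@dataclass
class GraphEstimate:
    nodes: list[str]
    node_types: dict[str, str]       # "continuous" | "binary"
    adjacency: pd.DataFrame          # signed symmetric weights, zero diagonal
    selected_lambda: dict[str, float]

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1:]:
                w = self.adjacency.loc[a, b]
                if w != 0:
                    out.append((a, b, float(w)))
        return out


def _ebic(loglik: float, k_nonzero: int, n: int, n_cand: int, gamma: float) -> float:
    return -2.0 * loglik + k_nonzero * math.log(n) \
        + 2.0 * gamma * k_nonzero * math.log(max(n_cand, 1))


def _lambda_max_gaussian(X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n)


def _refit_ebic(X: np.ndarray, y: np.ndarray, support: tuple,
                node_type: str, n: int, p: int,
                gamma: float) -> tuple[float, np.ndarray]:
    """Unpenalized ML refit on a candidate support and its EBIC score."""
    b = np.zeros(X.shape[1])
    idx = list(support)
    if node_type == "continuous":
        if idx:
            Xa = np.column_stack([np.ones(n), X[:, idx]])
            beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
            resid = y - Xa @ beta
            b[idx] = beta[1:]
        else:
            resid = y - y.mean()
        sigma2 = max(float(np.mean(resid ** 2)), 1e-12)
        ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    else:
        if idx:
            refit = LogisticRegression(C=1e10, max_iter=5000)
            refit.fit(X[:, idx], y)
            z = refit.decision_function(X[:, idx])
            b[idx] = refit.coef_[0]
        else:
            pbar = min(max(y.mean(), 1e-12), 1 - 1e-12)
            z = np.full(n, math.log(pbar / (1 - pbar)))
        ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    return _ebic(ll, len(idx), n, p, gamma), b


def fit_mixed_graphical_model(table: pd.DataFrame,
                              node_types: dict[str, str],
                              lambda_grid: np.ndarray | None = None,
                              ebic_gamma: float = 0.25,
                              n_lambda: int = 50) -> GraphEstimate:
    """Pairwise mixed graphical model by nodewise L1-penalized regression.

    Continuous nodes are standardized internally and regressed by lasso;
    binary nodes (coded 0/1) by L1-penalized logistic regression.  Each
    node's penalty is chosen by the extended BIC with parameter
    ``ebic_gamma`` over a log-spaced grid from the node's lambda_max down by
    1e-3.  The lasso path proposes candidate supports; the EBIC of each
    support is scored on its unpenalized maximum-likelihood refit (the
    likelihood the criterion is defined for), which avoids the bias of
    scoring shrunken coefficients.  An edge is kept only if both directed
    coefficients are nonzero (AND rule); its weight is the signed mean of
    the two standardized refit coefficients, set to zero if their signs
    conflict.
    """
    nodes = list(node_types)
    if len(nodes) < 3:
        raise ValueError("need >= 3 nodes")
    data = table[nodes].dropna()
    n = len(data)
    Xs = {}
    for v in nodes:
        x = data[v].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"zero-variance node {v!r}")
        if node_types[v] == "continuous":
            Xs[v] = (x - x.mean()) / x.std(ddof=0)
        elif node_types[v] == "binary":
            vals = set(np.unique(x))
            if not vals <= {0.0, 1.0}:
                raise ValueError(f"binary node {v!r} must be coded 0/1")
            Xs[v] = x
        else:
            raise ValueError(f"unknown node type for {v!r}")

    coef = pd.DataFrame(0.0, index=nodes, columns=nodes)  # row: response node
    sel_lambda = {}
    for v in nodes:
        others = [w for w in nodes if w != v]
        X = np.column_stack([Xs[w] for w in others])
        y = Xs[v]
        p = X.shape[1]
        if node_types[v] == "continuous":
            lmax = max(_lambda_max_gaussian(X, y), 1e-10)
        else:
            pbar = y.mean()
            lmax = max(float(np.max(np.abs(X.T @ (y - pbar))) / n), 1e-10)
        grid = (np.geomspace(lmax, lmax * 1e-3, n_lambda)
                if lambda_grid is None else np.asarray(lambda_grid))
        scored: dict[tuple, tuple] = {}  # support -> (ebic, refit coefs)
        best = None
        for lam in grid:
            if node_types[v] == "continuous":
                model = Lasso(alpha=lam, max_iter=10_000)
                model.fit(X, y)
                support = tuple(np.flatnonzero(model.coef_ != 0))
            else:
                model = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam),
                                           solver="liblinear", max_iter=2000)
                model.fit(X, y)
                support = tuple(np.flatnonzero(model.coef_[0] != 0))
            if support not in scored:
                scored[support] = _refit_ebic(X, y, support,
                                              node_types[v], n, p, ebic_gamma)
            score, b = scored[support]
            if best is None or score < best[0]:
                best = (score, lam, b)
        _, lam, b = best
        sel_lambda[v] = float(lam)
        for w, bw in zip(others, b):
            coef.loc[v, w] = bw

    adj = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for i, a in enumerate(nodes):
        for b_ in nodes[i + 1:]:
            c1, c2 = coef.loc[a, b_], coef.loc[b_, a]
            if c1 != 0 and c2 != 0:
                if np.sign(c1) == np.sign(c2):
                    w = 0.5 * (c1 + c2)
                    adj.loc[a, b_] = adj.loc[b_, a] = w
    return GraphEstimate(nodes=nodes, node_types=dict(node_types),
                         adjacency=adj, selected_lambda=sel_lambda)
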