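"""Multimember linear mixed-effects models fit by REML.

The analysis model for every response metric is::

    Response ~ Condition * Treatment * Testing_time + Site
               + (1 | Individual)  [multimember]  + (1 | Pair)

where an observation from a paired release loads on *both* member birds with
weight 0.5 each (a multiple-membership random effect), and solo observations
load on their single bird with weight 1.  The marginal covariance is

    V = sigma2_resid * I + sigma2_individual * Z1 Z1' + sigma2_pair * Z2 Z2'

and the variance components are estimated by restricted maximum likelihood,
with fixed effects by GLS at the optimum.  Fixed-effect p-values are Wald
tests against the standard normal (no denominator-df correction), matching
the convention of reporting t = estimate / SE with normal reference.

Planned contrasts (simple effects at chosen factor levels) are obtained by
refitting the identical model with releveled factors; the REML log-likelihood
is invariant to releveling, and the releveled coefficient equals the
contrast-vector statistic c'beta / sqrt(c' vcov c) from the original fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_solve

from . import geo as _geo
from .errors import RankDeficiencyError
from .trackio import CONDITIONS, SITES, TESTING_TIMES, TREATMENTS

if _geo._HAVE_NUMBA:
    from numba import njit as _njit

    @_njit(cache=True)
    def _profiled_eval(G, C, A, w, n, p):
        """Compiled core of the profiled REML criterion (q x q algebra)."""
        q = w.size
        M = np.eye(q) + G * np.outer(w, w)
        Lm = np.linalg.cholesky(M)
        logdetW = 0.0
        for i in range(q):
            logdetW += 2.0 * np.log(Lm[i, i])
        Cw = C * w.reshape(-1, 1)
        S = np.linalg.solve(M, Cw)
        full = A - Cw.T @ S
        XtWiX = full[:p, :p].copy()
        XtWiy = full[:p, p].copy()
        ytWiy = full[p, p]
        Lx = np.linalg.cholesky(XtWiX)
        beta = np.linalg.solve(XtWiX, XtWiy)
        rss = ytWiy - beta @ XtWiy
        if rss < 1e-300:
            rss = 1e-300
        sigma2 = rss / (n - p)
        logdetXtWiX = 0.0
        for i in range(p):
            logdetXtWiX += 2.0 * np.log(Lx[i, i])
        ll = -0.5 * (
            (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdetW + logdetXtWiX
        )
        return ll, beta, sigma2, XtWiX

__all__ = [
    "ModelSpec",
    "ModelFit",
    "WaldResult",
    "build_design",
    "fit_reml",
    "reml_loglik",
    "wald_tests",
    "contrast_from_fit",
    "planned_contrast",
    "residual_diagnostics",
    "better_solo_comparison",
]

_FACTORS = {
    "condition": CONDITIONS,
    "treatment": TREATMENTS,
    "testing_time": TESTING_TIMES,
    "site": SITES,
}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed formula: full three-way factorial of condition, treatment and
    testing time, plus an additive site effect; dummy (treatment) coding
    against the given reference levels."""

    response: str = "log_mean_nnd"
    reference_levels: dict = field(
        default_factory=lambda: {
            "condition": "paired",
            "treatment": "forgetting",
            "testing_time": "baseline",
            "site": "A",
        }
    )
    pair_weight: float = 0.5  # multimember weight per member of a paired row

    def relevel(self, **levels: str) -> "ModelSpec":
        refs = dict(self.reference_levels)
        for factor, level in levels.items():
            if factor not in _FACTORS:
                raise ValueError(f"unknown factor {factor!r}")
            if level not in _FACTORS[factor]:
                raise ValueError(f"unknown level {level!r} for factor {factor!r}")
            refs[factor] = level
        return replace(self, reference_levels=refs)


@dataclass
class ModelFit:
    """REML estimates: fixed effects, variance components and diagnostics."""

    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    term_names: list[str]
    sigma2: dict[str, float]
    loglik_reml: float
    n_obs: int
    converged: bool

    def coef(self, term: str) -> float:
        return float(self.beta[self.term_names.index(term)])


@dataclass(frozen=True)
class WaldResult:
    """A single estimate / SE / t / two-sided normal p."""

    term: str
    estimate: float
    se: float

    @property
    def t_value(self) -> float:
        return self.estimate / self.se

    @property
    def p_value(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.t_value)))


def _nonref_level(factor: str, ref: str) -> str:
    levels = _FACTORS[factor]
    others = [l for l in levels if l != ref]
    return others[0]


def build_design(rows: pd.DataFrame, spec: ModelSpec):
    """Build (y, X, Z_individual, Z_pair, term_names, individual/pair ids).

    ``rows`` needs columns: the response, condition, treatment, testing_time,
    site, bird_a, bird_b (None/NaN for solo rows) and pair_id.  Rows with a
    missing response are dropped.  X carries the intercept, the three main
    effects, all two-way and the three-way interaction of condition,
    treatment and testing time, plus site: nine columns.
    """
    df = rows.dropna(subset=[spec.response]).reset_index(drop=True)
    if df.empty:
        raise RankDeficiencyError(f"no rows with non-missing {spec.response}")
    y = df[spec.response].to_numpy(dtype=np.float64)
    n = len(df)

    dummies = {}
    for factor in ("condition", "treatment", "testing_time", "site"):
        ref = spec.reference_levels[factor]
        other = _nonref_level(factor, ref)
        present = set(df[factor].unique())
        if len(present) < 2:
            raise RankDeficiencyError(
                f"factor {factor!r} has a single level {sorted(present)} after subsetting"
            )
        dummies[factor] = (
            (df[factor] == other).to_numpy(dtype=np.float64),
            f"{factor}[{other}]",
        )

    cols = [np.ones(n)]
    names = ["(Intercept)"]
    main = ["condition", "treatment", "testing_time"]
    for f in main:
        cols.append(dummies[f][0])
        names.append(dummies[f][1])
    for f1, f2 in itertools.combinations(main, 2):
        cols.append(dummies[f1][0] * dummies[f2][0])
        names.append(f"{dummies[f1][1]}:{dummies[f2][1]}")
    cols.append(dummies[main[0]][0] * dummies[main[1]][0] * dummies[main[2]][0])
    names.append(":".join(dummies[f][1] for f in main))
    cols.append(dummies["site"][0])
    names.append(dummies["site"][1])
    X = np.column_stack(cols)

    birds = sorted(
        set(df["bird_a"]) | {b for b in df["bird_b"] if isinstance(b, str) and b}
    )
    bird_index = {b: j for j, b in enumerate(birds)}
    Z_ind = np.zeros((n, len(birds)))
    for i, (a, b) in enumerate(zip(df["bird_a"], df["bird_b"])):
        if isinstance(b, str) and b:
            Z_ind[i, bird_index[a]] = spec.pair_weight
            Z_ind[i, bird_index[b]] = spec.pair_weight
        else:
            Z_ind[i, bird_index[a]] = 1.0

    pairs = sorted(set(df["pair_id"]))
    pair_index = {p: j for j, p in enumerate(pairs)}
    Z_pair = np.zeros((n, len(pairs)))
    for i, p in enumerate(df["pair_id"]):
        Z_pair[i, pair_index[p]] = 1.0

    return y, X, Z_ind, Z_pair, names, birds, pairs


def reml_loglik(
    y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray], sigma2s: list[float]
) -> float:
    """REML log-likelihood at explicit variance components.

    ``sigma2s[0]`` is the residual variance; subsequent entries pair with the
    random-effect design matrices in ``Zs``.  Direct dense evaluation, used
    both to report the criterion at the optimum and as the quantity a grid
    oracle can maximise independently.
    """
    n, p = X.shape
    V = sigma2s[0] * np.eye(n)
    for Z, s2 in zip(Zs, sigma2s[1:]):
        if s2 > 0:
            V += s2 * (Z @ Z.T)
    L = np.linalg.cholesky(V)
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    return -0.5 * (
        (n - p) * np.log(2.0 * np.pi) + logdetV + logdetXtViX + quad
    )


class _ProfiledREML:
    """Profiled REML criterion over variance ratios gamma_k = sigma2_k / sigma2.

    The Woodbury identity reduces every evaluation to q x q algebra
    (q = total random-effect levels) on cross-products precomputed once:
    with U = Z D (D = per-column sqrt(gamma)),
    W^-1 = I - U (I + U'U)^-1 U' and X'W^-1 X = X'X - (U'X)'(I + U'U)^-1 U'X.
    """

    def __init__(self, y, X, Zs):
        self.n, self.p = X.shape
        self.block_sizes = [Z.shape[1] for Z in Zs]
        Z = np.concatenate(Zs, axis=1) if Zs else np.zeros((self.n, 0))
        Xy = np.concatenate((X, y[:, None]), axis=1)
        self.G = Z.T @ Z
        self.C = Z.T @ Xy
        self.A = Xy.T @ Xy

    def _weights(self, gammas) -> np.ndarray:
        return np.concatenate(
            [np.full(m, np.sqrt(g)) for m, g in zip(self.block_sizes, gammas)]
        )

    def __call__(self, gammas):
        """Return (loglik, beta, sigma2_resid, XtWiX) at the given ratios."""
        n, p = self.n, self.p
        w = self._weights(gammas)
        q = len(w)
        if _geo._HAVE_NUMBA and q:
            return _profiled_eval(self.G, self.C, self.A, w, n, p)
        if q and np.any(w > 0):
            M = np.eye(q) + self.G * np.outer(w, w)
            Lm = np.linalg.cholesky(M)
            logdetW = 2.0 * np.sum(np.log(np.diag(Lm)))
            Cw = self.C * w[:, None]
            full = self.A - Cw.T @ cho_solve((Lm, True), Cw)
        else:
            logdetW = 0.0
            full = self.A
        XtWiX = full[:p, :p]
        XtWiy = full[:p, p]
        ytWiy = full[p, p]
        Lx = np.linalg.cholesky(XtWiX)
        beta = cho_solve((Lx, True), XtWiy)
        rss = float(ytWiy - beta @ XtWiy)
        sigma2 = max(rss, 1e-300) / (n - p)
        logdetXtWiX = 2.0 * np.sum(np.log(np.diag(Lx)))
        ll = -0.5 * (
            (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdetW + logdetXtWiX
        )
        return ll, beta, sigma2, XtWiX


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    component_names: tuple[str, ...] = ("individual", "pair"),
    tol: float = 1e-10,
    n_starts: int = 3,
    seed: int = 0,
) -> ModelFit:
    """Maximise the REML criterion over the variance components.

    Optimisation runs on the log variance-ratio scale with ``n_starts``
    seeded starting points (multi-start guards against boundary traps);
    ratios below 1e-8 after optimisation are snapped to an exact boundary
    zero.  Non-convergence is flagged on the returned fit, never raised.
    """
    n, p = X.shape
    if n <= p:
        raise RankDeficiencyError(f"n_obs={n} <= rank(X)={p}")
    k = len(Zs)
    profiled = _ProfiledREML(y, X, Zs)

    def neg_ll(log_g):
        g = np.exp(np.clip(log_g, -30.0, 30.0))
        try:
            ll, *_ = profiled(g)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k), np.full(k, -4.0)]
    while len(starts) < n_starts:
        starts.append(rng.uniform(-4.0, 3.0, size=k))
    best = None
    converged = False
    for x0 in starts[:n_starts]:
        res = optimize.minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": tol, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    g = np.exp(np.clip(best.x, -30.0, 30.0))
    g[g < 1e-8] = 0.0  # boundary fit: component at zero, reported not raised
    ll, beta, sigma2, XtWiX = profiled(g)
    vcov = sigma2 * np.linalg.inv(XtWiX)
    se = np.sqrt(np.diag(vcov))
    sigma2s = {"resid": float(sigma2)}
    for name, gi in zip(component_names, g):
        sigma2s[name] = float(gi * sigma2)
    loglik = reml_loglik(y, X, Zs, [sigma2] + [gi * sigma2 for gi in g])
    return ModelFit(
        beta=beta,
        se=se,
        vcov=vcov,
        term_names=[],
        sigma2=sigma2s,
        loglik_reml=float(loglik),
        n_obs=n,
        converged=converged,
    )


def fit_model(rows: pd.DataFrame, spec: ModelSpec, **kwargs) -> ModelFit:
    """Convenience: design + REML fit, with term names attached."""
    y, X, Z_ind, Z_pair, names, _, _ = build_design(rows, spec)
    fit = fit_reml(y, X, [Z_ind, Z_pair], **kwargs)
    fit.term_names = names
    return fit


def wald_tests(fit: ModelFit) -> list[WaldResult]:
    """Per-coefficient Wald tests: t = estimate / SE, two-sided normal p."""
    names = fit.term_names or [f"b{i}" for i in range(len(fit.beta))]
    return [
        WaldResult(term=nm, estimate=float(b), se=float(s))
        for nm, b, s in zip(names, fit.beta, fit.se)
    ]


def contrast_from_fit(fit: ModelFit, c: np.ndarray, term: str = "contrast") -> WaldResult:
    """Wald result for the linear combination c'beta of an existing fit."""
    c = np.asarray(c, dtype=np.float64)
    est = float(c @ fit.beta)
    se = float(np.sqrt(c @ fit.vcov @ c))
    return WaldResult(term=term, estimate=est, se=se)


def planned_contrast(
    rows: pd.DataFrame,
    spec: ModelSpec,
    new_reference_levels: dict[str, str],
    term: str,
    **kwargs,
) -> tuple[WaldResult, ModelFit]:
    """Refit the identical model with releveled factors; report one term.

    Releveling reparameterises the same model, so the REML log-likelihood is
    unchanged and the reported coefficient is the requested simple effect
    (e.g. solo vs paired at memory testing within the forgetting treatment).
    """
    releveled = spec.relevel(**new_reference_levels)
    fit = fit_model(rows, releveled, **kwargs)
    if term not in fit.term_names:
        raise ValueError(f"term {term!r} not in model: {fit.term_names}")
    i = fit.term_names.index(term)
    return WaldResult(term=term, estimate=float(fit.beta[i]), se=float(fit.se[i])), fit


def residual_diagnostics(fit: ModelFit, y, X, Zs):
    """KS normality test and QQ data for the standardised marginal residuals.

    Residuals r = y - X beta are whitened with the Cholesky factor of the
    fitted marginal covariance V, then compared to N(0, 1) with a one-sample
    Kolmogorov-Smirnov test (the estimated-parameter correction is ignored,
    as in common practice).  Returns (ks_statistic, ks_p, qq) where qq is a
    DataFrame of (theoretical, empirical) quantile pairs, sorted.
    """
    n = len(y)
    sigma2s = [fit.sigma2["resid"]] + [
        fit.sigma2[k] for k in fit.sigma2 if k != "resid"
    ]
    V = sigma2s[0] * np.eye(n)
    for Z, s2 in zip(Zs, sigma2s[1:]):
        if s2 > 0:
            V += s2 * (Z @ Z.T)
    L = np.linalg.cholesky(V)
    from scipy.linalg import solve_triangular

    e = solve_triangular(L, y - X @ fit.beta, lower=True)
    ks_stat, ks_p = stats.kstest(e, "norm")
    emp = np.sort(e)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"theoretical": theo, "empirical": emp})
    return float(ks_stat), float(ks_p), qq


def better_solo_comparison(
    rows: pd.DataFrame, metric: str = "mean_nnd_m"
) -> tuple[pd.DataFrame, list[str]]:
    """Reduce the table to pairs vs the *better* solo bird of each pair.

    Within each (pair, site, treatment, testing time) cell, the solo rows of
    the two member birds are matched by their order of release; for each
    matched pair of solo observations the bird with the smaller value of
    ``metric`` is kept.  The selection is metric-specific: the better bird
    may differ between metrics, so the reduced tables for different metrics
    can have different sizes.  Pairs with solo data from only one member are
    excluded and logged.  Paired rows pass through unchanged.
    """
    logs: list[str] = []
    keep_idx: list[int] = []
    df = rows.reset_index(drop=True)
    paired_mask = df["condition"] == "paired"
    keep_idx.extend(df.index[paired_mask])
    solo = df[~paired_mask & df[metric].notna()]
    for (pair, site, treat, tt), grp in solo.groupby(
        ["pair_id", "site", "treatment", "testing_time"], sort=True
    ):
        birds = sorted(grp["bird_a"].unique())
        if len(birds) < 2:
            logs.append(
                f"{pair}/{site}/{treat}/{tt}: only one member tested solo; excluded"
            )
            continue
        seq_a = grp[grp["bird_a"] == birds[0]].sort_values("release_order")
        seq_b = grp[grp["bird_a"] == birds[1]].sort_values("release_order")
        for (ia, ra), (ib, rb) in zip(seq_a.iterrows(), seq_b.iterrows()):
            keep_idx.append(ia if ra[metric] <= rb[metric] else ib)
    out = df.loc[sorted(keep_idx)].reset_index(drop=True)
    return out, logs
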