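"""Linear mixed-effects regression of assemblage metrics on the resource gradient.

The model mirrors the standard repeated-measures design for plot-level
metrics observed over several years: for row i (one plot x guild x year),

    y_i = x_i' beta + u_plot(i) + e_i,
    u_plot ~ N(0, s2_plot),   e_i ~ N(0, s2_guild(i)),

with fixed effects guild (reference ST), year as a factor (reference =
first year), resource (PC1), stand-age axis (PC2), guild x resource and
guild x year interactions.  The residual variance differs between guilds
(the two guilds' metrics have very different spread), and the plot random
intercept absorbs repeated measurement of the same plots.

Fitting maximizes the restricted likelihood (REML) numerically over the
three log-variance parameters; fixed effects come from profiled GLS.  The
random-intercept structure makes the marginal covariance block-diagonal by
plot, so each REML evaluation works on small per-plot blocks.  Effects are
summarized by z = estimate / SE, i.e. the estimate standardized against an
expected mean of zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger("sporocarp")


@dataclass
class ModelSpec:
    """Fixed/random structure of the assemblage-metric regression."""

    response: str
    guild_term: bool = True
    year_term: bool = True
    resource_term: bool = True
    age_term: bool = True
    guild_resource_interaction: bool = True
    guild_year_interaction: bool = True
    three_way_interaction: bool = False  # guild x resource x year, off by default
    random_intercept: bool = True
    heteroscedastic: bool = True  # per-guild residual variance


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the optimizer result."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the aliased columns."""


@dataclass
class RegressionReport:
    """Fitted fixed effects, variance components and fit summary."""

    response: str
    coefficients: pd.DataFrame  # term, estimate, se, z
    variance_components: dict[str, float]
    reml_loglik: float
    adj_r2: float
    n_obs: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def z(self, term: str) -> float:
        row = self.coefficients.set_index("term").loc[term]
        return float(row["z"])


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the fixed effects (reference: guild ST, first year)."""
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["(Intercept)"]
    g = (data["guild"] == "ECM").astype(float).to_numpy() if "guild" in data else None
    years = sorted(data["year"].unique()) if "year" in data else []
    if spec.guild_term:
        if g is None:
            raise ValueError("guild term requested but no guild column")
        cols.append(g)
        names.append("guild[ECM]")
    year_dummies: dict[int, np.ndarray] = {}
    if spec.year_term and len(years) > 1:
        for y in years[1:]:
            year_dummies[y] = (data["year"] == y).astype(float).to_numpy()
            cols.append(year_dummies[y])
            names.append(f"year[{y}]")
    r = data["resource"].to_numpy(float) if "resource" in data else None
    if spec.resource_term:
        cols.append(r)
        names.append("resource")
    if spec.age_term:
        cols.append(data["age_axis"].to_numpy(float))
        names.append("age_axis")
    if spec.guild_resource_interaction and spec.guild_term and spec.resource_term:
        cols.append(g * r)
        names.append("guild[ECM]:resource")
    if spec.guild_year_interaction and spec.guild_term:
        for y, dummy in year_dummies.items():
            cols.append(g * dummy)
            names.append(f"guild[ECM]:year[{y}]")
    if spec.three_way_interaction and spec.guild_term and spec.resource_term:
        for y, dummy in year_dummies.items():
            cols.append(g * r * dummy)
            names.append(f"guild[ECM]:resource:year[{y}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR diagnostics
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        aliased = [names[j] for j in np.argsort(diag)[: X.shape[1] - rank]]
        raise RankDeficiencyError(f"design matrix rank deficient; aliased terms: {aliased}")
    return X, names


def _plot_blocks(data: pd.DataFrame) -> list[np.ndarray]:
    idx = np.arange(len(data))
    return [idx[data["plot_id"].to_numpy() == p] for p in pd.unique(data["plot_id"])]


def fit_mixed(
    data: pd.DataFrame,
    response: str,
    spec: ModelSpec | None = None,
    maxiter: int = 2000,
) -> RegressionReport:
    """Fit the mixed model by REML and report z-values per fixed term.

    ``data`` holds one row per plot x guild x year with columns plot_id,
    guild, year, resource, age_axis and the response.  Rows with a missing
    response (e.g. undefined SES) are dropped with a log line.
    """
    if spec is None:
        spec = ModelSpec(response=response)
    work = data.dropna(subset=[response]).reset_index(drop=True)
    n_dropped = len(data) - len(work)
    if n_dropped:
        logger.info("fit_mixed(%s): dropped %d row(s) with missing response", response, n_dropped)
    if len(work) < 5:
        raise ValueError(f"fit_mixed({response}): too few rows ({len(work)})")
    y = work[response].to_numpy(float)
    X, names = build_design(work, spec)
    n, p = X.shape

    if np.ptp(y) == 0:
        coef = pd.DataFrame({
            "term": names,
            "estimate": [y[0]] + [0.0] * (p - 1),
            "se": np.nan,
            "z": np.nan,
        })
        return RegressionReport(
            response, coef, {}, np.nan, np.nan, n, True,
            flags=["constant_response"],
        )

    blocks = _plot_blocks(work)
    guild_is_ecm = (
        (work["guild"] == "ECM").to_numpy()
        if spec.heteroscedastic and "guild" in work
        else np.zeros(n, dtype=bool)
    )

    def profile(theta: np.ndarray):
        """Profiled REML pieces at variance parameters theta (log scale)."""
        s2_plot = np.exp(theta[0]) if spec.random_intercept else 0.0
        k = 1 if spec.random_intercept else 0
        s2_ecm = np.exp(theta[k])
        s2_st = np.exp(theta[k + 1]) if spec.heteroscedastic else s2_ecm
        resid_var = np.where(guild_is_ecm, s2_ecm, s2_st)
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        logdetV = 0.0
        for b in blocks:
            D = resid_var[b]
            Xb, yb = X[b], y[b]
            if s2_plot == 0.0:
                Vinv_X = Xb / D[:, None]
                Vinv_y = yb / D
                logdetV += np.log(D).sum()
            else:
                # Woodbury for V = s2_plot * 11' + diag(D)
                dinv = 1.0 / D
                denom = 1.0 + s2_plot * dinv.sum()
                logdetV += np.log(D).sum() + np.log(denom)
                correction = s2_plot / denom
                Vinv_X = dinv[:, None] * Xb - np.outer(dinv, dinv @ Xb) * correction
                Vinv_y = dinv * yb - dinv * (dinv @ yb) * correction
            XtViX += Xb.T @ Vinv_X
            XtViy += Xb.T @ Vinv_y
            ytViy += yb @ Vinv_y
        beta = np.linalg.solve(XtViX, XtViy)
        quad = ytViy - beta @ XtViy
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        reml = -0.5 * (logdetV + logdetXtViX + quad)
        return reml, beta, XtViX

    def objective(theta: np.ndarray) -> float:
        try:
            reml, _, _ = profile(theta)
        except np.linalg.LinAlgError:
            return 1e12
        return -reml if np.isfinite(reml) else 1e12

    var_y = float(np.var(y, ddof=1))
    k = 1 if spec.random_intercept else 0
    n_theta = k + (2 if spec.heteroscedastic else 1)
    base = np.log(max(var_y, 1e-12))
    theta0 = np.full(n_theta, base)
    if spec.random_intercept:
        theta0[0] = np.log(max(var_y / 4.0, 1e-12))
    # log-variances bounded well below/above the response variance: keeps the
    # optimizer finite when a component is effectively zero
    bounds = [(base - 30.0, base + 10.0)] * n_theta
    result = minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                      options={"maxiter": maxiter})
    if not result.success:
        result = minimize(
            objective, result.x, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
        )
    if not result.success:
        raise ConvergenceError(
            f"REML optimization did not converge for {response}: {result.message}",
            trace=result,
        )
    result.x = np.clip(result.x, [b[0] for b in bounds], [b[1] for b in bounds])
    theta = result.x
    reml, beta, XtViX = profile(theta)
    cov = np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    coef = pd.DataFrame({"term": names, "estimate": beta, "se": se, "z": z})
    if not np.isfinite(z).all():
        raise ConvergenceError(f"non-finite z-value in {response} fit", trace=result)

    varcomp: dict[str, float] = {}
    if spec.random_intercept:
        varcomp["plot_intercept_var"] = float(np.exp(theta[0]))
    varcomp["residual_var_ECM"] = float(np.exp(theta[k]))
    varcomp["residual_var_ST"] = (
        float(np.exp(theta[k + 1])) if spec.heteroscedastic else float(np.exp(theta[k]))
    )

    fitted = X @ beta
    r = np.corrcoef(fitted, y)[0, 1]
    adj_r2 = 1.0 - (1.0 - r**2) * (n - 1) / max(n - p, 1)
    return RegressionReport(
        response, coef, varcomp, float(reml), float(adj_r2), n, True,
        metadata={
            "adj_r2_definition": (
                "1 - (1-r^2)(n-1)/(n-p), r = corr(fixed-effect fitted, observed)"
            ),
            "optimizer": "Nelder-Mead on log-variance parameters",
        },
    )


def significance_class(ses_values) -> pd.Series:
    """Classify SES values: 'low' (< -2), 'high' (> 2), 'ns' otherwise.

    Undefined (NaN) SES propagates as missing.
    """
    s = pd.Series(ses_values, dtype=float)
    out = pd.Series(pd.NA, index=s.index, dtype="object")
    out[s < -2] = "low"
    out[s > 2] = "high"
    out[(s >= -2) & (s <= 2)] = "ns"
    return out
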