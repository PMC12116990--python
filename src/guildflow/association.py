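"""Guild-metabolite association with a subject random intercept.

For every (guild, analyte) pair, the analyte concentration is regressed on
the guild's arcsine-square-root-transformed relative abundance with a random
intercept per subject:

    y_ij = beta0 + beta1 * AST(a_ij) + u_i + e_ij,
    u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)

fit by maximum likelihood with a one-dimensional profile over the variance
ratio lambda = sigma_u^2 / sigma_e^2 (beta and sigma_e^2 have closed-form
GLS/ML solutions given lambda).  The slope's Wald statistic is referred to a
t distribution with n_subjects - 2 degrees of freedom (the between-within
convention; guild abundance varies mostly between subjects, so the normal
reference is anticonservative at cohort sizes in the tens).
Benjamini-Hochberg runs across all tested pairs.  A negative slope encodes
"reduced guild abundance with increased metabolite concentration".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .stats import benjamini_hochberg
from .tables import AbundanceTable, MetaboliteTable, SampleMetadata, align


def ast_transform(p):
    """Arcsine square-root transform, arcsin(sqrt(p)), for proportions."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


@dataclass
class RandomInterceptFit:
    intercept: float
    slope: float
    var_subject: float
    var_residual: float
    slope_se: float
    log_likelihood: float
    n_obs: int
    n_subjects: int


def _profile_loglik(lam: float, y, X, groups):
    """ML log-likelihood profiled over beta and sigma_e^2 at fixed lambda.

    V_i = I + lam * J for subject i; Sherman-Morrison gives
    V_i^{-1} = I - lam / (1 + lam * n_i) * J and |V_i| = 1 + lam * n_i.
    Returns (loglik, beta, sigma_e^2, XtVinvX).
    """
    n = len(y)
    xtvx = np.zeros((X.shape[1], X.shape[1]))
    xtvy = np.zeros(X.shape[1])
    ytvy = 0.0
    logdet = 0.0
    for idx in groups:
        Xi, yi = X[idx], y[idx]
        ni = len(idx)
        c = lam / (1.0 + lam * ni)
        sx, sy = Xi.sum(axis=0), yi.sum()
        xtvx += Xi.T @ Xi - c * np.outer(sx, sx)
        xtvy += Xi.T @ yi - c * sx * sy
        ytvy += yi @ yi - c * sy * sy
        logdet += np.log1p(lam * ni)
    try:
        beta = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError:
        # x (numerically) constant within every subject at this lambda:
        # fall back to the minimum-norm solution; the likelihood still
        # penalizes such lambda, so the optimizer moves away from it
        beta = np.linalg.pinv(xtvx) @ xtvy
    rss = ytvy - beta @ xtvy  # (y - Xb)' V^{-1} (y - Xb) at the GLS optimum
    rss = max(rss, 1e-300)
    sigma2 = rss / n
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return loglik, beta, sigma2, xtvx


def random_intercept_fit(y, x, subjects) -> RandomInterceptFit:
    """ML fit of y = b0 + b1 x + u_subject + e via profile likelihood.

    The variance ratio is optimized on a log scale (bounded golden-section /
    Brent search); the boundary candidate lambda = 0 (ordinary least
    squares) is always evaluated, so the returned likelihood is never below
    the OLS likelihood.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    subjects = np.asarray(subjects)
    if not (y.shape == x.shape == subjects.shape):
        raise ValueError("y, x, subjects must have equal length")
    if len(y) < 3:
        raise ValueError("need >= 3 observations")
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("need >= 2 subjects")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    X = np.column_stack([np.ones_like(x), x])
    groups = [np.where(subjects == s)[0] for s in uniq]

    def neg(log_lam: float) -> float:
        return -_profile_loglik(np.exp(log_lam), y, X, groups)[0]

    opt = minimize_scalar(neg, bounds=(-15.0, 15.0), method="bounded",
                          options={"xatol": 1e-10})
    candidates = [(0.0, _profile_loglik(0.0, y, X, groups))]
    lam_hat = float(np.exp(opt.x))
    candidates.append((lam_hat, _profile_loglik(lam_hat, y, X, groups)))
    lam, (loglik, beta, sigma2, xtvx) = max(candidates, key=lambda c: c[1][0])
    cov = sigma2 * np.linalg.pinv(xtvx)
    return RandomInterceptFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        var_subject=float(lam * sigma2),
        var_residual=float(sigma2),
        slope_se=float(np.sqrt(cov[1, 1])),
        log_likelihood=float(loglik),
        n_obs=len(y),
        n_subjects=len(uniq),
    )


def associate(
    guild_table: AbundanceTable,
    metabolite_table: MetaboliteTable,
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Random-intercept association of every guild with every analyte.

    Returns one row per (guild, analyte) pair sorted by BH q then |slope|;
    pairs with fewer than 3 shared observations are flagged, not fit.
    """
    from scipy import stats as sps

    guild_table, metadata_g = align(guild_table, metadata)
    shared = [s for s in guild_table.sample_ids if s in set(metabolite_table.sample_ids)]
    if not shared:
        raise ValueError("no samples shared between guild and metabolite tables")
    guild_table = guild_table.select_samples(shared)
    metabolite_table = metabolite_table.select_samples(shared)
    subjects = metadata_g.select(shared).subjects_of(shared)

    rows = []
    for gi, guild in enumerate(guild_table.feature_ids):
        x = ast_transform(np.clip(guild_table.values[gi], 0.0, 1.0))
        for ai, analyte in enumerate(metabolite_table.analyte_ids):
            y = metabolite_table.concentrations[ai]
            row = {
                "guild_id": guild,
                "analyte_id": analyte,
                "n_samples": len(shared),
                "n_subjects": len(np.unique(subjects)),
            }
            if len(shared) < 3 or np.ptp(x) == 0:
                row.update(slope=np.nan, slope_se=np.nan, wald_t=np.nan,
                           p_value=np.nan, flagged=True)
            else:
                fit = random_intercept_fit(y, x, subjects)
                t = fit.slope / fit.slope_se if fit.slope_se > 0 else np.inf
                df = fit.n_subjects - 2
                row.update(
                    slope=fit.slope,
                    slope_se=fit.slope_se,
                    wald_t=t,
                    p_value=float(2.0 * sps.t.sf(abs(t), df)),
                    flagged=False,
                )
            rows.append(row)
    result = pd.DataFrame(rows)
    ok = ~result["p_value"].isna()
    q = np.full(len(result), np.nan)
    if ok.any():
        q[ok.to_numpy()] = benjamini_hochberg(result.loc[ok, "p_value"].to_numpy())
    result["bh_q"] = q
    return result.sort_values(
        ["bh_q", "slope"], key=lambda s: s.abs() if s.name == "slope" else s,
        ascending=[True, False],
    ).reset_index(drop=True)
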