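"""Repeated-measures screening statistics.

The screening cascade applied to every omic layer of a longitudinal cohort:
a repeated-measures one-way ANOVA per feature, Benjamini-Hochberg FDR across
features (screen threshold q <= 0.25), then Friedman + Nemenyi (and
optionally Dunnett-vs-baseline) post-hoc tests on the features that pass.
Two-timepoint comparisons are gated on Shapiro-Wilk normality of the paired
differences: paired t when normal, Wilcoxon signed-rank otherwise.

Also houses the a-priori power analysis for the repeated-measures
within-factors F test (G*Power conventions) and the supplement dose
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, MetaboliteTable, SampleMetadata


# ---------------------------------------------------------------------------
# univariate building blocks


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's AS R94 approximation)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if len(x) > 5000:
        raise ValueError("Shapiro-Wilk approximation valid up to n = 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    w, p = sps.shapiro(x)
    return float(w), float(p)


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    degenerate: bool = False


def compare_two_timepoints(before, after, alpha_normality: float = 0.05) -> ComparisonResult:
    """Paired two-timepoint comparison with a normality gate.

    Shapiro-Wilk on the paired differences decides the branch: paired t when
    p >= alpha_normality, two-sided Wilcoxon signed-rank otherwise (exact
    null distribution for <= 25 nonzero differences, normal approximation
    with continuity correction above; zero differences dropped).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired vectors must have equal length")
    if len(before) < 3:
        raise ValueError("need >= 3 complete pairs")
    d = after - before
    if np.all(d == 0):
        return ComparisonResult("degenerate", 0.0, 1.0, degenerate=True)
    if np.ptp(d) == 0:
        # constant nonzero shift: normality undefined, fall to Wilcoxon
        normal = False
    else:
        normal = shapiro_wilk(d)[1] >= alpha_normality
    if normal:
        stat, p = sps.ttest_rel(after, before)
        return ComparisonResult("paired_t", float(stat), float(p))
    nonzero = d[d != 0]
    method = "exact" if len(nonzero) <= 25 else "approx"
    try:
        stat, p = sps.wilcoxon(
            d, zero_method="wilcox", correction=(method == "approx"), method=method
        )
    except ValueError:
        # exact method refuses ties on some versions; fall back to approx
        stat, p = sps.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return ComparisonResult("wilcoxon", float(stat), float(p))


def friedman_test(block: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square on a subjects x timepoints block (complete-case).

    Mid-ranks for ties, tie-corrected Q, chi-square reference with k-1 df.
    Rows containing missing values are dropped.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] < 3:
        raise ValueError("need a 2-D block with >= 3 timepoints")
    block = block[~np.isnan(block).any(axis=1)]
    if block.shape[0] < 2:
        raise ValueError("need >= 2 complete subjects")
    if np.all(np.ptp(block, axis=1) == 0):
        return 0.0, 1.0  # every subject flat across timepoints
    q, p = sps.friedmanchisquare(*block.T)
    return float(q), float(p)


def nemenyi_posthoc(block: np.ndarray) -> np.ndarray:
    """All-pairs Nemenyi p-values after a Friedman test.

    Standardized mean-rank differences referred to the studentized range
    distribution (q / sqrt(2) convention, k groups, infinite df).  Returns a
    symmetric k x k matrix with unit diagonal.
    """
    block = np.asarray(block, dtype=float)
    block = block[~np.isnan(block).any(axis=1)]
    n, k = block.shape
    if n < 2 or k < 3:
        raise ValueError("need >= 2 complete subjects and >= 3 timepoints")
    ranks = np.apply_along_axis(sps.rankdata, 1, block)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    with np.errstate(invalid="ignore"):
        p = sps.studentized_range.sf(diff / se, k, np.inf)
    p = np.where(np.isnan(p), 1.0, p)
    np.fill_diagonal(p, 1.0)
    return np.clip((p + p.T) / 2.0, 0.0, 1.0)


def dunnett_vs_baseline(
    block: np.ndarray,
    timepoints: list[str],
    baseline: str,
    n_mc: int = 100_000,
    seed: int = 0,
) -> dict[str, float]:
    """Paired many-to-one (Dunnett) comparisons against a baseline timepoint.

    Each non-baseline timepoint is compared to baseline by its paired
    t-statistic; adjusted p-values come from the maximum of an equicorrelated
    (rho = 1/2) multivariate t with n-1 df, integrated by seeded Monte Carlo.
    """
    block = np.asarray(block, dtype=float)
    if baseline not in timepoints:
        raise ValueError(f"baseline {baseline!r} not among timepoints")
    block = block[~np.isnan(block).any(axis=1)]
    n = block.shape[0]
    if n < 3:
        raise ValueError("need >= 3 complete subjects")
    b = timepoints.index(baseline)
    others = [j for j in range(len(timepoints)) if j != b]
    k = len(others)
    t_obs = np.empty(k)
    for m, j in enumerate(others):
        d = block[:, j] - block[:, b]
        sd = d.std(ddof=1)
        t_obs[m] = 0.0 if sd == 0 else d.mean() / (sd / np.sqrt(n))
    rng = np.random.default_rng(seed)
    common = rng.standard_normal((n_mc, 1))
    own = rng.standard_normal((n_mc, k))
    z = np.sqrt(0.5) * common + np.sqrt(0.5) * own  # equicorrelated rho = 1/2
    w = rng.chisquare(n - 1, size=(n_mc, 1)) / (n - 1)
    tmax = np.abs(z / np.sqrt(w)).max(axis=1)
    return {
        timepoints[j]: float((tmax >= abs(t_obs[m])).mean())
        for m, j in enumerate(others)
    }


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up q-values (monotone-enforced adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-feature screening cascade


@dataclass
class ContrastPlan:
    """Baseline timepoint and the label pairs to report post hoc."""

    baseline: str = "0"
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("-5", "0"), ("0", "2"), ("0", "4"), ("0", "10")]
    )

    def __post_init__(self) -> None:
        self.contrasts = [(str(a), str(b)) for a, b in self.contrasts]
        if not self.contrasts:
            raise ValueError("contrast plan is empty")


def rm_oneway_anova(block: np.ndarray) -> tuple[float, float]:
    """Repeated-measures one-way ANOVA (subject as block) on complete cases."""
    block = np.asarray(block, dtype=float)
    block = block[~np.isnan(block).any(axis=1)]
    s, t = block.shape
    if s < 2 or t < 2:
        raise ValueError("need >= 2 complete subjects and >= 2 timepoints")
    grand = block.mean()
    ss_treat = s * ((block.mean(axis=0) - grand) ** 2).sum()
    ss_block = t * ((block.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((block - grand) ** 2).sum()
    ss_err = ss_total - ss_treat - ss_block
    df1, df2 = t - 1, (t - 1) * (s - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        return np.inf if ss_treat > 0 else 0.0, 0.0 if ss_treat > 0 else 1.0
    f = (ss_treat / df1) / ms_err
    return float(f), float(sps.f.sf(f, df1, df2))


def _blocks_by_feature(
    values: np.ndarray,
    sample_ids: list[str],
    metadata: SampleMetadata,
    timepoints: list[str],
):
    """Pivot rows into subject x timepoint blocks (NaN where a sample is absent)."""
    subjects = metadata.subjects_of(sample_ids)
    tps = metadata.timepoints_of(sample_ids)
    subj_levels = list(dict.fromkeys(subjects))
    si = np.array([subj_levels.index(s) for s in subjects])
    ti = np.array([timepoints.index(t) for t in tps])
    blocks = np.full((values.shape[0], len(subj_levels), len(timepoints)), np.nan)
    blocks[:, si, ti] = values
    return blocks


def screen_features(
    table: AbundanceTable | MetaboliteTable,
    metadata: SampleMetadata,
    plan: ContrastPlan | None = None,
    q_threshold: float = 0.25,
    posthoc: str = "nemenyi",
    blocked_anova: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen every feature for a timepoint effect; post-hoc the survivors.

    Per feature: repeated-measures one-way ANOVA p (or an unblocked one-way
    ANOVA when ``blocked_anova=False``), BH q across features, then Friedman
    + Nemenyi (and/or Dunnett vs baseline) for features with q <= threshold.
    Features with fewer than 2 complete subjects are flagged, not dropped.
    """
    plan = plan or ContrastPlan()
    if posthoc not in ("nemenyi", "dunnett", "both"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    if isinstance(table, MetaboliteTable):
        feature_ids, values, sample_ids = (
            table.analyte_ids, table.concentrations, table.sample_ids,
        )
    else:
        feature_ids, values, sample_ids = table.feature_ids, table.values, table.sample_ids
    timepoints = [t for t in metadata.timepoints if t in set(metadata.timepoints_of(sample_ids))]
    for a, b in plan.contrasts:
        for lab in (a, b):
            if lab not in timepoints:
                raise ValueError(f"contrast timepoint {lab!r} not present in data")
    blocks = _blocks_by_feature(values, list(sample_ids), metadata, timepoints)

    rows = []
    for i, fid in enumerate(feature_ids):
        block = blocks[i]
        complete = block[~np.isnan(block).any(axis=1)]
        row: dict = {"feature_id": fid, "n_complete": int(complete.shape[0])}
        if complete.shape[0] < 2:
            row.update(screen_F=np.nan, screen_p=np.nan, insufficient=True)
        else:
            if blocked_anova:
                f, p = rm_oneway_anova(complete)
            else:
                f, p = sps.f_oneway(*complete.T)
            row.update(screen_F=float(f), screen_p=float(p), insufficient=False)
        rows.append(row)
    result = pd.DataFrame(rows)

    ok = ~result["screen_p"].isna()
    q = np.full(len(result), np.nan)
    if ok.any():
        q[ok.to_numpy()] = benjamini_hochberg(result.loc[ok, "screen_p"].to_numpy())
    result["bh_q"] = q
    result["selected"] = result["bh_q"] <= q_threshold

    nemenyi_cols = {c: np.full(len(result), np.nan) for c in plan.contrasts}
    dunnett_cols = {
        t: np.full(len(result), np.nan) for t in timepoints if t != plan.baseline
    }
    friedman_q = np.full(len(result), np.nan)
    friedman_p = np.full(len(result), np.nan)
    for i in np.where(result["selected"].to_numpy())[0]:
        block = blocks[i]
        complete = block[~np.isnan(block).any(axis=1)]
        fr_q, fr_p = friedman_test(complete)
        friedman_q[i], friedman_p[i] = fr_q, fr_p
        if posthoc in ("nemenyi", "both"):
            pmat = nemenyi_posthoc(complete)
            for (a, b), col in nemenyi_cols.items():
                col[i] = pmat[timepoints.index(a), timepoints.index(b)]
        if posthoc in ("dunnett", "both"):
            padj = dunnett_vs_baseline(complete, timepoints, plan.baseline, seed=seed)
            for t, col in dunnett_cols.items():
                col[i] = padj[t]
    result["friedman_Q"] = friedman_q
    result["friedman_p"] = friedman_p
    if posthoc in ("nemenyi", "both"):
        for (a, b), col in nemenyi_cols.items():
            result[f"posthoc_p[{a} vs {b}]"] = col
            result[f"sig[{a} vs {b}]"] = col < 0.05
    if posthoc in ("dunnett", "both"):
        for t, col in dunnett_cols.items():
            result[f"dunnett_p[{t} vs {plan.baseline}]"] = col
    return result


# ---------------------------------------------------------------------------
# power analysis and dose arithmetic


@dataclass
class PowerSpec:
    """Repeated-measures within-factors F-test specification (G*Power style)."""

    effect_size_f: float = 0.3
    alpha: float = 0.05
    target_power: float = 0.85
    n_groups: int = 1
    n_measurements: int = 4
    corr_among_rm: float = 0.5
    nonsphericity: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_size_f <= 0:
            raise ValueError("effect_size_f must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.n_measurements < 2:
            raise ValueError("need >= 2 measurements")
        if not 0 <= self.corr_among_rm < 1:
            raise ValueError("corr_among_rm must be in [0, 1)")
        if not 0 < self.nonsphericity <= 1:
            raise ValueError("nonsphericity must be in (0, 1]")


def rm_anova_power(spec: PowerSpec, n: int) -> float:
    """Power of the within-factors repeated-measures F test at sample size n.

    Noncentrality lambda = f^2 * n * m * eps / (1 - rho), numerator df
    (m - 1) * eps, denominator df (n - 1) * (m - 1) * eps; power is the
    noncentral-F mass beyond the central-F critical value.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    f2 = spec.effect_size_f**2
    m, eps, rho = spec.n_measurements, spec.nonsphericity, spec.corr_among_rm
    lam = f2 * n * m * eps / (1.0 - rho)
    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    crit = sps.f.isf(spec.alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def required_n(spec: PowerSpec, n_max: int = 10_000) -> tuple[int, float]:
    """Smallest n whose power reaches the target, with the achieved power."""
    for n in range(2, n_max + 1):
        power = rm_anova_power(spec, n)
        if power >= spec.target_power:
            return n, power
    raise ValueError(f"target power not reached by n = {n_max}")


def pac_dose(
    dose_mass_g: float,
    doses_per_day: int,
    gp_fraction: float,
    pac_fraction: float,
) -> tuple[float, float]:
    """Daily grape-polyphenol and proanthocyanidin mass from the dosing scheme.

    gp = dose_mass * doses_per_day * gp_fraction;  pac = gp * pac_fraction.
    """
    if dose_mass_g < 0:
        raise ValueError("dose mass must be >= 0")
    if doses_per_day < 0:
        raise ValueError("doses_per_day must be >= 0")
    for name, frac in (("gp_fraction", gp_fraction), ("pac_fraction", pac_fraction)):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    gp = dose_mass_g * doses_per_day * gp_fraction
    return gp, gp * pac_fraction
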