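"""Sample-level distances, PCoA, covariate-adjusted PCoA, and stratified PERMANOVA.

Community profiles are compared by Bray-Curtis (presence + abundance) or
Jaccard (presence only) dissimilarity; protein/metabolite profiles by
Euclidean distance on per-feature z-scores.  PCoA eigendecomposes the
Gower-centered squared-distance kernel; the covariate-adjusted variant
(aPCoA) projects the covariate's indicator space out of the kernel first, so
ordination shows the variation left over after removing, e.g., inter-subject
differences — the dominant axis in longitudinal gut microbiome data, where
samples otherwise cluster by person rather than by treatment.

Significance of timepoint differences uses PERMANOVA with permutations
restricted to within-subject shuffles (each subject's samples trade labels
only among themselves), which preserves the repeated-measures structure
under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .guilds import DistanceMatrix, PermanovaResult, permanova
from .tables import AbundanceTable, MetaboliteTable, SampleMetadata, TableError

logger = logging.getLogger(__name__)

EIG_TOL = 1e-10


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes, axes by non-increasing eigenvalue
    eigenvalues: np.ndarray  # positive eigenvalues only
    negative_eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    adjustment: str = "none"


def sample_distance(table, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise sample distances under bray_curtis, jaccard, or euclidean_z."""
    if isinstance(table, MetaboliteTable):
        values, sample_ids = table.concentrations, table.sample_ids
        relative = False
    else:
        values, sample_ids = table.values, table.sample_ids
        relative = table.mode == "relative"
    X = values.T  # samples x features
    if metric in ("bray_curtis", "jaccard") and not relative:
        raise TableError(f"{metric} requires a relative abundance table")
    if metric == "bray_curtis":
        totals = X.sum(axis=1)
        if (totals == 0).any():
            logger.warning(
                "bray_curtis: %d all-zero sample(s); their mutual distance set to 0",
                int((totals == 0).sum()),
            )
        d = squareform(pdist(X, metric="braycurtis"))
        d = np.nan_to_num(d, nan=0.0)  # all-zero vs all-zero
    elif metric == "jaccard":
        d = squareform(pdist(X > 0, metric="jaccard"))
    elif metric == "euclidean_z":
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            logger.warning(
                "euclidean_z: dropped %d zero-variance feature(s)", int((~keep).sum())
            )
        if not keep.any():
            raise TableError("all features have zero variance")
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        d = squareform(pdist(Z, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(sample_ids), d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    c = np.eye(n) - np.ones((n, n)) / n
    return c @ a @ c


def _eigen_result(
    g: np.ndarray, sample_ids: list[str], adjustment: str
) -> OrdinationResult:
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > EIG_TOL
    neg = eigval < -EIG_TOL
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords -= coords.mean(axis=0)  # numerically exact zero column means
    total = eigval[pos].sum()
    prop = eigval[pos] / total if total > 0 else eigval[pos]
    return OrdinationResult(
        list(sample_ids), coords, eigval[pos], eigval[neg], prop, adjustment
    )


def pcoa(D: DistanceMatrix) -> OrdinationResult:
    """Classical principal coordinates analysis (Torgerson scaling).

    Axes with negative eigenvalues (non-Euclidean distances) are reported
    but discarded; no Lingoes/Cailliez correction is applied.
    """
    if D.n < 3:
        raise ValueError("need >= 3 samples")
    return _eigen_result(_gower_center(D.values), D.item_ids, "none")


def adjusted_pcoa(
    D: DistanceMatrix,
    metadata: SampleMetadata,
    covariate: str = "subject_id",
) -> OrdinationResult:
    """PCoA after projecting out a categorical covariate (aPCoA).

    The Gower-centered kernel G is replaced by (I - H) G (I - H), where H
    projects onto the covariate's indicator column space; the resulting
    coordinates are orthogonal to every covariate contrast.
    """
    if D.n < 3:
        raise ValueError("need >= 3 samples")
    if covariate in (None, "none", "intercept"):
        return pcoa(D)
    if covariate not in metadata.frame.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    frame = metadata.frame
    levels = pd.Series(
        frame[covariate].to_numpy(), index=frame["sample_id"]
    ).loc[D.item_ids]
    uniq = list(dict.fromkeys(levels))
    if len(uniq) >= D.n:
        raise ValueError("covariate has as many levels as samples; nothing remains")
    X = np.equal.outer(levels.to_numpy(), np.array(uniq)).astype(float)
    q, _ = np.linalg.qr(X)
    h = q @ q.T
    ih = np.eye(D.n) - h
    g = ih @ _gower_center(D.values) @ ih
    res = _eigen_result(g, D.item_ids, f"covariate:{covariate}")
    return res


def stratified_permanova(
    D: DistanceMatrix,
    metadata: SampleMetadata,
    factor: str = "timepoint",
    strata: str = "subject_id",
    levels: tuple[str, str] | None = None,
    n_permutations: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """PERMANOVA on a factor with permutations restricted within strata.

    ``levels`` restricts to a pairwise contrast (e.g. day 0 vs day 10) on
    the subset of samples at those two levels; subjects contributing fewer
    than 2 samples to the contrast are dropped with a warning.
    """
    df = metadata.frame.set_index("sample_id").loc[D.item_ids].reset_index()
    df[factor] = df[factor].astype(str)
    if levels is not None:
        levels = tuple(str(x) for x in levels)
        df = df[df[factor].isin(levels)]
    counts = df.groupby(strata)[factor].count()
    keep_strata = counts[counts >= 2].index
    dropped = len(counts) - len(keep_strata)
    if dropped:
        logger.warning(
            "stratified_permanova: dropped %d stratum(a) with a single sample", dropped
        )
    df = df[df[strata].isin(keep_strata)]
    if df.empty or df[factor].nunique() < 2:
        raise ValueError("no testable samples remain for the contrast")
    pos = {s: i for i, s in enumerate(D.item_ids)}
    idx = np.array([pos[s] for s in df["sample_id"]])
    return permanova(
        D.submatrix(idx),
        df[factor].to_numpy(),
        n_permutations=n_permutations,
        seed=seed,
        strata=df[strata].to_numpy(),
        exhaustive=exhaustive,
    )


def pairwise_day_permanova(
    D: DistanceMatrix,
    metadata: SampleMetadata,
    baseline: str = "0",
    n_permutations: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Baseline-vs-day stratified PERMANOVA for every non-baseline timepoint.

    Raw p per pair (no correction across day pairs); mirrors reporting one
    row per day contrast.
    """
    rows = []
    for i, tp in enumerate(t for t in metadata.timepoints if t != baseline):
        res = stratified_permanova(
            D, metadata, levels=(baseline, tp),
            n_permutations=n_permutations, seed=seed + i,
        )
        rows.append(
            {
                "contrast": f"{baseline} vs {tp}",
                "pseudo_F": res.pseudo_F,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        )
    return pd.DataFrame(rows)


def ordination_frame(res: OrdinationResult, n_axes: int = 2) -> pd.DataFrame:
    """Coordinates of the leading axes as a tidy frame (for TSV output)."""
    k = min(n_axes, res.coordinates.shape[1])
    data = {"sample_id": res.sample_ids}
    for j in range(k):
        data[f"PCo{j + 1}"] = res.coordinates[:, j]
    return pd.DataFrame(data)
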