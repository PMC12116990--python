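"""Co-abundance guild inference.

The core procedure: keep prevalent features, compute the repeated-measures
(within-subject) correlation between every feature pair, convert to a
correlation distance (1 - r), build a Ward tree over features, then descend
the tree from the root running a permutational MANOVA at every internal node
— the two child clades are the groups, the correlation distance the metric —
and stop splitting where the clades are not significantly different.  The
resulting tree cut is the guild partition.

Within-subject correlation (Bland & Altman): deviations from each subject's
own mean are correlated, so a feature pair counts as co-abundant when it
co-varies *within* individuals over time, not merely because both track the
large, stable between-person differences in community composition::

    r = sum_it (x_it - xbar_i)(y_it - ybar_i)
        / sqrt( sum (x_it - xbar_i)^2 * sum (y_it - ybar_i)^2 )

PERMANOVA here follows the standard pseudo-F on a distance matrix with the
(1 + b) / (1 + m) permutation p-value, optionally with permutations
restricted to strata, and an exhaustive mode that enumerates every distinct
relabeling (used for small problems and for oracle checks).
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import to_tree

from .tables import AbundanceTable, SampleMetadata, TableError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class FilterParams:
    """Prevalence threshold: fraction of samples with strictly positive abundance."""

    min_prevalence: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.min_prevalence <= 1:
            raise ValueError("min_prevalence must be in (0, 1]")


@dataclass
class FilterReport:
    n_total: int
    n_kept: int
    abundance_share: float  # kept features' share of summed abundance


@dataclass
class DistanceMatrix:
    item_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square over item_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.item_ids)

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        return self.values[np.ix_(idx, idx)]


@dataclass
class LinkageTree:
    """Ward merge tree in scipy linkage format (heights are Ward.D2 distances)."""

    item_ids: list[str]
    linkage: np.ndarray
    variant: str = "ward.D2"

    def __post_init__(self) -> None:
        n = len(self.item_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows")


@dataclass
class GuildPartition:
    """feature_id -> guild label (integers numbered in tree-traversal order)."""

    assignments: dict[str, int]

    @property
    def n_guilds(self) -> int:
        return len(set(self.assignments.values()))

    def labels_for(self, item_ids: list[str]) -> np.ndarray:
        return np.array([self.assignments[i] for i in item_ids])

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for item, g in self.assignments.items():
            out.setdefault(g, []).append(item)
        return out


@dataclass
class CutParams:
    alpha: float = 0.001
    n_permutations: int = 9999
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# prevalence filter


def filter_prevalent(table: AbundanceTable, params: FilterParams | None = None):
    """Keep features present (> 0) in at least ceil(min_prevalence * n) samples."""
    params = params or FilterParams()
    if table.mode != "relative":
        raise TableError("prevalence filter expects a relative table")
    need = math.ceil(params.min_prevalence * table.n_samples)
    present = (table.values > 0).sum(axis=1)
    keep = present >= need
    if not keep.any():
        raise TableError("no features pass the prevalence filter")
    total = table.values.sum()
    share = float(table.values[keep].sum() / total) if total > 0 else 0.0
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    report = FilterReport(table.n_features, int(keep.sum()), share)
    logger.info(
        "prevalence filter: kept %d/%d features holding %.4f of abundance",
        report.n_kept, report.n_total, report.abundance_share,
    )
    return table.select_features(kept_ids), report


# ---------------------------------------------------------------------------
# repeated-measures correlation


def _center_within_subjects(x: np.ndarray, subjects: np.ndarray) -> np.ndarray:
    """Subtract each subject's own mean (x may be 1-D or features-x-samples)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out = np.empty_like(x)
    for s in np.unique(subjects):
        cols = subjects == s
        out[:, cols] = x[:, cols] - x[:, cols].mean(axis=1, keepdims=True)
    return out


class UndefinedCorrelationError(ValueError):
    """A variable has zero within-subject variance everywhere."""


def repeated_measures_correlation(x, y, subjects) -> float:
    """Within-subject correlation of two per-sample vectors.

    Subjects with a single sample contribute nothing (their deviation is 0);
    at least 2 subjects with >= 2 samples each are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    if not (x.shape == y.shape == subjects.shape):
        raise ValueError("x, y, subjects must have equal length")
    counts = np.unique(subjects, return_counts=True)[1]
    if (counts >= 2).sum() < 2 and len(counts) > 1:
        raise ValueError("need >= 2 subjects with >= 2 samples each")
    xc = _center_within_subjects(x, subjects)[0]
    yc = _center_within_subjects(y, subjects)[0]
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError(
            "zero within-subject variance; correlation undefined"
        )
    return float(np.clip((xc @ yc) / np.sqrt(sx * sy), -1.0, 1.0))


def correlation_distance_matrix(
    table: AbundanceTable,
    metadata: SampleMetadata,
    method: str = "within_subject",
) -> DistanceMatrix:
    """All-pairs correlation distance D = 1 - r between features.

    ``method="within_subject"`` (default) uses the repeated-measures
    correlation; ``"pearson"`` uses the plain correlation across all samples.
    Features with zero (within-subject) variance get r = 0 against everything
    (distance 1), with a logged warning, so the matrix stays complete.
    """
    subjects = metadata.subjects_of(table.sample_ids)
    if method == "within_subject":
        centered = _center_within_subjects(table.values, subjects)
    elif method == "pearson":
        centered = table.values - table.values.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown method {method!r}")
    norms = np.sqrt((centered**2).sum(axis=1))
    degenerate = norms == 0
    if degenerate.any():
        logger.warning(
            "correlation_distance_matrix: %d feature(s) with zero variance; "
            "their correlations set to 0 (distance 1)",
            int(degenerate.sum()),
        )
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe[:, None]
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.feature_ids), d)


# ---------------------------------------------------------------------------
# Ward tree (Ward.D2: Lance-Williams on squared distances)


def ward_tree(D: DistanceMatrix) -> LinkageTree:
    """Agglomerative Ward tree over the distance matrix.

    Lance-Williams update on squared distances (the Ward.D2 convention, the
    one R's ``hclust(method="ward.D2")`` and scipy's ``linkage(..., "ward")``
    implement); merge heights are the square roots of the merged squared
    distances.  Ties in the merge choice are broken by the smallest
    (row, column) index pair, making the tree deterministic.
    """
    n = D.n
    if n < 2:
        raise ValueError("need at least 2 items")
    d2 = D.values.astype(float) ** 2
    np.fill_diagonal(d2, np.inf)
    active = list(range(n))  # positions into d2
    node_id = list(range(n))  # scipy node ids
    sizes = np.ones(n)
    Z = np.zeros((n - 1, 4))
    # grow d2 in place: rows/cols for new clusters appended
    d2 = np.pad(d2, ((0, n - 1), (0, n - 1)), constant_values=np.inf)
    sizes = np.concatenate([sizes, np.zeros(n - 1)])
    for step in range(n - 1):
        sub = d2[np.ix_(active, active)]
        flat = np.argmin(sub)  # first occurrence = smallest (row, col) pair
        ai, aj = divmod(int(flat), len(active))
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        hi, hj = node_id[ai], node_id[aj]
        new = n + step
        ni, nj = sizes[i], sizes[j]
        Z[step] = (min(hi, hj), max(hi, hj), np.sqrt(d2[i, j]), ni + nj)
        # Lance-Williams (Ward) on squared distances
        rest = [k for k in active if k not in (i, j)]
        if rest:
            rest = np.array(rest)
            nk = sizes[rest]
            upd = (
                (ni + nk) * d2[i, rest]
                + (nj + nk) * d2[j, rest]
                - nk * d2[i, j]
            ) / (ni + nj + nk)
            d2[new, rest] = upd
            d2[rest, new] = upd
        sizes[new] = ni + nj
        keep = [(p, nid) for p, nid in zip(active, node_id) if p not in (i, j)]
        active = [p for p, _ in keep] + [new]
        node_id = [nid for _, nid in keep] + [new]
    return LinkageTree(list(D.item_ids), Z)


# ---------------------------------------------------------------------------
# PERMANOVA


def _ss_terms(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    N = len(labels)
    ss_total = d2.sum() / (2.0 * N)
    ss_within = 0.0
    for g in groups:
        mask = (labels == g).astype(float)
        n_g = mask.sum()
        ss_within += (mask @ d2 @ mask) / (2.0 * n_g)
    return ss_total, ss_within


def _pseudo_f(ss_total, ss_within, N, a):
    denom = ss_within / (N - a)
    if denom == 0.0:
        return np.inf
    return ((ss_total - ss_within) / (a - 1)) / denom


def _perm_f_batch(d2: np.ndarray, perm_labels: np.ndarray, groups, ss_total, N, a):
    """Pseudo-F for a batch of label vectors (P x N), vectorized."""
    ss_w = np.zeros(perm_labels.shape[0])
    for g in groups:
        M = (perm_labels == g).astype(float)
        n_g = M[0].sum()  # group sizes invariant under permutation
        ss_w += np.einsum("pi,ij,pj->p", M, d2, M) / (2.0 * n_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((ss_total - ss_w) / (a - 1)) / (ss_w / (N - a))
    f[ss_w == 0.0] = np.inf
    return f


def _enumerate_relabelings(labels: np.ndarray, strata: np.ndarray | None):
    """All distinct label arrangements (within strata if given), incl. identity."""
    if strata is None:
        seen = set()
        for perm in itertools.permutations(labels.tolist()):
            if perm not in seen:
                seen.add(perm)
                yield np.array(perm, dtype=labels.dtype)
    else:
        idx_by_stratum = [np.where(strata == s)[0] for s in np.unique(strata)]
        per_stratum = []
        for idx in idx_by_stratum:
            opts = sorted({p for p in itertools.permutations(labels[idx].tolist())})
            per_stratum.append([(idx, np.array(p, dtype=labels.dtype)) for p in opts])
        for combo in itertools.product(*per_stratum):
            out = labels.copy()
            for idx, vals in combo:
                out[idx] = vals
            yield out


def permanova(
    D: DistanceMatrix | np.ndarray,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
    strata=None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix.

    ``strata`` restricts permutations to shuffle labels only within each
    stratum (e.g. within each subject).  ``exhaustive=True`` enumerates every
    distinct relabeling instead of sampling; the reported p is then
    #{F_perm >= F_obs} / #relabelings (the identity counts itself, so this is
    the (1 + b) / (1 + m) estimator over the full permutation group).
    """
    values = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    N = len(labels)
    if values.shape != (N, N):
        raise ValueError("labels length must match distance matrix size")
    if N < 3:
        raise ValueError("need at least 3 items")
    groups, counts = np.unique(labels, return_counts=True)
    a = len(groups)
    if a < 2:
        raise ValueError("need at least 2 groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    if strata is not None:
        strata = np.asarray(strata)
        if strata.shape != labels.shape:
            raise ValueError("strata length must match labels")

    d2 = values**2
    ss_total, ss_within = _ss_terms(d2, labels, groups)
    f_obs = _pseudo_f(ss_total, ss_within, N, a)

    if exhaustive:
        count = 0
        hits = 0
        for lab in _enumerate_relabelings(labels, strata):
            stt, ssw = _ss_terms(d2, lab, groups)
            f = _pseudo_f(ss_total, ssw, N, a)
            count += 1
            if f >= f_obs - 1e-12:
                hits += 1
            if count > 1_000_000:
                raise ValueError("exhaustive enumeration too large")
        return PermanovaResult(float(f_obs), hits / count, count - 1)

    rng = np.random.default_rng(seed)
    P = int(n_permutations)
    perm = np.empty((P, N), dtype=labels.dtype)
    if strata is None:
        for p in range(P):
            perm[p] = labels[rng.permutation(N)]
    else:
        idx_by_stratum = [np.where(strata == s)[0] for s in np.unique(strata)]
        for p in range(P):
            row = labels.copy()
            for idx in idx_by_stratum:
                row[idx] = row[idx][rng.permutation(len(idx))]
            perm[p] = row
    f_perm = _perm_f_batch(d2, perm, groups, ss_total, N, a)
    b = int((f_perm >= f_obs - 1e-12).sum())
    return PermanovaResult(float(f_obs), (1 + b) / (1 + P), P)


# ---------------------------------------------------------------------------
# sequential tree cut


def _node_seed(seed: int, node_id: int) -> int:
    h = hashlib.sha256(f"{seed}:{node_id}".encode()).digest()
    return int.from_bytes(h[:4], "little")


def cut_tree_to_guilds(
    tree: LinkageTree,
    D: DistanceMatrix,
    params: CutParams | None = None,
) -> GuildPartition:
    """Descend the Ward tree, testing each split by PERMANOVA on D.

    At every internal node with >= 3 members the two child clades are tested;
    a significant difference (p <= alpha) recurses into both children,
    otherwise the node's members form one guild.  Nodes too small to test
    stop as guilds; single leaves reached by recursion become singleton
    guilds.  Each node draws its permutations from an RNG keyed on
    (seed, node id), so results do not depend on traversal order.  Guilds are
    numbered 1..K in pre-order (left-to-right across the tree).
    """
    params = params or CutParams()
    if tree.item_ids != D.item_ids:
        raise ValueError("tree and distance matrix cover different items")
    root = to_tree(tree.linkage)
    assignments: dict[str, int] = {}
    next_label = [0]

    def assign(node) -> None:
        next_label[0] += 1
        for leaf in node.pre_order(lambda x: x.id):
            assignments[tree.item_ids[leaf]] = next_label[0]

    def descend(node) -> None:
        if node.is_leaf():
            assign(node)
            return
        leaves_l = node.left.pre_order(lambda x: x.id)
        leaves_r = node.right.pre_order(lambda x: x.id)
        members = leaves_l + leaves_r
        if len(members) < 3:
            assign(node)
            return
        idx = np.array(members)
        labels = np.array([0] * len(leaves_l) + [1] * len(leaves_r))
        res = permanova(
            D.submatrix(idx),
            labels,
            n_permutations=params.n_permutations,
            seed=_node_seed(params.seed, node.id),
        )
        if res.p_value <= params.alpha:
            descend(node.left)
            descend(node.right)
        else:
            assign(node)

    descend(root)
    return GuildPartition(assignments)


# ---------------------------------------------------------------------------
# guild abundance


def guild_abundance(table: AbundanceTable, partition: GuildPartition) -> AbundanceTable:
    """Per-sample sum of member abundances for each guild."""
    missing = [f for f in table.feature_ids if f not in partition.assignments]
    if missing:
        raise ValueError(f"partition does not cover features: {missing[:5]}")
    extra = set(partition.assignments) - set(table.feature_ids)
    if extra:
        raise ValueError(f"partition has unknown features: {sorted(extra)[:5]}")
    members = partition.members()
    guild_ids = sorted(members)
    pos = {f: i for i, f in enumerate(table.feature_ids)}
    values = np.vstack(
        [table.values[[pos[f] for f in members[g]]].sum(axis=0) for g in guild_ids]
    )
    return AbundanceTable(
        [f"guild_{g}" for g in guild_ids], list(table.sample_ids), values, table.mode
    )
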