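"""Synthetic longitudinal cohorts with planted co-abundance guild structure.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of subjects sampled at a fixed grid of timepoints, strong
subject-level effects, features organized into co-abundant blocks (guilds)
through a shared latent factor, transient treatment effects at mid-study
timepoints, and metabolite variables coupled to a target guild's
(arcsine-square-root transformed) abundance.

Generative model for the log-abundance of feature ``g`` (member of block
``k``) in the sample of subject ``i`` at timepoint ``t``::

    log A_git = mu_g + u_ki + s_it
                + feature_sd * (sqrt(rho) * z_kit + sqrt(1 - rho) * e_git)
                + delta_k(t)

with ``u_ki ~ N(0, subject_sd^2)`` a guild-level subject intercept (each
background singleton is its own one-member guild), ``s_it ~ N(0,
sample_sd^2)`` a per-sample depth-like shift, ``z`` a latent block factor
and ``e`` feature-level noise (both standard normal), and ``delta_k(t)``
the per-timepoint log-fold-change for affected blocks.  Abundances are
exponentiated and closed to relative abundance per sample, so ``rho``
(``within_guild_corr``) is the target latent correlation between any two
members of the same block.

The subject intercept is deliberately guild-level, not global and not
feature-level.  A subject effect shared by every feature is a common factor
within each sample and cancels exactly under closure, leaving no persistent
compositional fingerprint at all; an independent per-feature intercept
rescales each member's within-subject deviations independently and so
erodes the co-abundance the blocks are meant to carry.  Letting each
subject carry each guild at its own stable level gives longitudinal samples
from the same person their characteristic tight clustering — the dominant
structure the downstream subject adjustments exist to remove — while guild
members remain co-abundant both within and across subjects.

One integer seed drives every draw through named substreams (abundance /
metabolites / outcomes), so adding one component never perturbs another's.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, MetaboliteTable, SampleMetadata

DEFAULT_TIMEPOINTS = ("-5", "0", "2", "4", "10")


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named RNG stream derived from one global seed."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


@dataclass
class CohortDesign:
    """Study layout: 27 subjects x 5 timepoints (16 F : 11 M) by default."""

    n_subjects: int = 27
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    sex_ratio: tuple[int, int] = (16, 11)  # (F, M)
    seed: int = 0

    def __post_init__(self) -> None:
        self.timepoints = tuple(str(t) for t in self.timepoints)
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        if min(self.sex_ratio) < 0 or sum(self.sex_ratio) == 0:
            raise ValueError("invalid sex_ratio")

    @property
    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def sexes(self) -> list[str]:
        n_f = round(self.n_subjects * self.sex_ratio[0] / sum(self.sex_ratio))
        return ["F"] * n_f + ["M"] * (self.n_subjects - n_f)

    def metadata(self) -> SampleMetadata:
        rows = []
        sexes = self.sexes()
        for i, subj in enumerate(self.subject_ids):
            for tp in self.timepoints:
                rows.append(
                    {
                        "sample_id": f"{subj}.t{tp}",
                        "subject_id": subj,
                        "timepoint": tp,
                        "sex": sexes[i],
                    }
                )
        return SampleMetadata(pd.DataFrame(rows), list(self.timepoints))


@dataclass
class GuildSpec:
    """Feature count, block layout, and variance components on the log scale.

    Features beyond ``sum(block_sizes)`` are background singletons: each is
    its own one-member guild in the ground truth.  The test-scale default is
    120 features as 10 blocks of 8 plus 40 singletons; the full study scale
    (~1500 features, ~170 guilds) is a configuration choice, not a default.
    """

    n_features: int = 120
    block_sizes: tuple[int, ...] = (8,) * 10
    within_guild_corr: float = 0.7
    subject_sd: float = 1.0
    sample_sd: float = 0.3
    feature_sd: float = 1.0
    base_log_mean_sd: float = 1.5

    def __post_init__(self) -> None:
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if sum(self.block_sizes) > self.n_features:
            raise ValueError("block sizes sum exceeds n_features")
        if not 0 < self.within_guild_corr < 1:
            raise ValueError("within_guild_corr must be in (0, 1)")
        for name in ("subject_sd", "sample_sd", "feature_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_blocks(self) -> int:
        """Number of ground-truth guilds (planted blocks + singletons)."""
        return len(self.block_sizes) + (self.n_features - sum(self.block_sizes))

    def block_of(self) -> np.ndarray:
        """Ground-truth guild index for every feature."""
        labels = np.empty(self.n_features, dtype=int)
        pos = 0
        for k, size in enumerate(self.block_sizes):
            labels[pos : pos + size] = k
            pos += size
        labels[pos:] = np.arange(len(self.block_sizes), self.n_blocks)
        return labels


@dataclass
class EffectSpec:
    """Per-timepoint log-fold-changes for affected guilds.

    ``effects`` maps guild index -> vector of log-fold-changes, one entry per
    timepoint in design order; the entry at the baseline timepoint must be 0.
    ``default_transient`` plants the study's signature pattern: suppression /
    increase at days 2 and 4 that reverts by day 10.
    """

    effects: dict[int, tuple[float, ...]] = field(default_factory=dict)
    baseline: str = "0"

    def validate(self, design: CohortDesign, guild_spec: GuildSpec) -> None:
        n_t = len(design.timepoints)
        if self.baseline not in design.timepoints:
            raise ValueError(f"baseline {self.baseline!r} not a design timepoint")
        b = design.timepoints.index(self.baseline)
        for k, vec in self.effects.items():
            if not 0 <= k < guild_spec.n_blocks:
                raise ValueError(f"guild index {k} out of range")
            if len(vec) != n_t:
                raise ValueError(
                    f"effect vector for guild {k} has length {len(vec)}, "
                    f"expected {n_t}"
                )
            if vec[b] != 0:
                raise ValueError(f"guild {k}: baseline effect must be 0")

    @classmethod
    def default_transient(
        cls,
        suppressed: tuple[int, ...] = (0,),
        increased: tuple[int, ...] = (1,),
        magnitude: float = 1.5,
    ) -> "EffectSpec":
        # pattern over (-5, 0, 2, 4, 10): hit at days 2/4, revert at day 10
        eff = {}
        for k in suppressed:
            eff[k] = (0.0, 0.0, -magnitude, -magnitude, 0.0)
        for k in increased:
            eff[k] = (0.0, 0.0, magnitude, magnitude, 0.0)
        return cls(effects=eff)


@dataclass
class MetaboliteSpec:
    """Analytes linearly coupled to one guild's AST-transformed abundance."""

    analytes: list[tuple[str, float, float, float, float]] = field(
        default_factory=lambda: [("HCA_like", 8.0, -5.0, 1.0, 0.5)]
    )  # (name, intercept, slope, subject_sd, residual_sd)
    target_guild: int = 0

    def __post_init__(self) -> None:
        for name, _, _, subject_sd, residual_sd in self.analytes:
            if residual_sd <= 0:
                raise ValueError(f"analyte {name!r}: residual_sd must be > 0")
            if subject_sd < 0:
                raise ValueError(f"analyte {name!r}: subject_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth saved alongside a simulated cohort, for recovery tests."""

    guild_of_feature: dict[str, int]
    effects: dict[int, tuple[float, ...]]
    subject_intercepts: dict[str, float]
    metabolite_slopes: dict[str, float] = field(default_factory=dict)

    def partition_labels(self, feature_ids: list[str]) -> np.ndarray:
        return np.array([self.guild_of_feature[f] for f in feature_ids])

    def members_of(self, guild: int) -> list[str]:
        return [f for f, k in self.guild_of_feature.items() if k == guild]


def simulate_abundance(
    design: CohortDesign,
    guild_spec: GuildSpec | None = None,
    effect_spec: EffectSpec | None = None,
    depth: int | None = None,
):
    """Draw one cohort; returns ``(AbundanceTable, SampleMetadata, SyntheticTruth)``.

    With ``depth`` set, counts are Poisson-sampled at that expected depth and
    the table is returned in counts mode; otherwise the closed relative table
    is returned directly.
    """
    guild_spec = guild_spec or GuildSpec()
    effect_spec = effect_spec or EffectSpec()
    effect_spec.validate(design, guild_spec)

    rng = substream(design.seed, "abundance")
    S, T, G = design.n_subjects, len(design.timepoints), guild_spec.n_features
    block = guild_spec.block_of()
    B = guild_spec.n_blocks

    mu = rng.normal(0.0, guild_spec.base_log_mean_sd, size=G)
    u = rng.normal(0.0, guild_spec.subject_sd, size=(B, S))
    s_shift = rng.normal(0.0, guild_spec.sample_sd, size=(S, T))
    z = rng.standard_normal(size=(B, S, T))
    eps = rng.standard_normal(size=(G, S, T))

    delta = np.zeros((B, T))
    for k, vec in effect_spec.effects.items():
        delta[k] = vec

    rho = guild_spec.within_guild_corr
    log_a = (
        mu[:, None, None]
        + u[block][:, :, None]
        + s_shift[None, :, :]
        + guild_spec.feature_sd
        * (np.sqrt(rho) * z[block] + np.sqrt(1.0 - rho) * eps)
        + delta[block][:, None, :]
    )
    raw = np.exp(log_a).reshape(G, S * T)

    metadata = design.metadata()
    feature_ids = [f"F{g + 1:03d}" for g in range(G)]
    sample_ids = metadata.sample_ids

    if depth is not None:
        expected = raw / raw.sum(axis=0) * float(depth)
        counts = rng.poisson(expected)
        table = AbundanceTable(feature_ids, sample_ids, counts.astype(float), "counts")
    else:
        table = AbundanceTable(feature_ids, sample_ids, raw / raw.sum(axis=0), "relative")

    truth = SyntheticTruth(
        guild_of_feature=dict(zip(feature_ids, block.tolist())),
        effects=dict(effect_spec.effects),
        # per-subject summary of the guild-level intercepts
        subject_intercepts=dict(zip(design.subject_ids, u.mean(axis=0).tolist())),
    )
    return table, metadata, truth


def simulate_metabolites(
    abundance: AbundanceTable,
    metadata: SampleMetadata,
    truth: SyntheticTruth,
    spec: MetaboliteSpec,
    seed: int,
) -> MetaboliteTable:
    """Analyte = intercept + slope * AST(target-guild abundance) + subject + noise.

    Negative draws are truncated at 0 (concentrations are non-negative).
    """
    known = set(truth.guild_of_feature.values())
    if spec.target_guild not in known:
        raise ValueError(f"unknown guild index {spec.target_guild}")
    members = truth.members_of(spec.target_guild)
    pos = {f: i for i, f in enumerate(abundance.feature_ids)}
    idx = [pos[f] for f in members if f in pos]
    if not idx:
        raise ValueError("target guild has no features in the abundance table")
    guild_ab = abundance.values[idx].sum(axis=0)
    x = np.arcsin(np.sqrt(np.clip(guild_ab, 0.0, 1.0)))

    rng = substream(seed, "metabolites")
    subjects = metadata.subjects_of(abundance.sample_ids)
    subj_levels = list(dict.fromkeys(subjects))
    subj_index = np.array([subj_levels.index(s) for s in subjects])

    names, rows = [], []
    for name, intercept, slope, subject_sd, residual_sd in spec.analytes:
        u = rng.normal(0.0, subject_sd, size=len(subj_levels))
        y = intercept + slope * x + u[subj_index] + rng.normal(0.0, residual_sd, x.shape)
        rows.append(np.maximum(y, 0.0))
        names.append(name)
        truth.metabolite_slopes[name] = slope
    return MetaboliteTable(names, list(abundance.sample_ids), np.vstack(rows))


def simulate_paired_outcome(
    design: CohortDesign,
    delta: float,
    sd: float,
    baseline_mean: float = 0.0,
    baseline_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-subject (baseline, followup) pairs with followup = baseline + delta + noise.

    Emulates a two-timepoint clinical outcome (e.g. a fasting blood panel
    before and after supplementation) for exercising the normality-gated
    paired test.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = substream(design.seed, "outcomes")
    base = rng.normal(baseline_mean, baseline_sd, size=design.n_subjects)
    follow = base + delta + rng.normal(0.0, sd, size=design.n_subjects)
    return pd.DataFrame(
        {"subject_id": design.subject_ids, "baseline": base, "followup": follow}
    )
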