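"""Tabular containers and TSV I/O shared by every pipeline stage.

Three containers circulate through the pipeline: a feature-by-sample
:class:`AbundanceTable` (genomes, guilds, or proteins), a per-sample
:class:`SampleMetadata` frame carrying the repeated-measures design
(subject, ordered timepoint, sex), and an analyte-by-sample
:class:`MetaboliteTable`.  All readers validate structure up front so the
statistics stages can assume clean inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLOSURE_TOL = 1e-8

METADATA_COLUMNS = ("sample_id", "subject_id", "timepoint", "sex")


class TableError(ValueError):
    """Structural problem in an input table."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise TableError(f"duplicate {what}: {dups}")


@dataclass
class AbundanceTable:
    """Features x samples matrix of non-negative abundances.

    ``mode`` is ``"counts"`` or ``"relative"``.  Relative tables produced by
    :func:`read_abundance_table` / :func:`close_to_relative` have columns
    summing to 1; downstream subsetting (e.g. prevalence filtering) may leave
    column sums below 1, which is permitted — the values remain fractions of
    the original whole-community total.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mode: str = "relative"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TableError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.mode not in ("counts", "relative"):
            raise TableError(f"unknown mode {self.mode!r}")
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.isfinite(self.values).all():
            raise TableError("non-finite or missing cells are not allowed")
        if (self.values < 0).any():
            f, s = np.argwhere(self.values < 0)[0]
            raise TableError(
                f"negative abundance at feature {self.feature_ids[f]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.mode == "relative":
            sums = self.values.sum(axis=0)
            over = sums > 1 + CLOSURE_TOL
            if over.any():
                bad = self.sample_ids[int(np.argmax(over))]
                raise TableError(f"relative column sums exceed 1 (sample {bad!r})")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def check_closed(self) -> None:
        """Require every column to sum to 1 (within tolerance)."""
        if self.mode != "relative":
            raise TableError("closure check applies to relative tables only")
        sums = self.values.sum(axis=0)
        bad = np.abs(sums - 1.0) > CLOSURE_TOL
        if bad.any():
            i = int(np.argmax(bad))
            raise TableError(
                f"sample {self.sample_ids[i]!r} sums to {sums[i]:.6g}, expected 1"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    def select_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return AbundanceTable(
            list(self.feature_ids), list(sample_ids), self.values[:, idx], self.mode
        )

    def select_features(self, feature_ids: list[str]) -> "AbundanceTable":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return AbundanceTable(
            list(feature_ids), list(self.sample_ids), self.values[idx, :], self.mode
        )


@dataclass
class SampleMetadata:
    """Per-sample design frame: subject, ordered timepoint, sex.

    ``timepoints`` fixes the ordering of the timepoint labels; contrasts and
    effect vectors always refer to these labels, never to numeric positions.
    """

    frame: pd.DataFrame
    timepoints: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise TableError(f"metadata missing columns: {missing}")
        df = self.frame.loc[:, list(METADATA_COLUMNS)].copy()
        for c in METADATA_COLUMNS:
            df[c] = df[c].astype(str)
        _check_unique(df["sample_id"], "sample ids in metadata")
        pairs = df[["subject_id", "timepoint"]]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise TableError(
                f"duplicate (subject, timepoint) pair: "
                f"({dup['subject_id']!r}, {dup['timepoint']!r})"
            )
        bad_sex = sorted(set(df["sex"]) - {"F", "M"})
        if bad_sex:
            raise TableError(f"sex must be F or M, got {bad_sex}")
        if not self.timepoints:
            # fall back to sorted-as-number order when labels are numeric
            labels = list(dict.fromkeys(df["timepoint"]))
            try:
                labels.sort(key=float)
            except ValueError:
                pass
            self.timepoints = labels
        unknown = sorted(set(df["timepoint"]) - set(self.timepoints))
        if unknown:
            raise TableError(f"timepoints not in declared order: {unknown}")
        df["timepoint"] = pd.Categorical(
            df["timepoint"], categories=self.timepoints, ordered=True
        )
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def subjects_of(self, sample_ids: list[str]) -> np.ndarray:
        m = self.frame.set_index("sample_id")["subject_id"]
        return m.loc[sample_ids].to_numpy()

    def timepoints_of(self, sample_ids: list[str]) -> np.ndarray:
        m = self.frame.set_index("sample_id")["timepoint"]
        return m.loc[sample_ids].astype(str).to_numpy()

    def select(self, sample_ids: list[str]) -> "SampleMetadata":
        df = self.frame.set_index("sample_id").loc[sample_ids].reset_index()
        return SampleMetadata(df, list(self.timepoints))


@dataclass
class MetaboliteTable:
    """Analytes x samples concentration matrix with per-analyte units."""

    analyte_ids: list[str]
    sample_ids: list[str]
    concentrations: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (len(self.analyte_ids), len(self.sample_ids)):
            raise TableError("concentration matrix shape mismatch")
        _check_unique(self.analyte_ids, "analyte ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.isfinite(self.concentrations).all():
            raise TableError("non-finite concentration")
        if (self.concentrations < 0).any():
            raise TableError("negative concentration")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.concentrations,
            index=list(self.analyte_ids),
            columns=list(self.sample_ids),
        )

    def select_samples(self, sample_ids: list[str]) -> "MetaboliteTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return MetaboliteTable(
            list(self.analyte_ids),
            list(sample_ids),
            self.concentrations[:, idx],
            dict(self.units),
        )


def _read_matrix(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            i = int(np.argmax(coerced.isna().to_numpy()))
            raise TableError(
                f"non-numeric cell at row {df.index[i]!r}, column {col!r}"
            ) from None
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    if out.isna().any().any():
        raise TableError("missing cells are not allowed")
    return out


def read_abundance_table(path, mode: str = "relative", sep: str = "\t") -> AbundanceTable:
    """Read a features-x-samples TSV (first column feature ids, header sample ids)."""
    df = _read_matrix(path, sep)
    table = AbundanceTable(
        df.index.tolist(), df.columns.tolist(), df.to_numpy(), mode=mode
    )
    if mode == "relative":
        table.check_closed()
    return table


def write_abundance_table(table: AbundanceTable, path, sep: str = "\t") -> None:
    df = table.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep=sep, float_format="%.12g")


def read_metadata(path, sep: str = "\t", timepoints: list[str] | None = None) -> SampleMetadata:
    df = pd.read_csv(path, sep=sep, dtype=str)
    return SampleMetadata(df, timepoints or [])


def write_metadata(metadata: SampleMetadata, path, sep: str = "\t") -> None:
    df = metadata.frame.copy()
    df["timepoint"] = df["timepoint"].astype(str)
    df.to_csv(path, sep=sep, index=False)


def read_metabolite_table(path, sep: str = "\t") -> MetaboliteTable:
    df = _read_matrix(path, sep)
    return MetaboliteTable(df.index.tolist(), df.columns.tolist(), df.to_numpy())


def write_metabolite_table(table: MetaboliteTable, path, sep: str = "\t") -> None:
    df = table.to_frame()
    df.index.name = "analyte_id"
    df.to_csv(path, sep=sep, float_format="%.12g")


def close_to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its sum (compositional closure)."""
    if table.mode != "counts":
        raise TableError("close_to_relative expects a counts table")
    sums = table.values.sum(axis=0)
    zero = sums == 0
    if zero.any():
        bad = table.sample_ids[int(np.argmax(zero))]
        raise TableError(f"sample {bad!r} has zero total count")
    return AbundanceTable(
        list(table.feature_ids),
        list(table.sample_ids),
        table.values / sums,
        mode="relative",
    )


def align(table, metadata: SampleMetadata):
    """Restrict a table and metadata to their shared samples, in a common order.

    Samples present on only one side are dropped with a logged warning; an
    empty intersection is an error.  Works for abundance and metabolite tables.
    """
    meta_ids = metadata.sample_ids
    shared = [s for s in table.sample_ids if s in set(meta_ids)]
    if not shared:
        raise TableError("no samples shared between table and metadata")
    n_dropped = (len(table.sample_ids) - len(shared)) + (len(meta_ids) - len(shared))
    if n_dropped:
        logger.warning("align: dropped %d unmatched sample(s)", n_dropped)
    return table.select_samples(shared), metadata.select(shared)
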