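"""Abundance profiles: data model, I/O, transforms, filtering and fold changes.

The central object is :class:`AbundanceTable`, a samples x features matrix of
nonnegative abundances together with a per-sample "unannotated" mass (reads
that could not be assigned to any feature).  Raw abundances are converted to
relative abundances by dividing each sample by its total *including* the
unannotated mass, so feature relative abundances generally sum to less than 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "FeatureGroupMap",
    "FoldChangeSpec",
    "TIMEPOINTS",
    "TIMEPOINT_MONTHS",
    "UNANNOTATED_COLUMN",
    "UNMAPPED_GROUP",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "to_relative",
    "aggregate",
    "filter_features",
    "log2_fold_change",
]

#: Canonical time points of the longitudinal design, in chronological order.
TIMEPOINTS = ("baseline", "3MO", "1Y")

#: Months after the intervention for each time point.
TIMEPOINT_MONTHS = {"baseline": 0.0, "3MO": 3.0, "1Y": 12.0}

#: Reserved column name for unannotated per-sample mass in on-disk tables.
UNANNOTATED_COLUMN = "unannotated"

#: Reserved group id receiving features absent from a FeatureGroupMap.
UNMAPPED_GROUP = "unmapped"

_REL_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input table or metadata violates its invariants."""


@dataclass
class AbundanceTable:
    """Samples x features abundance matrix plus per-sample unannotated mass.

    Parameters
    ----------
    data : pandas.DataFrame
        Nonnegative abundances, samples as rows, features as columns.
    unannotated : pandas.Series
        Per-sample mass not assigned to any feature (zero allowed), aligned
        with ``data.index``.
    kind : {"raw", "relative"}
        Whether values are raw abundances or relative abundances.  For
        relative tables each sample's feature sum plus unannotated mass must
        equal 1 within 1e-9.
    """

    data: pd.DataFrame
    unannotated: pd.Series | None = None
    kind: str = "raw"

    def __post_init__(self) -> None:
        if self.unannotated is None:
            self.unannotated = pd.Series(0.0, index=self.data.index)
        self.unannotated = self.unannotated.astype(float).reindex(self.data.index)
        self.data = self.data.astype(float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.kind not in ("raw", "relative"):
            raise ValidationError(f"unknown table kind {self.kind!r}")
        if self.data.shape[0] == 0:
            raise ValidationError("no samples")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dupes}")
        if self.data.isna().any().any():
            raise ValidationError("missing entries in abundance matrix")
        if (self.data.values < 0).any():
            r, c = np.argwhere(self.data.values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if self.unannotated.isna().any() or (self.unannotated.values < 0).any():
            raise ValidationError("unannotated mass must be nonnegative and complete")
        if self.kind == "relative":
            totals = self.data.sum(axis=1) + self.unannotated
            bad = totals[(totals - 1.0).abs() > _REL_TOL]
            if len(bad):
                raise ValidationError(
                    f"relative table rows do not sum to 1: {bad.index.tolist()}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = [s for s in sample_ids]
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"samples not in table: {sorted(missing)}")
        return AbundanceTable(
            self.data.loc[ids].copy(), self.unannotated.loc[ids].copy(), self.kind
        )

    def min_nonzero(self) -> float:
        """Smallest strictly positive feature abundance over the whole table."""
        vals = self.data.values
        pos = vals[vals > 0]
        if pos.size == 0:
            raise ValidationError("table has no nonzero entries")
        return float(pos.min())


@dataclass
class SampleMetadata:
    """Per-sample subject identity, time point, and clinical covariates.

    Wraps a DataFrame with required columns ``sample_id``, ``subject_id``
    and ``timepoint``; any further columns are covariates.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ("sample_id", "subject_id", "timepoint")
        for col in required:
            if col not in self.frame.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        self.frame = self.frame.reset_index(drop=True)
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        pair = self.frame[["subject_id", "timepoint"]]
        if pair.duplicated().any():
            dup = pair[pair.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate (subject, timepoint) pair: "
                f"({dup['subject_id']!r}, {dup['timepoint']!r})"
            )
        unknown = set(self.frame["timepoint"]) - set(TIMEPOINTS)
        if unknown:
            raise ValidationError(f"unknown timepoints: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def covariate_names(self) -> list[str]:
        skip = {"sample_id", "subject_id", "timepoint"}
        return [c for c in self.frame.columns if c not in skip]

    def samples_at(self, timepoint: str) -> pd.DataFrame:
        return self.frame[self.frame["timepoint"] == timepoint]

    def sample_for(self, subject_id: str, timepoint: str) -> str:
        rows = self.frame[
            (self.frame["subject_id"] == subject_id)
            & (self.frame["timepoint"] == timepoint)
        ]
        if len(rows) != 1:
            raise KeyError(f"no sample for subject {subject_id!r} at {timepoint!r}")
        return str(rows["sample_id"].iloc[0])


class FeatureGroupMap:
    """Many-to-one mapping from feature ids to group ids.

    Examples: species -> phylum, KEGG orthologous group -> module/pathway.
    """

    def __init__(self, mapping: Mapping[str, str]):
        if len(mapping) == 0:
            raise ValidationError("empty feature-group map")
        self.mapping = dict(mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def group_of(self, feature_id: str) -> str:
        return self.mapping.get(feature_id, UNMAPPED_GROUP)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureGroupMap":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValidationError("feature-group map needs two columns")
        dup = df[0].duplicated()
        if dup.any():
            raise ValidationError(f"feature mapped twice: {df[0][dup].tolist()}")
        return cls(dict(zip(df[0], df[1])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.mapping.items())).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass(frozen=True)
class FoldChangeSpec:
    """Pseudo-count specification for log2 fold changes.

    The pseudo-count defaults to the lowest nonzero relative abundance
    observed over the entire cohort table and is held fixed for every
    contrast and inside the leave-one-out compositionality test.
    """

    pseudo_count: float
    base: int = field(default=2)

    def __post_init__(self) -> None:
        if not self.pseudo_count > 0:
            raise ValidationError("pseudo-count must be > 0")
        if self.base != 2:
            raise ValidationError("fold changes are reported on the log2 scale")

    @classmethod
    def from_table(cls, table: AbundanceTable) -> "FoldChangeSpec":
        return cls(pseudo_count=table.min_nonzero())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_abundance_table(
    path: str | Path,
    kind: str | None = None,
    metadata: SampleMetadata | None = None,
) -> AbundanceTable:
    """Read a tab-separated abundance matrix.

    The canonical dialect has samples as rows (first column sample ids,
    header row of feature ids, optional reserved ``unannotated`` column).
    A samples-as-columns dialect is auto-detected by matching identifiers
    against ``metadata`` when supplied.  ``kind`` is inferred from per-sample
    sums when not given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValidationError("no samples")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValidationError("no samples")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if metadata is not None:
        known = set(metadata.sample_ids)
        row_hits = len(set(df.index) & known)
        col_hits = len(set(df.columns) & known)
        if col_hits > row_hits:
            df = df.T
    unannot = None
    if UNANNOTATED_COLUMN in df.columns:
        unannot = df[UNANNOTATED_COLUMN]
        df = df.drop(columns=[UNANNOTATED_COLUMN])
    if kind is None:
        totals = df.sum(axis=1) + (unannot if unannot is not None else 0.0)
        kind = "relative" if np.allclose(totals, 1.0, atol=1e-6) else "raw"
    return AbundanceTable(df, unannot, kind)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write the canonical samples-as-rows TSV (round-trips with the reader)."""
    out = table.data.copy()
    out[UNANNOTATED_COLUMN] = table.unannotated
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample by its total abundance including unannotated mass."""
    if table.kind == "relative":
        return table
    totals = table.data.sum(axis=1) + table.unannotated
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(f"zero total abundance for samples {zero.index.tolist()}")
    return AbundanceTable(
        table.data.div(totals, axis=0), table.unannotated / totals, "relative"
    )


def aggregate(table: AbundanceTable, group_map: FeatureGroupMap) -> AbundanceTable:
    """Sum feature abundances into groups (e.g. species into phyla).

    Features absent from the map are pooled into the reserved ``unmapped``
    group, so per-sample total mass is conserved exactly.
    """
    groups = [group_map.group_of(f) for f in table.feature_ids]
    agg = table.data.T.groupby(pd.Index(groups, name="group"), sort=True).sum().T
    agg.columns = [str(c) for c in agg.columns]
    return AbundanceTable(agg, table.unannotated.copy(), table.kind)


def filter_features(
    table: AbundanceTable,
    min_prevalence: float = 0.10,
    min_mean_abund: float = 0.01,
) -> AbundanceTable:
    """Remove rare, low-abundance features.

    A feature is kept when it is present (abundance strictly > 0) in at
    least ``min_prevalence`` of all samples pooled over time points AND its
    mean relative abundance across all samples is at least
    ``min_mean_abund`` (0.01 for taxa, 0.001 for functional units).
    """
    if not (0.0 <= min_prevalence <= 1.0) or not (0.0 <= min_mean_abund <= 1.0):
        raise ValidationError("filter thresholds must lie in [0, 1]")
    if table.kind != "relative":
        raise ValidationError("filter_features expects a relative-abundance table")
    prevalence = (table.data > 0).mean(axis=0)
    mean_abund = table.data.mean(axis=0)
    keep = table.data.columns[
        (prevalence >= min_prevalence) & (mean_abund >= min_mean_abund)
    ]
    removed = table.data.columns.difference(keep)
    # Mass of removed features joins the unannotated pool so the per-sample
    # sum-to-one invariant of relative tables is preserved.
    unannot = table.unannotated + table.data[removed].sum(axis=1)
    return AbundanceTable(table.data[keep].copy(), unannot, table.kind)


def log2_fold_change(
    x_t1: np.ndarray | pd.Series,
    x_t2: np.ndarray | pd.Series,
    spec: FoldChangeSpec,
) -> tuple[np.ndarray, float]:
    """Per-subject log2 fold changes with a pseudo-count, and their median.

    ``x_t1`` and ``x_t2`` are relative abundances of one feature over the
    same subjects at two time points, aligned by subject.
    """
    x1 = np.asarray(x_t1, dtype=float)
    x2 = np.asarray(x_t2, dtype=float)
    if x1.shape != x2.shape:
        raise ValidationError("fold change requires aligned per-subject vectors")
    if x1.size == 0:
        raise ValidationError("no shared subjects between time points")
    eps = spec.pseudo_count
    per_subject = np.log2((x2 + eps) / (x1 + eps))
    return per_subject, float(np.median(per_subject))
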