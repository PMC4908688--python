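"""Leave-one-taxon-out robustness test for compositional effects.

Relative abundances are constrained to sum to one, so a genuine change in
one taxon induces apparent changes in every other taxon (closure).  This
module implements the systematic check: for a focal taxon found
differentially abundant, exclude each other taxon in turn, renormalize the
remaining relative abundances to sum to one, and recompute the focal
taxon's fold change and paired Wilcoxon P value.  The *least significant*
(largest) P over all exclusions gauges whether the focal change survives
the hypothetical absence of any single other taxon: a closure artifact
driven by one dominant taxon loses significance the moment that taxon is
excluded, while a real change does not.

The unannotated read fraction is dropped before the test so the
renormalized taxa sum to one, and the fold-change pseudo-count is held
fixed at its full-table value rather than recomputed per exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import wilcoxon_signed_rank, paired_subjects
from .profiles import (
    AbundanceTable,
    FoldChangeSpec,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "CompositionalityReport",
    "exclude_and_renormalize",
    "loo_test",
    "fold_change_cloud",
    "reports_to_frames",
]

REPORT_COLUMNS = ["focal_id", "contrast", "excluded_id", "log2fc", "p"]
SUMMARY_COLUMNS = [
    "focal_id",
    "contrast",
    "baseline_log2fc",
    "baseline_p",
    "least_significant_p",
    "most_influential_excluded_id",
    "robust",
]


@dataclass
class CompositionalityReport:
    """Per-focal-feature outcome of the leave-one-out test."""

    focal_id: str
    contrast: str
    baseline_log2fc: float
    baseline_p: float
    records: pd.DataFrame  # columns: excluded_id, log2fc, p
    alpha: float = 0.05
    least_significant_p: float = field(init=False)
    most_influential_excluded_id: str = field(init=False)
    robust: bool = field(init=False)

    def __post_init__(self) -> None:
        self.least_significant_p = float(self.records["p"].max())
        idx = int(self.records["p"].to_numpy().argmax())
        self.most_influential_excluded_id = str(self.records["excluded_id"].iloc[idx])
        self.robust = bool(self.least_significant_p < self.alpha)


def exclude_and_renormalize(table: AbundanceTable, excluded: str) -> AbundanceTable:
    """Drop one feature and rescale each sample's remaining features to 1.

    The unannotated mass plays no part: renormalization divides by the
    per-sample sum of the remaining *feature* abundances only.
    """
    if excluded not in table.data.columns:
        raise KeyError(f"feature {excluded!r} not in table")
    rest = table.data.drop(columns=[excluded])
    if rest.shape[1] == 0:
        raise ValidationError("cannot exclude the only feature")
    totals = rest.sum(axis=1)
    dead = totals[totals <= 0]
    if len(dead):
        raise ValidationError(
            f"all remaining features are zero for samples {dead.index.tolist()}"
        )
    return AbundanceTable(rest.div(totals, axis=0), None, "relative")


def _drop_unannotated(table: AbundanceTable) -> pd.DataFrame:
    """Taxa-only working matrix renormalized so each sample sums to 1."""
    totals = table.data.sum(axis=1)
    dead = totals[totals <= 0]
    if len(dead):
        raise ValidationError(
            f"samples with zero feature mass: {dead.index.tolist()}"
        )
    return table.data.div(totals, axis=0)


def loo_test(
    table: AbundanceTable,
    metadata: SampleMetadata,
    t1: str,
    t2: str,
    focal_set: list[str] | None = None,
    spec: FoldChangeSpec | None = None,
    alpha: float = 0.05,
) -> list[CompositionalityReport]:
    """Run the leave-one-out compositionality test for each focal feature.

    For every focal feature f and every other retained feature e: exclude
    e, renormalize, recompute f's per-subject log2 fold changes (fixed
    pseudo-count) and the two-sided paired Wilcoxon P.  A focal feature is
    robust iff its largest P over all exclusions stays below ``alpha``.

    ``focal_set`` defaults in the pipeline to the features significant in
    the main contrast; an empty focal set yields an empty list.
    """
    if table.n_features < 2:
        raise ValidationError("leave-one-out test needs at least 2 features")
    if spec is None:
        spec = FoldChangeSpec.from_table(table)
    if focal_set is None:
        focal_set = table.feature_ids
    missing = set(focal_set) - set(table.feature_ids)
    if missing:
        raise KeyError(f"focal features not in table: {sorted(missing)}")
    if len(focal_set) == 0:
        return []

    subjects = paired_subjects(metadata, t1, t2)
    rows_t1 = [metadata.sample_for(s, t1) for s in subjects]
    rows_t2 = [metadata.sample_for(s, t2) for s in subjects]

    work = _drop_unannotated(table)
    v1 = work.loc[rows_t1].to_numpy()  # subjects x features, sums to 1
    v2 = work.loc[rows_t2].to_numpy()
    features = np.array(table.feature_ids)
    eps = spec.pseudo_count
    contrast = f"{t1}->{t2}"

    reports: list[CompositionalityReport] = []
    for f_idx in (int(np.flatnonzero(features == f)[0]) for f in focal_set):
        base_fc = np.log2((v2[:, f_idx] + eps) / (v1[:, f_idx] + eps))
        base_p = wilcoxon_signed_rank(v1[:, f_idx], v2[:, f_idx]).p
        recs = []
        for e_idx in range(len(features)):
            if e_idx == f_idx:
                continue
            denom1 = 1.0 - v1[:, e_idx]
            denom2 = 1.0 - v2[:, e_idx]
            if np.any(denom1 <= 0) or np.any(denom2 <= 0):
                raise ValidationError(
                    f"excluding {features[e_idx]!r} leaves a sample with no mass"
                )
            r1 = v1[:, f_idx] / denom1
            r2 = v2[:, f_idx] / denom2
            fc = float(np.median(np.log2((r2 + eps) / (r1 + eps))))
            p = wilcoxon_signed_rank(r1, r2).p
            recs.append({"excluded_id": features[e_idx], "log2fc": fc, "p": p})
        reports.append(
            CompositionalityReport(
                focal_id=str(features[f_idx]),
                contrast=contrast,
                baseline_log2fc=float(np.median(base_fc)),
                baseline_p=base_p,
                records=pd.DataFrame.from_records(recs),
                alpha=alpha,
            )
        )
    return reports


def fold_change_cloud(report: CompositionalityReport) -> pd.DataFrame:
    """Plot-ready per-exclusion fold changes for one focal feature.

    Adds the absolute deviation of each exclusion's fold change from the
    full-table value and flags the most influential exclusion (largest
    deviation); no flag is set when every deviation is zero.
    """
    if len(report.records) == 0:
        raise ValidationError("empty report")
    cloud = report.records.copy()
    cloud["focal_id"] = report.focal_id
    cloud["deviation"] = (cloud["log2fc"] - report.baseline_log2fc).abs()
    cloud["most_influential"] = False
    if cloud["deviation"].max() > 0:
        cloud.loc[cloud["deviation"].idxmax(), "most_influential"] = True
    return cloud[
        ["focal_id", "excluded_id", "log2fc", "p", "deviation", "most_influential"]
    ]


def reports_to_frames(
    reports: list[CompositionalityReport],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format record table and one-row-per-focal summary table."""
    long_rows, summary_rows = [], []
    for rep in reports:
        rec = rep.records.copy()
        rec.insert(0, "focal_id", rep.focal_id)
        rec.insert(1, "contrast", rep.contrast)
        long_rows.append(rec[REPORT_COLUMNS])
        summary_rows.append(
            {
                "focal_id": rep.focal_id,
                "contrast": rep.contrast,
                "baseline_log2fc": rep.baseline_log2fc,
                "baseline_p": rep.baseline_p,
                "least_significant_p": rep.least_significant_p,
                "most_influential_excluded_id": rep.most_influential_excluded_id,
                "robust": rep.robust,
            }
        )
    if not reports:
        return (
            pd.DataFrame(columns=REPORT_COLUMNS),
            pd.DataFrame(columns=SUMMARY_COLUMNS),
        )
    return (
        pd.concat(long_rows, ignore_index=True),
        pd.DataFrame(summary_rows)[SUMMARY_COLUMNS],
    )
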