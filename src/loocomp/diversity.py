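"""Alpha diversity, per-month-normalized changes, and meal-test AUC.

Richness counts strictly positive features; the Shannon index is reported
in nats (natural log).  Clinical trajectories are summarized by the
difference between time-point medians (delta) normalized by the months
separating the time points (delta-prime: /3 for baseline to 3 months, /9
for 3 months to 1 year).  Meal-test curves are integrated with the
trapezoidal rule over the supplied sampling times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .profiles import AbundanceTable, ValidationError

__all__ = [
    "NormalizedChange",
    "richness",
    "shannon",
    "normalized_change",
    "auc_trapezoid",
    "diversity_summary",
]


@dataclass(frozen=True)
class NormalizedChange:
    """Difference of medians (delta) and its per-month rate (delta-prime)."""

    delta: float
    delta_per_month: float
    months: float


def richness(sample) -> int:
    """Number of features with strictly positive abundance."""
    x = np.asarray(sample, dtype=float)
    if (x < 0).any():
        raise ValidationError("abundances must be nonnegative")
    return int((x > 0).sum())


def shannon(sample) -> float:
    """Shannon index in nats over the renormalized positive entries."""
    x = np.asarray(sample, dtype=float)
    if (x < 0).any():
        raise ValidationError("abundances must be nonnegative")
    if x.sum() <= 0:
        raise ValidationError("Shannon index undefined for an all-zero sample")
    return float(entropy(x))  # scipy normalizes and uses natural log


def normalized_change(values_t1, values_t2, months: float) -> NormalizedChange:
    """Median difference between time points, per month.

    delta = median(t2) - median(t1); delta-prime = delta / months.
    """
    if months <= 0:
        raise ValidationError("months must be > 0")
    v1 = np.asarray(values_t1, dtype=float)
    v2 = np.asarray(values_t2, dtype=float)
    if v1.size == 0 or v2.size == 0:
        raise ValidationError("both time points need at least one value")
    delta = float(np.median(v2) - np.median(v1))
    return NormalizedChange(delta=delta, delta_per_month=delta / months, months=months)


def auc_trapezoid(times, values) -> float:
    """Trapezoidal area under a sampled curve (e.g. postprandial glucose)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2 or t.shape != y.shape:
        raise ValidationError("need >= 2 aligned (time, value) points")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    return float(np.trapezoid(y, t))


def diversity_summary(
    table: AbundanceTable, gene_table: AbundanceTable | None = None
) -> pd.DataFrame:
    """Per-sample species richness and Shannon index (plus gene richness).

    ``gene_table``, when given, supplies gene richness from a gene-level
    abundance table aligned on the same samples.
    """
    rows = {
        "richness": [richness(table.data.loc[s]) for s in table.sample_ids],
        "shannon": [shannon(table.data.loc[s]) for s in table.sample_ids],
    }
    out = pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample_id"))
    if gene_table is not None:
        gene = gene_table.data.reindex(table.sample_ids)
        out["gene_richness"] = [richness(gene.loc[s]) for s in table.sample_ids]
    return out
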