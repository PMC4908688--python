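"""Paired differential-abundance testing between time points.

Per feature, a two-sided Wilcoxon signed-rank test compares relative
abundances of the subjects sampled at both time points, with the effect
size reported as the median per-subject log2 fold change (pseudo-count
added).  Multiple testing is handled by Benjamini-Hochberg q values and by
Storey q values with a polynomial-smoothed pi0 estimate.

The signed-rank P value is exact (full sign-assignment distribution) for
up to 25 nonzero differences without ties, and otherwise uses the normal
approximation with tie-corrected variance and a continuity correction.
Zero differences are discarded before ranking (Wilcoxon's original
treatment, matching common statistical-package defaults).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import (
    AbundanceTable,
    FoldChangeSpec,
    SampleMetadata,
    ValidationError,
    log2_fold_change,
)

__all__ = [
    "WilcoxonResult",
    "PValueDiagnostics",
    "paired_subjects",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "storey_q",
    "pvalue_diagnostics",
    "run_contrast",
    "RESULT_COLUMNS",
]

#: Column order of the differential-result table.
RESULT_COLUMNS = [
    "feature_id",
    "contrast",
    "n_pairs",
    "median_log2fc",
    "W",
    "p",
    "q_bh",
    "q_storey",
    "significant",
]

EXACT_LIMIT = 25  # largest m for which the exact sign-assignment P is used
ZERO_TOL = 1e-10  # relative threshold below which a difference counts as zero


@dataclass(frozen=True)
class WilcoxonResult:
    W: float
    p: float
    n_used: int  # nonzero differences entering the ranking
    degenerate: bool = False  # all differences zero
    exact: bool = True


@dataclass(frozen=True)
class PValueDiagnostics:
    """P-value histogram plus the estimated proportion of true nulls."""

    bin_edges: np.ndarray
    counts: np.ndarray
    pi0: float


def paired_subjects(metadata: SampleMetadata, t1: str, t2: str) -> list[str]:
    """Subjects with a sample at both time points, in sorted order."""
    s1 = set(metadata.samples_at(t1)["subject_id"])
    s2 = set(metadata.samples_at(t2)["subject_id"])
    shared = sorted(s1 & s2)
    if not shared:
        raise ValidationError(f"no subjects sampled at both {t1!r} and {t2!r}")
    return shared


def _exact_sf_counts(m: int) -> np.ndarray:
    """Counts of the null W distribution over 0..m(m+1)/2 (no ties).

    Dynamic program equivalent to enumerating all 2^m sign assignments:
    each rank r independently contributes 0 or r to the positive-rank sum.
    """
    max_w = m * (m + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, m + 1):
        counts[r:] += counts[: max_w + 1 - r].copy()
    return counts


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on differences y - x.

    Returns the sum of positive-signed ranks W and a two-sided P computed
    as min(1, 2 x one-sided).  With every difference zero the test is
    degenerate: W = 0, P = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("wilcoxon requires two aligned 1-D vectors")
    if x.size == 0:
        raise ValidationError("wilcoxon requires at least one pair")
    d = y - x
    # differences below ~machine precision of the pair's magnitude are
    # treated as zeros so exact algebraic ties stay ties after roundoff
    scale = np.maximum(np.abs(x), np.abs(y))
    d = d[np.abs(d) > ZERO_TOL * scale]
    m = d.size
    if m == 0:
        return WilcoxonResult(W=0.0, p=1.0, n_used=0, degenerate=True)
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_pos = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < m

    if m <= EXACT_LIMIT and not has_ties:
        counts = _exact_sf_counts(m)
        total = counts.sum()
        w_int = int(round(w_pos))
        p_le = counts[: w_int + 1].sum() / total
        p_ge = counts[w_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(W=w_pos, p=p, n_used=m, exact=True)

    mean = m * (m + 1) / 4.0
    tie_sizes = np.unique(absd, return_counts=True)[1]
    var = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(tie_sizes**3 - tie_sizes) / 48.0
    if var <= 0:
        return WilcoxonResult(W=w_pos, p=1.0, n_used=m, exact=False)
    # continuity correction pulls W half a unit toward the null mean
    diff = w_pos - mean
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    one_sided = stats.norm.sf(abs(z))
    return WilcoxonResult(W=w_pos, p=min(1.0, 2.0 * one_sided), n_used=m, exact=False)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty P-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


def estimate_pi0(p, lambda_grid=None) -> float:
    """Estimate the proportion of true null hypotheses.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a grid of lambda,
    smoothed by a least-squares cubic polynomial and evaluated at the
    largest lambda, then clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValidationError("lambda grid must lie in (0, 1)")
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in grid])
    if grid.size >= 4:
        coef = np.polynomial.polynomial.polyfit(grid, pi0_l, deg=3)
        pi0 = float(np.polynomial.polynomial.polyval(grid.max(), coef))
    else:
        pi0 = float(pi0_l[-1])
    return float(np.clip(pi0, 1e-8, 1.0))


def storey_q(p, lambda_grid=None) -> tuple[np.ndarray, float]:
    """Storey q values: pi0-scaled BH-style step-up values.

    Needs at least two P values; pi0 is unstable below ~10.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 2:
        raise ValidationError("storey_q needs at least 2 P values")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("P values must lie in [0, 1]")
    pi0 = estimate_pi0(p, lambda_grid)
    q = np.minimum(1.0, pi0 * bh_fdr(p))
    return q, pi0


def pvalue_diagnostics(p, n_bins: int = 20) -> PValueDiagnostics:
    """Histogram of the P-value distribution plus the pi0 estimate."""
    p = np.asarray(p, dtype=float)
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    pi0 = estimate_pi0(p) if p.size >= 10 else 1.0
    return PValueDiagnostics(bin_edges=edges, counts=counts, pi0=pi0)


def run_contrast(
    table: AbundanceTable,
    metadata: SampleMetadata,
    t1: str,
    t2: str,
    spec: FoldChangeSpec,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired Wilcoxon test for every feature between two time points.

    ``table`` holds relative abundances (already feature-filtered) for the
    samples of both time points.  Returns one row per feature with columns
    ``feature_id, contrast, n_pairs, median_log2fc, W, p, q_bh, q_storey,
    significant``, sorted by P with stable tie order by feature id.
    Significance uses the fixed unadjusted cutoff ``p < alpha``, with the
    attained FDR reported alongside rather than thresholding on q.
    """
    subjects = paired_subjects(metadata, t1, t2)
    if len(subjects) < 2:
        raise ValidationError("need at least 2 paired subjects for a contrast")
    rows_t1 = [metadata.sample_for(s, t1) for s in subjects]
    rows_t2 = [metadata.sample_for(s, t2) for s in subjects]
    m1 = table.data.loc[rows_t1].to_numpy()
    m2 = table.data.loc[rows_t2].to_numpy()

    contrast = f"{t1}->{t2}"
    records = []
    for j, feature in enumerate(table.feature_ids):
        res = wilcoxon_signed_rank(m1[:, j], m2[:, j])
        _, med = log2_fold_change(m1[:, j], m2[:, j], spec)
        records.append(
            {
                "feature_id": feature,
                "contrast": contrast,
                "n_pairs": len(subjects),
                "median_log2fc": med,
                "W": res.W,
                "p": res.p,
            }
        )
    out = pd.DataFrame.from_records(records)
    out["q_bh"] = bh_fdr(out["p"].to_numpy())
    if len(out) >= 10:
        out["q_storey"] = storey_q(out["p"].to_numpy())[0]
    else:
        # too few tests for a stable pi0 estimate; fall back to pi0 = 1
        out["q_storey"] = out["q_bh"]
    out["significant"] = out["p"] < alpha
    out = out.sort_values(["p", "feature_id"], kind="mergesort").reset_index(drop=True)
    return out[RESULT_COLUMNS]
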