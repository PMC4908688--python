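"""Community-level ordination and distance-based variance decomposition.

PCA is performed on log10-transformed relative abundances.  PERMANOVA
partitions the variability of a Canberra distance matrix by sample
covariates, with significance assessed by permuting sample labels
(pseudo-F, 10,000 permutations by default).  Covariates are tested
marginally — one single-covariate model each — because sequential
sums of squares depend on term order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import canberra as _scipy_canberra, pdist, squareform
from sklearn.decomposition import PCA

from .differential import bh_fdr
from .profiles import AbundanceTable, SampleMetadata, ValidationError

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "log10_transform",
    "pca",
    "canberra",
    "canberra_matrix",
    "permanova",
    "permanova_screen",
]


@dataclass
class OrdinationResult:
    """Per-sample principal-component coordinates and explained variance."""

    coordinates: pd.DataFrame  # samples x components, columns PC1, PC2, ...
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x components


@dataclass
class PermanovaResult:
    covariate: str
    pseudo_f: float
    r2: float
    p: float
    n_samples: int
    n_perm: int
    q_bh: float | None = None


def log10_transform(table: AbundanceTable, eps: float) -> pd.DataFrame:
    """Entrywise log10(x + eps) of the relative abundances."""
    if not eps > 0:
        raise ValidationError("pseudo-count must be > 0")
    return np.log10(table.data + eps)


def pca(matrix: pd.DataFrame | np.ndarray, n_components: int | None = None) -> OrdinationResult:
    """Principal component analysis of a samples x features matrix.

    Columns are centered; components come from the sample covariance
    spectrum.  Sign convention: within each component the loading of
    largest magnitude is made positive, so results are deterministic.
    """
    X = pd.DataFrame(matrix)
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(X.to_numpy())
    comps = model.components_  # k x features
    for i in range(comps.shape[0]):
        j = int(np.abs(comps[i]).argmax())
        if comps[i, j] < 0:
            comps[i] *= -1.0
            coords[:, i] *= -1.0
    names = [f"PC{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=X.index, columns=names),
        explained_variance_ratio=model.explained_variance_ratio_,
        loadings=pd.DataFrame(comps.T, index=X.columns, columns=names),
    )


def canberra(u, v) -> float:
    """Canberra distance: sum of |u_i - v_i| / (|u_i| + |v_i|).

    Coordinates that are zero in both vectors contribute nothing.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError("canberra requires equal-length vectors")
    return float(_scipy_canberra(u, v))


def canberra_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Symmetric Canberra distance matrix over the table's samples."""
    d = squareform(pdist(table.data.to_numpy(), metric="canberra"))
    return pd.DataFrame(d, index=table.data.index, columns=table.data.index)


def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist**2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _hat_matrix(covariate: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection onto the single-covariate design (with intercept).

    Categorical covariates are one-hot coded; numeric covariates enter as
    a centered column.  Returns (H, df_model).
    """
    n = covariate.shape[0]
    if covariate.dtype.kind in "ifu" and np.unique(covariate).size > 2:
        x = covariate.astype(float)
        X = np.column_stack([np.ones(n), x - x.mean()])
    else:
        levels, codes = np.unique(covariate, return_inverse=True)
        if levels.size < 2:
            raise ValidationError("constant covariate")
        X = np.zeros((n, levels.size))
        X[np.arange(n), codes] = 1.0
    q, r = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * abs(r[0, 0])))
    q = q[:, :rank]
    return q @ q.T, rank - 1


def permanova(
    dist: pd.DataFrame | np.ndarray,
    covariate,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    name: str = "covariate",
) -> PermanovaResult:
    """One-covariate PERMANOVA on a distance matrix.

    Decomposes the Gower-centered inner-product matrix against the
    covariate's design.  P = (1 + #{permuted F >= observed F}) / (n_perm + 1),
    permuting the covariate's sample labels.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    cov = np.asarray(covariate)
    if cov.shape[0] != n:
        raise ValidationError("covariate length does not match distance matrix")

    G = _gower_center(D)
    H, df_model = _hat_matrix(cov)
    if df_model < 1:
        raise ValidationError("constant covariate")
    ss_total = np.float64(np.trace(G))
    df_resid = n - df_model - 1
    tiny = 1e-12 * abs(ss_total)

    def pseudo_f(ss_m: np.float64) -> np.float64:
        # residual SS may round to a tiny negative under perfect separation;
        # clip so the statistic becomes +inf rather than a huge negative
        ss_r = max(ss_total - ss_m, np.float64(0.0))
        if ss_r <= tiny:
            return np.float64(np.inf)
        return (ss_m / df_model) / (ss_r / df_resid)

    ss_model = np.sum(G * H)  # trace(HGH) = trace(GH), H idempotent
    f_obs = pseudo_f(ss_model)
    r2 = float(np.clip(ss_model / ss_total, 0.0, 1.0))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # trace(G_perm H) with G_perm = P^T G P equals sum over the permuted view
    hits = 0
    f_tol = 1e-10 * abs(f_obs) if np.isfinite(f_obs) else 0.0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = G[np.ix_(perm, perm)]
        f_perm = pseudo_f(np.sum(gp * H))
        # tolerance: a permutation reproducing the observed grouping must
        # count as a tie despite roundoff in the permuted trace
        if f_perm >= f_obs - f_tol:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermanovaResult(
        covariate=name, pseudo_f=float(f_obs), r2=r2, p=p, n_samples=n, n_perm=n_perm
    )


def permanova_screen(
    dist: pd.DataFrame,
    metadata: SampleMetadata,
    covariates: list[str],
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Marginal PERMANOVA per covariate, BH-corrected across the screen.

    Samples with a missing value for a covariate are dropped for that
    covariate only (the distance submatrix is used).
    """
    if not covariates:
        raise ValidationError("empty covariate list")
    if not isinstance(dist, pd.DataFrame):
        raise ValidationError("screen requires a labeled distance matrix")
    meta = metadata.frame.set_index("sample_id")
    rng = np.random.default_rng(seed)
    results: list[PermanovaResult] = []
    for cov_name in covariates:
        if cov_name not in meta.columns:
            raise ValidationError(f"covariate {cov_name!r} not in metadata")
        values = meta.loc[dist.index, cov_name]
        ok = values.notna()
        sub = dist.loc[ok.values, ok.values]
        res = permanova(
            sub.to_numpy(),
            values[ok.values].to_numpy(),
            n_perm=n_perm,
            seed=rng,
            name=cov_name,
        )
        results.append(res)
    frame = pd.DataFrame(
        {
            "covariate": [r.covariate for r in results],
            "pseudo_f": [r.pseudo_f for r in results],
            "r2": [r.r2 for r in results],
            "p": [r.p for r in results],
            "n_samples": [r.n_samples for r in results],
            "n_perm": [r.n_perm for r in results],
        }
    )
    frame["q_bh"] = bh_fdr(frame["p"].to_numpy())
    return frame
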