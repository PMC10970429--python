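"""Unsigned weighted co-expression network construction.

From a peptides x animals log2-intensity matrix the network is built in
three steps shared with the WGCNA lineage:

* similarity  ``s_ij = |cor(x_i, x_j)|`` (pairwise-complete Pearson),
* adjacency   ``a_ij = s_ij ** beta`` with the soft-threshold power beta
  chosen so the connectivity distribution approximates a power law
  (scale-free topology criterion), and
* topological overlap
  ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
  with ``k_i = sum_{u != i} a_iu``; TOM dissimilarity is ``1 - TOM``.

All matrices are returned as labelled square pandas DataFrames with unit
diagonal (zero diagonal for the dissimilarity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScaleFreeFit",
    "drop_unusable_peptides",
    "similarity_matrix",
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom_similarity",
    "tom_dissimilarity",
]

MIN_SHARED_OBS = 4


@dataclass(frozen=True)
class ScaleFreeFit:
    """Scale-free topology fit for one soft-threshold power.

    ``r_squared`` is signed: the R^2 of the binned log-log regression when
    the slope is negative (the scale-free direction), its negation
    otherwise.  ``reliable`` is False when fewer than 3 non-empty bins
    supported the fit.
    """

    beta: int
    r_squared: float
    slope: float
    mean_k: float
    n_bins_used: int = 0

    @property
    def reliable(self) -> bool:
        return self.n_bins_used >= 3


def drop_unusable_peptides(
    X: pd.DataFrame, min_observed: int = MIN_SHARED_OBS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove peptide rows that cannot enter a correlation.

    Rows with fewer than ``min_observed`` observed values or zero variance
    across observed animals are dropped.  Returns (kept matrix, drop log
    with columns peptide_id/reason).
    """
    n_obs = X.notna().sum(axis=1)
    variances = X.var(axis=1, ddof=0)
    too_few = n_obs < min_observed
    flat = ~too_few & (variances.fillna(0.0) == 0.0)
    reasons = []
    for pid in X.index[too_few]:
        reasons.append((pid, "fewer_than_%d_observed" % min_observed))
    for pid in X.index[flat]:
        reasons.append((pid, "zero_variance"))
    drop_log = pd.DataFrame(reasons, columns=["peptide_id", "reason"])
    return X.loc[~(too_few | flat)], drop_log


def similarity_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Absolute pairwise-complete Pearson correlation between peptide rows.

    Pairs sharing fewer than 4 observed animals get similarity 0 (logged
    via a warning).  Diagonal is set to 1.
    """
    # pandas corr() on the transposed matrix is pairwise-complete Pearson.
    S = X.T.corr(method="pearson", min_periods=MIN_SHARED_OBS).abs()
    n_bad = int(np.isnan(S.to_numpy()).sum()) - int(np.isnan(np.diag(S)).sum())
    if n_bad > 0:
        warnings.warn(
            f"{n_bad} peptide pairs share < {MIN_SHARED_OBS} observations; "
            "their similarity was set to 0",
            stacklevel=2,
        )
    S = S.fillna(0.0)
    arr = S.to_numpy()
    np.fill_diagonal(arr, 1.0)
    return pd.DataFrame(arr, index=X.index, columns=X.index)


def adjacency(S: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Soft-threshold the similarity: ``A = S ** beta`` elementwise."""
    if int(beta) != beta or beta < 1:
        raise ValueError(f"beta must be an integer >= 1, got {beta!r}")
    A = S.pow(int(beta))
    arr = A.to_numpy()
    np.fill_diagonal(arr, 1.0)
    return pd.DataFrame(arr, index=S.index, columns=S.columns)


def connectivity(A: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Whole-network connectivity ``k_i = sum_{j != i} A_ij`` (self excluded)."""
    arr = np.asarray(A, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("adjacency must be square")
    k = arr.sum(axis=1) - np.diag(arr)
    if isinstance(A, pd.DataFrame):
        return pd.Series(k, index=A.index, name="k")
    return k


def scale_free_fit(k: np.ndarray | pd.Series, n_bins: int = 10) -> ScaleFreeFit:
    """Assess whether a connectivity vector follows a power law.

    k is discretized into ``n_bins`` equal-width bins; log10 of the
    per-bin frequency is regressed on log10 of the bin-center
    connectivity (log-scale center) over non-empty bins.  A strongly negative slope with high
    R^2 indicates scale-free topology; the returned ``r_squared`` carries
    R^2 with the slope's scale-free sign convention (positive only when
    the slope is negative).
    """
    k = np.asarray(k, dtype=float)
    k = k[np.isfinite(k)]
    if k.size == 0 or np.ptp(k) == 0:
        raise ValueError("degenerate connectivity: all values equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    # the regression lives in log-log space, so each bin is represented
    # by its log-scale center (geometric mean of its edges); fall back to
    # the arithmetic midpoint when the lower edge is not positive
    lo, hi = edges[:-1], edges[1:]
    centers = np.where(lo > 0, np.sqrt(np.clip(lo, 0, None) * hi), (lo + hi) / 2.0)
    nonempty = counts > 0
    dk = centers[nonempty]
    p_dk = counts[nonempty] / k.size
    # A bin whose mean connectivity is zero cannot enter the log-log fit.
    usable = dk > 0
    dk, p_dk = dk[usable], p_dk[usable]
    if dk.size < 2:
        raise ValueError("degenerate connectivity: fewer than 2 usable bins")
    if dk.size < 3:
        warnings.warn(
            "scale-free fit used fewer than 3 bins; R^2 is unreliable",
            stacklevel=2,
        )
    x, y = np.log10(dk), np.log10(p_dk)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    signed = r2 if slope < 0 else -r2
    return ScaleFreeFit(
        beta=0,
        r_squared=float(signed),
        slope=float(slope),
        mean_k=float(k.mean()),
        n_bins_used=int(dk.size),
    )


def pick_soft_threshold(
    X: pd.DataFrame,
    beta_grid: list[int] | None = None,
    r2_threshold: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest power meeting the scale-free topology criterion.

    Returns ``(beta, table)`` where the table holds one row per candidate
    power (beta, r_squared, slope, mean_k).  If no power reaches
    ``r2_threshold``, the argmax-r_squared power is returned with a
    warning.
    """
    if beta_grid is None:
        beta_grid = list(range(1, 21))
    if len(beta_grid) == 0:
        raise ValueError("beta_grid must be nonempty")
    if not (0 < r2_threshold < 1):
        raise ValueError("r2_threshold must be in (0, 1)")

    S = similarity_matrix(X)
    rows = []
    for beta in beta_grid:
        k = connectivity(adjacency(S, beta))
        try:
            fit = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            rows.append((beta, np.nan, np.nan, float(np.mean(k))))
            continue
        rows.append((beta, fit.r_squared, fit.slope, fit.mean_k))
    table = pd.DataFrame(rows, columns=["beta", "r_squared", "slope", "mean_k"])

    ok = table[table["r_squared"] >= r2_threshold]
    if len(ok):
        chosen = int(ok["beta"].iloc[0])
    else:
        chosen = int(table.loc[table["r_squared"].idxmax(), "beta"])
        warnings.warn(
            f"no power reached scale-free R^2 >= {r2_threshold}; "
            f"using argmax beta={chosen}",
            stacklevel=2,
        )
    return chosen, table


def _check_symmetric(arr: np.ndarray, tol: float = 1e-9) -> None:
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(arr, arr.T, atol=tol, rtol=0):
        raise ValueError(f"matrix is asymmetric beyond {tol}")


def tom_similarity(A: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap of a weighted adjacency matrix.

    For i != j, with ``k_i`` the self-excluded connectivity::

        TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    and ``TOM_ii = 1``.  The numerator's cross term is computed in matrix
    form as ``(A @ A)_ij - a_ii a_ij - a_ij a_jj``.
    """
    arr = np.asarray(A, dtype=float)
    _check_symmetric(arr)
    diag = np.diag(arr).copy()
    k = arr.sum(axis=1) - diag
    cross = arr @ arr
    # remove the u == i and u == j terms from the full sum over u
    cross = cross - diag[:, None] * arr - arr * diag[None, :]
    numer = cross + arr
    denom = np.minimum.outer(k, k) + 1.0 - arr
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    # clip tiny fp excursions
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(A, pd.DataFrame):
        return pd.DataFrame(tom, index=A.index, columns=A.columns)
    return tom


def tom_dissimilarity(TOM: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """``D = 1 - TOM`` elementwise with zero diagonal."""
    D = 1.0 - np.asarray(TOM, dtype=float)
    np.fill_diagonal(D, 0.0)
    if isinstance(TOM, pd.DataFrame):
        return pd.DataFrame(D, index=TOM.index, columns=TOM.columns)
    return D
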