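"""Relating peptides and modules to the learning index.

Peptide significance (PS) is the marginal Pearson correlation of a
peptide's log2-intensity profile with the learning index; module
significance averages |PS| over a module's members.  Standard peptide
screening filters the intensity matrix on |PS| before network
construction.  Network screening (NS) blends the marginal signal with the
module-level signal:

    NS_i = alpha * |cor(x_i, y)|
         + (1 - alpha) * |cor(ME_m(i), y)| * |kME_i|

for peptides in non-grey modules (grey peptides keep only the marginal
term).  The blend is this package's reconstruction of the named
procedure; alpha defaults to 0.5.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .modules import GREY

__all__ = [
    "peptide_significance",
    "standard_peptide_screening",
    "module_significance",
    "network_screening",
]


def _pairwise_cor_with_trait(X: pd.DataFrame, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Per-row Pearson r with y over pairwise-complete animals, plus n used."""
    yv = y.loc[X.columns].to_numpy(dtype=float)
    rs = np.empty(len(X))
    ns = np.empty(len(X), dtype=int)
    for i, (_, row) in enumerate(X.iterrows()):
        x = row.to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(yv)
        ns[i] = int(ok.sum())
        if ns[i] < 4 or np.std(x[ok]) == 0:
            rs[i] = np.nan
            continue
        rs[i] = np.corrcoef(x[ok], yv[ok])[0, 1]
    return rs, ns


def peptide_significance(X: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    """Marginal Pearson correlation of each peptide with the learning index.

    Returns a DataFrame indexed by peptide with columns ``cor`` (signed r),
    ``p_value`` (two-sided, t distribution with n-2 df) and ``n``.
    Requires a non-constant index observed for >= 4 animals per peptide.
    """
    yv = y.loc[X.columns].to_numpy(dtype=float)
    if np.std(yv) == 0:
        raise ValueError("learning index is constant; correlations undefined")
    rs, ns = _pairwise_cor_with_trait(X, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rs * np.sqrt((ns - 2) / (1.0 - rs**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(ns - 2, 1))
    p = np.where(np.isclose(np.abs(rs), 1.0), 0.0, p)
    out = pd.DataFrame({"cor": rs, "p_value": p, "n": ns}, index=X.index)
    out.index.name = "peptide_id"
    return out


def standard_peptide_screening(
    X: pd.DataFrame, y: pd.Series, threshold: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain peptides whose |cor with learning index| meets the threshold.

    Returns (filtered matrix, screening table with a ``passed`` column).
    An empty result is a warning, not an error.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    table = peptide_significance(X, y)
    # 1e-12 slack so exactly collinear peptides survive a threshold of 1.0
    table["passed"] = table["cor"].abs() >= threshold - 1e-12
    kept = X.loc[table.index[table["passed"].fillna(False)]]
    if kept.empty:
        warnings.warn("screening retained no peptides", stacklevel=2)
    return kept, table


def module_significance(
    screening: pd.DataFrame, assignment: pd.Series
) -> pd.Series:
    """Mean |peptide significance| per non-grey module."""
    shared = screening.index.intersection(assignment.index)
    abs_r = screening.loc[shared, "cor"].abs()
    labels = assignment.loc[shared]
    ms = abs_r.groupby(labels).mean()
    ms = ms.drop(index=GREY, errors="ignore")
    ms.name = "module_significance"
    return ms.sort_values(ascending=False)


def network_screening(
    X: pd.DataFrame,
    y: pd.Series,
    ME: pd.DataFrame,
    assignment: pd.Series,
    membership: pd.DataFrame,
    alpha: float = 0.5,
    top_k: int = 30,
) -> pd.DataFrame:
    """Blend marginal and module-level evidence into one peptide ranking.

    Returns peptides sorted by descending NS with columns ``ns``,
    ``abs_cor``, ``module``, ``kme_own``, ``rank`` and a boolean
    ``top`` flag for the first ``top_k``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    ps = peptide_significance(X, y)
    abs_cor = ps["cor"].abs()

    yv = y.loc[ME.columns].to_numpy(dtype=float)
    me_trait = {}
    for m in ME.index:
        me_trait[m] = abs(float(np.corrcoef(ME.loc[m].to_numpy(), yv)[0, 1]))

    rows = []
    for pid in X.index:
        m = assignment.get(pid, GREY)
        marginal = float(abs_cor.get(pid, np.nan))
        if m != GREY and m in ME.index:
            kme = float(membership.loc[pid, m])
            ns = alpha * marginal + (1 - alpha) * me_trait[m] * abs(kme)
        else:
            kme = np.nan
            ns = alpha * marginal
        rows.append((pid, ns, marginal, m, kme))
    out = pd.DataFrame(
        rows, columns=["peptide_id", "ns", "abs_cor", "module", "kme_own"]
    ).set_index("peptide_id")
    out = out.sort_index().sort_values("ns", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    out["top"] = out["rank"] <= top_k
    return out
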