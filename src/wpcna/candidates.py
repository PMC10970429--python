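"""Candidate phosphopeptide prioritization.

Two complementary routes identify peptides that may explain a learning
deficit:

* **Individual level** — for a focal (outlier) animal, the cumulative
  distance of each peptide's intensity from three comparison-group means,

      CumDist = (I0 - avg I_bt) + (I0 - avg I_st) + (I0 - avg I_sn),

  sorted by magnitude within the learning-relevant modules; the top 10
  are candidates.
* **Group level** — pooled-variance two-sample t-tests across five
  genotype x exposure contrasts; within each contrast peptides are ranked
  by |log2 fold change| and by -log10 p (1 = most extreme), and the
  integrative rank sums all 10 ranks (5 contrasts x 2 ranks).  Low sums
  flag blast-relevant peptides.

TOM edges above a threshold are exported for network visualization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .modules import GREY

__all__ = [
    "DEFAULT_CONTRASTS",
    "cumulative_distance",
    "cumulative_distance_table",
    "rank_candidate_peptides",
    "group_de",
    "integrative_rank",
    "export_tom_edges",
]

DEFAULT_CONTRASTS = (
    ("rTg4510-blast", "rTg4510-sham"),
    ("nc-blast", "nc-sham"),
    ("rTg4510-blast", "nc-blast"),
    ("rTg4510-blast", "nc-sham"),
    ("rTg4510-sham", "nc-sham"),
)


def cumulative_distance(
    i0: float, mean_bt: float, mean_st: float, mean_sn: float
) -> float:
    """Signed sum of the focal intensity's distances to three group means."""
    for v in (i0, mean_bt, mean_st, mean_sn):
        if not np.isfinite(v):
            raise ValueError("cumulative distance needs finite inputs")
    return (i0 - mean_bt) + (i0 - mean_st) + (i0 - mean_sn)


def cumulative_distance_table(
    X: pd.DataFrame,
    metadata: pd.DataFrame,
    focal_animal: str,
    comparison_groups: tuple[str, str, str] = (
        "rTg4510-blast",
        "rTg4510-sham",
        "nc-sham",
    ),
    exclude_focal_from_own_group: bool = True,
) -> pd.DataFrame:
    """Per-peptide cumulative distance of one focal animal from group means.

    Group means are taken over the animals metadata assigns to each
    comparison group; by default the focal animal is excluded from its
    own group's mean.  Peptides with a missing focal intensity are
    skipped (logged via warning).
    """
    if focal_animal not in X.columns:
        raise KeyError(f"focal animal {focal_animal!r} not in intensity matrix")
    group_members = {}
    for g in comparison_groups:
        members = metadata.index[metadata["group"] == g].tolist()
        if exclude_focal_from_own_group and focal_animal in members:
            members = [a for a in members if a != focal_animal]
        if not members:
            raise ValueError(f"comparison group {g!r} has no animals")
        group_members[g] = members

    i0 = X[focal_animal]
    missing = i0.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} peptides missing in focal animal were skipped",
            stacklevel=2,
        )
    means = {g: X[m].mean(axis=1) for g, m in group_members.items()}
    g1, g2, g3 = comparison_groups
    cumdist = 3.0 * i0 - (means[g1] + means[g2] + means[g3])
    out = pd.DataFrame(
        {
            "i0": i0,
            "mean_bt": means[g1],
            "mean_st": means[g2],
            "mean_sn": means[g3],
            "cumdist": cumdist,
            "abs_cumdist": cumdist.abs(),
        }
    ).loc[~missing]
    out.index.name = "peptide_id"
    return out


def rank_candidate_peptides(
    table: pd.DataFrame,
    assignment: pd.Series,
    modules_of_interest: list[str],
    top_n: int = 10,
) -> pd.DataFrame:
    """Top candidates by |cumulative distance| within selected modules.

    Ties break lexicographically on peptide id for determinism.  The
    ``direction`` column marks whether the focal animal's intensity is
    increased or decreased relative to the comparison groups.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    members = assignment.index[assignment.isin(modules_of_interest)]
    sub = table.loc[table.index.intersection(members)].copy()
    sub["module"] = assignment.loc[sub.index]
    sub = sub.sort_index().sort_values(
        "abs_cumdist", ascending=False, kind="mergesort"
    )
    sub["direction"] = np.where(sub["cumdist"] >= 0, "increased", "decreased")
    return sub.head(top_n)


def group_de(
    X: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    effect: str = "mean_difference",
) -> pd.DataFrame:
    """Pooled-variance two-sample t-test for one group contrast.

    ``effect`` selects the log2 fold-change column: "mean_difference"
    (difference of group means of log2 intensities, the default) or
    "mean_ratio" (ratio of group mean log2 intensities).  Peptides with
    fewer than 2 observations in either group yield NA rows.  Degenerate
    zero-variance shifts get p = 0 and a flag.
    """
    group_a, group_b = contrast
    a_ids = metadata.index[metadata["group"] == group_a]
    b_ids = metadata.index[metadata["group"] == group_b]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError(f"contrast {contrast} needs >= 2 animals per group")
    A = X[a_ids].to_numpy(dtype=float)
    B = X[b_ids].to_numpy(dtype=float)

    rows = []
    for i, pid in enumerate(X.index):
        a = A[i][np.isfinite(A[i])]
        b = B[i][np.isfinite(B[i])]
        if len(a) < 2 or len(b) < 2:
            rows.append((pid, np.nan, np.nan, np.nan, np.nan, "insufficient_obs"))
            continue
        ma, mb = float(a.mean()), float(b.mean())
        if effect == "mean_difference":
            fc = ma - mb
        elif effect == "mean_ratio":
            fc = ma / mb if mb != 0 else np.nan
        else:
            raise ValueError(f"unknown effect {effect!r}")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            p = 1.0 if ma == mb else 0.0
            rows.append((pid, fc, p, ma, mb, "zero_variance"))
            continue
        _, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append((pid, fc, float(p), ma, mb, ""))
    out = pd.DataFrame(
        rows, columns=["peptide_id", "log2fc", "p_value", "mean_a", "mean_b", "flag"]
    ).set_index("peptide_id")
    out.attrs["contrast"] = contrast
    return out


def integrative_rank(
    de_tables: dict[str, pd.DataFrame],
    peptides: pd.Index | list[str],
    top_k: int = 40,
    require_five: bool = True,
) -> pd.DataFrame:
    """Sum per-contrast ranks by |log2fc| and -log10 p into one ordering.

    Within each contrast (rank set) peptides are ranked descending by
    |log2fc| and descending by -log10 p, rank 1 = most extreme, ties get
    average ranks.  The integrative rank is the sum of all ranks (5
    contrasts x 2 = 10 with the default design); smaller is stronger.
    """
    if require_five and len(de_tables) != 5:
        raise ValueError(
            f"expected exactly 5 contrasts, got {len(de_tables)} "
            "(pass require_five=False to override)"
        )
    peptides = pd.Index(peptides)
    out = pd.DataFrame(index=peptides.sort_values())
    total = np.zeros(len(out))
    for name, table in de_tables.items():
        sub = table.loc[out.index]
        rank_fc = sub["log2fc"].abs().rank(ascending=False, method="average")
        # -log10 p descending == p ascending; rank on p directly so the
        # ordering depends only on the order of p-values
        rank_p = sub["p_value"].rank(ascending=True, method="average")
        out[f"rank_fc_{name}"] = rank_fc
        out[f"rank_p_{name}"] = rank_p
        total += rank_fc.to_numpy() + rank_p.to_numpy()
    out["integrative_rank"] = total
    out = out.sort_values("integrative_rank", kind="mergesort")
    out["top"] = np.arange(1, len(out) + 1) <= top_k
    out.index.name = "peptide_id"
    return out


def export_tom_edges(
    TOM: pd.DataFrame,
    assignment: pd.Series,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Undirected edge list of peptide pairs with TOM strictly above threshold.

    Each edge appears once (source < target lexicographic position) with
    both endpoints' module labels, ready for import into network
    visualization tools.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    arr = TOM.to_numpy(dtype=float)
    ids = list(TOM.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = arr[iu, ju] > threshold
    rows = [
        (
            ids[i],
            ids[j],
            float(arr[i, j]),
            assignment.get(ids[i], GREY),
            assignment.get(ids[j], GREY),
        )
        for i, j in zip(iu[keep], ju[keep])
    ]
    return pd.DataFrame(
        rows, columns=["source", "target", "weight", "source_module", "target_module"]
    )
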