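"""Module detection on the topological-overlap dendrogram.

Peptides are clustered by average-linkage hierarchical clustering of the
TOM dissimilarity; modules are read off the tree with one of three cut
strategies:

* **static** — a single horizontal cut at a fixed height; clusters below
  the minimum size become "grey" (unassigned),
* **dynamic tree** — after a high static pre-cut, each cluster's branch is
  recursively split wherever the merge-height profile shows a pronounced
  drop-then-rise fluctuation (controlled by ``deep_split``), using the
  dendrogram alone,
* **dynamic hybrid** — the dynamic-tree cores plus a PAM-like stage that
  attaches grey peptides to the nearest module when their average
  dissimilarity to its members falls within the module's joining radius.

Each module is summarized by its eigenpeptide: the first right singular
vector of the standardized module block over animals — one signed score
per animal per module.  Module membership kME(i, m) = cor(x_i, ME_m).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MODULE_COLORS",
    "GREY",
    "peptide_tree",
    "cut_static",
    "cut_dynamic_tree",
    "cut_dynamic_hybrid",
    "assign_colors",
    "module_eigenpeptides",
    "module_membership",
    "eigenpeptide_dendrogram",
    "mds_embed",
]

GREY = "grey"

# WGCNA-style palette: labels assigned by decreasing module size so the
# largest module is always "turquoise".
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta",
)


def _as_condensed(D: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list]:
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("dissimilarity must be square")
    ids = list(D.index) if isinstance(D, pd.DataFrame) else list(range(arr.shape[0]))
    return squareform(arr, checks=False), ids


def peptide_tree(
    D: pd.DataFrame | np.ndarray, linkage_method: str = "average"
) -> tuple[np.ndarray, list]:
    """Agglomerative tree over peptides from TOM dissimilarity.

    Returns (scipy linkage matrix, leaf ids in input order).  Linkage is
    average by default; complete is the alternative used for the
    eigenpeptide display in some analyses.
    """
    if linkage_method not in ("average", "complete"):
        raise ValueError("linkage_method must be 'average' or 'complete'")
    condensed, ids = _as_condensed(D)
    return linkage(condensed, method=linkage_method), ids


def _label_from_clusters(
    ids: list, flat: np.ndarray, min_size: int
) -> pd.Series:
    labels = pd.Series(flat, index=ids).astype(object)
    sizes = labels.value_counts()
    small = sizes[sizes < min_size].index
    labels[labels.isin(small)] = GREY
    return labels


def cut_static(
    tree: np.ndarray,
    ids: list,
    cut_height: float,
    min_size: int = 20,
) -> pd.Series:
    """Flat clusters from one horizontal cut; small clusters become grey."""
    max_h = float(tree[:, 2].max()) if len(tree) else 0.0
    if not 0 < cut_height:
        raise ValueError("cut_height must be positive")
    if max_h > 0 and cut_height >= max_h:
        warnings.warn("cut_height at or above tree top: single cluster", stacklevel=2)
    flat = fcluster(tree, t=cut_height, criterion="distance")
    return assign_colors(_label_from_clusters(ids, flat, min_size))


class _Node:
    __slots__ = ("leaves", "height", "children", "min_merge")

    def __init__(self, leaves, height, children, min_merge):
        self.leaves = leaves  # list of leaf indices
        self.height = height  # merge height at this node (0 for leaves)
        self.children = children  # (left, right) or None
        self.min_merge = min_merge  # lowest merge height in the subtree


def _build_nodes(tree: np.ndarray, n: int) -> list[_Node]:
    nodes = [_Node([i], 0.0, None, np.inf) for i in range(n)]
    for left_id, right_id, height, _ in tree:
        left, right = nodes[int(left_id)], nodes[int(right_id)]
        min_merge = min(float(height), left.min_merge, right.min_merge)
        nodes.append(
            _Node(left.leaves + right.leaves, float(height), (left, right), min_merge)
        )
    return nodes


def _split_branch(node: _Node, tau: float, min_size: int, out: list) -> None:
    """Recursive fluctuation split.

    The merge-height profile of a branch that contains two real modules
    drops sharply below the branch's own merge height and rises again
    inside each child.  The branch is split when that drop — the gap
    between its merge height and the taller child's internal height —
    exceeds ``tau`` as a fraction of the branch's merge height, and at
    least one child is large enough to be a module.
    """
    if node.children is None or len(node.leaves) < min_size:
        out.append(node.leaves)
        return
    left, right = node.children
    child_h = max(left.height, right.height)
    gap = (node.height - child_h) / node.height if node.height > 0 else 0.0
    big_children = sum(len(c.leaves) >= min_size for c in (left, right))
    if gap >= tau and big_children >= 1:
        _split_branch(left, tau, min_size, out)
        _split_branch(right, tau, min_size, out)
    else:
        out.append(node.leaves)


def cut_dynamic_tree(
    tree: np.ndarray,
    ids: list,
    min_size: int = 20,
    deep_split: int = 2,
    cut_height: float | None = None,
) -> pd.Series:
    """Adaptive top-down branch decomposition using dendrogram heights only.

    A static pre-cut just below the tree top (99% of the maximum merge
    height unless ``cut_height`` is given) yields initial clusters; each
    is then recursively split wherever the drop between a branch's merge
    height and its children's internal heights exceeds
    ``tau = 0.9 - 0.2 * deep_split`` as a fraction of the branch's merge
    height.  Higher ``deep_split`` (0-3) splits more aggressively.
    Branches below ``min_size`` end up grey.
    """
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    if deep_split not in (0, 1, 2, 3):
        raise ValueError("deep_split must be in {0, 1, 2, 3}")
    n = len(ids)
    tau = 0.9 - 0.2 * deep_split
    max_h = float(tree[:, 2].max()) if len(tree) else 0.0
    if cut_height is None:
        cut_height = 0.99 * max_h
    flat = fcluster(tree, t=cut_height, criterion="distance")

    nodes = _build_nodes(tree, n)
    # Each pre-cut cluster is a subtree; its root is the largest node whose
    # leaves all carry the same flat label.
    pure: list[int | None] = [int(flat[i]) for i in range(n)] + [None] * len(tree)
    roots: dict[int, _Node] = {}
    for i in range(n):
        roots[pure[i]] = nodes[i]
    for j, (a, b, _, _) in enumerate(tree, start=n):
        la, lb = pure[int(a)], pure[int(b)]
        pure[j] = la if (la == lb and la is not None) else None
        if pure[j] is not None:
            roots[pure[j]] = nodes[j]

    clusters: list[list[int]] = []
    for root in roots.values():
        out: list[list[int]] = []
        _split_branch(root, tau, min_size, out)
        clusters.extend(out)

    labels = np.zeros(n, dtype=int)
    for label, leaves in enumerate(clusters, start=1):
        labels[np.asarray(leaves, dtype=int)] = label
    return assign_colors(_label_from_clusters(ids, labels, min_size))


def cut_dynamic_hybrid(
    tree: np.ndarray,
    ids: list,
    D: pd.DataFrame | np.ndarray,
    min_size: int = 20,
    deep_split: int = 2,
    pam_stage: bool = True,
    cut_height: float | None = None,
) -> pd.Series:
    """Dynamic-tree cores plus PAM-like rescue of unassigned peptides.

    Each grey peptide is attached to the module with the smallest average
    dissimilarity to the module's members, provided that distance lies
    within the module's joining radius (the largest average
    within-module distance of any current member).
    """
    cores = cut_dynamic_tree(tree, ids, min_size=min_size, deep_split=deep_split,
                             cut_height=cut_height)
    if not pam_stage:
        return cores
    arr = np.asarray(D, dtype=float)
    labels = cores.copy()
    module_names = [m for m in labels.unique() if m != GREY]
    if not module_names:
        return labels
    pos = {pid: i for i, pid in enumerate(ids)}
    member_idx = {
        m: np.array([pos[p] for p in labels.index[labels == m]]) for m in module_names
    }
    radius = {}
    for m, idx in member_idx.items():
        sub = arr[np.ix_(idx, idx)]
        # joining radius: typical member-to-co-member average distance
        avg = (sub.sum(axis=1)) / max(len(idx) - 1, 1)
        radius[m] = float(avg.mean())
    for pid in labels.index[labels == GREY]:
        i = pos[pid]
        dists = {m: float(arr[i, idx].mean()) for m, idx in member_idx.items()}
        best = min(dists, key=dists.get)
        if dists[best] <= radius[best]:
            labels[pid] = best
    return labels


def assign_colors(labels: pd.Series) -> pd.Series:
    """Rename raw cluster labels to size-ordered color names.

    The largest module becomes "turquoise", the next "blue", and so on;
    grey stays grey.  Ties in size break by first appearance for
    determinism.
    """
    non_grey = labels[labels != GREY]
    if non_grey.empty:
        return labels.astype(object)
    sizes = non_grey.value_counts()  # sorted desc, stable for ties
    if len(sizes) > len(MODULE_COLORS):
        palette = list(MODULE_COLORS) + [
            f"module{i}" for i in range(len(MODULE_COLORS), len(sizes))
        ]
    else:
        palette = list(MODULE_COLORS)
    mapping = {old: palette[rank] for rank, old in enumerate(sizes.index)}
    mapping[GREY] = GREY
    out = labels.map(mapping)
    out.name = "module"
    return out


def _standardize_rows(X: pd.DataFrame) -> pd.DataFrame:
    """Impute missing cells with the peptide's mean, then z-score each row."""
    Z = X.apply(lambda row: row.fillna(row.mean()), axis=1)
    mu = Z.mean(axis=1)
    sd = Z.std(axis=1, ddof=1)
    sd = sd.replace(0.0, 1.0)
    return Z.sub(mu, axis=0).div(sd, axis=0)


def module_eigenpeptides(
    X: pd.DataFrame, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First-principal-component summary of each module over animals.

    Rows of ``X`` are mean-imputed and standardized, then each non-grey
    module block is decomposed by SVD; the eigenpeptide is the leading
    right singular vector (unit norm, zero mean across animals),
    sign-oriented so that it correlates positively with the module's mean
    profile.  Returns (ME table: modules x animals, variance-explained
    Series per module).
    """
    Z = _standardize_rows(X)
    modules = [m for m in assignment.unique() if m != GREY]
    scores = {}
    varexp = {}
    for m in sorted(modules):
        members = assignment.index[assignment == m]
        block = Z.loc[members].to_numpy(dtype=float)
        if block.shape[0] == 1:
            warnings.warn(
                f"module {m!r} has a single peptide; returning its "
                "standardized profile",
                stacklevel=2,
            )
            v = block[0] / np.linalg.norm(block[0])
            scores[m] = v
            varexp[m] = 1.0
            continue
        _, s, vt = np.linalg.svd(block, full_matrices=False)
        me = vt[0]
        mean_profile = block.mean(axis=0)
        if np.dot(me, mean_profile) < 0:
            me = -me
        scores[m] = me
        varexp[m] = float(s[0] ** 2 / np.sum(s**2))
    ME = pd.DataFrame(scores, index=X.columns).T
    ME.index.name = "module"
    return ME, pd.Series(varexp, name="variance_explained")


def module_membership(X: pd.DataFrame, ME: pd.DataFrame) -> pd.DataFrame:
    """kME(i, m) = Pearson cor(x_i, ME_m) for every peptide x module."""
    if not X.columns.equals(ME.columns):
        raise ValueError("animal columns of X and ME must align")
    Z = _standardize_rows(X)
    zx = Z.to_numpy(dtype=float)
    zx = (zx - zx.mean(axis=1, keepdims=True))
    zx /= np.where(
        np.linalg.norm(zx, axis=1, keepdims=True) == 0,
        1.0,
        np.linalg.norm(zx, axis=1, keepdims=True),
    )
    me = ME.to_numpy(dtype=float)
    me = me - me.mean(axis=1, keepdims=True)
    me /= np.linalg.norm(me, axis=1, keepdims=True)
    kme = zx @ me.T
    return pd.DataFrame(kme, index=X.index, columns=ME.index)


def eigenpeptide_dendrogram(ME: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Average-linkage clustering of modules at dissimilarity 1 - cor."""
    if len(ME) < 2:
        raise ValueError("need at least 2 modules")
    corr = np.corrcoef(ME.to_numpy(dtype=float))
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    return Z, list(ME.index)


def mds_embed(D: pd.DataFrame | np.ndarray, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of a dissimilarity.

    Double-centers ``-D^2 / 2``, takes the top ``dims`` eigenvectors
    scaled by the square root of their eigenvalues.  Requested dimensions
    beyond the number of positive eigenvalues raise; negative eigenvalues
    (non-Euclidean input) are dropped with a warning.
    """
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("dissimilarity must be square")
    n = arr.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (arr**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigval[0]), 1.0)
    n_pos = int(np.sum(eigval > tol))
    if (eigval < -tol).any():
        warnings.warn(
            "dissimilarity is non-Euclidean: negative eigenvalues dropped",
            stacklevel=2,
        )
    if dims > n_pos:
        raise ValueError(
            f"requested {dims} dimensions but only {n_pos} positive eigenvalues"
        )
    coords = eigvec[:, :dims] * np.sqrt(eigval[:dims])
    ids = list(D.index) if isinstance(D, pd.DataFrame) else list(range(n))
    return pd.DataFrame(coords, index=ids, columns=[f"mds{i + 1}" for i in range(dims)])
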