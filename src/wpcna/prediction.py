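"""ROC assessment of whether module eigenpeptides predict learning level.

Learning levels are binarized (positive = level >= 4, i.e. index at or
above the cohort mean).  For each module the eigenpeptide scores across
animals are evaluated as a classifier:

* AUC by Mann-Whitney pair counting with ties contributing 1/2,
* Hanley-McNeil asymptotic standard error with
  Q1 = A / (2 - A), Q2 = 2 A^2 / (1 + A),
* 95% CI = A +/- 1.96 SE clipped to [0, 1],
* two-sided p versus AUC = 0.5 from a normal approximation with the
  standard error evaluated under the null (A = 0.5),
* K-S statistic: the maximum vertical distance between the ROC curve and
  the chance diagonal, max over thresholds of |TPR - FPR|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "binarize_level",
    "roc_analysis",
    "predict_learning",
    "logistic_fit",
]


@dataclass(frozen=True)
class ROCResult:
    module: str
    auc: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    ks: float
    n_pos: int
    n_neg: int
    flipped_auc: float | None = None  # reported when auc < 0.5


def binarize_level(levels: pd.Series, positive_threshold: int = 4) -> pd.Series:
    """Positive iff learning level >= threshold (default 4 = at/above mean)."""
    if positive_threshold not in (1, 2, 3, 4, 5):
        raise ValueError("positive_threshold must be in 1..5")
    labels = (levels >= positive_threshold).astype(bool)
    labels.name = "positive"
    return labels


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical (FPR, TPR) points sweeping thresholds high to low."""
    order = np.argsort(-scores, kind="mergesort")
    s, lab = scores[order], labels[order]
    n_pos = int(lab.sum())
    n_neg = len(lab) - n_pos
    tp = np.cumsum(lab)
    fp = np.cumsum(~lab)
    # threshold only between distinct score values
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    return fpr, tpr


def roc_analysis(
    scores: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    module: str = "",
) -> ROCResult:
    """Nonparametric ROC of a per-animal score against binary labels.

    Needs at least one positive and one negative animal.  When the AUC is
    below 0.5 the flipped-orientation AUC (1 - AUC) is also reported;
    both are retained.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if s.shape != lab.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")

    pos, neg = s[lab], s[~lab]
    # Mann-Whitney pair counting, ties count 1/2
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = float((greater + 0.5 * ties) / (n_pos * n_neg))

    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    ci = (max(auc - 1.96 * se, 0.0), min(auc + 1.96 * se, 1.0))
    se0 = _hanley_mcneil_se(0.5, n_pos, n_neg)
    z = (auc - 0.5) / se0
    p = float(2.0 * stats.norm.sf(abs(z)))

    fpr, tpr = _roc_curve(s, lab)
    ks = float(np.max(np.abs(tpr - fpr)))

    return ROCResult(
        module=module,
        auc=auc,
        se=se,
        ci95=ci,
        p_value=p,
        ks=ks,
        n_pos=n_pos,
        n_neg=n_neg,
        flipped_auc=(1.0 - auc) if auc < 0.5 else None,
    )


def predict_learning(
    ME: pd.DataFrame,
    outcomes: pd.DataFrame,
    positive_threshold: int = 4,
) -> pd.DataFrame:
    """ROC of every module eigenpeptide against binarized learning level.

    ``outcomes`` is the behavior table (animal-indexed, with ``level``).
    Returns one row per module sorted by AUC descending with K-S as the
    tiebreak.
    """
    if not set(ME.columns) <= set(outcomes.index):
        raise ValueError("every animal in ME must have an outcome")
    labels = binarize_level(outcomes.loc[ME.columns, "level"], positive_threshold)
    rows = []
    for m in ME.index:
        r = roc_analysis(ME.loc[m], labels, module=str(m))
        rows.append(
            {
                "module": r.module,
                "auc": r.auc,
                "se": r.se,
                "ci_lo": r.ci95[0],
                "ci_hi": r.ci95[1],
                "p_value": r.p_value,
                "ks": r.ks,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
            }
        )
    out = pd.DataFrame(rows).set_index("module")
    return out.sort_values(["auc", "ks"], ascending=False, kind="mergesort")


def logistic_fit(
    ME: pd.DataFrame, labels: pd.Series, modules: list[str] | None = None
) -> pd.DataFrame:
    """Multiple logistic regression of binary learning state on eigenpeptides.

    Restricted to at most 3 modules at cohort sizes around 20 animals to
    avoid quasi-complete separation; separation is detected and flagged
    rather than allowed to diverge silently.  Returns a coefficient table
    with columns coef, se, converged, separation.
    """
    import statsmodels.api as sm

    if modules is None:
        modules = list(ME.index[:3])
    if len(modules) > 3:
        raise ValueError("logistic fit offered for at most 3 modules")
    if len(labels) <= len(modules) + 1:
        raise ValueError("need more animals than coefficients")
    Xmat = sm.add_constant(ME.loc[modules].T.to_numpy(dtype=float))
    yvec = labels.loc[ME.columns].astype(int).to_numpy()

    separation = False
    converged = False
    coefs = np.full(len(modules) + 1, np.nan)
    ses = np.full(len(modules) + 1, np.nan)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(yvec, Xmat).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        coefs = res.params
        ses = res.bse
        fitted = res.predict(Xmat)
        if np.all((fitted < 1e-8) | (fitted > 1 - 1e-8)):
            separation = True
    except Exception:  # PerfectSeparationError and friends
        separation = True
    out = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
        },
        index=["intercept"] + list(modules),
    )
    out["converged"] = converged and not separation
    out["separation"] = separation
    return out
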