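"""Scoring of event rankings against truth and the clustering check.

``rank_roc_auc`` restricts a ranked call list to its top-k entries
before scoring (the fair-comparison rule: every method contributes the
same number of calls) and computes the AUC through the Mann-Whitney
rank-sum identity with mid-ranks for ties.

``clustering_discrimination`` reproduces the case-study check: cut a
hierarchical dendrogram (Euclidean distance on PSI profiles) into two
clusters, assign clusters to the case/control groups by majority, and
report sensitivity and specificity for the case group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    auc: float
    roc: pd.DataFrame  # fpr, tpr, threshold
    n_pos: int
    n_neg: int


def rank_roc_auc(
    calls: pd.DataFrame,
    truth: Mapping[str, bool],
    top_k: int | None = None,
    score_col: str = "score",
    id_col: str = "event_id",
) -> RocResult:
    """AUC of a ranked call list against planted/null truth.

    ``calls`` must be free of duplicate ids and ``truth`` must cover every
    called id.  ``top_k`` truncates the ranking (by descending score)
    before scoring; a single-class subset raises.
    """
    if calls[id_col].duplicated().any():
        raise ValueError("duplicate ids in the call list")
    missing = set(calls[id_col]) - set(truth)
    if missing:
        raise ValueError(f"truth does not cover {len(missing)} called ids")
    ranked = calls.sort_values(
        [score_col, id_col], ascending=[False, True], kind="mergesort"
    )
    if top_k is not None:
        ranked = ranked.head(top_k)
    y = np.array([bool(truth[i]) for i in ranked[id_col]])
    s = ranked[score_col].to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: truth has a single class in the top-k list")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return RocResult(auc, roc, n_pos, n_neg)


@dataclass
class ClusteringResult:
    sensitivity: float
    specificity: float
    assignments: pd.Series  # sample -> predicted group
    degenerate: bool


def clustering_discrimination(
    psi_subset: pd.DataFrame,
    group_labels: Sequence[str],
    method: str = "complete",
    case_label: str = "case",
) -> ClusteringResult:
    """Two-group discrimination of samples from their PSI profiles.

    Missing values are imputed with the event mean (clustering only);
    samples are clustered on Euclidean distance with the given linkage
    (complete or average), the tree is cut at two clusters, and each
    cluster takes the majority group label.
    """
    labels = pd.Series(list(group_labels), index=psi_subset.columns)
    if labels.nunique() != 2:
        raise ValueError("exactly two groups required")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("need at least two samples per group")

    x = psi_subset.to_numpy(dtype=float)
    means = np.nanmean(x, axis=1)
    fill = np.where(np.isnan(x), means[:, None], x)
    fill = np.nan_to_num(fill)  # events missing everywhere
    dist = pdist(fill.T, metric="euclidean")
    z = linkage(dist, method=method)
    cut = fcluster(z, t=2, criterion="maxclust")

    degenerate = len(np.unique(cut)) < 2
    if degenerate:
        logger.warning("dendrogram cut produced a single cluster")

    # majority assignment of clusters to groups
    pred = pd.Series(index=labels.index, dtype=object)
    for cl in np.unique(cut):
        members = labels[cut == cl]
        pred[members.index] = members.value_counts().idxmax()

    is_case = labels == case_label
    pred_case = pred == case_label
    tp = int((is_case & pred_case).sum())
    fn = int((is_case & ~pred_case).sum())
    tn = int((~is_case & ~pred_case).sum())
    fp = int((~is_case & pred_case).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return ClusteringResult(sens, spec, pred, degenerate)
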