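"""Two-stage discriminative random walk with restart (DRaWR).

Stage 1 runs two walks on the full network -- one restarting at the
query gene set Q, one at the background set B of all gene nodes -- and
ranks AS-event and pathway nodes jointly by the difference of stationary
probabilities, ``statP_Q - statP_B``.  The top ``num_feats`` feature
nodes (ties at the boundary kept) plus all gene nodes form a subnetwork,
re-normalized exactly like the full network, on which stage 2 repeats
both walks to produce the final rankings.  Gene nodes are scored by
their stage-2 query stationary probability and calibrated against
random queries of the same size with an empirical permutation P value

    P_i^perm = (1/N) * sum_n I(theta_i^n > pi_hat_i).

The walk iterates ``pi_{t+1} = (1 - c) T pi_t + c v`` from a uniform
start until the max-norm change drops below ``tol``; with restart
probability c the iteration contracts by at least (1 - c) per step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import HeterogeneousNetwork, NetworkParams, build_network

logger = logging.getLogger(__name__)


@dataclass
class QueryConfig:
    """Walk and calibration parameters.

    restart: probability c of jumping back to the restart set each step.
    tol: L-inf convergence tolerance on successive iterates.
    num_feats: feature nodes (AS + pathway, jointly) kept for stage 2.
    n_perm: permutation count for the gene-node calibration (0 disables).
    num_folds: optional cross-validation folds for the retrieval diagnostic.
    """

    restart: float = 0.7
    tol: float = 1e-6
    max_iter: int = 1000
    num_feats: int = 1000
    n_perm: int = 1000
    num_folds: int | None = None
    seed: int = 0


@dataclass
class RWRResult:
    pi: np.ndarray
    iterations: int
    converged: bool


def _check_transition(T: sp.spmatrix) -> None:
    colsum = np.asarray(T.sum(axis=0)).ravel()
    if T.nnz and not np.allclose(colsum[colsum > 0], 1.0, atol=1e-9):
        raise ValueError("T is not column-stochastic")


def rwr(
    T: sp.spmatrix,
    v: np.ndarray,
    c: float = 0.7,
    tol: float = 0.05,
    max_iter: int = 1000,
    check: bool = True,
) -> RWRResult:
    """Iterate pi_{t+1} = (1-c) T pi_t + c v from a uniform start.

    ``v`` may be a vector or a matrix of restart columns (walked jointly).
    Non-convergence within ``max_iter`` is flagged, not raised.
    """
    if not (0.0 < c < 1.0):
        raise ValueError("restart probability must be in (0, 1)")
    if check:
        _check_transition(T)
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    V = v[:, None] if single else v
    n = T.shape[0]
    pi = np.full_like(V, 1.0 / n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        nxt = (1.0 - c) * (T @ pi) + c * V
        delta = np.abs(nxt - pi).max()
        pi = nxt
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("RWR did not converge in %d iterations", max_iter)
    return RWRResult(pi[:, 0] if single else pi, it, converged)


def restart_vector(net: HeterogeneousNetwork, members: np.ndarray) -> np.ndarray:
    """Uniform restart vector over the boolean node mask ``members``."""
    v = np.zeros(net.n)
    k = int(members.sum())
    if k == 0:
        raise ValueError("restart set is empty")
    v[members] = 1.0 / k
    return v


def _resolve_query(net: HeterogeneousNetwork, query: Sequence[str]) -> np.ndarray:
    gene_ids = set(net.node_ids[net.gene_mask])
    q = [g for g in query if g in gene_ids]
    dropped = len(set(query)) - len(set(q))
    if dropped:
        logger.warning("%d query genes absent from the network; dropped", dropped)
    if not q:
        raise ValueError("query has no genes in the network")
    mask = np.isin(net.node_ids, list(set(q)))
    return mask & net.gene_mask


@dataclass
class StageRanking:
    """Per-node scores from one DRaWR stage.

    ``table`` holds node_id, kind, statP_Q, statP_B, score for every node;
    ``score`` is statP_Q - statP_B (the feature relevance measure).
    """

    table: pd.DataFrame

    def feature_ranking(self) -> pd.DataFrame:
        feats = self.table[self.table["kind"] != "gene"].copy()
        feats = feats.sort_values(
            ["score", "node_id"], ascending=[False, True], kind="mergesort"
        )
        feats["rank"] = feats["score"].rank(method="min", ascending=False).astype(int)
        return feats.reset_index(drop=True)

    def gene_scores(self) -> pd.DataFrame:
        return self.table[self.table["kind"] == "gene"].reset_index(drop=True)


def _run_stage(
    net: HeterogeneousNetwork,
    T: sp.spmatrix,
    query_mask: np.ndarray,
    cfg: QueryConfig,
) -> StageRanking:
    vq = restart_vector(net, query_mask)
    vb = restart_vector(net, net.gene_mask)
    res = rwr(
        T,
        np.column_stack([vq, vb]),
        c=cfg.restart,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        check=False,
    )
    pq, pb = res.pi[:, 0], res.pi[:, 1]
    table = pd.DataFrame(
        {
            "node_id": net.node_ids,
            "kind": [net.kind_of(i) for i in range(net.n)],
            "statP_Q": pq,
            "statP_B": pb,
            "score": pq - pb,
        }
    )
    return StageRanking(table)


def stage1(
    net: HeterogeneousNetwork, query: Sequence[str], cfg: QueryConfig | None = None
) -> StageRanking:
    """Full-network query and background walks; joint feature ranking."""
    cfg = cfg or QueryConfig()
    T = net.transition()
    return _run_stage(net, T, _resolve_query(net, query), cfg)


def prune_to_subnetwork(
    net: HeterogeneousNetwork, ranking: StageRanking, num_feats: int
) -> HeterogeneousNetwork:
    """Keep all gene nodes plus the top ``num_feats`` features (ties kept)."""
    if num_feats < 1:
        raise ValueError("num_feats must be >= 1")
    feats = ranking.feature_ranking()
    if num_feats >= len(feats):
        logger.info("num_feats >= feature count; subnetwork equals network")
        return net
    cutoff = feats["score"].iloc[num_feats - 1]
    kept_ids = set(feats.loc[feats["score"] >= cutoff, "node_id"])
    keep = net.gene_mask | np.isin(net.node_ids, list(kept_ids))
    return net.subnetwork(keep)


def stage2(
    subnet: HeterogeneousNetwork, query: Sequence[str], cfg: QueryConfig | None = None
) -> StageRanking:
    """Re-run both walks on the pruned subnetwork; final rankings."""
    cfg = cfg or QueryConfig()
    T = subnet.transition()
    return _run_stage(subnet, T, _resolve_query(subnet, query), cfg)


@dataclass
class PermutationResult:
    """Empirical calibration of gene-node stationary probabilities."""

    table: pd.DataFrame  # gene_id, statP, perm_p, significant
    n_perm: int


def permutation_test(
    subnet: HeterogeneousNetwork,
    query: Sequence[str],
    observed: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    cfg: QueryConfig | None = None,
    alpha: float = 0.05,
    batch: int = 64,
) -> PermutationResult:
    """Compare observed gene stat-P against random same-size queries.

    Null queries are sampled uniformly without replacement from the gene
    nodes of the subnetwork; each permutation reruns the stage-2 query
    walk.  ``observed`` is the stage-2 gene table (gene node_id, statP_Q).
    """
    cfg = cfg or QueryConfig()
    rng = np.random.default_rng(seed)
    T = subnet.transition()
    gene_idx = np.nonzero(subnet.gene_mask)[0]
    q_mask = _resolve_query(subnet, query)
    q_size = int(q_mask.sum())

    obs = observed.set_index("node_id")["statP_Q"].reindex(
        subnet.node_ids[subnet.gene_mask]
    )
    pi_hat = obs.to_numpy()
    exceed = np.zeros(len(gene_idx))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        V = np.zeros((subnet.n, b))
        for j in range(b):
            pick = rng.choice(gene_idx, size=q_size, replace=False)
            V[pick, j] = 1.0 / q_size
        res = rwr(T, V, c=cfg.restart, tol=cfg.tol, max_iter=cfg.max_iter, check=False)
        theta = res.pi[subnet.gene_mask]
        exceed += (theta > pi_hat[:, None]).sum(axis=1)
        done += b
    pvals = exceed / n_perm
    table = pd.DataFrame(
        {
            "gene_id": subnet.node_ids[subnet.gene_mask],
            "statP": pi_hat,
            "perm_p": pvals,
            "significant": pvals < alpha,
        }
    )
    return PermutationResult(table, n_perm)


def empirical_pvalues(null_draws: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """P_i = (1/N) sum_n I(theta_i^n > pi_hat_i) for null matrix (nodes x N)."""
    null_draws = np.atleast_2d(null_draws)
    return (null_draws > np.asarray(observed)[:, None]).mean(axis=1)


def crossval_diagnostic(
    net: HeterogeneousNetwork,
    query: Sequence[str],
    num_folds: int = 5,
    seed: int = 0,
    cfg: QueryConfig | None = None,
) -> list[float]:
    """Held-out query retrieval: per-fold rank AUC of left-out query genes.

    The query is split into ``num_folds`` disjoint folds; for each fold
    stage 1 runs with the remaining query genes and the held-out genes
    are scored against all non-query gene nodes by statP_Q - statP_B.
    """
    cfg = cfg or QueryConfig()
    q_mask = _resolve_query(net, query)
    q_idx = np.nonzero(q_mask)[0]
    if len(q_idx) < num_folds:
        raise ValueError("query smaller than the number of folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(q_idx)
    folds = np.array_split(perm, num_folds)
    T = net.transition()
    aucs: list[float] = []
    for fold in folds:
        retained = np.setdiff1d(q_idx, fold)
        mask = np.zeros(net.n, bool)
        mask[retained] = True
        ranking = _run_stage(net, T, mask, cfg)
        scores = ranking.table["score"].to_numpy()
        candidates = net.gene_mask.copy()
        candidates[retained] = False
        held = np.zeros(net.n, bool)
        held[fold] = True
        cand_scores = scores[candidates]
        cand_truth = held[candidates]
        aucs.append(_rank_auc(cand_scores, cand_truth))
    return aucs


def _rank_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    from scipy.stats import rankdata

    pos = truth.astype(bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: single-class truth")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class FIParams:
    """End-to-end pipeline parameters (network + walk + calibration)."""

    network: NetworkParams = field(default_factory=NetworkParams)
    query_cfg: QueryConfig = field(default_factory=QueryConfig)
    low_var: float | None = None
    prop_na: float = 0.05
    prop_extreme: float = 1.0
    alpha: float = 0.05

    def manifest(self) -> dict:
        return {
            "network": asdict(self.network),
            "walk": asdict(self.query_cfg),
            "low_var": self.low_var,
            "prop_na": self.prop_na,
            "prop_extreme": self.prop_extreme,
            "alpha": self.alpha,
        }


@dataclass
class FIResult:
    as_table: pd.DataFrame
    gene_table: pd.DataFrame
    pathway_table: pd.DataFrame
    subnetwork_edges: pd.DataFrame
    manifest: dict
    crossval_auc: list[float] | None = None


def run_fi(
    expr: pd.DataFrame,
    psi: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    ref_edges: Sequence[tuple[str, str]],
    query: Sequence[str],
    params: FIParams | None = None,
) -> FIResult:
    """Filter inputs, build the network, run DRaWR, calibrate, and tabulate.

    Deterministic given ``params.query_cfg.seed``.  With ``n_perm == 0``
    the permutation columns are empty and the significant subnetwork is
    not extracted.
    """
    from .events import filter_events

    params = params or FIParams()
    cfg = params.query_cfg

    psi_f = filter_events(
        psi,
        low_var=params.low_var,
        prop_na=params.prop_na,
        prop_extreme=params.prop_extreme,
    )
    try:
        net = build_network(expr, psi_f, gene_sets, ref_edges, params.network)
    except ValueError as exc:
        raise ValueError(f"[network] {exc}") from exc

    try:
        s1 = stage1(net, query, cfg)
    except ValueError as exc:
        raise ValueError(f"[stage1] {exc}") from exc
    subnet = prune_to_subnetwork(net, s1, cfg.num_feats)
    try:
        s2 = stage2(subnet, query, cfg)
    except ValueError as exc:
        raise ValueError(f"[stage2] {exc}") from exc

    feats = s2.feature_ranking()
    as_table = feats[feats["kind"] == "as"].copy()
    as_table["type"] = [str(e).split(":")[0] for e in as_table["node_id"]]
    as_table["gene_id"] = [
        str(e).split(":")[1] if ":" in str(e) else "" for e in as_table["node_id"]
    ]
    as_table = as_table.rename(columns={"node_id": "event_id"})[
        ["event_id", "type", "gene_id", "statP_Q", "statP_B", "score", "rank"]
    ]
    as_table["rank"] = (
        as_table["score"].rank(method="min", ascending=False).astype(int)
    )
    if as_table.empty:
        logger.warning("no AS-event nodes in the final subnetwork")

    pathway_table = feats[feats["kind"] == "pathway"].copy()
    pathway_table = pathway_table.rename(columns={"node_id": "pathway_id"})[
        ["pathway_id", "statP_Q", "statP_B", "score", "rank"]
    ]
    pathway_table["rank"] = (
        pathway_table["score"].rank(method="min", ascending=False).astype(int)
    )

    genes_s2 = s2.gene_scores()
    if cfg.n_perm > 0:
        try:
            perm = permutation_test(
                subnet,
                query,
                genes_s2,
                n_perm=cfg.n_perm,
                seed=cfg.seed,
                cfg=cfg,
                alpha=params.alpha,
            )
        except ValueError as exc:
            raise ValueError(f"[permutation] {exc}") from exc
        gene_table = perm.table
    else:
        gene_table = pd.DataFrame(
            {
                "gene_id": genes_s2["node_id"],
                "statP": genes_s2["statP_Q"],
                "perm_p": np.nan,
                "significant": pd.array([pd.NA] * len(genes_s2), dtype="boolean"),
            }
        )
    gene_table = gene_table.sort_values(
        ["statP", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)

    subnetwork_edges = _significant_subnetwork(subnet, gene_table)

    cv = None
    if cfg.num_folds:
        cv = crossval_diagnostic(net, query, cfg.num_folds, seed=cfg.seed, cfg=cfg)

    manifest = params.manifest()
    manifest.update(
        {
            "n_query": len(list(query)),
            "n_nodes_full": int(net.n),
            "n_nodes_subnet": int(subnet.n),
            "n_events_ranked": int(len(as_table)),
        }
    )
    return FIResult(as_table, gene_table, pathway_table, subnetwork_edges, manifest, cv)


def _significant_subnetwork(
    subnet: HeterogeneousNetwork, gene_table: pd.DataFrame
) -> pd.DataFrame:
    """Edges among significant genes and their neighboring AS-event nodes."""
    cols = ["node1", "node2", "kind1", "kind2", "weight"]
    sig = gene_table[gene_table["significant"] == True]  # noqa: E712
    if sig.empty:
        return pd.DataFrame(columns=cols)
    sig_mask = np.isin(subnet.node_ids, sig["gene_id"].to_numpy())
    coo = sp.coo_matrix(sp.triu(subnet.M))
    as_mask = subnet.kinds == 1
    neighbor_as = np.zeros(subnet.n, bool)
    full = sp.coo_matrix(subnet.M)
    touch = sig_mask[full.row] & as_mask[full.col]
    neighbor_as[full.col[touch]] = True
    keep_nodes = sig_mask | neighbor_as
    keep_e = keep_nodes[coo.row] & keep_nodes[coo.col]
    rows, cols_i, w = coo.row[keep_e], coo.col[keep_e], coo.data[keep_e]
    order = np.lexsort((cols_i, rows))
    return pd.DataFrame(
        {
            "node1": subnet.node_ids[rows[order]],
            "node2": subnet.node_ids[cols_i[order]],
            "kind1": [subnet.kind_of(i) for i in rows[order]],
            "kind2": [subnet.kind_of(i) for i in cols_i[order]],
            "weight": w[order],
        }
    )
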