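"""Heterogeneous gene / AS-event / pathway network assembly.

The network has three node kinds.  Edges exist only between genes and
each of the three partner classes:

* gene-gene: ``|r_P|`` (absolute Pearson correlation of expression),
  restricted to pairs present in a reference interaction network;
* gene-AS: ``|r_S|`` (absolute Spearman correlation of expression vs
  PSI) kept only when it strictly exceeds the threshold ``tau``;
* gene-pathway: 1 for gene-set membership.

Feature-feature blocks (AS-AS, AS-pathway, pathway-pathway) are zero.

The adjacency matrix M is turned into a column-stochastic transition
matrix T in two steps: each non-zero block is first divided by the sum
of its own entries (equalizing the total probability mass carried by
each edge class), then every column is divided by its column sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

KIND_GENE, KIND_AS, KIND_PATHWAY = "gene", "as", "pathway"
_KIND_CODE = {KIND_GENE: 0, KIND_AS: 1, KIND_PATHWAY: 2}


@dataclass
class NetworkParams:
    """Tunables for network assembly.

    low_expr: genes with mean expression below this are dropped (FPKM units).
    cor_threshold: tau; gene-AS edges require |Spearman| strictly above it.
    log_transform: apply log2(x + 1) to expression before Pearson.
    min_pairs: minimum pairwise-complete observations for a Spearman edge.
    host_only: restrict gene-AS candidates to each event's host gene.
    mirrored_jointly: normalize a symmetric block pair by its joint sum
        instead of per-block (both conventions supported; per-block default).
    """

    low_expr: float = 1.0
    cor_threshold: float = 0.4
    log_transform: bool = True
    min_pairs: int = 5
    host_only: bool = False
    mirrored_jointly: bool = False


def filter_genes(expr: pd.DataFrame, low_expr: float = 1.0) -> pd.DataFrame:
    """Keep genes whose mean expression is >= ``low_expr`` (boundary kept)."""
    if expr.empty:
        raise ValueError("expression matrix is empty")
    keep = expr.mean(axis=1) >= low_expr
    out = expr.loc[keep]
    if out.empty:
        raise ValueError("no genes left after expression filtering")
    return out


def gene_gene_weights(
    expr: pd.DataFrame,
    ref_edges: Sequence[tuple[str, str]],
    log_transform: bool = True,
) -> list[tuple[str, str, float]]:
    """Weight reference-network edges by |Pearson correlation| of expression.

    Edges whose genes are absent from ``expr`` are dropped; zero-variance
    genes give weight 0 (logged).
    """
    genes = expr.index
    idx = {g: i for i, g in enumerate(genes)}
    x = expr.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x * x).sum(axis=1))
    out: list[tuple[str, str, float]] = []
    n_degenerate = 0
    for g1, g2 in ref_edges:
        if g1 == g2 or g1 not in idx or g2 not in idx:
            continue
        i, j = idx[g1], idx[g2]
        if norms[i] == 0 or norms[j] == 0:
            n_degenerate += 1
            continue
        r = float(x[i] @ x[j] / (norms[i] * norms[j]))
        out.append((g1, g2, abs(r)))
    if n_degenerate:
        logger.warning(
            "%d reference edges dropped: zero-variance gene(s)", n_degenerate
        )
    return out


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Average-rank each row of a complete (no-NaN) matrix."""
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty_like(values)
    n = values.shape[1]
    base = np.arange(1, n + 1, dtype=float)
    rows = np.arange(values.shape[0])[:, None]
    ranks[rows, order] = base
    # average ties
    srt = np.take_along_axis(values, order, axis=1)
    ties = srt[:, 1:] == srt[:, :-1]
    if ties.any():
        for i in np.nonzero(ties.any(axis=1))[0]:
            v = values[i]
            uniq, inv, counts = np.unique(v, return_inverse=True, return_counts=True)
            csum = np.concatenate(([0], np.cumsum(counts)))
            avg = (csum[:-1] + 1 + csum[1:]) / 2.0
            ranks[i] = avg[inv]
    return ranks


def _standardize_ranks(ranks: np.ndarray) -> np.ndarray:
    """Center and L2-normalize rows; all-tied rows become zero vectors."""
    c = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((c * c).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms > 0, c / np.where(norms > 0, norms, 1.0), 0.0)
    return z


def gene_as_weights(
    expr: pd.DataFrame,
    psi: pd.DataFrame,
    tau: float = 0.4,
    min_pairs: int = 5,
    host_only: bool = False,
    chunk: int = 512,
) -> sp.coo_matrix:
    """Absolute Spearman correlations |r_S| > tau between genes and events.

    Pairwise-complete: samples where an event's PSI is missing are dropped
    for that event before ranking.  Events sharing a missing-sample pattern
    are processed together so the whole candidate grid stays vectorized.
    Returns a sparse genes x events weight matrix aligned to the row
    orders of ``expr`` and ``psi``.
    """
    samples = expr.columns.intersection(psi.columns)
    if len(samples) == 0:
        raise ValueError("expression and PSI matrices share no samples")
    x = expr[samples].to_numpy(dtype=float)
    y = psi[samples].to_numpy(dtype=float)
    n_genes, n_events = x.shape[0], y.shape[0]

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    masks = np.isnan(y)
    # group events by missing pattern; complete events form one big group
    pattern_ids: dict[bytes, list[int]] = {}
    for e in range(n_events):
        pattern_ids.setdefault(masks[e].tobytes(), []).append(e)

    host_idx = None
    if host_only:
        gene_pos = {g: i for i, g in enumerate(expr.index)}
        host_idx = np.array(
            [
                gene_pos.get(str(eid).split(":")[1], -1)
                for eid in psi.index
            ]
        )

    for key, eids in pattern_ids.items():
        mask = np.frombuffer(key, dtype=bool)
        present = ~mask
        if present.sum() < min_pairs:
            continue
        gx = _standardize_ranks(_rank_rows(x[:, present]))
        ey = _standardize_ranks(_rank_rows(y[np.ix_(eids, present)]))
        eids_arr = np.asarray(eids)
        for start in range(0, len(eids), chunk):
            block_events = eids_arr[start : start + chunk]
            r = np.abs(gx @ ey[start : start + chunk].T)  # genes x chunk
            if host_idx is not None:
                keep_mask = np.zeros_like(r, dtype=bool)
                for jj, e in enumerate(block_events):
                    if host_idx[e] >= 0:
                        keep_mask[host_idx[e], jj] = True
                r = np.where(keep_mask, r, 0.0)
            gi, ej = np.nonzero(r > tau)
            if gi.size:
                rows.append(gi)
                cols.append(block_events[ej])
                vals.append(r[gi, ej])

    if rows:
        data = np.concatenate(vals)
        coo = sp.coo_matrix(
            (data, (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_genes, n_events),
        )
    else:
        coo = sp.coo_matrix((n_genes, n_events))
    return coo


def gene_pathway_weights(
    gene_ids: Sequence[str], gene_sets: Mapping[str, set[str]]
) -> tuple[sp.coo_matrix, list[str]]:
    """Binary membership edges; pathways with no surviving member are dropped."""
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    kept_paths: list[str] = []
    rows: list[int] = []
    cols: list[int] = []
    for pid in sorted(gene_sets):
        members = [gene_pos[g] for g in gene_sets[pid] if g in gene_pos]
        if not members:
            continue
        j = len(kept_paths)
        kept_paths.append(pid)
        rows.extend(members)
        cols.extend([j] * len(members))
    mat = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(gene_ids), len(kept_paths))
    )
    return mat, kept_paths


@dataclass
class HeterogeneousNetwork:
    """Node index plus symmetric block adjacency over three node kinds."""

    node_ids: np.ndarray  # object array of node identifiers
    kinds: np.ndarray  # int codes: 0 gene, 1 AS, 2 pathway
    M: sp.csr_matrix
    mirrored_jointly: bool = False
    _kind_names: tuple[str, str, str] = (KIND_GENE, KIND_AS, KIND_PATHWAY)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def kind_of(self, i: int) -> str:
        return self._kind_names[self.kinds[i]]

    @property
    def gene_mask(self) -> np.ndarray:
        return self.kinds == 0

    @property
    def feature_mask(self) -> np.ndarray:
        return self.kinds != 0

    def index_of(self, node_id: str) -> int:
        pos = np.nonzero(self.node_ids == node_id)[0]
        if pos.size == 0:
            raise KeyError(node_id)
        return int(pos[0])

    def transition(self) -> sp.csr_matrix:
        """Block-equalized, column-normalized transition matrix T."""
        return to_transition(self.M, self.kinds, self.mirrored_jointly)

    def subnetwork(self, keep: np.ndarray) -> "HeterogeneousNetwork":
        """Restrict to the boolean node mask ``keep``, dropping newly
        isolated nodes (logged)."""
        idx = np.nonzero(keep)[0]
        M = self.M[idx][:, idx].tocsr()
        node_ids = self.node_ids[idx]
        kinds = self.kinds[idx]
        # dropping features can isolate genes and vice versa; iterate
        while True:
            deg = np.asarray((M != 0).sum(axis=1)).ravel()
            alive = deg > 0
            if alive.all():
                break
            logger.info("removing %d isolated nodes from subnetwork", (~alive).sum())
            keep_i = np.nonzero(alive)[0]
            M = M[keep_i][:, keep_i].tocsr()
            node_ids = node_ids[keep_i]
            kinds = kinds[keep_i]
        return HeterogeneousNetwork(node_ids, kinds, M, self.mirrored_jointly)

    def nodes_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "kind": [self._kind_names[k] for k in self.kinds],
            }
        )


def assemble_adjacency(
    gene_ids: Sequence[str],
    event_ids: Sequence[str],
    pathway_ids: Sequence[str],
    gg_edges: Sequence[tuple[str, str, float]],
    ga: sp.spmatrix,
    gp: sp.spmatrix,
    mirrored_jointly: bool = False,
) -> HeterogeneousNetwork:
    """Build the symmetric block matrix M and drop isolated nodes.

    Node order: genes, then AS events, then pathways.  ``ga`` and ``gp``
    are genes x events / genes x pathways weight matrices aligned with
    the given id sequences.
    """
    universe: list[str] = list(gene_ids) + list(event_ids) + list(pathway_ids)
    if len(set(universe)) != len(universe):
        raise ValueError("node identifiers collide across kinds")
    n_g, n_a, n_p = len(gene_ids), len(event_ids), len(pathway_ids)
    if n_g == 0:
        raise ValueError("network needs at least one gene node")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for g1, g2, w in gg_edges:
        if w == 0:
            continue
        i, j = gene_pos[g1], gene_pos[g2]
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((w, w))
    M = sp.coo_matrix((vals, (rows, cols)), shape=(n_g + n_a + n_p,) * 2)

    ga = sp.coo_matrix(ga)
    gp = sp.coo_matrix(gp)
    blocks = [
        sp.coo_matrix(
            (ga.data, (ga.row, ga.col + n_g)), shape=M.shape
        ),
        sp.coo_matrix(
            (ga.data, (ga.col + n_g, ga.row)), shape=M.shape
        ),
        sp.coo_matrix(
            (gp.data, (gp.row, gp.col + n_g + n_a)), shape=M.shape
        ),
        sp.coo_matrix(
            (gp.data, (gp.col + n_g + n_a, gp.row)), shape=M.shape
        ),
    ]
    M = (M + blocks[0] + blocks[1] + blocks[2] + blocks[3]).tocsr()
    M.sum_duplicates()

    kinds = np.concatenate(
        [np.zeros(n_g, int), np.ones(n_a, int), np.full(n_p, 2, int)]
    )
    node_ids = np.array(universe, dtype=object)
    net = HeterogeneousNetwork(node_ids, kinds, M, mirrored_jointly)
    deg = np.asarray((net.M != 0).sum(axis=1)).ravel()
    if (deg == 0).any():
        logger.info("dropping %d isolated nodes", int((deg == 0).sum()))
        net = net.subnetwork(deg > 0)
    if not net.gene_mask.any():
        raise ValueError("network has no connected gene nodes")
    return net


def block_normalize(
    M: sp.spmatrix, kinds: np.ndarray, mirrored_jointly: bool = False
) -> sp.csr_matrix:
    """Step 1: divide every non-zero block M_XY by the sum of its entries,
    so each edge class carries unit total probability mass."""
    coo = sp.coo_matrix(M)
    if coo.nnz == 0:
        raise ValueError("adjacency matrix has no edges")
    block = _KIND_CODE_PAIR(kinds[coo.row], kinds[coo.col], mirrored_jointly)
    sums = np.bincount(block, weights=coo.data, minlength=9)
    data = coo.data / sums[block]
    return sp.csr_matrix((data, (coo.row, coo.col)), shape=M.shape)


def to_transition(
    M: sp.spmatrix, kinds: np.ndarray, mirrored_jointly: bool = False
) -> sp.csr_matrix:
    """Normalize M into a column-stochastic transition matrix T.

    Step 1 divides every non-zero block M_XY by the sum of its own entries
    (mirrored blocks separately by default, jointly if requested); step 2
    divides each column of the result by its column sum.
    """
    N = block_normalize(M, kinds, mirrored_jointly)
    colsum = np.asarray(N.sum(axis=0)).ravel()
    if np.any(colsum == 0):
        raise ValueError("zero column encountered; isolated node not removed")
    T = N @ sp.diags(1.0 / colsum)
    return T.tocsr()


def _KIND_CODE_PAIR(
    row_kinds: np.ndarray, col_kinds: np.ndarray, joint: bool
) -> np.ndarray:
    if joint:
        lo = np.minimum(row_kinds, col_kinds)
        hi = np.maximum(row_kinds, col_kinds)
        return lo * 3 + hi
    return row_kinds * 3 + col_kinds


def build_network(
    expr: pd.DataFrame,
    psi: pd.DataFrame,
    gene_sets: Mapping[str, set[str]],
    ref_edges: Sequence[tuple[str, str]],
    params: NetworkParams | None = None,
) -> HeterogeneousNetwork:
    """Compose filtering, edge weighting, and assembly into one call."""
    params = params or NetworkParams()
    expr_f = filter_genes(expr, params.low_expr)
    samples = expr_f.columns.intersection(psi.columns)
    expr_f = expr_f[samples]
    psi = psi[samples]
    gg = gene_gene_weights(expr_f, ref_edges, params.log_transform)
    ga = gene_as_weights(
        expr_f,
        psi,
        tau=params.cor_threshold,
        min_pairs=params.min_pairs,
        host_only=params.host_only,
    )
    gp, kept_paths = gene_pathway_weights(list(expr_f.index), gene_sets)
    if ga.nnz == 0:
        logger.warning("no gene-AS edges pass tau=%.3g", params.cor_threshold)
    return assemble_adjacency(
        list(expr_f.index),
        list(psi.index),
        kept_paths,
        gg,
        ga,
        gp,
        mirrored_jointly=params.mirrored_jointly,
    )
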