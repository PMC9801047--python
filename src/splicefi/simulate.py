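"""Matrix-level synthetic two-condition RNA-seq datasets with planted
differential splicing.

The generator emulates the statistical structure the pipeline consumes,
not reads: per-gene counts follow a negative-binomial distribution with
group-specific means for differentially expressed (DEG) genes; percent
spliced-in values for planted differential-splicing (DAS) events are
binomial proportions around a group-specific dominant-isoform usage
(case 0.8/0.6/0.4 versus control 0.2), with the number of binomial
trials tied to the gene's read count so that lower sequencing depth
yields noisier PSI.  Null events share one uniform usage across both
groups.  A scale-free reference interaction network, one DAS-enriched
pathway plus decoy gene sets, and a DEG-derived query list complete the
pipeline inputs.

Depth levels are expressed as a multiplier relative to the lowest level:
mean base coverages of 150x/65x/50x/30x/15x map to depth_factor
10 / 4.3 / 3.3 / 2 / 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

#: coverage-level analogues, relative to the lowest depth
DEPTH_PRESETS = {150: 10.0, 65: 4.3, 50: 3.3, 30: 2.0, 15: 1.0}


@dataclass
class SimParams:
    """Generator knobs; defaults reproduce the benchmark's favorable arm.

    n_genes / n_das: gene universe and number of true DAS genes.
    n_null_events: events planted on non-DAS genes with no group signal
        (total events = n_das + n_null_events).
    n_per_group: biological replicates per condition.
    usage_case / usage_ctrl: dominant-isoform proportion per group for
        planted events; their expected PSI difference is the usage gap.
    depth_factor: library-size multiplier (see DEPTH_PRESETS).
    nb_dispersion: NB dispersion phi, var = mu + phi * mu^2.
    frac_deg: fraction of genes with an expression shift of
        |log2 FC| >= lfc_deg; these supply the query list.
    trials_frac: fraction of a gene's reads informative for its event
        (binomial trial count for PSI sampling).
    miss_rate: extra missing-at-random PSI rate on top of zero-trial
        missingness.
    """

    n_genes: int = 8000
    n_das: int = 1000
    n_null_events: int = 3000
    n_per_group: int = 20
    usage_case: float = 0.8
    usage_ctrl: float = 0.2
    depth_factor: float = 1.0
    nb_dispersion: float = 0.1
    frac_deg: float = 0.05
    lfc_deg: float = 2.0
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    trials_frac: float = 0.2
    miss_rate: float = 0.01
    query_size_null: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_das >= self.n_genes:
            raise ValueError("n_das must be smaller than n_genes")
        for p in (self.usage_case, self.usage_ctrl):
            if not (0.0 < p < 1.0):
                raise ValueError("isoform usages must lie in (0, 1)")


@dataclass
class SimulatedDataset:
    expression: pd.DataFrame  # genes x samples, FPKM-like
    counts: pd.DataFrame  # genes x samples, integer reads
    psi: pd.DataFrame  # events x samples, NaN = missing
    event_truth: pd.DataFrame  # event_id, gene_id, planted
    gene_truth: pd.DataFrame  # gene_id, deg, das
    query: list[str]
    gene_sets: dict[str, set[str]]
    ref_edges: list[tuple[str, str]]
    group_labels: pd.Series  # sample -> "case"/"ctrl"
    params: SimParams


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_counts(
    params: SimParams, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Negative-binomial gene counts and FPKM-like values for two groups.

    DEG genes receive a signed log2 fold shift of at least ``lfc_deg`` in
    the case group.  Returns (counts, fpkm, gene_truth, group_labels).
    """
    genes = _gene_ids(params.n_genes)
    n = params.n_per_group
    samples = [f"case_{i:02d}" for i in range(n)] + [f"ctrl_{i:02d}" for i in range(n)]
    is_case = np.array([s.startswith("case") for s in samples])

    base_mu = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, params.n_genes)
    das_idx = rng.choice(params.n_genes, size=params.n_das, replace=False)
    n_deg = int(round(params.frac_deg * params.n_genes))
    deg_idx = rng.choice(params.n_genes, size=n_deg, replace=False)
    lfc = np.zeros(params.n_genes)
    if n_deg:
        magnitude = params.lfc_deg + rng.exponential(0.5, n_deg)
        sign = rng.choice([-1.0, 1.0], n_deg)
        lfc[deg_idx] = sign * magnitude

    mu = np.tile(base_mu[:, None], (1, 2 * n)) * params.depth_factor
    mu[:, is_case] *= 2.0 ** lfc[:, None]
    phi = params.nb_dispersion
    r = 1.0 / phi
    counts = rng.negative_binomial(r, r / (r + mu))

    lengths_kb = rng.lognormal(np.log(1.5), 0.3, params.n_genes)
    lib = counts.sum(axis=0).astype(float)
    fpkm = counts / lengths_kb[:, None] / (lib[None, :] / 1e6)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    fpkm_df = pd.DataFrame(fpkm, index=genes, columns=samples)
    gene_truth = pd.DataFrame(
        {
            "gene_id": genes,
            "deg": np.isin(np.arange(params.n_genes), deg_idx),
            "das": np.isin(np.arange(params.n_genes), das_idx),
            "log2fc": lfc,
        }
    )
    groups = pd.Series(
        np.where(is_case, "case", "ctrl"), index=samples, name="group"
    )
    return counts_df, fpkm_df, gene_truth, groups


def simulate_psi(
    params: SimParams,
    rng: np.random.Generator,
    counts: pd.DataFrame,
    gene_truth: pd.DataFrame,
    groups: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial PSI values; planted events track group usage, nulls do not.

    Each DAS gene hosts one planted event; ``n_null_events`` non-DAS genes
    host one null event each with a shared uniform usage.  Trial counts
    are Binomial(gene count, trials_frac); zero trials give missing PSI.
    """
    das_genes = gene_truth.loc[gene_truth["das"], "gene_id"].tolist()
    non_das = gene_truth.loc[~gene_truth["das"], "gene_id"].tolist()
    n_null = min(params.n_null_events, len(non_das))
    null_hosts = list(rng.choice(non_das, size=n_null, replace=False))

    host_genes = das_genes + null_hosts
    planted = np.array([True] * len(das_genes) + [False] * n_null)
    types = rng.choice(["SE", "A3SS", "A5SS", "RI", "MXE"], size=len(host_genes),
                       p=[0.4, 0.2, 0.15, 0.15, 0.1])

    event_ids = []
    for k, (g, t) in enumerate(zip(host_genes, types)):
        a = 10_000 + 1_000 * k
        event_ids.append(f"{t}:{g}:chr1:+:{a}-{a + 120}:{a + 300}-{a + 420}")

    is_case = (groups == "case").to_numpy()
    cmat = counts.loc[host_genes].to_numpy()
    trials = rng.binomial(cmat, params.trials_frac)

    usage = np.empty((len(host_genes), len(groups)))
    usage[planted] = np.where(is_case, params.usage_case, params.usage_ctrl)
    null_usage = rng.uniform(0.05, 0.95, n_null)
    usage[~planted] = np.tile(null_usage[:, None], (1, len(groups)))

    incl = rng.binomial(trials, usage)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(trials > 0, incl / np.maximum(trials, 1), np.nan)
    if params.miss_rate > 0:
        psi = np.where(rng.random(psi.shape) < params.miss_rate, np.nan, psi)

    psi_df = pd.DataFrame(psi, index=event_ids, columns=counts.columns)
    truth = pd.DataFrame(
        {"event_id": event_ids, "gene_id": host_genes, "planted": planted}
    )
    return psi_df, truth


def simulate_reference_network(
    params: SimParams, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Scale-free (Barabasi-Albert, m = 2) gene-gene interaction network.

    The graph is connected, so every DAS gene has a path to every DEG gene.
    """
    genes = _gene_ids(params.n_genes)
    g = nx.barabasi_albert_graph(params.n_genes, 2, seed=int(rng.integers(2**31)))
    return [(genes[a], genes[b]) for a, b in sorted(g.edges())]


def simulate_pathways(
    params: SimParams,
    rng: np.random.Generator,
    gene_truth: pd.DataFrame,
    n_decoys: int = 20,
    set_size: int = 100,
) -> dict[str, set[str]]:
    """One DAS-enriched pathway plus random decoy sets."""
    das = gene_truth.loc[gene_truth["das"], "gene_id"].to_numpy()
    other = gene_truth.loc[~gene_truth["das"], "gene_id"].to_numpy()
    n_das_members = min(int(0.8 * set_size), len(das))
    relevant = set(rng.choice(das, n_das_members, replace=False)) | set(
        rng.choice(other, set_size - n_das_members, replace=False)
    )
    sets = {"PW_RELEVANT": relevant}
    all_genes = gene_truth["gene_id"].to_numpy()
    for d in range(n_decoys):
        sets[f"PW_DECOY{d:02d}"] = set(
            rng.choice(all_genes, set_size // 2, replace=False)
        )
    return sets


def generate_dataset(params: SimParams | None = None) -> SimulatedDataset:
    """Compose counts, PSI, references, and query into one dataset.

    The query is the DEG truth list; if no genes are differentially
    expressed (a signal-free run), a random query of ``query_size_null``
    genes is drawn instead so the pipeline stays runnable.
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    counts, fpkm, gene_truth, groups = simulate_counts(params, rng)
    psi, event_truth = simulate_psi(params, rng, counts, gene_truth, groups)
    ref_edges = simulate_reference_network(params, rng)
    gene_sets = simulate_pathways(params, rng, gene_truth)
    query = gene_truth.loc[gene_truth["deg"], "gene_id"].tolist()
    if not query:
        query = list(
            rng.choice(gene_truth["gene_id"], params.query_size_null, replace=False)
        )
    return SimulatedDataset(
        expression=fpkm,
        counts=counts,
        psi=psi,
        event_truth=event_truth,
        gene_truth=gene_truth,
        query=query,
        gene_sets=gene_sets,
        ref_edges=ref_edges,
        group_labels=groups,
        params=params,
    )


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus truth tables and a manifest."""
    from . import io as sio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "psi": out / "psi.tsv",
        "gmt": out / "pathways.gmt",
        "network": out / "reference_network.tsv",
        "query": out / "query.txt",
        "event_truth": out / "truth_events.tsv",
        "gene_truth": out / "truth_genes.tsv",
        "groups": out / "groups.tsv",
        "manifest": out / "manifest.json",
    }
    sio.write_matrix(ds.expression, paths["expression"], index_name="gene_id")
    sio.write_matrix(ds.psi, paths["psi"], index_name="event_id")
    sio.write_gmt(ds.gene_sets, paths["gmt"])
    sio.write_edge_list(ds.ref_edges, paths["network"])
    sio.write_gene_list(ds.query, paths["query"])
    ds.event_truth.to_csv(paths["event_truth"], sep="\t", index=False)
    ds.gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)
    ds.group_labels.rename_axis("sample_id").reset_index().to_csv(
        paths["groups"], sep="\t", index=False
    )
    paths["manifest"].write_text(json.dumps(asdict(ds.params), indent=2) + "\n")
    return paths
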