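import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

from splicefi import (
    GeneModel,
    HeterogeneousNetwork,
    Transcript,
    assemble_adjacency,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def _tx(tx_id, exons, chrom="chr1", strand="+"):
    return Transcript(tx_id=tx_id, chrom=chrom, strand=strand, exons=tuple(exons))


@pytest.fixture
def five_gene_model():
    """One gene per event type; expected events enumerated by hand."""
    m = GeneModel()
    # SE: cassette exon 300-400 skipped by the 200->500 junction
    m.add_transcript("gSE", _tx("gSE.t1", [(100, 200), (300, 400), (500, 600)]))
    m.add_transcript("gSE", _tx("gSE.t2", [(100, 200), (500, 600)]))
    # A5SS on +: alternative donors 200 vs 250, shared acceptor 500
    m.add_transcript("gA5", _tx("gA5.t1", [(100, 200), (500, 600)]))
    m.add_transcript("gA5", _tx("gA5.t2", [(100, 250), (500, 600)]))
    # A3SS on +: shared donor 200, alternative acceptors 450 vs 500
    m.add_transcript("gA3", _tx("gA3.t1", [(100, 200), (500, 600)]))
    m.add_transcript("gA3", _tx("gA3.t2", [(100, 200), (450, 600)]))
    # RI: exon pair vs merged exon
    m.add_transcript("gRI", _tx("gRI.t1", [(100, 200), (300, 400)]))
    m.add_transcript("gRI", _tx("gRI.t2", [(100, 400)]))
    # MXE: exclusive exons 300-400 / 500-600 sharing both flank junctions
    m.add_transcript("gMXE", _tx("gMXE.t1", [(100, 200), (300, 400), (700, 800)]))
    m.add_transcript("gMXE", _tx("gMXE.t2", [(100, 200), (500, 600), (700, 800)]))
    return m


FIVE_GENE_EXPECTED = {
    ("SE", "gSE", (200, 300, 400, 500)),
    ("A5SS", "gA5", (100, 200, 250, 500)),
    ("A3SS", "gA3", (200, 450, 500, 600)),
    ("RI", "gRI", (100, 200, 300, 400)),
    ("MXE", "gMXE", (200, 300, 400, 500, 600, 700)),
}


def random_network(rng, n_g=8, n_a=4, n_p=2) -> HeterogeneousNetwork:
    """Random connected heterogeneous fixture for walk/normalization tests."""
    genes = [f"g{i}" for i in range(n_g)]
    events = [f"SE:g{i}:chr1:+:1-2:3-4#{i}" for i in range(n_a)]
    paths = [f"pw{i}" for i in range(n_p)]
    gg = []
    for i in range(1, n_g):  # random tree keeps genes connected
        j = int(rng.integers(0, i))
        gg.append((genes[i], genes[j], float(rng.uniform(0.2, 1.0))))
    for _ in range(n_g):
        i, j = rng.integers(0, n_g, 2)
        if i != j:
            gg.append((genes[i], genes[j], float(rng.uniform(0.2, 1.0))))
    ga = sp.random(n_g, n_a, density=0.5, random_state=np.random.RandomState(int(rng.integers(2**31))))
    ga.data = 0.2 + 0.8 * rng.random(ga.nnz)
    for j in range(n_a):  # every feature touches at least one gene
        ga = ga.tolil()
        if ga[:, j].nnz == 0:
            ga[int(rng.integers(0, n_g)), j] = float(rng.uniform(0.2, 1.0))
    gp = sp.lil_matrix((n_g, n_p))
    for j in range(n_p):
        for i in rng.choice(n_g, size=2, replace=False):
            gp[int(i), j] = 1.0
    return assemble_adjacency(genes, events, paths, gg, ga.tocoo(), gp.tocoo())


@pytest.fixture
def toy_net():
    """Deterministic 8-node fixture: 4 genes, 2 AS events, 2 pathways.

    f_query is adjacent only to g0/g1; f_other only to g2/g3 with the
    same topology, so a {g0, g1} query must rank f_query above f_other.
    """
    genes = ["g0", "g1", "g2", "g3"]
    events = ["SE:gx:chr1:+:1-2:3-4", "SE:gy:chr1:+:5-6:7-8"]
    paths = ["pwA", "pwB"]
    gg = [("g0", "g1", 0.9), ("g1", "g2", 0.5), ("g2", "g3", 0.9)]
    ga = sp.coo_matrix(
        (np.array([0.8, 0.8, 0.8, 0.8]), (np.array([0, 1, 2, 3]), np.array([0, 0, 1, 1]))),
        shape=(4, 2),
    )
    gp = sp.coo_matrix(
        (np.array([1.0, 1.0, 1.0, 1.0]), (np.array([0, 1, 2, 3]), np.array([0, 0, 1, 1]))),
        shape=(4, 2),
    )
    return assemble_adjacency(genes, events, paths, gg, ga, gp)


def dense_rwr_oracle(T, v, c):
    """Closed-form stationary vector: pi = c (I - (1-c) T)^-1 v."""
    Td = np.asarray(T.todense())
    n = Td.shape[0]
    return c * np.linalg.solve(np.eye(n) - (1 - c) * Td, np.asarray(v, float))


@pytest.fixture
def small_dataset():
    from splicefi import SimParams, generate_dataset

    params = SimParams(
        n_genes=600, n_das=60, n_null_events=60, n_per_group=8,
        depth_factor=3.3, frac_deg=0.08, seed=7,
    )
    return generate_dataset(params)
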