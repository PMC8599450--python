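"""CDR3 similarity networks from a normalised amino-acid-triplet kernel.

Sequence similarity is the length-3 spectrum kernel: the inner product
of triplet (3-mer) count vectors, counted with multiplicity, normalised
so that k(x, x) = 1:

    K(x, y) = sum_t c_x(t) c_y(t) / sqrt(k(x,x) k(y,y))

Two CDR3s are connected when K > 0.82 (a threshold optimised
previously for antigen-sharing TCR pairs); clusters are connected
components with at least two members.  Observed cluster counts around
expanded clones are normalised by the mean count around equally many
randomly selected clones (Nreal/Ncon), which corrects for the number of
expanded clones per sample.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KernelConfig:
    k: int = 3
    edge_threshold: float = 0.82
    min_len: int = 3

    def __post_init__(self) -> None:
        if self.k != 3:
            raise ValueError("the triplet kernel is defined for k = 3")
        if not 0 < self.edge_threshold < 1:
            raise ValueError("edge_threshold must lie in (0, 1)")


@dataclass
class SimilarityNetwork:
    """CDR3 nodes, kernel edges above threshold and their clusters.

    ``clusters`` are connected components of size >= 2, each a sorted
    tuple of CDR3s; singleton nodes are not clusters.  ``membership``
    maps a clustered CDR3 to its cluster index.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    clusters: list[tuple[str, ...]]
    graph: nx.Graph = field(repr=False)
    n_excluded_short: int = 0

    @property
    def membership(self) -> dict[str, int]:
        return {c: i for i, cl in enumerate(self.clusters) for c in cl}


@dataclass(frozen=True)
class NormalizedClusterCount:
    """Observed vs control cluster counts around expanded clones."""

    n_real: int
    n_control_mean: float
    n_controls: int
    control_counts: tuple[int, ...]
    ratio: float | None

    @property
    def is_defined(self) -> bool:
        return self.ratio is not None


def _triplet_counter(s: str) -> Counter:
    return Counter(s[i : i + 3] for i in range(len(s) - 2))


def triplet_kernel(s1: str, s2: str) -> float:
    """Normalised triplet spectrum kernel between two CDR3 sequences.

    Triplets are counted with multiplicity; the value is 1 iff the two
    triplet count vectors are proportional, 0 iff no triplet is shared.
    Sequences shorter than 3 residues have no triplets and are a caller
    error.
    """
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError("triplet kernel requires sequences of length >= 3")
    c1, c2 = _triplet_counter(s1), _triplet_counter(s2)
    k12 = sum(n * c2[t] for t, n in c1.items())
    k11 = sum(n * n for n in c1.values())
    k22 = sum(n * n for n in c2.values())
    return k12 / np.sqrt(k11 * k22)


def _kernel_matrix(seqs: list[str]) -> np.ndarray:
    """Dense normalised kernel matrix via a sparse 3-mer count matrix."""
    vocab: dict[str, int] = {}
    rows, cols, vals = [], [], []
    for i, s in enumerate(seqs):
        for t, n in _triplet_counter(s).items():
            j = vocab.setdefault(t, len(vocab))
            rows.append(i)
            cols.append(j)
            vals.append(n)
    x = sp.csr_matrix((vals, (rows, cols)), shape=(len(seqs), len(vocab)), dtype=np.float64)
    norms = np.sqrt(np.asarray(x.multiply(x).sum(axis=1)).ravel())
    k = (x @ x.T).toarray()
    return k / np.outer(norms, norms)


def build_network(
    cdr3_set: list[str], cfg: KernelConfig = KernelConfig()
) -> SimilarityNetwork:
    """Build the CDR3 similarity network at the configured threshold.

    The input is deduplicated; sequences shorter than ``min_len`` are
    excluded with a logged count.  Edges require kernel strictly above
    ``edge_threshold``; node and cluster orderings are deterministic.
    """
    uniq = sorted(set(cdr3_set))
    seqs = [s for s in uniq if len(s) >= max(cfg.min_len, 3)]
    n_short = len(uniq) - len(seqs)
    if n_short:
        logger.info("excluded %d CDR3s shorter than %d residues", n_short, max(cfg.min_len, 3))
    g = nx.Graph()
    g.add_nodes_from(seqs)
    edges: list[tuple[str, str, float]] = []
    if len(seqs) >= 2:
        k = _kernel_matrix(seqs)
        ii, jj = np.nonzero(np.triu(k > cfg.edge_threshold, 1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            edges.append((seqs[i], seqs[j], float(k[i, j])))
        g.add_weighted_edges_from(edges, weight="kernel")
    clusters = sorted(
        (tuple(sorted(comp)) for comp in nx.connected_components(g) if len(comp) >= 2),
    )
    return SimilarityNetwork(
        nodes=seqs, edges=edges, clusters=clusters, graph=g, n_excluded_short=n_short
    )


def count_expanded_clusters(net: SimilarityNetwork, expanded: set[str]) -> int:
    """Number of clusters containing at least one expanded CDR3."""
    known = expanded & set(net.nodes)
    missing = len(expanded) - len(known)
    if missing:
        logger.info("%d expanded CDR3s not present in the network (ignored)", missing)
    return sum(1 for cl in net.clusters if known.intersection(cl))


def normalized_cluster_count(
    net: SimilarityNetwork,
    expanded: set[str],
    n_controls: int = 10,
    seed: int | np.random.Generator | None = None,
    control_pool: str = "all",
) -> NormalizedClusterCount:
    """Nreal/Ncon normalised count of clusters holding expanded clones.

    Each control draw selects as many CDR3s as there are expanded ones,
    uniformly without replacement — by default from all network nodes
    regardless of cluster membership (``control_pool='all'``), or from
    unclustered nodes only (``control_pool='unclustered'``) — and
    recounts clusters around them.  The ratio is undefined (None) when
    the control mean is zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expanded_in_net = expanded & set(net.nodes)
    n_real = count_expanded_clusters(net, expanded_in_net)
    if control_pool == "all":
        pool = net.nodes
    elif control_pool == "unclustered":
        clustered = set(net.membership)
        pool = [n for n in net.nodes if n not in clustered]
    else:
        raise ValueError("control_pool must be 'all' or 'unclustered'")
    k = min(len(expanded_in_net), len(pool))
    controls = []
    for _ in range(n_controls):
        draw = set(rng.choice(len(pool), size=k, replace=False).tolist())
        picked = {pool[i] for i in draw}
        controls.append(count_expanded_clusters(net, picked))
    mean_con = float(np.mean(controls)) if controls else 0.0
    ratio = n_real / mean_con if mean_con > 0 else None
    if ratio is None:
        logger.info("normalised cluster count undefined: control mean is zero")
    return NormalizedClusterCount(
        n_real=n_real,
        n_control_mean=mean_con,
        n_controls=n_controls,
        control_counts=tuple(controls),
        ratio=ratio,
    )


def fate_cluster_proportions(
    pre_net: SimilarityNetwork, fates: dict[str, str]
) -> dict[str, float | None]:
    """Clusters-per-clone proportions for maintained vs replaced clones.

    For each fate class, the number of pre-treatment clusters containing
    at least one clone of that class divided by the number of clones of
    that class.  A class with no clones yields None.
    """
    out: dict[str, float | None] = {}
    for fate in ("maintained", "replaced"):
        members = {c for c, f in fates.items() if f == fate}
        if not members:
            out[fate] = None
            continue
        n_clusters = sum(1 for cl in pre_net.clusters if members.intersection(cl))
        out[fate] = n_clusters / len(members)
    return out
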