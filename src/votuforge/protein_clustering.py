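"""Genus/family clustering from amino-acid identity, and tANI clustering.

Genome pairs are scored by average amino-acid identity (AAI, the unweighted
mean percent identity over shared protein best hits) and by the fraction of
shared genes (denominator: the smaller per-genome gene count).  A rank
graph keeps edges passing the rank's thresholds — genus: >= 20% shared
genes and >= 40% AAI; family: >= 10% and >= 20% — and is partitioned with
the Markov Clustering algorithm (inflation 2.0 for genus, 1.2 for family).

The VIRIDIC-like route clusters genomes by *total* ANI (tANI: ANI
discounted by aligned genome fraction) with single-linkage components at
95% (species) and 70% (genus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .io_formats import ProteinHit
from .species_clustering import PairANI

__all__ = [
    "GenomePairAAI",
    "RankGraph",
    "TaniPair",
    "RANK_THRESHOLDS",
    "compute_aai",
    "build_rank_graph",
    "mcl",
    "compute_tani",
    "tani_cluster",
]

#: (min frac_shared, min AAI) per rank.
RANK_THRESHOLDS = {"genus": (0.20, 40.0), "family": (0.10, 20.0)}

AAI_MAX_EVALUE = 1e-5
AAI_MIN_COV = 50.0


@dataclass(frozen=True)
class GenomePairAAI:
    genome_a: str
    genome_b: str
    aai: float
    shared_genes: int
    frac_shared: float
    n_genes_a: int
    n_genes_b: int


@dataclass(frozen=True)
class TaniPair:
    genome_a: str
    genome_b: str
    tani: float


@dataclass
class RankGraph:
    graph: nx.Graph
    rank: str


def compute_aai(hits: Iterable[ProteinHit],
                gene_counts: Mapping[str, int]) -> list[GenomePairAAI]:
    """Per-pair AAI and shared-gene fraction from raw protein hits.

    Hits are filtered (evalue < 1e-5, both coverages >= 50%), then reduced
    to the best hit per (query protein, target genome) — ties broken by
    lower evalue, higher pident, lexicographic target protein.  For each
    unordered genome pair, shared genes and the AAI mean are taken over the
    kept hits whose queries belong to the smaller-gene-count genome, so the
    shared fraction is comparable between fragments and full genomes.
    """
    best: dict[tuple[str, str], ProteinHit] = {}
    for h in hits:
        if h.query_genome not in gene_counts:
            raise KeyError(f"protein {h.query_protein!r} maps to unknown genome {h.query_genome!r}")
        if h.target_genome not in gene_counts:
            raise KeyError(f"protein {h.target_protein!r} maps to unknown genome {h.target_genome!r}")
        if h.query_genome == h.target_genome:
            continue
        if h.evalue >= AAI_MAX_EVALUE or h.qcov < AAI_MIN_COV or h.tcov < AAI_MIN_COV:
            continue
        key = (h.query_protein, h.target_genome)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.pident, h.target_protein) < (cur.evalue, -cur.pident, cur.target_protein):
            best[key] = h

    # kept hits grouped by directed genome pair
    directed: dict[tuple[str, str], list[ProteinHit]] = {}
    for h in best.values():
        directed.setdefault((h.query_genome, h.target_genome), []).append(h)

    out = []
    seen: set[tuple[str, str]] = set()
    for (ga, gb) in directed:
        key = tuple(sorted((ga, gb)))
        if key in seen:
            continue
        seen.add(key)
        a, b = key
        # direction: queries from the smaller-gene-count genome (ties: lex)
        small = a if (gene_counts[a], a) <= (gene_counts[b], b) else b
        other = b if small == a else a
        kept = directed.get((small, other), [])
        if not kept:  # hits exist only in the other direction
            kept = directed.get((other, small), [])
        if not kept:
            continue
        shared = len(kept)
        aai = float(np.mean([h.pident for h in kept]))
        denom = min(gene_counts[a], gene_counts[b])
        out.append(GenomePairAAI(
            genome_a=a, genome_b=b, aai=aai, shared_genes=shared,
            frac_shared=shared / denom,
            n_genes_a=gene_counts[a], n_genes_b=gene_counts[b],
        ))
    return out


def build_rank_graph(pairs: Iterable[GenomePairAAI], rank: str,
                     nodes: Iterable[str] | None = None) -> RankGraph:
    """Threshold the AAI pair table into the weighted graph for one rank."""
    if rank not in RANK_THRESHOLDS:
        raise ValueError(f"rank must be one of {sorted(RANK_THRESHOLDS)}")
    min_frac, min_aai = RANK_THRESHOLDS[rank]
    g = nx.Graph()
    pairs = list(pairs)
    if nodes is None:
        for p in pairs:
            g.add_node(p.genome_a)
            g.add_node(p.genome_b)
    else:
        g.add_nodes_from(nodes)
    for p in pairs:
        if p.frac_shared >= min_frac and p.aai >= min_aai:
            g.add_edge(p.genome_a, p.genome_b, weight=p.aai)
    return RankGraph(g, rank)


def mcl(graph: RankGraph | nx.Graph,
        inflation: float,
        max_iter: int = 100,
        prune_threshold: float = 1e-5,
        tol: float = 1e-6) -> list[set[str]]:
    """Markov Clustering on a weighted undirected graph.

    Standard scheme: add self-loops (weight = the node's maximum incident
    edge weight, 1 for isolated nodes), column-normalize, then alternate
    expansion (matrix squaring) and inflation (elementwise power followed
    by renormalization) with pruning of entries below ``prune_threshold``
    until the matrix change drops below ``tol`` or ``max_iter`` is hit (a
    warning is issued and the current interpretation returned).  Clusters
    are the connected components of the converged matrix's support;
    deterministic given graph and parameters.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    g = graph.graph if isinstance(graph, RankGraph) else graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        return []
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    loop = m.max(axis=0)
    loop[loop == 0.0] = 1.0
    np.fill_diagonal(m, loop)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m                      # expansion
        m = np.power(m, inflation)     # inflation
        m[m < prune_threshold] = 0.0
        colsums = m.sum(axis=0, keepdims=True)
        colsums[colsums == 0.0] = 1.0
        m /= colsums
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations; "
                      "returning the current interpretation", RuntimeWarning)

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return [set(nodes[i] for i in comp) for comp in nx.connected_components(support)]


def compute_tani(pair: PairANI, mode: str = "mean") -> TaniPair:
    """Total ANI of a pair: ANI discounted by aligned genome fraction.

    ``mean`` (default): tani = ani * (qcov + tcov) / 2 / 100 — symmetric in
    genome length.  ``min``: tani = ani * min(qcov, tcov) / 100.
    """
    if mode == "mean":
        frac = (pair.qcov + pair.tcov) / 2.0 / 100.0
    elif mode == "min":
        frac = min(pair.qcov, pair.tcov) / 100.0
    else:
        raise ValueError("mode must be 'mean' or 'min'")
    return TaniPair(pair.query_id, pair.target_id, pair.ani * frac)


def tani_cluster(pairs: Iterable[TaniPair],
                 nodes: Iterable[str] | None = None,
                 species_thr: float = 95.0,
                 genus_thr: float = 70.0) -> dict[str, list[set[str]]]:
    """Single-linkage species/genus partitions from tANI edges.

    Components of the graph with edges at tani >= threshold, per rank; the
    species partition refines the genus partition because its edge set is a
    subset.
    """
    for name, thr in (("species_thr", species_thr), ("genus_thr", genus_thr)):
        if not 0.0 < thr <= 100.0:
            raise ValueError(f"{name} must lie in (0, 100]")
    pairs = list(pairs)
    all_nodes: set[str] = set(nodes) if nodes is not None else set()
    for p in pairs:
        all_nodes.update((p.genome_a, p.genome_b))
    out = {}
    for rank, thr in (("species", species_thr), ("genus", genus_thr)):
        g = nx.Graph()
        g.add_nodes_from(all_nodes)
        g.add_edges_from((p.genome_a, p.genome_b) for p in pairs if p.tani >= thr)
        out[rank] = [set(c) for c in nx.connected_components(g)]
    return out
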