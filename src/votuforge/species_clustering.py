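"""Merged-local-alignment ANI and greedy species-level vOTU clustering.

Pairwise ANI is the alignment-length-weighted mean identity over all local
alignments of a genome pair; per-genome coverage is the merged span of
those alignments divided by genome length.  Species-level clustering is
CD-HIT-like and greedy: genomes are processed longest-first and each joins
the first existing cluster centroid it matches at >= ``min_ani`` ANI with
>= ``min_tcov`` coverage of the shorter of the two sequences (the MIUViG
95/85 criterion), else founds a new cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GenomeRecord, LocalAlignment

__all__ = [
    "PairANI",
    "SpeciesCluster",
    "merge_intervals",
    "pair_ani",
    "compute_pair_anis",
    "greedy_cluster",
    "cross_catalog_overlap",
]


@dataclass(frozen=True)
class PairANI:
    """Merged ANI + bidirectional coverage summary of an ordered genome pair."""

    query_id: str
    target_id: str
    ani: float
    qcov: float
    tcov: float
    n_alignments: int


@dataclass(frozen=True)
class SpeciesCluster:
    centroid_id: str
    member_ids: tuple[str, ...]  # includes the centroid


def merge_intervals(intervals: Iterable[tuple[int, int]], seq_len: int | None = None):
    """Merge 0-based half-open intervals; return (merged, covered_length)."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for start, end in ivs:
        if start < 0 or start >= end:
            raise ValueError(f"invalid interval [{start},{end})")
        if seq_len is not None and end > seq_len:
            raise ValueError(f"interval [{start},{end}) exceeds sequence length {seq_len}")
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    covered = sum(e - s for s, e in merged)
    return [tuple(iv) for iv in merged], covered


def pair_ani(alignments: Sequence[LocalAlignment], qlen: int, tlen: int) -> PairANI | None:
    """Combine all local alignments of one ordered (query, target) pair.

    ANI is the alignment-length-weighted mean identity; coverage on each
    genome is computed from the union of (possibly overlapping) alignment
    spans.  Self-pairs are not admitted; an empty alignment set yields None
    (the pair is treated as ANI 0 downstream).
    """
    if not alignments:
        return None
    q, t = alignments[0].query_id, alignments[0].target_id
    if q == t:
        raise ValueError(f"self-pair {q} not admitted in pair_ani")
    for a in alignments:
        if (a.query_id, a.target_id) != (q, t):
            raise ValueError("alignments mix different (query,target) pairs")
    total = sum(a.aln_len for a in alignments)
    ani = sum(a.pident * a.aln_len for a in alignments) / total
    _, qcovered = merge_intervals([a.q_interval for a in alignments], qlen)
    _, tcovered = merge_intervals([a.t_interval for a in alignments], tlen)
    return PairANI(q, t, ani, 100.0 * qcovered / qlen, 100.0 * tcovered / tlen, len(alignments))


def compute_pair_anis(alignments: Iterable[LocalAlignment],
                      genome_lengths: Mapping[str, int]) -> list[PairANI]:
    """Group an alignment table by ordered pair and combine each group.

    Self-alignments are excluded before weighting.
    """
    groups: dict[tuple[str, str], list[LocalAlignment]] = {}
    for a in alignments:
        if a.is_self:
            continue
        for gid in (a.query_id, a.target_id):
            if gid not in genome_lengths:
                raise KeyError(f"alignment references unknown genome id {gid!r}")
        groups.setdefault((a.query_id, a.target_id), []).append(a)
    out = []
    for (q, t), alns in groups.items():
        pa = pair_ani(alns, genome_lengths[q], genome_lengths[t])
        if pa is not None:
            out.append(pa)
    return out


class _PairLookup:
    """Direction-agnostic lookup giving (ani, coverage-of-shorter, cov-of-g)."""

    def __init__(self, pairs: Iterable[PairANI], lengths: Mapping[str, int]):
        self.lengths = lengths
        self.by_pair: dict[tuple[str, str], PairANI] = {}
        for p in pairs:
            for gid in (p.query_id, p.target_id):
                if gid not in lengths:
                    raise KeyError(f"pair references unknown genome id {gid!r}")
            self.by_pair.setdefault((p.query_id, p.target_id), p)

    def stats(self, g: str, c: str) -> tuple[float, float, float] | None:
        p = self.by_pair.get((g, c))
        if p is not None:
            cov_g, cov_c = p.qcov, p.tcov
        else:
            p = self.by_pair.get((c, g))
            if p is None:
                return None
            cov_g, cov_c = p.tcov, p.qcov
        shorter_cov = cov_g if self.lengths[g] <= self.lengths[c] else cov_c
        return p.ani, shorter_cov, cov_g


def greedy_cluster(genomes: Sequence[GenomeRecord] | Mapping[str, int],
                   pairs: Iterable[PairANI],
                   min_ani: float = 95.0,
                   min_tcov: float = 85.0,
                   min_qcov: float = 0.0,
                   coverage_of: str = "shorter") -> list[SpeciesCluster]:
    """CD-HIT-like greedy clustering into species-level vOTUs.

    Genomes are processed in descending length order (ties broken by
    ascending id); each joins the earliest-founded centroid reached at
    ``ani >= min_ani`` with coverage >= ``min_tcov``.  ``coverage_of``
    selects whether that coverage is measured on the shorter of the two
    sequences (default, the MIUViG wording) or strictly on the centroid
    (``"target"``).  The result is a partition of the input.
    """
    if coverage_of not in ("shorter", "target"):
        raise ValueError("coverage_of must be 'shorter' or 'target'")
    if isinstance(genomes, Mapping):
        lengths = dict(genomes)
    else:
        lengths = {g.id: g.length for g in genomes}
    lookup = _PairLookup(pairs, lengths)
    order = sorted(lengths, key=lambda gid: (-lengths[gid], gid))

    centroids: list[str] = []
    members: dict[str, list[str]] = {}
    for g in order:
        placed = False
        for c in centroids:
            st = lookup.stats(g, c)
            if st is None:
                continue
            ani, shorter_cov, cov_g = st
            cov = shorter_cov if coverage_of == "shorter" else _target_cov(lookup, g, c)
            if ani >= min_ani and cov >= min_tcov and cov_g >= min_qcov:
                members[c].append(g)
                placed = True
                break
        if not placed:
            centroids.append(g)
            members[g] = [g]
    return [SpeciesCluster(c, tuple(members[c])) for c in centroids]


def _target_cov(lookup: _PairLookup, g: str, c: str) -> float:
    p = lookup.by_pair.get((g, c))
    if p is not None:
        return p.tcov
    return lookup.by_pair[(c, g)].qcov


def cross_catalog_overlap(catalog_a: Sequence[GenomeRecord] | Mapping[str, int],
                          catalog_b: Sequence[GenomeRecord] | Mapping[str, int],
                          pairs: Iterable[PairANI],
                          min_ani: float = 95.0,
                          min_tcov: float = 85.0) -> dict[str, int]:
    """Species-level overlap between two genome catalogs.

    The union is clustered at the species thresholds; a cluster is *shared*
    when it holds members from both catalogs.  Returns counts of shared
    clusters and clusters private to each catalog.
    """
    la = dict(catalog_a) if isinstance(catalog_a, Mapping) else {g.id: g.length for g in catalog_a}
    lb = dict(catalog_b) if isinstance(catalog_b, Mapping) else {g.id: g.length for g in catalog_b}
    collisions = set(la) & set(lb)
    if collisions:
        raise ValueError(
            f"{len(collisions)} genome ids occur in both catalogs (e.g. {sorted(collisions)[:3]}); "
            "prefix catalog ids before computing overlap")
    union = {**la, **lb}
    clusters = greedy_cluster(union, pairs, min_ani=min_ani, min_tcov=min_tcov)
    shared = only_a = only_b = 0
    for cl in clusters:
        has_a = any(m in la for m in cl.member_ids)
        has_b = any(m in lb for m in cl.member_ids)
        if has_a and has_b:
            shared += 1
        elif has_a:
            only_a += 1
        else:
            only_b += 1
    return {"shared": shared, "unique_to_a": only_a, "unique_to_b": only_b,
            "clusters": len(clusters)}
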