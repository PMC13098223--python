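"""Read-recruitment relative abundance with identity/aligned-fraction/breadth filters.

A read counts toward a genome only if its primary alignment passes
``min_identity`` (percent identity over alignment columns, edit-distance
based) and ``min_aligned`` (percent of the full read length aligned,
soft clips included in the denominator).  A genome registers in a sample
only if the passing reads cover >= ``min_breadth`` percent of its length;
below that, its read count and abundance are forced to exactly 0.  The
defaults (90 / 75 / 75) follow common practice for viral community
profiling with read mappers.

Relative abundance is reported as the fraction of the sample's total reads
recruited per genome; a within-virome normalization (fraction of recruited
reads) is available for composition analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .species_clustering import merge_intervals

__all__ = [
    "ReadAlignment",
    "AbundanceMatrix",
    "read_sam",
    "alignment_metrics",
    "recruit",
    "build_matrix",
    "mapped_fraction",
]

_QUERY_CONSUMING = frozenset("MIS=X")
_REF_CONSUMING = frozenset("MD=X")
_ALIGNED_QUERY = frozenset("MI=X")  # read bases inside the alignment
_ALIGNED_COLS = frozenset("MID=X")  # identity denominator (edit-distance consistent)


@dataclass(frozen=True)
class ReadAlignment:
    """One SAM record reduced to the fields recruitment needs."""

    read_id: str
    genome_id: str | None
    read_len: int
    cigar: tuple[tuple[str, int], ...]  # (op, length)
    edit_distance: int | None  # NM tag
    ref_start: int  # 0-based
    mapped: bool
    primary: bool


def read_sam(path: str | Path) -> list[ReadAlignment]:
    """Parse a text SAM file (subset: QNAME, FLAG, RNAME, POS, CIGAR, SEQ, NM)."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            mapped = not rec.is_unmapped
            cigar = tuple()
            if mapped and rec.cigartuples:
                ops = "MIDNSHP=XB"
                cigar = tuple((ops[op], length) for op, length in rec.cigartuples)
            read_len = rec.infer_read_length() or (rec.query_length or 0)
            out.append(ReadAlignment(
                read_id=rec.query_name,
                genome_id=rec.reference_name if mapped else None,
                read_len=read_len,
                cigar=cigar,
                edit_distance=rec.get_tag("NM") if rec.has_tag("NM") else None,
                ref_start=rec.reference_start if mapped else -1,
                mapped=mapped,
                primary=not (rec.is_secondary or rec.is_supplementary),
            ))
    return out


def alignment_metrics(a: ReadAlignment) -> tuple[float, float]:
    """(percent identity, percent of read aligned) of one primary alignment.

    Identity = 100 * (columns - NM) / columns with columns = M/=/X + I + D
    (consistent with the edit distance); aligned fraction = 100 * read
    bases consumed by M/=/X/I over the full read length including soft
    clips.  Pass ``identity_denominator="M"`` logic upstream if a
    match-columns-only convention is needed.
    """
    if not a.mapped or not a.primary:
        raise ValueError(f"read {a.read_id}: metrics require a mapped primary alignment")
    if a.edit_distance is None:
        raise ValueError(f"read {a.read_id}: NM tag missing")
    cols = sum(length for op, length in a.cigar if op in _ALIGNED_COLS)
    if cols == 0:
        raise ValueError(f"read {a.read_id}: CIGAR has no aligned columns")
    aligned_read_bases = sum(length for op, length in a.cigar if op in _ALIGNED_QUERY)
    identity = 100.0 * (cols - a.edit_distance) / cols
    if a.read_len <= 0:
        raise ValueError(f"read {a.read_id}: unknown read length")
    aligned_fraction = 100.0 * aligned_read_bases / a.read_len
    return identity, aligned_fraction


def _ref_span(a: ReadAlignment) -> tuple[int, int]:
    consumed = sum(length for op, length in a.cigar if op in _REF_CONSUMING)
    return (a.ref_start, a.ref_start + consumed)


@dataclass
class SampleRecruitment:
    """Per-sample recruitment result before matrix assembly."""

    counts: pd.Series         # reads recruited per genome (breadth-filtered)
    breadth: pd.Series        # percent of genome covered by passing reads
    total_reads: int          # all primary reads in the sample (incl. unmapped)


def recruit(alignments: Iterable[ReadAlignment],
            genome_lengths: Mapping[str, int],
            min_identity: float = 90.0,
            min_aligned: float = 75.0,
            min_breadth: float = 75.0,
            total_reads: int | None = None) -> SampleRecruitment:
    """Recruit one sample's reads against the vOTU catalog.

    Filter order follows read-mapper practice: per-read identity and
    aligned-fraction thresholds first, then the per-genome breadth filter
    over passing reads only.  Secondary and supplementary alignments never
    contribute.  ``total_reads`` defaults to the number of primary records
    (mapped + unmapped) seen.
    """
    counts: dict[str, int] = {g: 0 for g in genome_lengths}
    spans: dict[str, list[tuple[int, int]]] = {g: [] for g in genome_lengths}
    n_primary = 0
    for a in alignments:
        if not a.primary:
            continue
        n_primary += 1
        if not a.mapped:
            continue
        if a.genome_id not in genome_lengths:
            raise KeyError(f"read {a.read_id}: genome {a.genome_id!r} absent from length table")
        identity, aligned = alignment_metrics(a)
        if identity < min_identity or aligned < min_aligned:
            continue
        counts[a.genome_id] += 1
        spans[a.genome_id].append(_ref_span(a))

    breadth = {}
    for g, ivs in spans.items():
        glen = genome_lengths[g]
        clipped = [(s, min(e, glen)) for s, e in ivs]
        _, covered = merge_intervals(clipped, glen) if clipped else ([], 0)
        breadth[g] = 100.0 * covered / glen
        if breadth[g] < min_breadth:
            counts[g] = 0  # breadth filter forces exact zero

    total = total_reads if total_reads is not None else n_primary
    if total <= 0:
        raise ValueError("sample has zero total reads")
    genomes = sorted(genome_lengths)
    return SampleRecruitment(
        counts=pd.Series([counts[g] for g in genomes], index=genomes, dtype=int),
        breadth=pd.Series([breadth[g] for g in genomes], index=genomes, dtype=float),
        total_reads=total,
    )


@dataclass
class AbundanceMatrix:
    """Samples x vOTU relative abundances with companion totals and breadth."""

    abundance: pd.DataFrame   # fraction of sample reads recruited per vOTU
    counts: pd.DataFrame      # recruited read counts
    breadth: pd.DataFrame     # percent genome covered, per (sample, vOTU)
    totals: pd.Series         # total reads per sample
    metadata: pd.DataFrame | None = None  # indexed by sample_id

    def relative_within_virome(self) -> pd.DataFrame:
        """Composition normalized to recruited (not total) reads per sample."""
        sums = self.counts.sum(axis=1)
        out = self.counts.div(sums.replace(0, np.nan), axis=0).fillna(0.0)
        return out

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def votus(self) -> list[str]:
        return list(self.abundance.columns)


def build_matrix(per_sample: Mapping[str, SampleRecruitment],
                 metadata: pd.DataFrame | None = None) -> AbundanceMatrix:
    """Assemble per-sample recruitments into an AbundanceMatrix."""
    samples = sorted(per_sample)
    counts = pd.DataFrame({s: per_sample[s].counts for s in samples}).T
    breadth = pd.DataFrame({s: per_sample[s].breadth for s in samples}).T
    totals = pd.Series({s: per_sample[s].total_reads for s in samples}, dtype=int)
    abundance = counts.div(totals, axis=0)
    if metadata is not None:
        missing = [s for s in samples if s not in metadata.index]
        if missing:
            raise KeyError(f"samples without metadata: {missing[:5]}")
        metadata = metadata.loc[samples]
    return AbundanceMatrix(abundance=abundance, counts=counts, breadth=breadth,
                           totals=totals, metadata=metadata)


def mapped_fraction(matrix: AbundanceMatrix,
                    by_region: bool = False):
    """Percent of each sample's reads recruited to the catalog.

    With ``by_region=True`` (requires attached metadata) also returns the
    per-region mean and standard deviation.
    """
    if (matrix.totals <= 0).any():
        raise ValueError("sample with zero total reads")
    per_sample = 100.0 * matrix.abundance.sum(axis=1)
    if not by_region:
        return per_sample
    if matrix.metadata is None or "region" not in matrix.metadata.columns:
        raise ValueError("by_region requires metadata with a 'region' column")
    grouped = per_sample.groupby(matrix.metadata["region"]).agg(["mean", "std"])
    return per_sample, grouped
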