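"""Readers and writers for the external formats the pipeline touches.

All external coordinates follow the BLAST convention (1-based, inclusive);
conversion to the 0-based half-open intervals used by every internal
interval routine happens exactly once, at this boundary, via the
``q_interval`` / ``t_interval`` accessors of :class:`LocalAlignment`.

Missing values are represented as ``None`` (never silently coerced to 0);
operations that need an absent field fail loudly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomeRecord",
    "LocalAlignment",
    "ProteinHit",
    "SampleMetadata",
    "FormatError",
    "GUT_REGIONS",
    "read_fasta",
    "write_fasta",
    "read_alignment_table",
    "write_alignment_table",
    "read_qc_table",
    "write_qc_table",
    "read_metadata",
    "write_metadata",
    "read_cluster_table",
    "write_cluster_table",
    "read_abundance_table",
    "write_abundance_table",
]


class FormatError(ValueError):
    """Raised on malformed input files (dialect violations, bad values)."""


#: The seven gut-region levels admitted in sample metadata.
GUT_REGIONS = ("crop", "duodenum", "jejunum", "ileum", "caeca", "colorectum", "feces")

_VALID_NT = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence (viral contig or draft genome)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("genome record with empty id")
        if not self.sequence:
            raise FormatError(f"genome {self.id!r} has empty sequence")
        if not _VALID_NT.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise FormatError(f"genome {self.id!r} contains invalid characters {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LocalAlignment:
    """One nucleotide local alignment (BLAST outfmt-6 row).

    Coordinates are stored as parsed (1-based inclusive, query always
    ascending).  Minus-strand rows (tstart > tend) are normalized at parse
    time to ascending target coordinates with ``strand == "-"``.
    """

    query_id: str
    target_id: str
    pident: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    tstart: int
    tend: int
    evalue: float
    bitscore: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.aln_len < 1:
            raise FormatError(f"alignment {self.query_id}/{self.target_id}: aln_len < 1")
        if not 0.0 <= self.pident <= 100.0:
            raise FormatError(f"alignment {self.query_id}/{self.target_id}: pident {self.pident} outside [0,100]")
        if self.qstart > self.qend:
            raise FormatError(f"alignment {self.query_id}/{self.target_id}: qstart > qend")
        if self.tstart > self.tend:
            raise FormatError(f"alignment {self.query_id}/{self.target_id}: tstart > tend after normalization")

    @property
    def is_self(self) -> bool:
        return self.query_id == self.target_id

    @property
    def q_interval(self) -> tuple[int, int]:
        """Query span as a 0-based half-open interval."""
        return (self.qstart - 1, self.qend)

    @property
    def t_interval(self) -> tuple[int, int]:
        """Target span as a 0-based half-open interval (strand ignored)."""
        return (self.tstart - 1, self.tend)


@dataclass(frozen=True)
class ProteinHit:
    """A protein-vs-protein search hit between two genomes."""

    query_protein: str
    target_protein: str
    query_genome: str
    target_genome: str
    pident: float
    qcov: float
    tcov: float
    evalue: float

    def __post_init__(self) -> None:
        for name in ("qcov", "tcov"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise FormatError(f"protein hit {self.query_protein}->{self.target_protein}: {name}={v} outside [0,100]")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample metadata; optional fields are None when absent."""

    sample_id: str
    region: str
    country: str | None = None
    breed: str | None = None
    diet: str | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.region not in GUT_REGIONS:
            raise FormatError(f"sample {self.sample_id!r}: unknown gut region {self.region!r} (expected one of {GUT_REGIONS})")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Parse a (possibly line-wrapped) multi-record FASTA file.

    Lowercase bases are uppercased.  Duplicate ids, empty sequences and
    malformed headers raise :class:`FormatError` naming the line number.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if cur_id is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"{path}: record {cur_id!r} (line {cur_line}) has empty sequence")
        try:
            records.append(GenomeRecord(cur_id, seq))
        except FormatError as e:
            raise FormatError(f"{path}: line {cur_line}: {e}") from None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: malformed header at line {lineno}")
                cur_id = header.split()[0]
                cur_line = lineno
                chunks = []
                if cur_id in seen:
                    raise FormatError(f"{path}: duplicate sequence id {cur_id!r} at line {lineno}")
                seen.add(cur_id)
            else:
                if cur_id is None:
                    raise FormatError(f"{path}: sequence data before any header at line {lineno}")
                chunks.append(line.strip())
    _flush()
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular alignments (BLAST outfmt 6 dialect)

_ALN_COLUMNS = [
    "query_id", "target_id", "pident", "aln_len", "mismatches", "gap_opens",
    "qstart", "qend", "tstart", "tend", "evalue", "bitscore",
]


def read_alignment_table(path: str | Path) -> list[LocalAlignment]:
    """Parse a 12-column tab-separated local-alignment table.

    Minus-strand rows are normalized to ascending target coordinates with a
    strand flag.  Self-alignments are retained (flagged via ``is_self``).
    """
    out: list[LocalAlignment] = []
    with open(path) as fh:
        for rowno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path}: row {rowno}: expected 12 columns, got {len(parts)}")
            try:
                tstart, tend = int(parts[8]), int(parts[9])
                strand = "+"
                if tstart > tend:
                    tstart, tend, strand = tend, tstart, "-"
                out.append(LocalAlignment(
                    query_id=parts[0], target_id=parts[1],
                    pident=float(parts[2]), aln_len=int(parts[3]),
                    mismatches=int(parts[4]), gap_opens=int(parts[5]),
                    qstart=int(parts[6]), qend=int(parts[7]),
                    tstart=tstart, tend=tend,
                    evalue=float(parts[10]), bitscore=float(parts[11]),
                    strand=strand,
                ))
            except (ValueError, FormatError) as e:
                raise FormatError(f"{path}: row {rowno}: {e}") from None
    return out


def write_alignment_table(alignments: Iterable[LocalAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            tstart, tend = (a.tend, a.tstart) if a.strand == "-" else (a.tstart, a.tend)
            fh.write("\t".join(str(v) for v in (
                a.query_id, a.target_id, a.pident, a.aln_len, a.mismatches,
                a.gap_opens, a.qstart, a.qend, tstart, tend, a.evalue, a.bitscore,
            )) + "\n")


# ---------------------------------------------------------------------------
# Contig QC table (CheckV-summary dialect)

_QC_REQUIRED = [
    "contig_id", "contig_length", "completeness", "contamination",
    "viral_genes", "host_genes", "termini",
]
_QC_MISSING = {"", "NA", "NaN", "nan", "None"}
_TERMINI_LEVELS = {"DTR", "ITR", "provirus", "none"}


def read_qc_table(path: str | Path):
    """Parse the per-contig quality table into ContigQCRecord objects.

    ``completeness`` may be missing (``NA``) and is then carried as absent
    (None), never as 0.
    """
    from .genome_qc import ContigQCRecord  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _QC_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    for rowno, row in enumerate(df.itertuples(index=False), 2):
        comp_raw = row.completeness.strip()
        completeness = None if comp_raw in _QC_MISSING else float(comp_raw)
        if completeness is not None and not 0.0 <= completeness <= 100.0:
            raise FormatError(f"{path}: row {rowno}: completeness {completeness} outside [0,100]")
        termini = row.termini.strip()
        if termini not in _TERMINI_LEVELS:
            raise FormatError(f"{path}: row {rowno}: unknown termini value {termini!r}")
        records.append(ContigQCRecord(
            contig_id=row.contig_id,
            length=int(row.contig_length),
            completeness=completeness,
            contamination=float(row.contamination),
            viral_genes=int(row.viral_genes),
            host_genes=int(row.host_genes),
            termini=termini,
        ))
    ids = [r.contig_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate contig_id values")
    return records


def write_qc_table(records, path: str | Path, extra_columns: Sequence[str] = ()) -> None:
    cols = list(_QC_REQUIRED) + list(extra_columns)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            comp = "NA" if r.completeness is None else f"{r.completeness:g}"
            row = [r.contig_id, str(r.length), comp, f"{r.contamination:g}",
                   str(r.viral_genes), str(r.host_genes), r.termini]
            for c in extra_columns:
                v = getattr(r, c, None)
                row.append("" if v is None else str(v))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata

def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "region"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for opt in ("country", "breed", "diet", "sex"):
            v = getattr(row, opt, "")
            kwargs[opt] = v if v not in _QC_MISSING else None
        out.append(SampleMetadata(sample_id=row.sample_id, region=row.region, **kwargs))
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample_id values")
    return out


def write_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in metadata:
        rows.append({
            "sample_id": m.sample_id, "region": m.region,
            "country": m.country or "NA", "breed": m.breed or "NA",
            "diet": m.diet or "NA", "sex": m.sex or "NA",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def metadata_frame(metadata: Iterable[SampleMetadata]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id (absent -> NaN)."""
    df = pd.DataFrame([{
        "sample_id": m.sample_id, "region": m.region, "country": m.country,
        "breed": m.breed, "diet": m.diet, "sex": m.sex,
    } for m in metadata])
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# Cluster and abundance tables

def write_cluster_table(clusters, path: str | Path) -> None:
    """Two-column (cluster_id/centroid, member) TSV, one row per member."""
    with open(path, "w") as fh:
        fh.write("cluster\tmember\n")
        for c in clusters:
            cid = c.centroid_id if hasattr(c, "centroid_id") else c[0]
            members = c.member_ids if hasattr(c, "member_ids") else c[1]
            for m in members:
                fh.write(f"{cid}\t{m}\n")


def read_cluster_table(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["cluster", "member"]:
        raise FormatError(f"{path}: expected header 'cluster\\tmember'")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.cluster, []).append(row.member)
    return out


def write_abundance_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative abundance entries")
    return df
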