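"""Contig retention filters, terminal-repeat detection and quality tiers.

A viral contig enters the catalog when it satisfies either of two rules:

* RULE-A: completeness >= 50, viral genes > 0, viral genes > 3 x host genes
* RULE-B: length >= 20,000 bp, completeness >= 40, viral genes > 0,
  viral genes > 3 x host genes

Retained contigs are tiered: *complete* when a genome-closure signal is
present (direct terminal repeat, inverted terminal repeat, or provirus
boundaries taken from the upstream QC table), otherwise *high* at
completeness >= 90, *medium* at >= 50, *low* below.

Terminal repeats are required to be strictly terminal: a DTR is a prefix of
length >= ``min_repeat_len`` repeated, in the same orientation, as the
suffix of the sequence; an ITR is a prefix whose reverse complement is the
suffix.  The exact-match search (the default, ``max_mismatches=0``) runs in
linear time: DTR candidates are exactly the borders of the sequence
(computed with the Knuth-Morris-Pratt failure function), ITR length is the
longest common prefix of the sequence and its reverse complement.  A repeat
may cover at most half the sequence, so prefix and suffix never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import GenomeRecord

__all__ = [
    "ContigQCRecord",
    "TerminiCall",
    "detect_termini",
    "apply_retention_filters",
    "assign_quality_tier",
    "run_qc",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

RULE_A_MIN_COMPLETENESS = 50.0
RULE_B_MIN_COMPLETENESS = 40.0
RULE_B_MIN_LENGTH = 20_000
VIRAL_TO_HOST_RATIO = 3.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ContigQCRecord:
    """One putative viral contig with its quality evaluation."""

    contig_id: str
    length: int
    completeness: float | None
    contamination: float
    viral_genes: int
    host_genes: int
    termini: str = "none"  # DTR | ITR | provirus | none
    tier: str | None = None  # complete | high | medium | low | rejected
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        if self.viral_genes < 0 or self.host_genes < 0:
            raise ValueError(f"{self.contig_id}: negative gene counts")
        if self.completeness is not None and not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"{self.contig_id}: completeness outside [0,100]")


@dataclass(frozen=True)
class TerminiCall:
    kind: str  # DTR | ITR | none
    repeat_length: int = 0
    mismatches: int = 0
    undetectable: bool = False  # sequence too short to search


def _kmp_borders(seq: str) -> list[int]:
    """All border lengths of ``seq`` (prefix == suffix), longest first."""
    n = len(seq)
    pi = np.zeros(n, dtype=np.int64)
    k = 0
    for i in range(1, n):
        while k > 0 and seq[i] != seq[k]:
            k = pi[k - 1]
        if seq[i] == seq[k]:
            k += 1
        pi[i] = k
    borders = []
    b = int(pi[n - 1])
    while b > 0:
        borders.append(b)
        b = int(pi[b - 1])
    return borders


def _lcp(a: str, b: str) -> int:
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    n = min(len(aa), len(bb))
    neq = np.nonzero(aa[:n] != bb[:n])[0]
    return int(neq[0]) if neq.size else n


def _best_repeat_with_mismatches(seq: str, other: str, min_len: int, max_mm: int) -> tuple[int, int]:
    """Longest k <= n//2 with hamming(seq[:k], other[-k:]) <= max_mm.

    Returns (length, mismatches) or (0, 0).  Quadratic scan; used only for
    the mismatch-tolerant configuration.
    """
    n = len(seq)
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(other.encode(), dtype=np.uint8)
    for k in range(n // 2, min_len - 1, -1):
        mm = int(np.count_nonzero(a[:k] != b[n - k:]))
        if mm <= max_mm:
            return k, mm
    return 0, 0


def detect_termini(genome: GenomeRecord, min_repeat_len: int = 20, max_mismatches: int = 0) -> TerminiCall:
    """Detect a strictly terminal direct or inverted repeat.

    DTR takes precedence over ITR when both qualify; the reported
    ``repeat_length`` is the maximal qualifying length.  Sequences shorter
    than ``2 * min_repeat_len`` are flagged undetectable.
    """
    if min_repeat_len < 1:
        raise ValueError("min_repeat_len must be >= 1")
    seq = genome.sequence
    n = len(seq)
    if n <= 2 * min_repeat_len:
        return TerminiCall("none", undetectable=True)

    rc = reverse_complement(seq)
    if max_mismatches == 0:
        dtr_len = next((b for b in _kmp_borders(seq) if b <= n // 2), 0)
        dtr_mm = 0
        # prefix_k(seq) == revcomp(suffix_k(seq)) == prefix_k(revcomp(seq))
        itr_len = min(_lcp(seq, rc), n // 2)
        itr_mm = 0
    else:
        dtr_len, dtr_mm = _best_repeat_with_mismatches(seq, seq, min_repeat_len, max_mismatches)
        itr_len, itr_mm = _itr_with_mismatches(seq, rc, min_repeat_len, max_mismatches)

    if dtr_len >= min_repeat_len:
        return TerminiCall("DTR", dtr_len, dtr_mm)
    if itr_len >= min_repeat_len:
        return TerminiCall("ITR", itr_len, itr_mm)
    return TerminiCall("none")


def _itr_with_mismatches(seq: str, rc: str, min_len: int, max_mm: int) -> tuple[int, int]:
    # prefix_k(seq) vs revcomp(suffix_k(seq)) == prefix_k(rc): cumulative scan
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(rc.encode(), dtype=np.uint8)
    half = len(seq) // 2
    mm = np.cumsum(a[:half] != b[:half])
    ok = np.nonzero(mm <= max_mm)[0]
    if ok.size == 0:
        return 0, 0
    k = int(ok[-1]) + 1
    return (k, int(mm[k - 1])) if k >= min_len else (0, 0)


# ---------------------------------------------------------------------------
# Retention filters

def _first_failure(rec: ContigQCRecord) -> str | None:
    """None if the record is retained, else the first failed clause."""
    if rec.completeness is None:
        return "completeness_absent"
    # RULE-A, clauses in stated order
    reason = None
    if rec.completeness < RULE_A_MIN_COMPLETENESS:
        reason = f"completeness<{RULE_A_MIN_COMPLETENESS:g}"
    elif rec.viral_genes <= 0:
        reason = "viral_genes==0"
    elif rec.viral_genes <= VIRAL_TO_HOST_RATIO * rec.host_genes:
        reason = "viral_genes<=3x_host_genes"
    else:
        return None
    # RULE-B rescue for long contigs
    if (rec.length >= RULE_B_MIN_LENGTH
            and rec.completeness >= RULE_B_MIN_COMPLETENESS
            and rec.viral_genes > 0
            and rec.viral_genes > VIRAL_TO_HOST_RATIO * rec.host_genes):
        return None
    return reason


def apply_retention_filters(records) -> tuple[list[ContigQCRecord], list[ContigQCRecord]]:
    """Split records into (kept, rejected) by the two retention rules.

    Records with absent completeness are rejected (both rules condition on
    it).  Rejected records carry the first failed clause in
    ``reject_reason``.
    """
    kept, rejected = [], []
    for rec in records:
        reason = _first_failure(rec)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append(replace(rec, tier="rejected", reject_reason=reason))
    return kept, rejected


def assign_quality_tier(record: ContigQCRecord) -> str:
    """Quality tier of a retained record.

    Closure signals dominate: any terminal-repeat or provirus call yields
    *complete* regardless of the completeness estimate.
    """
    if record.termini in ("DTR", "ITR", "provirus"):
        return "complete"
    if record.completeness is None:
        raise ValueError(f"{record.contig_id}: completeness absent; record did not pass retention filters")
    if record.completeness >= 90.0:
        return "high"
    if record.completeness >= 50.0:
        return "medium"
    return "low"


def run_qc(records, genomes=None, min_repeat_len: int = 20, max_mismatches: int = 0):
    """Full QC pass: termini detection (when sequences are supplied),
    retention filtering, and tier assignment.

    ``genomes`` maps contig ids to :class:`GenomeRecord`; detected DTR/ITR
    override a ``none`` termini field, while ``provirus`` calls from the
    input table are trusted as-is.  Returns (kept, rejected) with ``tier``
    set on every kept record.
    """
    if genomes is not None:
        by_id = {g.id: g for g in genomes} if not isinstance(genomes, dict) else genomes
        updated = []
        for rec in records:
            if rec.termini == "none" and rec.contig_id in by_id:
                call = detect_termini(by_id[rec.contig_id], min_repeat_len, max_mismatches)
                if call.kind != "none":
                    rec = replace(rec, termini=call.kind)
            updated.append(rec)
        records = updated
    kept, rejected = apply_retention_filters(records)
    kept = [replace(r, tier=assign_quality_tier(r)) for r in kept]
    return kept, rejected
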