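"""Independent reference implementations used only as test oracles.

Each oracle is deliberately naive (brute force, per-base bitmaps, textbook
recursions) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_termini(seq: str, min_repeat_len: int, max_mismatches: int) -> tuple[str, int]:
    """All-prefix/suffix comparison: (kind, maximal qualifying length)."""
    n = len(seq)
    if n <= 2 * min_repeat_len:
        return ("none", 0)
    best_dtr = best_itr = 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    for k in range(min_repeat_len, n // 2 + 1):
        if int((arr[:k] != arr[n - k:]).sum()) <= max_mismatches:
            best_dtr = k
        if int((arr[:k] != rc[:k]).sum()) <= max_mismatches:
            best_itr = k
    if best_dtr >= min_repeat_len:
        return ("DTR", best_dtr)
    if best_itr >= min_repeat_len:
        return ("ITR", best_itr)
    return ("none", 0)


def bitmap_coverage(intervals, length: int) -> int:
    """Per-base bitmap count of covered positions."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())


def global_identity(a: str, b: str, count_gaps: bool = True) -> float:
    """Needleman-Wunsch percent identity via Biopython's pairwise aligner.

    Unit mismatch/gap costs (edit-distance-like scoring).  With
    ``count_gaps`` (default) identity is matched columns over all alignment
    columns including gaps; without, gap columns are excluded from the
    denominator (substitution-only identity).
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + (counts.gaps if count_gaps else 0)
    return 100.0 * counts.identities / cols


def reference_mcl(adj: np.ndarray, inflation: float, max_iter: int = 200,
                  prune: float = 1e-5, tol: float = 1e-6) -> list[set[int]]:
    """Textbook Markov Clustering with attractor-based cluster read-off.

    Self-loops at the per-column max weight, column-stochastic updates,
    clusters extracted by union-find over attractor rows.
    """
    m = adj.astype(float).copy()
    n = m.shape[0]
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    for i in range(n):
        m[i, i] = loops[i]
    m = m / m.sum(axis=0)
    for _ in range(max_iter):
        prev = m.copy()
        m = np.linalg.matrix_power(m, 2)
        m = m ** inflation
        m[m < prune] = 0.0
        s = m.sum(axis=0)
        s[s == 0] = 1.0
        m = m / s
        if np.max(np.abs(m - prev)) < tol:
            break
    # union-find over rows with nonzero diagonal (attractors)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    attractors = [i for i in range(n) if m[i, i] > 0]
    for a in attractors:
        for j in range(n):
            if m[a, j] > 0:
                union(a, j)
    # nodes not touched by any attractor row become singletons
    clusters: dict[int, set[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(i)
    return list(clusters.values())


def mutate_sequence(seq: str, sub_rate: float, indel_rate: float,
                    rng: np.random.Generator) -> str:
    """Simple per-base mutator for oracle fixtures (independent of the
    package generator)."""
    bases = "ACGT"
    out = []
    for ch in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(bases[rng.integers(4)])  # insertion before
        if rng.random() < sub_rate:
            ch = bases[(bases.index(ch) + 1 + rng.integers(3)) % 4]
        out.append(ch)
    return "".join(out)
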