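"""Community-level statistics for the vOTU abundance matrix.

Implements the ecology layer of the catalog: observed richness,
region-wise core viromes, species-accumulation curves (random permutation
scheme), Bray-Curtis dissimilarity, one-way PERMANOVA (distance-based
pseudo-F with a label-permutation p-value), classical PCoA, rank tests
(Wilcoxon rank-sum and Kruskal-Wallis with tie corrections), host-group
abundance aggregation, and a negative-binomial richness regression with
breed, diet and their interaction.

Presence throughout means abundance strictly greater than zero *after* the
recruitment breadth filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceMatrix

__all__ = [
    "PermanovaResult",
    "AccumulationCurve",
    "richness",
    "prevalence",
    "core_virome",
    "accumulation_curve",
    "bray_curtis",
    "permanova",
    "pcoa",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "rank_tests",
    "host_group_abundance",
    "nb_richness_model",
]


def _abundance_frame(matrix) -> pd.DataFrame:
    return matrix.abundance if isinstance(matrix, AbundanceMatrix) else matrix


# ---------------------------------------------------------------------------
# Richness, prevalence, core virome

def richness(matrix) -> pd.Series:
    """Observed vOTU count (entries > 0) per sample."""
    df = _abundance_frame(matrix)
    return (df > 0).sum(axis=1)


def prevalence(matrix, groups: pd.Series | None = None) -> pd.DataFrame:
    """Per (group, vOTU) presence fraction; one 'all' group when ungrouped."""
    df = _abundance_frame(matrix) > 0
    if groups is None:
        groups = pd.Series("all", index=df.index)
    groups = groups.loc[df.index]
    rows = []
    for g, sub in df.groupby(groups):
        n = len(sub)
        pres = sub.sum(axis=0)
        for votu, np_ in pres.items():
            rows.append({"group": g, "votu": votu, "n_present": int(np_),
                         "n_samples": n, "prevalence": np_ / n})
    return pd.DataFrame(rows)


def core_virome(matrix, metadata: pd.DataFrame,
                thresholds: Sequence[float] = (0.25, 0.50, 0.75)) -> pd.DataFrame:
    """Count of vOTUs reaching each prevalence threshold, per gut region.

    Prevalence is computed within each region only (other samples are
    excluded from the denominator).
    """
    df = _abundance_frame(matrix)
    if "region" not in metadata.columns:
        raise ValueError("metadata must carry a 'region' column")
    prev = prevalence(df, metadata.loc[df.index, "region"])
    rows = []
    for region, sub in prev.groupby("group"):
        for thr in thresholds:
            rows.append({"region": region, "threshold": thr,
                         "n_core": int((sub["prevalence"] >= thr).sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Accumulation curves

@dataclass
class AccumulationCurve:
    mean: np.ndarray  # mean distinct vOTUs at step k (1-based steps)
    sd: np.ndarray
    n_perm: int


def accumulation_curve(matrix, n_perm: int = 1000, seed: int | None = None) -> AccumulationCurve:
    """Species-accumulation curve under random sample-order permutation.

    For each permutation of the sample order the cumulative number of
    distinct vOTUs is recorded at every step; mean and standard deviation
    are taken across permutations.  The final mean always equals the total
    number of distinct vOTUs.
    """
    df = _abundance_frame(matrix)
    presence = (df.values > 0)
    n = presence.shape[0]
    if n < 2:
        raise ValueError("accumulation curve requires >= 2 samples")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm, n), dtype=np.int64)
    for p in range(n_perm):
        order = rng.permutation(n)
        seen = np.logical_or.accumulate(presence[order], axis=0)
        curves[p] = seen.sum(axis=1)
    return AccumulationCurve(mean=curves.mean(axis=0), sd=curves.std(axis=0, ddof=1),
                             n_perm=n_perm)


# ---------------------------------------------------------------------------
# Bray-Curtis, PERMANOVA, PCoA

def bray_curtis(matrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    df = _abundance_frame(matrix)
    x = df.values.astype(float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative entries")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int


def _ss_within(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    ss = 0.0
    for g in uniq:
        mask = (labels == g).astype(float)
        ng = mask.sum()
        ss += mask @ d2 @ mask / (2.0 * ng)
    return ss


def permanova(dist: pd.DataFrame | np.ndarray, groups: Sequence,
              n_perm: int = 999, seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within accumulates within-group
    pairs; pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)); R^2 =
    SS_between / SS_total.  The p-value is (1 + #{F_perm >= F_obs}) /
    (1 + n_perm) under free permutation of the group labels.
    """
    d = dist.values if isinstance(dist, pd.DataFrame) else np.asarray(dist, dtype=float)
    labels = np.asarray(list(groups))
    n = d.shape[0]
    if d.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix and group labels are inconsistent")
    uniq, counts = np.unique(labels, return_counts=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"every group needs >= 2 samples (offending: {list(small)})")

    d2 = d ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = _ss_within(d2, labels, uniq)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ss_w = _ss_within(d2, perm, uniq)
        ss_b = ss_total - ss_w
        f_perm = (ss_b / (k - 1)) / (ss_w / (n - k))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p=float(p), n_perm=n_perm)


def pcoa(dist: pd.DataFrame | np.ndarray):
    """Classical scaling (principal coordinates) of a distance matrix.

    Eigendecomposition of the Gower-centered squared-distance matrix; axes
    ordered by eigenvalue, coordinates scaled by sqrt(eigenvalue) on
    positive axes.  Negative eigenvalues are reported, their axes dropped.
    Returns (coordinates DataFrame, eigenvalues array).
    """
    d = dist.values if isinstance(dist, pd.DataFrame) else np.asarray(dist, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=index, columns=cols), evals


# ---------------------------------------------------------------------------
# Rank tests

def _rank_sum_exact_sf(w: float, n1: int, n2: int) -> float:
    """Two-sided exact p for the rank-sum statistic of group 1 (no ties).

    Distribution of the sum of n1 ranks drawn from 1..n1+n2, by the classic
    shift/convolution recursion.
    """
    n = n1 + n2
    max_w = n1 * (2 * n - n1 + 1) // 2
    # counts[j][s] = number of j-subsets of {1..i} with rank sum s
    counts = np.zeros((n1 + 1, max_w + 1))
    counts[0, 0] = 1.0
    for i in range(1, n + 1):
        for j in range(min(i, n1), 0, -1):
            counts[j, i:] += counts[j - 1, : max_w + 1 - i]
    total = counts[n1].sum()
    probs = counts[n1] / total
    mean = n1 * (n + 1) / 2.0
    dev = abs(w - mean)
    support = np.arange(max_w + 1)
    p = probs[np.abs(support - mean) >= dev - 1e-9].sum()
    return float(min(1.0, p))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      continuity_threshold: int = 25) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the pooled sample is small (<= 25) and tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction.  Degenerate data (zero variance) yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    u = w - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    n = n1 + n2
    if not has_ties and n <= continuity_threshold:
        p = _rank_sum_exact_sf(w, n1, n2)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts ** 3 - tie_counts).sum()
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            return {"W": float(w), "U": float(u), "p": 1.0, "method": "degenerate"}
        z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        p = float(min(1.0, p))
        method = "normal"
    return {"W": float(w), "U": float(u), "p": float(p), "method": method}


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> dict:
    """Kruskal-Wallis H with tie correction; chi-square p-value."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(groups))
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups")
    n = len(values)
    ranks = stats.rankdata(values)
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[labels == g].sum() ** 2 / (labels == g).sum() for g in uniq
    ) - 3 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    if correction == 0.0:
        return {"H": 0.0, "df": len(uniq) - 1, "p": 1.0}
    h /= correction
    df = len(uniq) - 1
    return {"H": float(h), "df": df, "p": float(stats.chi2.sf(h, df))}


def rank_tests(values: Sequence[float], groups: Sequence) -> dict:
    """Kruskal-Wallis plus the pairwise Wilcoxon matrix (raw and
    Holm-adjusted p-values)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(groups))
    uniq = list(np.unique(labels))
    kw = kruskal_wallis(values, labels)
    rows = []
    for a, b in combinations(uniq, 2):
        res = wilcoxon_rank_sum(values[labels == a], values[labels == b])
        rows.append({"group_a": a, "group_b": b, "W": res["W"], "p": res["p"],
                     "method": res["method"]})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_holm"] = multipletests(pairwise["p"], method="holm")[1]
    return {"kruskal": kw, "pairwise": pairwise}


# ---------------------------------------------------------------------------
# Host aggregation and NB richness model

def host_group_abundance(matrix, host_table: pd.DataFrame,
                         rank: str = "family") -> pd.DataFrame:
    """Sum per-sample abundances over vOTUs sharing a predicted host taxon.

    ``host_table`` is indexed by vOTU id with a column per rank holding the
    best-score host prediction; vOTUs without an assignment (absent from
    the table or NaN) pool into ``no_host``.  Per-sample totals are
    conserved.
    """
    df = _abundance_frame(matrix)
    if rank not in host_table.columns:
        raise ValueError(f"host table lacks a {rank!r} column")
    mapping = host_table[rank].reindex(df.columns)
    mapping = mapping.fillna("no_host").replace("", "no_host")
    return df.T.groupby(mapping.values).sum().T


def nb_richness_model(richness_counts: Sequence[int],
                      breed: Sequence, diet: Sequence) -> dict:
    """Negative-binomial GLM of richness on breed * diet (log link).

    Dispersion is estimated by maximum likelihood; if the fit collapses to
    the Poisson limit (alpha ~ 0 or non-convergence) a Poisson GLM is used
    instead, with a warning.  Returns the coefficient table (with rate
    ratios and Wald p-values) and the dispersion estimate.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = np.asarray(richness_counts)
    if not np.all(counts == np.floor(counts)) or (counts < 0).any():
        raise ValueError("richness must be nonnegative integer counts")
    data = pd.DataFrame({"richness": counts.astype(int),
                         "breed": list(breed), "diet": list(diet)})
    for col in ("breed", "diet"):
        if data[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    family_used = "negative_binomial"
    alpha = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.negativebinomial("richness ~ breed * diet", data).fit(disp=False, maxiter=200)
            alpha = float(fit.params.get("alpha", np.nan))
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            converged = False
        if not converged or not np.isfinite(alpha) or alpha <= 1e-8:
            warnings.simplefilter("default")
            if not converged or not np.isfinite(alpha):
                warnings.warn("NB dispersion estimate unstable; falling back to Poisson GLM",
                              RuntimeWarning)
            fit = smf.glm("richness ~ breed * diet", data,
                          family=sm.families.Poisson()).fit()
            family_used = "poisson"
            alpha = 0.0

    params = fit.params.drop(labels=["alpha"], errors="ignore")
    bse = fit.bse.drop(labels=["alpha"], errors="ignore")
    pvals = fit.pvalues.drop(labels=["alpha"], errors="ignore")
    table = pd.DataFrame({
        "coef": params, "se": bse, "rate_ratio": np.exp(params), "p": pvals,
    })
    return {"coefficients": table, "alpha": alpha, "family": family_used, "fit": fit}
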