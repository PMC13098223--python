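"""Synthetic inputs with ground truth for every pipeline stage.

The generator emulates, at desk scale, the structure of a gut virome
catalog study: hierarchically diverged viral lineages (family > genus >
species > variant) with controllable within-rank divergence, contigs
truncated to known completeness with DTR/ITR/provirus decoration,
nucleotide alignment tables from a real pairwise aligner, protein-hit
tables with designed identity distributions, and region-stratified read
sets with host-family niche structure (Lactobacillaceae-dominated proximal
gut vs Lachnospiraceae/Bacteroidaceae/Ruminococcaceae-dominated distal
gut).  Every output is a pure function of (spec, seed).

Divergence fields are *expected pairwise* per-base substitution distances
between sibling taxa at that rank; each child is mutated from its parent
at half that rate.  Small indels occur at one tenth of the substitution
rate with geometric(0.5) lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .genome_qc import ContigQCRecord, reverse_complement
from .io_formats import GenomeRecord, LocalAlignment, ProteinHit, SampleMetadata

__all__ = [
    "LineageSpec",
    "TruthSet",
    "CommunityDesign",
    "SimulatedCommunity",
    "evolve_lineages",
    "decorate_contigs",
    "emit_alignments",
    "emit_protein_hits",
    "simulate_community",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Bacterial host families used for niche structure.
HOST_FAMILIES = ("Lactobacillaceae", "Lachnospiraceae", "Bacteroidaceae", "Ruminococcaceae")

PROXIMAL_REGIONS = ("crop", "duodenum", "jejunum", "ileum")
DISTAL_REGIONS = ("caeca", "colorectum", "feces")


@dataclass(frozen=True)
class LineageSpec:
    """Shape and divergence of the simulated viral lineage hierarchy."""

    n_families: int = 4
    genera_per_family: int = 2
    species_per_genus: int = 5
    variants_per_species: int = 3
    within_species_div: float = 0.02
    within_genus_div: float = 0.15
    within_family_div: float = 0.30
    genome_len_range: tuple[int, int] = (10_000, 20_000)

    def __post_init__(self) -> None:
        if not (self.within_species_div < self.within_genus_div < self.within_family_div):
            raise ValueError("divergences must increase with rank")
        if self.within_species_div > 0.05:
            raise ValueError("within_species_div above 0.05 breaks the 95% ANI species criterion")

    @property
    def n_species(self) -> int:
        return self.n_families * self.genera_per_family * self.species_per_genus

    @property
    def n_genomes(self) -> int:
        return self.n_species * self.variants_per_species


@dataclass
class TruthSet:
    """Ground-truth labels: one row per genome; sample tables filled in by
    the community simulator."""

    genomes: pd.DataFrame  # index genome_id: species_id, genus_id, family_id, host_family, host_genus, length, [termini, completeness, tier]
    samples: pd.DataFrame | None = None       # index sample_id: region, country, breed, diet
    composition: pd.DataFrame | None = None   # samples x genomes, true within-virome proportions

    def labels(self, rank: str) -> pd.Series:
        col = {"species": "species_id", "genus": "genus_id", "family": "family_id"}[rank]
        return self.genomes[col]


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _mutate(arr: np.ndarray, sub_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitutions at ``sub_rate`` plus indels at a tenth of it."""
    out = arr.copy()
    n = len(out)
    n_sub = rng.binomial(n, sub_rate)
    if n_sub:
        pos = rng.choice(n, size=n_sub, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=n_sub)) % 4
    n_indel = rng.binomial(n, sub_rate / 10.0)
    if n_indel:
        pieces = []
        cut_points = np.sort(rng.choice(n, size=n_indel, replace=False))
        prev = 0
        for cp in cut_points:
            pieces.append(out[prev:cp])
            length = rng.geometric(0.5)
            if rng.random() < 0.5:  # deletion
                prev = min(n, cp + length)
            else:  # insertion
                pieces.append(rng.integers(0, 4, size=length, dtype=out.dtype))
                prev = cp
        pieces.append(out[prev:])
        out = np.concatenate(pieces)
    return out


def evolve_lineages(spec: LineageSpec = LineageSpec(), seed: int | None = None
                    ) -> tuple[list[GenomeRecord], TruthSet]:
    """Simulate the lineage hierarchy; returns genomes plus their truth.

    Family roots are drawn i.i.d. uniform over {A,C,G,T}; each descendant
    is mutated from its parent at half the rank's pairwise divergence, so
    the expected distance between two siblings matches the designed value.
    Host families/genera are assigned per viral family/genus so that host
    niches align with lineage structure.
    """
    rng = np.random.default_rng(seed)
    genomes: list[GenomeRecord] = []
    rows = []
    for fi in range(spec.n_families):
        flen = int(rng.integers(spec.genome_len_range[0], spec.genome_len_range[1] + 1))
        froot = rng.integers(0, 4, size=flen, dtype=np.uint8)
        fam_id = f"fam{fi:02d}"
        host_family = HOST_FAMILIES[fi % len(HOST_FAMILIES)]
        for gi in range(spec.genera_per_family):
            groot = _mutate(froot, spec.within_family_div / 2.0, rng)
            gen_id = f"{fam_id}.gen{gi:02d}"
            host_genus = f"{host_family[:-4]}_g{gi}"
            for si in range(spec.species_per_genus):
                sroot = _mutate(groot, spec.within_genus_div / 2.0, rng)
                sp_id = f"{gen_id}.sp{si:02d}"
                for vi in range(spec.variants_per_species):
                    if spec.within_species_div == 0.0:
                        variant = sroot
                    else:
                        variant = _mutate(sroot, spec.within_species_div / 2.0, rng)
                    gid = f"{sp_id}.v{vi}"
                    genomes.append(GenomeRecord(gid, _decode(variant)))
                    rows.append({"genome_id": gid, "species_id": sp_id,
                                 "genus_id": gen_id, "family_id": fam_id,
                                 "host_family": host_family, "host_genus": host_genus,
                                 "length": len(variant)})
    truth = TruthSet(genomes=pd.DataFrame(rows).set_index("genome_id"))
    return genomes, truth


# ---------------------------------------------------------------------------
# Contig decoration (completeness truncation, termini, gene counts)

DEFAULT_TIER_DESIGN = {"complete": 0.20, "high": 0.25, "medium": 0.45, "low": 0.10}
DEFAULT_TERMINI_MIX = {"DTR": 0.80, "ITR": 0.15, "provirus": 0.05}


def decorate_contigs(genomes: Sequence[GenomeRecord], truth: TruthSet,
                     seed: int | None = None,
                     tier_design: Mapping[str, float] = DEFAULT_TIER_DESIGN,
                     termini_mix: Mapping[str, float] = DEFAULT_TERMINI_MIX,
                     host_gene_fraction: float = 0.15,
                     junk_fraction: float = 0.0,
                     repeat_len_range: tuple[int, int] = (25, 60),
                     ) -> tuple[list[GenomeRecord], list[ContigQCRecord]]:
    """Turn full genomes into partial contigs with a consistent QC table.

    Each genome is assigned a designed quality tier: *complete* contigs
    keep their full sequence and gain a DTR/ITR decoration (or a trusted
    provirus call), the rest are truncated to a completeness fraction drawn
    for the tier (high 90-100, medium 50-90, low 40-50).  Viral/host gene
    counts are drawn so retained contigs satisfy the viral > 3x host rule;
    a ``junk_fraction`` of contigs is instead made to fail retention
    (low completeness).  The truth table gains termini/completeness/tier
    columns.
    """
    rng = np.random.default_rng(seed)
    tiers = list(tier_design)
    tier_p = np.array([tier_design[t] for t in tiers], dtype=float)
    tier_p /= tier_p.sum()
    term_kinds = list(termini_mix)
    term_p = np.array([termini_mix[k] for k in term_kinds], dtype=float)
    term_p /= term_p.sum()

    contigs: list[GenomeRecord] = []
    qc: list[ContigQCRecord] = []
    truth_cols = {"termini": [], "completeness": [], "designed_tier": []}
    for g in genomes:
        seq = g.sequence
        termini = "none"
        if junk_fraction > 0 and rng.random() < junk_fraction:
            tier = "junk"
            comp = float(rng.uniform(5.0, 39.9))
            seq = seq[: max(1, round(comp / 100.0 * len(seq)))]
        else:
            tier = tiers[rng.choice(len(tiers), p=tier_p)]
            if tier == "complete":
                comp = 100.0
                termini = term_kinds[rng.choice(len(term_kinds), p=term_p)]
                rep = int(rng.integers(repeat_len_range[0], repeat_len_range[1] + 1))
                if termini == "DTR":
                    seq = seq + seq[:rep]
                elif termini == "ITR":
                    seq = seq + reverse_complement(seq[:rep])
            else:
                lo, hi = {"high": (90.0, 99.9), "medium": (50.0, 89.9), "low": (40.0, 49.9)}[tier]
                comp = float(rng.uniform(lo, hi))
                seq = seq[: max(1, round(comp / 100.0 * len(seq)))]
        viral = max(1, int(rng.poisson(len(seq) / 1000.0)))
        host = 0
        if rng.random() < host_gene_fraction:
            cap = int((viral - 1) // 3)
            if cap > 0:
                host = int(rng.integers(1, cap + 1))
        contigs.append(GenomeRecord(g.id, seq))
        # provirus boundary calls come from the upstream QC tool, so the
        # table (not the sequence) carries them
        qc.append(ContigQCRecord(
            contig_id=g.id, length=len(seq), completeness=comp,
            contamination=float(rng.uniform(0.0, 5.0)),
            viral_genes=viral, host_genes=host,
            termini="provirus" if termini == "provirus" else "none",
        ))
        truth_cols["termini"].append(termini)
        truth_cols["completeness"].append(comp)
        truth_cols["designed_tier"].append(tier)
    for col, vals in truth_cols.items():
        truth.genomes[col] = pd.Series(vals, index=[g.id for g in genomes])
    return contigs, qc


# ---------------------------------------------------------------------------
# Pairwise nucleotide alignments

def _kmer_set(seq: str, k: int) -> set[int]:
    return {hash(seq[i:i + k]) for i in range(0, len(seq) - k + 1)}


def _parse_edlib_cigar(cigar: str) -> tuple[int, int, int, int]:
    """(match_or_mismatch_cols, ins_bases, del_bases, gap_opens)."""
    m = ins = dele = opens = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            length = int(num)
            num = ""
            if ch in "M=X":
                m += length
            elif ch == "I":
                ins += length
                opens += 1
            elif ch == "D":
                dele += length
                opens += 1
    return m, ins, dele, opens


def _align_pair(a: GenomeRecord, b: GenomeRecord) -> LocalAlignment | None:
    """End-to-end alignment of a pair via edit-distance DP (edlib)."""
    res = edlib.align(a.sequence, b.sequence, mode="NW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    m, ins, dele, opens = _parse_edlib_cigar(res["cigar"])
    cols = m + ins + dele
    mismatches = res["editDistance"] - ins - dele
    matches = m - mismatches
    pident = 100.0 * matches / cols
    return LocalAlignment(
        query_id=a.id, target_id=b.id, pident=round(pident, 3), aln_len=cols,
        mismatches=mismatches, gap_opens=opens,
        qstart=1, qend=a.length, tstart=1, tend=b.length,
        evalue=0.0, bitscore=round(2.0 * max(matches, 1), 1),
    )


def _kmer_anchored_alignments(a: GenomeRecord, b: GenomeRecord, k: int = 15,
                              min_run: int = 100) -> list[LocalAlignment]:
    """Built-in exact-seed, ungapped-extension local aligner.

    Shared k-mers on a common diagonal are merged into one ungapped block;
    identity is measured directly on the spanned substrings.  Intended for
    fixture generation, not a general aligner.
    """
    pos_b: dict[str, list[int]] = {}
    for j in range(len(b.sequence) - k + 1):
        pos_b.setdefault(b.sequence[j:j + k], []).append(j)
    diags: dict[int, list[int]] = {}
    for i in range(len(a.sequence) - k + 1):
        for j in pos_b.get(a.sequence[i:i + k], ()):
            diags.setdefault(i - j, []).append(i)
    out = []
    max_gap = 4 * k  # split unrelated seed clusters sharing a diagonal
    for diag, starts in diags.items():
        starts.sort()
        runs, run = [], [starts[0]]
        for s in starts[1:]:
            if s - run[-1] <= max_gap:
                run.append(s)
            else:
                runs.append(run)
                run = [s]
        runs.append(run)
        for run in runs:
            qs, qe = run[0], run[-1] + k
            if qe - qs < min_run:
                continue
            ts, te = qs - diag, qe - diag
            if ts < 0 or te > len(b.sequence):
                continue
            sub_a = np.frombuffer(a.sequence[qs:qe].encode(), dtype=np.uint8)
            sub_b = np.frombuffer(b.sequence[ts:te].encode(), dtype=np.uint8)
            matches = int((sub_a == sub_b).sum())
            cols = qe - qs
            pident = 100.0 * matches / cols
            if pident < 60.0:
                continue
            out.append(LocalAlignment(
                query_id=a.id, target_id=b.id, pident=round(pident, 3), aln_len=cols,
                mismatches=cols - matches, gap_opens=0,
                qstart=qs + 1, qend=qe, tstart=ts + 1, tend=te,
                evalue=0.0, bitscore=round(2.0 * matches, 1),
            ))
    return out


def emit_alignments(genomes: Sequence[GenomeRecord], mode: str = "oracle",
                    min_est_identity: float = 0.70, k: int = 15,
                    symmetric: bool = True) -> list[LocalAlignment]:
    """All-vs-all local-alignment table for a genome set.

    Candidate pairs are pre-filtered by k-mer containment (estimated
    identity = containment^(1/k) >= ``min_est_identity``); candidates are
    aligned end-to-end by edit-distance DP (``oracle``) or by the built-in
    k-mer-anchored ungapped aligner (``kmer``).  Self pairs are omitted;
    with ``symmetric`` both row directions are emitted.
    """
    if mode not in ("oracle", "kmer"):
        raise ValueError("mode must be 'oracle' or 'kmer'")
    kmers = [_kmer_set(g.sequence, k) for g in genomes]
    out: list[LocalAlignment] = []
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            inter = len(kmers[i] & kmers[j])
            denom = min(len(kmers[i]), len(kmers[j]))
            if denom == 0:
                continue
            est = (inter / denom) ** (1.0 / k) if inter else 0.0
            if est < min_est_identity:
                continue
            if mode == "oracle":
                aln = _align_pair(genomes[i], genomes[j])
                alns = [aln] if aln is not None else []
            else:
                alns = _kmer_anchored_alignments(genomes[i], genomes[j], k=k)
            for a in alns:
                out.append(a)
                if symmetric:
                    out.append(LocalAlignment(
                        query_id=a.target_id, target_id=a.query_id,
                        pident=a.pident, aln_len=a.aln_len,
                        mismatches=a.mismatches, gap_opens=a.gap_opens,
                        qstart=a.tstart, qend=a.tend, tstart=a.qstart, tend=a.qend,
                        evalue=a.evalue, bitscore=a.bitscore,
                    ))
    return out


# ---------------------------------------------------------------------------
# Protein-hit fixtures

def emit_protein_hits(truth: TruthSet, seed: int | None = None,
                      mean_genes: int = 20,
                      genus_frac: float = 0.40, genus_aai: float = 55.0,
                      family_frac: float = 0.15, family_aai: float = 25.0,
                      aai_sd: float = 3.0,
                      ) -> tuple[list[ProteinHit], dict[str, int]]:
    """Protein-hit tables with designed identity/sharing structure.

    Gene counts are Poisson around ``mean_genes`` (min 5).  Same-genus
    genome pairs share ~``genus_frac`` of the smaller genome's genes at
    identities ~N(genus_aai, aai_sd); same-family, different-genus pairs
    share ~``family_frac`` at ~N(family_aai, aai_sd); cross-family pairs
    share nothing.  Identities are clipped to keep designed pairs on the
    intended side of the genus (40%) and family (20%) thresholds.
    """
    rng = np.random.default_rng(seed)
    gdf = truth.genomes
    ids = list(gdf.index)
    gene_counts = {g: max(5, int(rng.poisson(mean_genes))) for g in ids}
    hits: list[ProteinHit] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if gdf.loc[a, "genus_id"] == gdf.loc[b, "genus_id"]:
                frac, aai_mu, clip = genus_frac, genus_aai, (42.0, 95.0)
            elif gdf.loc[a, "family_id"] == gdf.loc[b, "family_id"]:
                frac, aai_mu, clip = family_frac, family_aai, (20.5, 39.0)
            else:
                continue
            small, other = (a, b) if gene_counts[a] <= gene_counts[b] else (b, a)
            n_shared = max(1, round(frac * gene_counts[small]))
            q_idx = rng.choice(gene_counts[small], size=n_shared, replace=False)
            t_idx = rng.choice(gene_counts[other], size=n_shared, replace=False)
            idents = np.clip(rng.normal(aai_mu, aai_sd, size=n_shared), *clip)
            for qi, ti, pid in zip(q_idx, t_idx, idents):
                hits.append(ProteinHit(
                    query_protein=f"{small}_p{qi}", target_protein=f"{other}_p{ti}",
                    query_genome=small, target_genome=other,
                    pident=float(round(pid, 2)),
                    qcov=float(rng.uniform(60.0, 100.0)),
                    tcov=float(rng.uniform(60.0, 100.0)),
                    evalue=float(10.0 ** rng.uniform(-50.0, -10.0)),
                ))
    return hits, gene_counts


# ---------------------------------------------------------------------------
# Community and read simulation

@dataclass
class CommunityDesign:
    """Region-stratified community model with host-family niches."""

    region_host_weights: dict[str, dict[str, float]] = field(default_factory=lambda: {
        **{r: {"Lactobacillaceae": 0.70, "Lachnospiraceae": 0.10,
               "Bacteroidaceae": 0.10, "Ruminococcaceae": 0.10}
           for r in PROXIMAL_REGIONS},
        **{r: {"Lactobacillaceae": 0.10, "Lachnospiraceae": 0.30,
               "Bacteroidaceae": 0.30, "Ruminococcaceae": 0.30}
           for r in DISTAL_REGIONS},
    })
    dispersion: float = 0.5          # gamma noise on per-genome weights (mean 1)
    viral_read_fraction: float = 0.015
    read_length: int = 150
    region_present_fraction: dict[str, float] | None = None  # richness gradient

    def __post_init__(self) -> None:
        for region, weights in self.region_host_weights.items():
            total = sum(weights.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"host-family weights for {region!r} sum to {total}, not 1")


@dataclass
class SimulatedCommunity:
    metadata: pd.DataFrame            # index sample_id: region, country, breed, diet, sex
    composition: pd.DataFrame         # samples x genomes, true within-virome proportions
    sam_paths: dict[str, Path]
    reads_per_sample: int


def _make_reads_sam(fh, genome: GenomeRecord, count: int, read_len: int,
                    error_rate: float, rng: np.random.Generator, name_prefix: str) -> None:
    if count == 0:
        return
    n = genome.length
    starts = rng.integers(0, n - read_len + 1, size=count)
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    for r, s in enumerate(starts):
        read = arr[s:s + read_len].copy()
        n_err = rng.binomial(read_len, error_rate)
        if n_err:
            pos = rng.choice(read_len, size=n_err, replace=False)
            # substitute with a uniformly different base
            cur = read[pos]
            idx = np.searchsorted(_BASES, cur)
            read[pos] = _BASES[(idx + rng.integers(1, 4, size=n_err)) % 4]
        fh.write(f"{name_prefix}.{r}\t0\t{genome.id}\t{int(s) + 1}\t60\t{read_len}M\t*\t0\t0\t"
                 f"{read.tobytes().decode()}\t*\tNM:i:{int(n_err)}\n")


def simulate_community(genomes: Sequence[GenomeRecord], truth: TruthSet,
                       design: CommunityDesign = CommunityDesign(),
                       n_samples_per_region: int = 10,
                       reads_per_sample: int = 5000,
                       error_rate: float = 0.02,
                       seed: int | None = None,
                       regions: Sequence[str] | None = None,
                       out_dir: str | Path = ".",
                       countries: Sequence[str] = ("Germany", "China"),
                       breeds: Sequence[str] = ("LB", "LSL"),
                       diets: Sequence[str] = ("control", "phosphorus"),
                       fixed_composition: Mapping[str, float] | None = None,
                       ) -> SimulatedCommunity:
    """Simulate per-sample read sets as primary-only SAM files.

    Per sample: a vOTU composition is drawn from the region's host-family
    mixture with multiplicative gamma noise (or taken verbatim from
    ``fixed_composition``); the viral read count is binomial at
    ``viral_read_fraction``; reads start uniformly along their genome and
    carry i.i.d. substitution errors with correct CIGAR/NM; non-viral reads
    are emitted as unmapped records.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if regions is None:
        regions = list(design.region_host_weights)
    gids = [g.id for g in genomes]
    by_id = {g.id: g for g in genomes}
    host_family = truth.genomes["host_family"].reindex(gids)
    fam_sizes = host_family.value_counts()

    header = ["@HD\tVN:1.6\tSO:unsorted"] + [
        f"@SQ\tSN:{g.id}\tLN:{g.length}" for g in genomes
    ]

    meta_rows, comp_rows, sam_paths = [], [], {}
    sample_no = 0
    for region in regions:
        weights = design.region_host_weights.get(region)
        if weights is None and fixed_composition is None:
            raise ValueError(f"no host-family weights for region {region!r}")
        for _ in range(n_samples_per_region):
            sid = f"S{sample_no:04d}"
            sample_no += 1
            present = np.ones(len(gids), dtype=bool)
            if design.region_present_fraction is not None:
                frac = design.region_present_fraction.get(region, 1.0)
                if frac < 1.0:
                    n_present = max(1, int(round(frac * len(gids))))
                    present[:] = False
                    present[rng.choice(len(gids), size=n_present, replace=False)] = True
            if fixed_composition is not None:
                comp = np.array([fixed_composition.get(g, 0.0) for g in gids])
            else:
                base = np.array([
                    weights.get(host_family[g], 0.0) / max(1, fam_sizes.get(host_family[g], 1))
                    for g in gids
                ])
                noise = rng.gamma(1.0 / design.dispersion, design.dispersion, size=len(gids))
                comp = base * noise * present
            total = comp.sum()
            if total <= 0:
                raise ValueError(f"sample {sid}: empty composition")
            comp = comp / total

            n_viral = rng.binomial(reads_per_sample, design.viral_read_fraction)
            per_genome = rng.multinomial(n_viral, comp)
            path = out_dir / f"{sid}.sam"
            with open(path, "w") as fh:
                fh.write("\n".join(header) + "\n")
                for g_idx, c in enumerate(per_genome):
                    _make_reads_sam(fh, by_id[gids[g_idx]], int(c), design.read_length,
                                    error_rate, rng, f"{sid}.g{g_idx}")
                for u in range(reads_per_sample - n_viral):
                    fh.write(f"{sid}.u{u}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
            sam_paths[sid] = path
            meta_rows.append({
                "sample_id": sid, "region": region,
                "country": countries[sample_no % len(countries)],
                "breed": breeds[sample_no % len(breeds)],
                "diet": diets[sample_no % len(diets)],
                "sex": None,
            })
            comp_rows.append(pd.Series(comp, index=gids, name=sid))

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    composition = pd.DataFrame(comp_rows)
    truth.samples = metadata
    truth.composition = composition
    return SimulatedCommunity(metadata=metadata, composition=composition,
                              sam_paths=sam_paths, reads_per_sample=reads_per_sample)
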