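import numpy as np
import pytest

from votuforge.abundance import build_matrix, read_sam, recruit
from votuforge.genome_qc import detect_termini, run_qc
from votuforge.species_clustering import compute_pair_anis
from votuforge.synthetic_data import (
    CommunityDesign,
    LineageSpec,
    decorate_contigs,
    emit_alignments,
    emit_protein_hits,
    evolve_lineages,
    simulate_community,
)

from _oracles import global_identity
from conftest import SEED


class TestEvolveLineages:
    def test_zero_divergence_gives_identical_variants(self):
        spec = LineageSpec(n_families=1, genera_per_family=1, species_per_genus=1,
                           variants_per_species=3, within_species_div=0.0,
                           genome_len_range=(2000, 3000))
        genomes, truth = evolve_lineages(spec, seed=SEED)
        assert genomes[0].sequence == genomes[1].sequence == genomes[2].sequence

    def test_divergence_spec_must_increase_with_rank(self):
        with pytest.raises(ValueError):
            LineageSpec(within_species_div=0.2, within_genus_div=0.15)

    def test_between_species_identity_matches_design(self):
        # 15% designed pairwise divergence -> ~85% global identity
        spec = LineageSpec(n_families=1, genera_per_family=1, species_per_genus=2,
                           variants_per_species=1, within_genus_div=0.15,
                           genome_len_range=(3000, 4000))
        genomes, _ = evolve_lineages(spec, seed=SEED)
        # the divergence parameter is a substitution rate, so measure
        # substitution-only identity (gap columns excluded); coincident
        # hits push it slightly above the naive 85%
        ident = global_identity(genomes[0].sequence, genomes[1].sequence,
                                count_gaps=False)
        assert ident == pytest.approx(85.5, abs=1.5)

    def test_determinism(self):
        spec = LineageSpec(n_families=1, genera_per_family=1, species_per_genus=2,
                           genome_len_range=(2000, 3000))
        a, _ = evolve_lineages(spec, seed=SEED)
        b, _ = evolve_lineages(spec, seed=SEED)
        assert [(g.id, g.sequence) for g in a] == [(g.id, g.sequence) for g in b]

    def test_within_species_pairs_respect_species_ani(self, small_lineage):
        spec, genomes, truth = small_lineage
        by_id = {g.id: g for g in genomes}
        ok = total = 0
        for sp, members in truth.genomes.groupby("species_id").groups.items():
            members = list(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    total += 1
                    ident = global_identity(by_id[members[i]].sequence,
                                            by_id[members[j]].sequence)
                    if ident >= 95.0:
                        ok += 1
        assert ok / total >= 0.99


class TestDecorateContigs:
    def test_complete_contigs_close_the_loop_with_termini_detection(self, small_lineage):
        spec, genomes, truth = small_lineage
        contigs, qc = decorate_contigs(genomes, truth, seed=SEED)
        by_id = {c.id: c for c in contigs}
        for gid, row in truth.genomes.iterrows():
            if row["termini"] in ("DTR", "ITR"):
                call = detect_termini(by_id[gid])
                assert call.kind == row["termini"]

    def test_low_completeness_short_contigs_rejected_downstream(self, small_lineage):
        spec, genomes, truth = small_lineage
        contigs, qc = decorate_contigs(genomes, truth, seed=SEED, junk_fraction=0.3)
        kept, rejected = run_qc(qc, contigs)
        junk = set(truth.genomes.index[truth.genomes["designed_tier"] == "junk"])
        assert junk and junk <= {r.contig_id for r in rejected}

    def test_designed_tier_proportions_recovered(self):
        # long genomes so RULE-B retains the designed low tier
        spec = LineageSpec(n_families=4, genera_per_family=1, species_per_genus=5,
                           variants_per_species=1, genome_len_range=(50_000, 60_000))
        genomes, truth = evolve_lineages(spec, seed=SEED)
        genomes = genomes * 100  # replicate label-wise for counting only
        design = {"complete": 0.20, "high": 0.25, "medium": 0.45, "low": 0.10}
        rng_ids = [f"{g.id}.r{i}" for i, g in enumerate(genomes)]
        from votuforge.io_formats import GenomeRecord
        import pandas as pd
        genomes = [GenomeRecord(rid, g.sequence) for rid, g in zip(rng_ids, genomes)]
        truth2 = type(truth)(genomes=pd.DataFrame(index=rng_ids))
        contigs, qc = decorate_contigs(genomes, truth2, seed=SEED, tier_design=design)
        kept, rejected = run_qc(qc, contigs)
        assert len(rejected) == 0
        n = len(kept)
        for tier, frac in design.items():
            observed = sum(1 for k in kept if k.tier == tier) / n
            assert observed == pytest.approx(frac, abs=0.03)


class TestEmitAlignments:
    def test_identical_pair_full_identity(self, rng):
        from votuforge.io_formats import GenomeRecord
        from conftest import random_sequence
        seq = random_sequence(rng, 3000)
        a, b = GenomeRecord("a", seq), GenomeRecord("b", seq)
        alns = emit_alignments([a, b])
        fwd = [x for x in alns if x.query_id == "a"]
        assert fwd[0].pident == 100.0
        assert fwd[0].q_interval == (0, 3000) and fwd[0].t_interval == (0, 3000)

    def test_distant_pair_filtered(self, rng):
        from votuforge.io_formats import GenomeRecord
        from conftest import random_sequence
        a = GenomeRecord("a", random_sequence(rng, 3000))
        b = GenomeRecord("b", random_sequence(rng, 3000))
        assert emit_alignments([a, b]) == []

    def test_recomputed_ani_tracks_realized_divergence(self, small_lineage):
        spec, genomes, truth = small_lineage
        sub = genomes[:4]  # two variants each of two species, same genus
        lengths = {g.id: g.length for g in sub}
        pairs = compute_pair_anis(emit_alignments(sub), lengths)
        by = {(p.query_id, p.target_id): p for p in pairs}
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                p = by.get((sub[i].id, sub[j].id))
                if p is None:
                    continue
                oracle = global_identity(sub[i].sequence, sub[j].sequence)
                assert p.ani == pytest.approx(oracle, abs=0.5)

    def test_kmer_mode_close_to_oracle_on_similar_pair(self, small_lineage):
        spec, genomes, truth = small_lineage
        sp = truth.genomes.groupby("species_id").groups
        members = list(next(iter(sp.values())))
        sub = [g for g in genomes if g.id in members]
        lengths = {g.id: g.length for g in sub}
        oracle_ani = compute_pair_anis(emit_alignments(sub, mode="oracle"), lengths)
        kmer_ani = compute_pair_anis(emit_alignments(sub, mode="kmer"), lengths)
        o = {(p.query_id, p.target_id): p.ani for p in oracle_ani}
        k = {(p.query_id, p.target_id): p.ani for p in kmer_ani}
        shared = set(o) & set(k)
        assert shared
        for key in shared:
            assert abs(o[key] - k[key]) < 2.0


class TestEmitProteinHits:
    def test_cross_family_pairs_share_nothing(self, small_lineage):
        spec, genomes, truth = small_lineage
        hits, _ = emit_protein_hits(truth, seed=SEED)
        gdf = truth.genomes
        for h in hits:
            assert gdf.loc[h.query_genome, "family_id"] == gdf.loc[h.target_genome, "family_id"]

    def test_determinism(self, small_lineage):
        spec, genomes, truth = small_lineage
        h1, c1 = emit_protein_hits(truth, seed=SEED)
        h2, c2 = emit_protein_hits(truth, seed=SEED)
        assert h1 == h2 and c1 == c2


class TestSimulateCommunity:
    def test_zero_error_rate_gives_perfect_identities(self, tmp_path, small_lineage):
        from votuforge.abundance import alignment_metrics
        spec, genomes, truth = small_lineage
        sim = simulate_community(genomes, truth, CommunityDesign(viral_read_fraction=1.0),
                                 n_samples_per_region=1, reads_per_sample=500,
                                 error_rate=0.0, seed=SEED, regions=["ileum"],
                                 out_dir=tmp_path)
        alns = [a for a in read_sam(next(iter(sim.sam_paths.values()))) if a.mapped]
        assert alns
        assert all(alignment_metrics(a)[0] == 100.0 for a in alns)

    def test_mean_read_identity_matches_error_rate(self, tmp_path, small_lineage):
        from votuforge.abundance import alignment_metrics
        spec, genomes, truth = small_lineage
        sim = simulate_community(genomes, truth, CommunityDesign(viral_read_fraction=1.0),
                                 n_samples_per_region=1, reads_per_sample=10_000,
                                 error_rate=0.02, seed=SEED, regions=["ileum"],
                                 out_dir=tmp_path)
        alns = [a for a in read_sam(next(iter(sim.sam_paths.values()))) if a.mapped]
        idents = [alignment_metrics(a)[0] for a in alns]
        assert np.mean(idents) == pytest.approx(98.0, abs=0.3)

    def test_composition_rows_normalized_and_deterministic(self, tmp_path, small_lineage):
        spec, genomes, truth = small_lineage
        kw = dict(n_samples_per_region=2, reads_per_sample=200, seed=SEED,
                  regions=["ileum", "caeca"])
        sim1 = simulate_community(genomes, truth, out_dir=tmp_path / "a", **kw)
        sim2 = simulate_community(genomes, truth, out_dir=tmp_path / "b", **kw)
        assert np.allclose(sim1.composition.sum(axis=1), 1.0)
        assert sim1.composition.equals(sim2.composition)
        sams1 = [p.read_text().split("\n", 2)[2] for p in sim1.sam_paths.values()]
        sams2 = [p.read_text().split("\n", 2)[2] for p in sim2.sam_paths.values()]
        assert sams1 == sams2
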