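"""Simulator unit and property tests: genome composition, haplotype SNPs,
shattering round-trips, offspring karyotypes, read dosage, and tracks."""

import numpy as np
import pytest

from shatterscan import simulate as sim


class TestMakeGenome:
    def test_deterministic_for_fixed_seed(self):
        a = sim.make_genome(1, [20_000], gc=0.36, seed=7)
        b = sim.make_genome(1, [20_000], gc=0.36, seed=7)
        assert a.chromosomes == b.chromosomes

    def test_different_seed_differs(self):
        a = sim.make_genome(1, [20_000], gc=0.36, seed=7)
        b = sim.make_genome(1, [20_000], gc=0.36, seed=8)
        assert a.chromosomes != b.chromosomes

    def test_gc_content_within_two_percent(self):
        g = sim.make_genome(1, [1_000_000], gc=0.36, seed=7)
        seq = g.seq("chr1")
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.36) < 0.02

    @pytest.mark.parametrize("bad_len", [0, -5, 500])
    def test_short_or_nonpositive_length_rejected(self, bad_len):
        with pytest.raises(ValueError):
            sim.make_genome(1, [bad_len], gc=0.4, seed=0)

    def test_bad_gc_rejected(self):
        with pytest.raises(ValueError):
            sim.make_genome(1, [20_000], gc=1.5, seed=0)


class TestDeriveHaplotypes:
    def test_snp_count_within_binomial_bounds(self):
        g = sim.make_genome(1, [1_000_000], seed=1)
        hp = sim.derive_haplotypes(g, snp_rate=0.001, seed=2)
        n = len(hp.snps)
        mu, sd = 1000, np.sqrt(1_000_000 * 0.001 * 0.999)
        assert abs(n - mu) < 3 * sd

    def test_alleles_differ_and_ref_matches(self):
        g = sim.make_genome(1, [50_000], seed=1)
        hp = sim.derive_haplotypes(g, snp_rate=0.002, seed=2)
        seq = g.seq("chr1")
        for chrom, pos, a, b in hp.snps:
            assert a != b
            assert seq[pos] == a

    def test_positions_strictly_increasing(self):
        g = sim.make_genome(1, [200_000], seed=1)
        hp = sim.derive_haplotypes(g, 0.001, seed=3)
        pos = [p for _, p, _, _ in hp.snps]
        assert pos == sorted(set(pos))

    def test_zero_rate_gives_empty_list(self):
        g = sim.make_genome(1, [50_000], seed=1)
        assert sim.derive_haplotypes(g, 0.0, seed=2).snps == []

    def test_rate_out_of_range_rejected(self):
        g = sim.make_genome(1, [50_000], seed=1)
        with pytest.raises(ValueError):
            sim.derive_haplotypes(g, 0.5, seed=2)


class TestShatter:
    def test_round_trip_reproduces_rearranged_sequence(self, shatter_sim):
        ref = shatter_sim.genome.seq("chr1")
        assert shatter_sim.event.apply(ref) == shatter_sim.rearranged

    def test_junction_count_is_kept_fragments_minus_one(self):
        g = sim.make_genome(1, [500_000], seed=5)
        _, ev, _ = sim.shatter(g, ("chr1", 0, 300_000), 14, loss_fraction=0.0, seed=6)
        assert len(ev.fragments) == 14
        assert ev.n_junctions == 13

    def test_loss_destroys_junctions_exactly(self):
        g = sim.make_genome(1, [500_000], seed=5)
        _, ev, _ = sim.shatter(g, ("chr1", 0, 300_000), 14, loss_fraction=0.4, seed=6)
        assert ev.n_junctions == len(ev.fragments) - 1
        assert len(ev.fragments) + len(ev.lost_fragments) == 14

    def test_fragments_partition_region_minus_losses(self):
        g = sim.make_genome(1, [500_000], seed=5)
        _, ev, _ = sim.shatter(g, ("chr1", 0, 300_000), 10, loss_fraction=0.3, seed=2)
        ivs = sorted(
            [(s, e) for s, e, _ in ev.fragments] + list(ev.lost_fragments)
        )
        assert ivs[0][0] == 0 and ivs[-1][1] == 300_000
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 == s2

    def test_all_microhomology_mix_gives_mh_junctions(self):
        g = sim.make_genome(1, [500_000], seed=5)
        _, ev, _ = sim.shatter(
            g, ("chr1", 0, 300_000), 10, loss_fraction=0.0,
            repair_mix={"microhomology": 1.0}, seed=7,
        )
        assert all(j.repair_class == "microhomology" for j in ev.junctions_truth)
        assert all(1 <= j.mh_len for j in ev.junctions_truth)
        assert all(j.planted_trim <= 29 for j in ev.junctions_truth)

    def test_insertion_lengths_in_range(self):
        g = sim.make_genome(1, [500_000], seed=5)
        _, ev, _ = sim.shatter(
            g, ("chr1", 0, 300_000), 10, loss_fraction=0.0,
            repair_mix={"insertion": 1.0}, seed=8,
        )
        assert all(1 <= len(j.planted_ins) <= 80 for j in ev.junctions_truth)

    def test_identity_permutation_preserves_sequence(self):
        g = sim.make_genome(1, [50_000], seed=9)
        for s in range(30):
            g2, ev, rearr = sim.shatter(
                g, ("chr1", 0, 20_000), 2, loss_fraction=0.0,
                repair_mix={"perfect": 1.0}, seed=s,
            )
            if [f[2] for f in ev.fragments] == ["+", "+"] and ev.fragments[0][0] == 0:
                assert rearr == g2.seq("chr1")[:20_000]
                return
        pytest.fail("identity permutation never drawn in 30 seeds")

    def test_derange_avoids_identity(self):
        g = sim.make_genome(1, [50_000], seed=9)
        for s in range(20):
            _, ev, _ = sim.shatter(
                g, ("chr1", 0, 20_000), 2, loss_fraction=0.0,
                repair_mix={"perfect": 1.0}, seed=s, derange=True,
            )
            assert not (
                ev.fragments[0][0] == 0 and [f[2] for f in ev.fragments] == ["+", "+"]
            )

    def test_sequence_outside_region_unchanged(self):
        g = sim.make_genome(1, [200_000], seed=3)
        g2, _, _ = sim.shatter(g, ("chr1", 50_000, 150_000), 8, seed=4)
        assert g2.seq("chr1")[:50_000] == g.seq("chr1")[:50_000]
        assert g2.seq("chr1")[150_000:] == g.seq("chr1")[150_000:]

    def test_bad_region_and_fragment_count_rejected(self):
        g = sim.make_genome(1, [50_000], seed=1)
        with pytest.raises(ValueError):
            sim.shatter(g, ("chr1", 0, 60_000), 4)
        with pytest.raises(ValueError):
            sim.shatter(g, ("chr1", 0, 10_000), 1)
        with pytest.raises(ValueError):
            sim.shatter(g, ("chr1", 0, 100), 200)


@pytest.fixture(scope="module")
def setup():
    g = sim.make_genome(2, [100_000, 60_000], seed=2)
    g2, ev, _ = sim.shatter(g, ("chr1", 10_000, 60_000), 5, seed=3)
    hp = sim.derive_haplotypes(g2, 0.001, seed=4)
    return g2, hp, ev


class TestMakeOffspring:
    def test_meiosis_I_trisomic_multiset(self, setup):
        g, hp, ev = setup
        k = sim.make_offspring(g, hp, ev, "meiosis_I", seed=5)
        pos = next(s for s, e, _ in ev.fragments) + 1
        ms = sorted(k.haplotype_multiset("chr1", pos))
        assert ms in (["A", "A", "B"], ["A", "B", "B"])
        assert "A" in ms and "B" in ms  # two different maternal haplotypes

    def test_meiosis_II_same_maternal_haplotype(self, setup):
        g, hp, ev = setup
        k = sim.make_offspring(g, hp, ev, "meiosis_II", seed=5)
        maternal = [c for c in k.copies_of("chr1") if c.parent == "maternal"]
        assert len(maternal) == 2
        assert maternal[0].haplotype == maternal[1].haplotype
        pos = next(s for s, e, _ in ev.fragments) + 1
        assert sorted(k.haplotype_multiset("chr1", pos)) == ["A", "B", "B"]

    def test_balanced_two_copies_everywhere(self, setup):
        g, hp, _ = setup
        k = sim.make_offspring(g, hp, None, "balanced", seed=6)
        for chrom in g.names:
            for pos in (0, 5_000, 50_000):
                if pos < g.lengths[chrom]:
                    assert len(k.haplotype_multiset(chrom, pos)) == 2

    def test_paternal_copy_always_haplotype_A(self, setup):
        g, hp, ev = setup
        for stage in ("balanced", "meiosis_I", "meiosis_II"):
            k = sim.make_offspring(g, hp, ev, stage, seed=7)
            for c in k.copies:
                if c.parent == "paternal":
                    assert c.haplotype == "A"

    def test_unknown_stage_rejected(self, setup):
        g, hp, ev = setup
        with pytest.raises(ValueError):
            sim.make_offspring(g, hp, ev, "mitosis", seed=0)


class TestSimulateReads:
    def test_copy_number_scales_coverage(self, shatter_sim):
        # coverage over a region present in c copies ~ depth * c / 2
        fx = shatter_sim
        depth = np.zeros(fx.genome.lengths["chr1"] // 1000)
        for rec in fx.records:
            for key in ("mate1", "mate2"):
                pos = rec[key][0]
                depth[min(pos // 1000, len(depth) - 1)] += 100 / 1000
        chrom, rs, re = fx.region
        outside = np.r_[depth[20 : rs // 1000 - 1], depth[re // 1000 + 1 : -20]]
        assert abs(outside.mean() - 30.0) < 1.5
        kept = fx.event.kept_intervals()
        inside = np.concatenate(
            [depth[s // 1000 + 1 : e // 1000 - 1] for s, e in kept if e - s > 4000]
        )
        assert abs(inside.mean() - 45.0) < 3.0

    def test_pair_straddling_junction_reports_distant_mates(self, shatter_sim):
        fx = shatter_sim
        distant = [
            r for r in fx.records
            if abs(r["mate1"][0] - r["mate2"][0]) > 2000
        ]
        assert len(distant) > 0
        # distant mate loci concentrate near truth breakpoints
        truth_bps = [
            p for j in fx.event.junctions_truth for (_, p, _) in (j.left_bp, j.right_bp)
        ]
        near = 0
        for r in distant:
            if all(
                min(abs(r[k][0] - bp) for bp in truth_bps) < 600
                for k in ("mate1", "mate2")
            ):
                near += 1
        assert near / len(distant) > 0.9

    def test_reads_reproducible_from_seed(self):
        g = sim.make_genome(1, [30_000], seed=1)
        hp = sim.derive_haplotypes(g, 0.001, seed=1)
        k = sim.make_offspring(g, hp, None, "balanced", seed=1)
        r1, _ = sim.simulate_reads(g, hp, k, depth=5, seed=9)
        r2, _ = sim.simulate_reads(g, hp, k, depth=5, seed=9)
        assert [(p.name, p.seq1, p.seq2) for p in r1.pairs] == [
            (p.name, p.seq1, p.seq2) for p in r2.pairs
        ]

    def test_invalid_parameters_rejected(self):
        g = sim.make_genome(1, [30_000], seed=1)
        hp = sim.derive_haplotypes(g, 0.001, seed=1)
        k = sim.make_offspring(g, hp, None, "balanced", seed=1)
        with pytest.raises(ValueError):
            sim.simulate_reads(g, hp, k, depth=0)
        with pytest.raises(ValueError):
            sim.simulate_reads(g, hp, k, depth=10, read_len=10)


class TestMakeTracks:
    def test_track_fraction_realized(self):
        g = sim.make_genome(1, [2_000_000], seed=4)
        tracks = sim.make_tracks(g, {"gene": (0.25, 2000)}, seed=5)
        covered = sum(e - s for _, s, e in tracks["gene"])
        assert abs(covered - 500_000) <= 50_000

    def test_track_intervals_non_overlapping(self):
        g = sim.make_genome(1, [500_000], seed=4)
        tracks = sim.make_tracks(g, {"te": (0.2, 3000)}, seed=6)
        ivs = sorted((s, e) for _, s, e in tracks["te"])
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2

    def test_zero_fraction_empty(self):
        g = sim.make_genome(1, [100_000], seed=4)
        assert sim.make_tracks(g, {"x": (0.0, 1000)}, seed=1)["x"] == []

    def test_fraction_above_one_rejected(self):
        g = sim.make_genome(1, [100_000], seed=4)
        with pytest.raises(ValueError):
            sim.make_tracks(g, {"x": (1.5, 1000)}, seed=1)

    def test_partition_tracks_cover_genome_disjointly(self):
        g = sim.make_genome(1, [200_000], seed=4)
        names = [f"state{i}" for i in range(1, 10)]
        tracks = sim.make_partition_tracks(g, names, seed=7)
        all_ivs = sorted(
            (s, e) for name in names for _, s, e in tracks[name]
        )
        assert all_ivs[0][0] == 0 and all_ivs[-1][1] == 200_000
        for (s1, e1), (s2, e2) in zip(all_ivs, all_ivs[1:]):
            assert e1 == s2  # contiguous and non-overlapping
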