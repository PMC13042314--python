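"""Generator contracts: divergences, composition bookkeeping, fragmentation,
reads, repeat insertion, and marker planting — all against ground truth."""

import numpy as np
import pytest

from polyphase.seqs import decode, p_distance, revcomp_str
from polyphase.simulate import (
    AncestryModel,
    PolyploidSpec,
    RepeatFamilySpec,
    compose_polyploid,
    default_model,
    fragment_to_contigs,
    hexaploid_ab_spec,
    insert_repeats,
    make_tully_fixture,
    plant_markers,
    simulate_ancestral_genomes,
    simulate_reads,
    tully_spec,
)


class TestAncestralGenomes:
    def test_zero_divergence_yields_identical_lineages(self):
        model = AncestryModel(n_base_chromosomes=2, base_lengths=(10_000, 10_000), seed=4)
        g = simulate_ancestral_genomes(model)
        for i in range(2):
            assert np.array_equal(g["A"][i], g["B"][i])
            assert np.array_equal(g["A"][i], g["C"][i])

    def test_pairwise_divergences_match_model(self):
        model = default_model(seed=1, length=100_000)
        g = simulate_ancestral_genomes(model)
        p_ab = p_distance(g["A"][0], g["B"][0])
        assert 0.024 <= p_ab <= 0.036  # 3% +- 20%
        for x, y in (("A", "C"), ("B", "C")):
            p = p_distance(g[x][2], g[y][2])
            assert 0.8 * 0.12 <= p <= 1.2 * 0.12

    def test_deterministic_under_fixed_seed(self):
        model = default_model(seed=9, length=20_000, n_base_chromosomes=2)
        g1 = simulate_ancestral_genomes(model)
        g2 = simulate_ancestral_genomes(model)
        for anc in g1:
            for a, b in zip(g1[anc], g2[anc]):
                assert np.array_equal(a, b)

    def test_saturated_divergence_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            AncestryModel(divergence={("A", "C"): 0.8})

    def test_short_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="10 kb"):
            AncestryModel(n_base_chromosomes=1, base_lengths=(5_000,))


class TestComposePolyploid:
    def test_tully_composition_counts(self, tully_small):
        polyploid, truth = tully_small
        assert len(polyploid) == 48
        by_anc = {}
        for rec in truth.chromosomes:
            by_anc[rec.ancestry] = by_anc.get(rec.ancestry, 0) + 1
        assert by_anc == {"A": 14, "B": 22, "C": 12}
        assert "chr1B2" in polyploid  # naming convention chr{base}{anc}{hap}

    def test_hexaploid_has_no_c(self, hexaploid_small):
        polyploid, truth = hexaploid_small
        assert len(polyploid) == 36
        assert all(rec.ancestry != "C" for rec in truth.chromosomes)

    def test_haploid_one_record_per_base(self, ancestral_default):
        genomes, _ = ancestral_default
        spec = PolyploidSpec(per_chromosome_copies={i: {"B": 1} for i in range(1, 7)})
        polyploid, truth = compose_polyploid(genomes, spec, seed=0)
        assert len(polyploid) == 6
        assert sorted(r.base_index for r in truth.chromosomes) == list(range(1, 7))

    def test_haplotype_divergence_is_realized(self, ancestral_default):
        genomes, _ = ancestral_default
        spec = PolyploidSpec(per_chromosome_copies={1: {"A": 2}})
        polyploid, _ = compose_polyploid(genomes, spec, haplotype_divergence=0.01, seed=3)
        p = p_distance(polyploid["chr1A1"], polyploid["chr1A2"])
        assert 0.005 <= p <= 0.015

    def test_missing_ancestral_sequence_rejected(self, ancestral_default):
        genomes, _ = ancestral_default
        spec = PolyploidSpec(per_chromosome_copies={1: {"Z": 1}})
        with pytest.raises(ValueError, match="no ancestral sequence"):
            compose_polyploid(genomes, spec)


class TestFragmentation:
    def test_contigs_partition_chromosomes_exactly(self, tully_small):
        polyploid, _ = tully_small
        contigs, plan = fragment_to_contigs(polyploid, mean_contig_length=7_000, seed=2)
        total = 0
        for chrom, seq in polyploid.items():
            parts = [
                contigs[c.contig_id]
                for c in plan.objects[chrom]
                if hasattr(c, "contig_id")
            ]
            rebuilt = np.concatenate(parts)
            assert np.array_equal(rebuilt, seq)
            total += sum(p.size for p in parts)
        assert total == sum(s.size for s in polyploid.values())

    def test_single_contig_when_mean_exceeds_length(self, tully_small):
        polyploid, _ = tully_small
        contigs, plan = fragment_to_contigs(polyploid, mean_contig_length=10**9, seed=2)
        assert len(contigs) == len(polyploid)

    def test_breakpoints_deterministic(self, tully_small):
        polyploid, _ = tully_small
        c1, _ = fragment_to_contigs(polyploid, mean_contig_length=9_000, seed=7)
        c2, _ = fragment_to_contigs(polyploid, mean_contig_length=9_000, seed=7)
        assert list(c1) == list(c2)
        assert all(np.array_equal(c1[k], c2[k]) for k in c1)


class TestReads:
    def test_error_free_reads_are_exact_substrings(self, hexaploid_small):
        polyploid, _ = hexaploid_small
        sub = {k: polyploid[k] for k in list(polyploid)[:2]}
        reads = simulate_reads(sub, coverage_per_copy=2, error_rate=0.0, seed=5)
        texts = {cid: decode(seq) for cid, seq in sub.items()}
        for name, r1, src in zip(reads.names, reads.seq1, reads.source):
            assert r1 in texts[src] or revcomp_str(r1) in texts[src]

    def test_single_chromosome_genome_all_reads_labelled_to_it(self, hexaploid_small):
        polyploid, _ = hexaploid_small
        one = {"chr1A1": polyploid["chr1A1"]}
        reads = simulate_reads(one, coverage_per_copy=3, seed=6)
        assert set(reads.source) == {"chr1A1"}

    def test_read_fractions_track_chromosome_dosage(self, hexaploid_small):
        """Equal-length chromosomes at uniform coverage: per-subgenome read
        fractions within 2 points of chromosome-count fractions."""
        polyploid, truth = hexaploid_small
        reads = simulate_reads(polyploid, coverage_per_copy=20 / 6, seed=7)
        frac = reads.source_fractions(truth.ancestry_map())
        assert abs(100 * frac["A"] - 100 * 12 / 36) < 2
        assert abs(100 * frac["B"] - 100 * 24 / 36) < 2

    def test_nonpositive_coverage_rejected(self, hexaploid_small):
        polyploid, _ = hexaploid_small
        with pytest.raises(ValueError, match="coverage"):
            simulate_reads(polyploid, coverage_per_copy=0)


class TestRepeatInsertion:
    def test_age_zero_gives_identical_ltrs(self, ancestral_default):
        genomes, _ = ancestral_default
        fam = RepeatFamilySpec("young", "A", 3000, 500, 5, 0.0, 0.0)
        _, insertions = insert_repeats(genomes, [fam], seed=1)
        assert insertions
        assert all(i.ltr5 == i.ltr3 for i in insertions)

    def test_mean_ltr_divergence_tracks_age(self, ancestral_default):
        """Age 1 Myr at mu = 1.3e-8 -> expected LTR p-distance ~ 2 mu T =
        0.026; mean over >= 50 copies within +-30%."""
        genomes, _ = ancestral_default
        fam = RepeatFamilySpec("dated", "A", 3000, 500, 10, 1.0, 0.0, 1.3e-8)
        _, insertions = insert_repeats(genomes, [fam], seed=2)
        assert len(insertions) >= 50
        ps = [
            np.mean([a != b for a, b in zip(i.ltr5, i.ltr3)]) for i in insertions
        ]
        assert 0.7 * 0.026 <= np.mean(ps) <= 1.3 * 0.026

    def test_ancestry_specific_family_stays_out_of_other_lineages(self, ancestral_default):
        genomes, _ = ancestral_default
        fam = RepeatFamilySpec("c_only", "C", 3000, 500, 5, 1.0, 0.1)
        _, insertions = insert_repeats(genomes, [fam], seed=3)
        assert insertions and all(i.ancestry == "C" for i in insertions)

    def test_element_longer_than_chromosome_rejected(self):
        model = AncestryModel(n_base_chromosomes=1, base_lengths=(10_000,), seed=1)
        genomes = simulate_ancestral_genomes(model)
        fam = RepeatFamilySpec("huge", None, 50_000, 500, 1, 1.0, 0.1)
        with pytest.raises(ValueError, match="longer than chromosome"):
            insert_repeats(genomes, [fam], seed=1)

    def test_ltr_must_fit_inside_element(self):
        with pytest.raises(ValueError, match="LTR"):
            RepeatFamilySpec("bad", None, 1000, 600, 1, 1.0, 0.1)


class TestMarkers:
    def test_truth_copy_number_equals_base_chromosome_copies(self, tully_with_markers):
        _, markers, truth = tully_with_markers
        # marker 1 homed on base 1 (2A+4B+2C = 8), marker 5 on base 5 (3+3+2 = 8)
        assert truth.marker_copy_number("marker0001") == 8
        assert truth.marker_copy_number("marker0005") == 8
        assert all(truth.marker_copy_number(m) == 8 for m in markers)

    def test_haploid_spec_gives_single_copies(self, ancestral_default):
        genomes, _ = ancestral_default
        spec = PolyploidSpec(per_chromosome_copies={i: {"A": 1} for i in range(1, 7)})
        polyploid, truth = compose_polyploid(genomes, spec, seed=1)
        _, markers = plant_markers(polyploid, truth, n_markers=6, seed=2)
        assert all(truth.marker_copy_number(m) == 1 for m in markers)

    def test_markers_planted_once_per_haplotype_copy(self, tully_with_markers):
        _, markers, truth = tully_with_markers
        for mid, places in truth.markers.items():
            seq_ids = [p.seq_id for p in places]
            assert len(seq_ids) == len(set(seq_ids))


def test_spec_totals_bookkeeping():
    spec = tully_spec()
    assert spec.totals == {"A": 14, "B": 22, "C": 12}
    assert spec.n_chromosomes == 48
    hexa = hexaploid_ab_spec()
    assert hexa.totals == {"A": 12, "B": 24}
    assert hexa.n_chromosomes == 36


def test_fixture_deterministic_end_to_end():
    p1, _ = make_tully_fixture(seed=8, length=10_000, families=False)
    p2, _ = make_tully_fixture(seed=8, length=10_000, families=False)
    assert all(np.array_equal(p1[k], p2[k]) for k in p1)
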