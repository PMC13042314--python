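"""Chaining, unique-link filtering, AGP round trips, and fused references."""

import numpy as np
import pytest

from polyphase.align import AnchorAlignment
from polyphase.scaffold import (
    AgpComponent,
    AgpGap,
    AgpPlan,
    anchor_contigs,
    apply_agp,
    build_fused_reference,
    chain_alignments,
    filter_unique_links,
    liftover_position,
)
from polyphase.seqs import decode, encode, random_seq, revcomp
from polyphase.simulate import (
    PolyploidSpec,
    compose_polyploid,
    default_model,
    fragment_to_contigs,
    simulate_ancestral_genomes,
)


def block(q, t, qs, qe, ts, te, strand="+", qlen=50_000, tlen=100_000):
    return AnchorAlignment(
        query_id=q,
        query_len=qlen,
        q_start=qs,
        q_end=qe,
        target_id=t,
        target_len=tlen,
        t_start=ts,
        t_end=te,
        strand=strand,
        aligned_bases=qe - qs,
    )


class TestChaining:
    def test_colinear_blocks_merge_into_one_chain(self):
        alns = [
            block("q", "t", 0, 8000, 0, 8000),
            block("q", "t", 9000, 17_000, 9000, 17_000),
        ]
        chains = chain_alignments(alns, max_gap=100_000, min_chain_len=10_000)
        assert len(chains) == 1
        assert chains[0].aligned_bases == 16_000

    def test_short_chain_dropped_by_min_length(self):
        alns = [block("q", "t", 0, 9000, 0, 9000)]
        assert chain_alignments(alns, min_chain_len=10_000) == []

    def test_opposite_strands_never_chain_together(self):
        alns = [
            block("q", "t", 0, 8000, 0, 8000, "+"),
            block("q", "t", 9000, 17_000, 20_000, 28_000, "-"),
        ]
        chains = chain_alignments(alns, min_chain_len=5_000)
        assert len(chains) == 2
        assert {c.strand for c in chains} == {"+", "-"}

    def test_target_jump_beyond_max_gap_starts_new_chain(self):
        alns = [
            block("q", "t", 0, 8000, 0, 8000),
            block("q", "t", 9000, 17_000, 60_000, 68_000),
        ]
        chains = chain_alignments(alns, max_gap=10_000, min_chain_len=5_000)
        assert len(chains) == 2


class TestUniqueLinkFilter:
    def test_multi_target_query_is_dropped_entirely(self):
        chains = chain_alignments(
            [
                block("q1", "t1", 0, 12_000, 0, 12_000),
                block("q1", "t2", 12_000, 25_000, 0, 13_000),
            ],
            min_chain_len=10_000,
        )
        assert len(chains) == 2
        assert filter_unique_links(chains) == []

    def test_one_to_one_links_are_retained(self):
        chains = chain_alignments(
            [
                block("q1", "t1", 0, 12_000, 0, 12_000),
                block("q2", "t1", 0, 12_000, 30_000, 42_000),
                block("q3", "t2", 0, 12_000, 0, 12_000),
            ],
            min_chain_len=10_000,
        )
        kept = filter_unique_links(chains)
        assert sorted(c.query_id for c in kept) == ["q1", "q2", "q3"]

    def test_target_overlap_drops_both(self):
        chains = chain_alignments(
            [
                block("q1", "t1", 0, 12_000, 0, 12_000),
                block("q2", "t1", 0, 12_000, 6_000, 18_000),
            ],
            min_chain_len=10_000,
        )
        assert filter_unique_links(chains) == []

    def test_idempotent(self):
        chains = chain_alignments(
            [
                block("q1", "t1", 0, 12_000, 0, 12_000),
                block("q2", "t1", 0, 12_000, 30_000, 42_000),
                block("q2", "t2", 0, 12_000, 0, 12_000),
            ],
            min_chain_len=10_000,
        )
        once = filter_unique_links(chains)
        assert filter_unique_links(once) == once


class TestAgp:
    def test_gap_record_adds_n_run(self):
        contigs = {"a": "ACGT" * 25, "b": "TTTT" * 25}
        plan = AgpPlan(
            objects={
                "chr": [
                    AgpComponent("a", "+", 1, 100),
                    AgpGap(length=100),
                    AgpComponent("b", "+", 1, 100),
                ]
            }
        )
        out = apply_agp(plan, contigs)["chr"]
        assert out.size == 300
        assert np.all(out[100:200] == 255)  # N run

    def test_reversed_component_is_reverse_complemented(self):
        contigs = {"a": "AACCGGTTAC"}
        plan = AgpPlan(objects={"chr": [AgpComponent("a", "-", 1, 10)]})
        assert np.array_equal(apply_agp(plan, contigs)["chr"], revcomp(encode("AACCGGTTAC")))

    def test_missing_contig_and_bad_span_raise(self):
        plan = AgpPlan(objects={"chr": [AgpComponent("nope", "+", 1, 10)]})
        with pytest.raises(KeyError):
            apply_agp(plan, {})
        plan2 = AgpPlan(objects={"chr": [AgpComponent("a", "+", 1, 99)]})
        with pytest.raises(ValueError):
            apply_agp(plan2, {"a": "ACGT"})

    def test_duplicate_contig_rejected(self):
        plan = AgpPlan(
            objects={"chr": [AgpComponent("a", "+", 1, 4), AgpComponent("a", "+", 1, 4)]}
        )
        with pytest.raises(ValueError, match="more than once"):
            plan.validate()

    def test_agp_text_round_trip(self):
        plan = AgpPlan(
            objects={
                "chr1": [
                    AgpComponent("a", "+", 1, 100),
                    AgpGap(length=100),
                    AgpComponent("b", "-", 1, 50),
                ]
            }
        )
        text = plan.to_agp()
        assert text.startswith("##agp-version\t2.1")
        back = AgpPlan.from_agp(text)
        contigs = {"a": "ACGT" * 25, "b": "AC" * 25}
        assert np.array_equal(
            apply_agp(plan, contigs)["chr1"], apply_agp(back, contigs)["chr1"]
        )


@pytest.fixture(scope="module")
def haploid_genome():
    """Six distinct 30 kb chromosomes (one ancestry, one haplotype)."""
    model = default_model(seed=17, length=30_000)
    genomes = simulate_ancestral_genomes(model)
    spec = PolyploidSpec(per_chromosome_copies={i: {"A": 1} for i in range(1, 7)})
    polyploid, _ = compose_polyploid(genomes, spec, seed=1)
    return polyploid


class TestAnchoring:
    def test_round_trip_reconstructs_chromosomes(self, haploid_genome):
        contigs, _ = fragment_to_contigs(
            haploid_genome, mean_contig_length=10_000, min_length=7_000, seed=3
        )
        plan, unplaced = anchor_contigs(contigs, haploid_genome, min_chain_len=5_000)
        assert unplaced == []
        rebuilt = apply_agp(plan, contigs)
        for chrom, seq in haploid_genome.items():
            got = rebuilt[chrom]
            assert np.array_equal(got[got != 255], seq)

    def test_unrelated_contig_stays_unplaced(self, haploid_genome):
        rng = np.random.default_rng(99)
        contigs, _ = fragment_to_contigs(
            haploid_genome, mean_contig_length=15_000, min_length=7_000, seed=4
        )
        contigs["alien"] = random_seq(15_000, rng)
        plan, unplaced = anchor_contigs(contigs, haploid_genome, min_chain_len=5_000)
        assert "alien" in unplaced

    def test_whole_chromosome_contig_single_component(self, haploid_genome):
        chrom = list(haploid_genome)[0]
        contigs = {"whole": haploid_genome[chrom]}
        plan, unplaced = anchor_contigs(contigs, haploid_genome, min_chain_len=5_000)
        assert unplaced == []
        comps = plan.objects[chrom]
        assert len(comps) == 1 and comps[0].contig_id == "whole"

    def test_duplicate_reference_ids_rejected(self, haploid_genome):
        class Dup(dict):
            def __iter__(self):
                yield from ["x", "x"]

        with pytest.raises(ValueError, match="distinct"):
            anchor_contigs({}, Dup(x="ACGT"), alignments=[])


class TestFusedReference:
    @pytest.fixture()
    def nine_chromosomes(self):
        rng = np.random.default_rng(23)
        return {f"chr{i}": random_seq(12_000, rng) for i in range(1, 10)}

    def test_nine_to_six_fusion(self, nine_chromosomes):
        fused, lift = build_fused_reference(
            nine_chromosomes, [("chr1", "chr7"), ("chr2", "chr4"), ("chr5", "chr6")]
        )
        assert len(fused) == 6
        assert set(fused) == {"chr1+chr7", "chr2+chr4", "chr5+chr6", "chr3", "chr8", "chr9"}

    def test_empty_map_is_identity(self, nine_chromosomes):
        fused, _ = build_fused_reference(nine_chromosomes, [])
        assert set(fused) == set(nine_chromosomes)
        assert all(np.array_equal(fused[c], nine_chromosomes[c]) for c in fused)

    def test_liftover_coordinate_arithmetic(self, nine_chromosomes):
        gap = 100
        fused, lift = build_fused_reference(
            nine_chromosomes, [("chr2", "chr4")], gap_length=gap
        )
        pos = 1234
        new_chrom, new_pos = liftover_position(lift, "chr4", pos)
        assert new_chrom == "chr2+chr4"
        assert new_pos == len(nine_chromosomes["chr2"]) + gap + pos
        # the lifted base is the same base
        assert fused["chr2+chr4"][new_pos] == nine_chromosomes["chr4"][pos]

    def test_liftover_is_bijective_on_covered_coordinates(self, nine_chromosomes):
        fused, lift = build_fused_reference(
            nine_chromosomes, [("chr1", "chr7"), ("chr5", "chr6")]
        )
        seen = set()
        for _, row in lift.iterrows():
            for pos in (0, int(row["old_length"]) - 1):
                key = liftover_position(lift, row["old_chrom"], pos)
                assert key not in seen
                seen.add(key)

    def test_reuse_and_missing_chromosomes_rejected(self, nine_chromosomes):
        with pytest.raises(ValueError, match="twice"):
            build_fused_reference(nine_chromosomes, [("chr1", "chr2"), ("chr1", "chr3")])
        with pytest.raises(KeyError):
            build_fused_reference(nine_chromosomes, [("chr1", "chr99")])
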