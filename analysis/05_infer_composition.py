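#!/usr/bin/env python
"""Subgenome composition from competitive read mapping.

Part 1 reproduces the worked arithmetic for a hexaploid accession from its
per-subgenome read counts (33.32% A / 66.19% B -> 12A + 24B = AABBBB,
ratio 1A:2B). Part 2 simulates an AABBBB accession sharing ancestry with
the 48-chromosome reference, assigns its reads competitively by shared
k-mers, and re-infers the composition from the observed shares.
"""

import argparse
from pathlib import Path

from polyphase.composition import (
    competitive_assign,
    composition_from_reads,
    coverage_table,
    expected_proportions,
    infer_composition,
)
from polyphase.simulate import (
    compose_polyploid,
    default_model,
    hexaploid_ab_spec,
    simulate_ancestral_genomes,
    simulate_reads,
    tully_spec,
)

PUBLISHED_COUNTS = {"A": 15_646_090, "B": 31_076_742, "C": 230_974}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=101)
    ap.add_argument("--length", type=int, default=20_000)
    ap.add_argument("--coverage", type=float, default=20.0, help="accession sample depth")
    ap.add_argument("--out", type=Path, default=Path("results/composition"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    print("== worked example: hexaploid accession, published read counts ==")
    table = coverage_table(PUBLISHED_COUNTS, {"A": "A", "B": "B", "C": "C"})
    print(table.to_string(index=False))
    est = infer_composition(dict(zip(table["subgenome"], table["percent"])), N=36)
    print(f"fit: {est.counts} -> {est.formula} ({est.ratio}), residual {est.residual:.2f}")
    print("expected shares for the 48-chromosome reference:",
          expected_proportions({"A": 14, "B": 22, "C": 12}, decimals=0))

    print("\n== simulated AABBBB accession vs 48-chromosome reference ==")
    model = default_model(seed=args.seed, length=args.length)
    genomes = simulate_ancestral_genomes(model)
    reference, ref_truth = compose_polyploid(genomes, tully_spec(), seed=args.seed + 1)
    accession, _ = compose_polyploid(genomes, hexaploid_ab_spec(), seed=args.seed + 2)
    reads = simulate_reads(
        accession, coverage_per_copy=args.coverage / 6, seed=args.seed + 3
    )
    result = competitive_assign(reads, reference, k=21, seed=args.seed + 3)
    sg_map = ref_truth.ancestry_map()
    table = coverage_table(result.counts, sg_map)
    table.to_csv(args.out / "coverage_table.tsv", sep="\t", index=False)
    print(f"{len(reads)} pairs simulated, {result.unassigned} unassigned")
    print(table.to_string(index=False))
    est = composition_from_reads(result.counts, sg_map, N=36)
    print(f"fit: {est.counts} -> {est.formula} ({est.ratio}), residual {est.residual:.2f}")


if __name__ == "__main__":
    main()
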