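#!/usr/bin/env python
"""Generate the synthetic aneuploid octoploid fixture genome.

Builds the 48-chromosome genome (14A + 22B + 12C over 6 base chromosomes;
AABBBBCC for bases 1-4, AAABBBCC for 5-6) with subgenome-specific LTR
families and planted single-copy markers, fragments it into contigs, and
writes everything plus full ground truth under results/fixture/.
"""

import argparse
from pathlib import Path

from polyphase import io as pio
from polyphase.simulate import fragment_to_contigs, make_tully_fixture, plant_markers


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--length", type=int, default=50_000, help="base chromosome length")
    ap.add_argument("--out", type=Path, default=Path("results/fixture"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    polyploid, truth = make_tully_fixture(seed=args.seed, length=args.length)
    polyploid, markers = plant_markers(
        polyploid, truth, n_markers=18, marker_length=500, seed=args.seed + 3
    )
    contigs, plan = fragment_to_contigs(
        polyploid, mean_contig_length=args.length // 3, min_length=12_000, seed=args.seed + 4
    )

    pio.write_fasta(polyploid, args.out / "genome.fa")
    pio.write_fasta(markers, args.out / "markers.fa")
    pio.write_fasta(contigs, args.out / "contigs.fa")
    (args.out / "truth.agp").write_text(plan.to_agp())
    for name, df in pio.truth_tables(truth).items():
        df.to_csv(args.out / f"truth_{name}.tsv", sep="\t", index=False)

    total = sum(s.size for s in polyploid.values())
    print(f"genome: {len(polyploid)} chromosomes, {total/1e6:.2f} Mb total")
    print(f"contigs: {len(contigs)}; markers: {len(markers)} (8 copies each expected)")
    print(f"outputs under {args.out}/")


if __name__ == "__main__":
    main()
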