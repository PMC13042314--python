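#!/usr/bin/env python
"""Estimate ploidy and chromosome number from single-copy markers.

Aligns the planted markers back to the fixture genome, builds the
copy-number histogram, and multiplies the modal multiplicity by the base
chromosome number (x = 6). On the aneuploid octoploid fixture every base
chromosome has 8 copies, so the mode is 8 and the estimate is 48.
"""

import argparse
from pathlib import Path

from polyphase.ploidy import (
    count_marker_copies,
    estimate_chromosome_number,
    histogram_table,
    modal_copy_fraction,
)
from polyphase.simulate import make_tully_fixture, plant_markers


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--length", type=int, default=30_000)
    ap.add_argument("--markers", type=int, default=18)
    ap.add_argument("--base", type=int, default=6)
    ap.add_argument("--out", type=Path, default=Path("results/ploidy"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    polyploid, truth = make_tully_fixture(seed=args.seed, length=args.length)
    polyploid, markers = plant_markers(
        polyploid, truth, n_markers=args.markers, marker_length=500, seed=args.seed + 3
    )
    hist = count_marker_copies(markers, polyploid)
    mode, frac = modal_copy_fraction(hist)
    table = histogram_table(hist)
    table.to_csv(args.out / "marker_copy_histogram.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"modal copy number {mode} ({100 * frac:.1f}% of markers)")
    print(
        f"estimated chromosomes: {mode} x {args.base} = "
        f"{estimate_chromosome_number(mode, args.base)}"
    )


if __name__ == "__main__":
    main()
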