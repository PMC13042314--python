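"""Ploidy estimation from single-copy marker multiplicity.

In a haplotype-resolved polyploid assembly, a truly single-copy marker
(one copy per haploid genome, the single-copy BUSCO situation) aligns once
per haplotype chromosome, so the modal alignment count over many markers
estimates the ploidy, and ploidy x base chromosome number estimates the
chromosome count. The marker alignment engine is the internal seed
aligner refined with an edit-distance check (edlib), so the module needs
no external tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np

from .align import SeedIndex, align_query
from .seqs import as_array, decode, revcomp


@dataclass
class MarkerCopyHistogram:
    """Copy count per marker, plus the derived histogram."""

    copies: dict[str, int]

    @property
    def n_markers(self) -> int:
        return len(self.copies)

    def histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for c in self.copies.values():
            hist[c] = hist.get(c, 0) + 1
        return hist

    def fractions(self) -> dict[int, float]:
        n = self.n_markers
        return {c: v / n for c, v in self.histogram().items()}

    def missing(self) -> list[str]:
        return sorted(m for m, c in self.copies.items() if c == 0)


def _dedupe_loci(loci: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge hits whose intervals overlap >= 50% of the shorter one."""
    loci = sorted(loci)
    merged: list[tuple[int, int]] = []
    for s, e in loci:
        if merged:
            ps, pe = merged[-1]
            overlap = min(pe, e) - max(ps, s)
            shorter = min(pe - ps, e - s)
            if shorter > 0 and overlap >= 0.5 * shorter:
                merged[-1] = (min(ps, s), max(pe, e))
                continue
        merged.append((s, e))
    return merged


def count_marker_copies(
    markers: dict,
    target_sequences: dict,
    min_coverage: float = 0.9,
    min_identity: float = 0.9,
    k: int = 15,
    max_occ: int = 200,
) -> MarkerCopyHistogram:
    """Count distinct loci where each marker aligns well enough.

    A locus counts when the seed cluster covers at least ``min_coverage``
    of the marker and the edlib edit distance of the marker against the
    local target window gives identity >= ``min_identity``. Overlapping
    hits on one locus are counted once; markers with no locus are recorded
    with copy count 0.
    """
    if not markers or not target_sequences:
        raise ValueError("markers and targets must be non-empty")
    index = SeedIndex(target_sequences, k=k, max_occ=max_occ)
    targets = {tid: as_array(s) for tid, s in target_sequences.items()}
    copies: dict[str, int] = {}
    for mid, mseq in markers.items():
        marr = as_array(mseq)
        mlen = marr.size
        max_dist = math.floor((1.0 - min_identity) * mlen)
        alns = align_query(mid, marr, index, min_seeds=3, secondary_ratio=0.0)
        loci: dict[str, list[tuple[int, int]]] = {}
        for aln in alns:
            if aln.q_span < min_coverage * mlen:
                continue
            pad = int(0.1 * mlen) + 16
            t = targets[aln.target_id]
            ws, we = max(0, aln.t_start - pad), min(t.size, aln.t_end + pad)
            window = decode(t[ws:we])
            query = marr if aln.strand == "+" else revcomp(marr)
            res = edlib.align(decode(query), window, mode="HW", task="locations", k=max_dist)
            if res["editDistance"] < 0:
                continue
            loc = res["locations"][0]
            loci.setdefault(aln.target_id, []).append((ws + loc[0], ws + loc[1] + 1))
        copies[mid] = sum(len(_dedupe_loci(v)) for v in loci.values())
    return MarkerCopyHistogram(copies=copies)


def modal_copy_fraction(hist: MarkerCopyHistogram | dict[int, int]) -> tuple[int, float]:
    """Modal copy number and the fraction of markers at the mode.

    Ties are broken toward the larger copy number.
    """
    histogram = hist.histogram() if isinstance(hist, MarkerCopyHistogram) else dict(hist)
    if not histogram or sum(histogram.values()) == 0:
        raise ValueError("empty histogram")
    n = sum(histogram.values())
    mode = max(histogram, key=lambda c: (histogram[c], c))
    return mode, histogram[mode] / n


def estimate_chromosome_number(modal_copy: int, base_number: int) -> int:
    """Chromosome count = modal marker multiplicity x base number (x)."""
    if modal_copy < 1 or base_number < 1:
        raise ValueError("both arguments must be >= 1")
    return modal_copy * base_number


def histogram_table(hist: MarkerCopyHistogram):
    """Histogram as a tidy DataFrame (copy_number, n_markers, fraction)."""
    import pandas as pd

    h = hist.histogram()
    n = hist.n_markers
    return pd.DataFrame(
        {
            "copy_number": sorted(h),
            "n_markers": [h[c] for c in sorted(h)],
            "fraction": [h[c] / n for c in sorted(h)],
        }
    )


def naive_copy_count(marker: str, targets: dict) -> int:
    """Exhaustive exact-substring oracle (both strands) for planted,
    error-free markers; used for validation only."""
    total = 0
    rc = decode(revcomp(as_array(marker)))
    for seq in targets.values():
        s = seq if isinstance(seq, str) else decode(np.asarray(seq, dtype=np.uint8))
        for probe in {marker, rc}:
            start = 0
            while True:
                i = s.find(probe, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total
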