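"""Seed-based pairwise anchoring of queries to a reference.

A deliberately simple alignment engine: exact k-mer seeds are located on a
sorted forward-strand index of the reference, seeds are clustered by
(target, strand, diagonal), and each cluster becomes an
:class:`AnchorAlignment` whose ``aligned_bases`` is a conservative estimate
from the distinct matched seed positions. Queries are matched on both
strands by also seeding their reverse complement.

This engine backs marker copy counting and contig anchoring on synthetic
and small real inputs; for genome-scale work an external PAF (e.g. from
minimap2) can be fed to the downstream chaining and filtering steps
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmers import _forward_codes
from .seqs import as_array, revcomp


@dataclass
class AnchorAlignment:
    """One local alignment block (PAF-like, 0-based half-open coordinates)."""

    query_id: str
    query_len: int
    q_start: int
    q_end: int
    target_id: str
    target_len: int
    t_start: int
    t_end: int
    strand: str  # '+' or '-'
    aligned_bases: int

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end <= self.query_len):
            raise ValueError(f"bad query span on {self.query_id}")
        if not (0 <= self.t_start < self.t_end <= self.target_len):
            raise ValueError(f"bad target span on {self.target_id}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        span = min(self.q_end - self.q_start, self.t_end - self.t_start)
        self.aligned_bases = min(self.aligned_bases, span)

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_span(self) -> int:
        return self.t_end - self.t_start


class SeedIndex:
    """Sorted forward-strand k-mer index over a set of reference sequences."""

    def __init__(self, references: dict, k: int = 21, max_occ: int = 100):
        if not references:
            raise ValueError("empty reference set")
        self.k = k
        self.ids = list(references)
        self.lengths: dict[str, int] = {}
        codes_all = []
        pos_all = []
        ref_all = []
        for ri, rid in enumerate(self.ids):
            arr = as_array(references[rid])
            self.lengths[rid] = arr.size
            codes, ok = _forward_codes(arr, k)
            pos = np.nonzero(ok)[0]
            codes_all.append(codes[ok])
            pos_all.append(pos)
            ref_all.append(np.full(pos.size, ri, dtype=np.int32))
        codes = np.concatenate(codes_all)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = np.concatenate(pos_all)[order].astype(np.int64)
        self.ref = np.concatenate(ref_all)[order]
        if max_occ:
            # mask hyper-repetitive seeds (repeat families, homopolymers)
            left = np.searchsorted(self.codes, self.codes, side="left")
            right = np.searchsorted(self.codes, self.codes, side="right")
            keep = (right - left) <= max_occ
            self.codes = self.codes[keep]
            self.pos = self.pos[keep]
            self.ref = self.ref[keep]

    def hits(self, arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(query_pos, ref_idx, target_pos) for every forward seed match."""
        codes, ok = _forward_codes(arr, self.k)
        qpos = np.nonzero(ok)[0]
        codes = codes[ok]
        left = np.searchsorted(self.codes, codes, side="left")
        right = np.searchsorted(self.codes, codes, side="right")
        widths = right - left
        total = int(widths.sum())
        if total == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e.astype(np.int32), e
        starts = np.repeat(left, widths)
        offsets = np.arange(total) - np.repeat(np.cumsum(widths) - widths, widths)
        idx = starts + offsets
        return np.repeat(qpos, widths), self.ref[idx], self.pos[idx]


def _clusters_to_alignments(
    qid: str,
    qlen: int,
    index: SeedIndex,
    qpos: np.ndarray,
    ref: np.ndarray,
    tpos: np.ndarray,
    strand: str,
    k: int,
    band: int,
    max_gap: int,
    min_seeds: int,
) -> list[AnchorAlignment]:
    if qpos.size == 0:
        return []
    diag = qpos - tpos if strand == "+" else qpos + tpos
    order = np.lexsort((tpos, diag, ref))
    qpos, ref, tpos, diag = qpos[order], ref[order], tpos[order], diag[order]
    breaks = np.nonzero(
        (np.diff(ref) != 0)
        | (np.abs(np.diff(diag)) > band)
        | (np.diff(tpos) > max_gap)
    )[0]
    bounds = np.concatenate([[0], breaks + 1, [qpos.size]])
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        n_seeds = int(np.unique(qpos[s:e]).size)
        if n_seeds < min_seeds:
            continue
        rid = index.ids[int(ref[s])]
        qs, qe = int(qpos[s:e].min()), int(qpos[s:e].max()) + k
        ts, te = int(tpos[s:e].min()), int(tpos[s:e].max()) + k
        out.append(
            AnchorAlignment(
                query_id=qid,
                query_len=qlen,
                q_start=qs,
                q_end=qe,
                target_id=rid,
                target_len=index.lengths[rid],
                t_start=ts,
                t_end=te,
                strand=strand,
                aligned_bases=n_seeds + k - 1,
            )
        )
    return out


def align_query(
    qid: str,
    query,
    index: SeedIndex,
    band: int = 100,
    max_gap: int = 100_000,
    min_seeds: int = 3,
    secondary_ratio: float = 0.0,
) -> list[AnchorAlignment]:
    """All seed-cluster alignments of one query against the index.

    ``secondary_ratio`` drops alignments scoring below that fraction of the
    query's best alignment (minimap2 ``-p`` style); 0 keeps everything,
    which is what multi-locus queries like single-copy markers need.
    """
    arr = as_array(query)
    k = index.k
    alns = []
    for strand, a in (("+", arr), ("-", revcomp(arr))):
        qpos, ref, tpos = index.hits(a)
        if strand == "-":
            # seed at position i of revcomp(query) covers query window
            # [qlen - k - i, qlen - i)
            qpos = arr.size - k - qpos
        alns.extend(
            _clusters_to_alignments(
                qid, arr.size, index, qpos, ref, tpos, strand, k, band, max_gap, min_seeds
            )
        )
    if alns and secondary_ratio > 0:
        best = max(a.aligned_bases for a in alns)
        alns = [a for a in alns if a.aligned_bases >= secondary_ratio * best]
    return alns


def align_to_reference(
    queries: dict,
    references: dict,
    k: int = 21,
    band: int = 100,
    max_gap: int = 100_000,
    min_seeds: int = 3,
    secondary_ratio: float = 0.0,
    max_occ: int = 100,
) -> list[AnchorAlignment]:
    """Anchor every query against the reference set."""
    index = SeedIndex(references, k=k, max_occ=max_occ)
    out: list[AnchorAlignment] = []
    for qid, seq in queries.items():
        out.extend(
            align_query(
                qid,
                seq,
                index,
                band=band,
                max_gap=max_gap,
                min_seeds=min_seeds,
                secondary_ratio=secondary_ratio,
            )
        )
    return out
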