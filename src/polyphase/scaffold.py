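"""Synteny-based contig anchoring, AGP plans, and fused references.

Implements reference-guided scaffolding in the RagTag style: contig/
reference alignments are chained per (query, target, strand), chains below
a minimum aligned length are dropped, links are restricted to strictly
one-to-one query/target relationships, and surviving contigs are ordered
and oriented along their target into an AGP v2.1 plan. Also builds "fused"
references — concatenating chromosome pairs to mimic a relative whose
karyotype differs by known fusion events (e.g. reducing a 9-chromosome
relative to the x = 6 karyotype via 1+7, 2+4, 5+6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AnchorAlignment, align_to_reference
from .seqs import as_array, revcomp

GAP_CODE = 255  # encodes N in the 2-bit alphabet


@dataclass
class AlignmentChain:
    """A colinear run of alignment blocks between one query and one target."""

    query_id: str
    target_id: str
    strand: str
    members: list[AnchorAlignment]
    aligned_bases: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int

    @property
    def t_mid(self) -> float:
        return (self.t_start + self.t_end) / 2.0


def chain_alignments(
    alignments: list[AnchorAlignment],
    max_gap: int = 100_000,
    min_chain_len: int = 10_000,
) -> list[AlignmentChain]:
    """Greedy colinear chaining per (query, target, strand).

    Blocks are taken in query order and appended while both the query gap
    and the target gap stay within ``max_gap`` and the target advances in
    the strand-consistent direction. Chains totalling fewer than
    ``min_chain_len`` aligned bases are discarded.
    """
    groups: dict[tuple[str, str, str], list[AnchorAlignment]] = {}
    for aln in alignments:
        groups.setdefault((aln.query_id, aln.target_id, aln.strand), []).append(aln)
    chains: list[AlignmentChain] = []
    for (qid, tid, strand), blocks in groups.items():
        blocks.sort(key=lambda a: a.q_start)
        open_chains: list[list[AnchorAlignment]] = []
        for aln in blocks:
            placed = False
            for chain in open_chains:
                last = chain[-1]
                q_gap = aln.q_start - last.q_end
                if q_gap > max_gap:
                    continue
                if strand == "+":
                    t_gap = aln.t_start - last.t_end
                else:
                    t_gap = last.t_start - aln.t_end
                if -aln.q_span < t_gap <= max_gap:
                    chain.append(aln)
                    placed = True
                    break
            if not placed:
                open_chains.append([aln])
        for members in open_chains:
            total = sum(a.aligned_bases for a in members)
            if total < min_chain_len:
                continue
            chains.append(
                AlignmentChain(
                    query_id=qid,
                    target_id=tid,
                    strand=strand,
                    members=members,
                    aligned_bases=total,
                    q_start=min(a.q_start for a in members),
                    q_end=max(a.q_end for a in members),
                    t_start=min(a.t_start for a in members),
                    t_end=max(a.t_end for a in members),
                )
            )
    return chains


def filter_unique_links(chains: list[AlignmentChain]) -> list[AlignmentChain]:
    """Keep only strictly one-to-one links.

    Two passes: first drop every chain whose query contig participates in
    more than one chain, then drop every chain whose target interval
    overlaps another retained chain's interval on the same target.
    Idempotent.
    """
    per_query: dict[str, int] = {}
    for c in chains:
        per_query[c.query_id] = per_query.get(c.query_id, 0) + 1
    retained = [c for c in chains if per_query[c.query_id] == 1]

    by_target: dict[str, list[AlignmentChain]] = {}
    for c in retained:
        by_target.setdefault(c.target_id, []).append(c)
    dropped: set[int] = set()
    for tchains in by_target.values():
        tchains.sort(key=lambda c: c.t_start)
        for a, b in zip(tchains, tchains[1:]):
            if b.t_start < a.t_end:  # overlap on target
                dropped.add(id(a))
                dropped.add(id(b))
    return [c for c in retained if id(c) not in dropped]


# ---------------------------------------------------------------------------
# AGP


@dataclass
class AgpComponent:
    contig_id: str
    orientation: str = "+"
    comp_beg: int = 1  # 1-based inclusive, AGP convention
    comp_end: int = 0

    @property
    def length(self) -> int:
        return self.comp_end - self.comp_beg + 1


@dataclass
class AgpGap:
    length: int = 100
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "align_genus"


@dataclass
class AgpPlan:
    """Ordered, oriented contig placements per output chromosome."""

    objects: dict[str, list[AgpComponent | AgpGap]] = field(default_factory=dict)

    def components(self) -> list[AgpComponent]:
        return [
            part
            for parts in self.objects.values()
            for part in parts
            if isinstance(part, AgpComponent)
        ]

    def used_contigs(self) -> list[str]:
        return [c.contig_id for c in self.components()]

    def validate(self) -> None:
        used = self.used_contigs()
        if len(used) != len(set(used)):
            raise ValueError("a contig appears more than once in the AGP plan")

    def to_agp(self) -> str:
        """Serialize as AGP v2.1 (1-based inclusive object coordinates)."""
        self.validate()
        lines = ["##agp-version\t2.1"]
        for obj, parts in self.objects.items():
            pos = 0
            for n, part in enumerate(parts, start=1):
                if isinstance(part, AgpComponent):
                    beg, end = pos + 1, pos + part.length
                    lines.append(
                        "\t".join(
                            [
                                obj,
                                str(beg),
                                str(end),
                                str(n),
                                "W",
                                part.contig_id,
                                str(part.comp_beg),
                                str(part.comp_end),
                                part.orientation,
                            ]
                        )
                    )
                    pos = end
                else:
                    beg, end = pos + 1, pos + part.length
                    lines.append(
                        "\t".join(
                            [
                                obj,
                                str(beg),
                                str(end),
                                str(n),
                                "N",
                                str(part.length),
                                part.gap_type,
                                part.linkage,
                                part.evidence,
                            ]
                        )
                    )
                    pos = end
        return "\n".join(lines) + "\n"

    @classmethod
    def from_agp(cls, text: str) -> "AgpPlan":
        plan = cls()
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            obj = f[0]
            parts = plan.objects.setdefault(obj, [])
            if f[4] in ("N", "U"):
                parts.append(
                    AgpGap(length=int(f[5]), gap_type=f[6], linkage=f[7], evidence=f[8])
                )
            else:
                parts.append(
                    AgpComponent(
                        contig_id=f[5],
                        orientation=f[8],
                        comp_beg=int(f[6]),
                        comp_end=int(f[7]),
                    )
                )
        return plan


def apply_agp(plan: AgpPlan, contigs: dict) -> dict[str, np.ndarray]:
    """Build chromosome sequences from an AGP plan.

    Gap records become N runs; '-' components are reverse complemented.
    """
    plan.validate()
    out: dict[str, np.ndarray] = {}
    for obj, parts in plan.objects.items():
        pieces = []
        for part in parts:
            if isinstance(part, AgpGap):
                pieces.append(np.full(part.length, GAP_CODE, dtype=np.uint8))
                continue
            if part.contig_id not in contigs:
                raise KeyError(f"missing contig {part.contig_id}")
            arr = as_array(contigs[part.contig_id])
            if not (1 <= part.comp_beg <= part.comp_end <= arr.size):
                raise ValueError(f"component span outside contig {part.contig_id}")
            piece = arr[part.comp_beg - 1 : part.comp_end]
            if part.orientation == "-":
                piece = revcomp(piece)
            pieces.append(piece)
        out[obj] = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    return out


def anchor_contigs(
    contigs: dict,
    reference: dict,
    min_chain_len: int = 10_000,
    k: int = 21,
    max_gap: int = 100_000,
    gap_length: int = 100,
    secondary_ratio: float = 0.95,
    alignments: list[AnchorAlignment] | None = None,
) -> tuple[AgpPlan, list[str]]:
    """Order and orient contigs along a reference into an AGP plan.

    Alignments (internal seed aligner by default, or a caller-supplied PAF
    parse) are chained and restricted to one-to-one links; each retained
    contig is placed whole on its single target, ordered by chain midpoint
    and oriented by chain strand, with fixed-length scaffold gaps between
    neighbours. Contigs without a retained chain are reported unplaced.
    """
    ids = list(reference)
    if len(ids) != len(set(ids)):
        raise ValueError("reference chromosome ids must be distinct")
    if alignments is None:
        alignments = align_to_reference(
            contigs, reference, k=k, max_gap=max_gap, secondary_ratio=secondary_ratio
        )
    chains = chain_alignments(alignments, max_gap=max_gap, min_chain_len=min_chain_len)
    kept = filter_unique_links(chains)

    by_target: dict[str, list[AlignmentChain]] = {}
    for c in kept:
        by_target.setdefault(c.target_id, []).append(c)
    plan = AgpPlan()
    placed: set[str] = set()
    contig_len = {cid: as_array(s).size for cid, s in contigs.items()}
    for tid in sorted(by_target):
        tchains = sorted(by_target[tid], key=lambda c: c.t_mid)
        parts: list[AgpComponent | AgpGap] = []
        for c in tchains:
            if parts:
                parts.append(AgpGap(length=gap_length))
            parts.append(
                AgpComponent(
                    contig_id=c.query_id,
                    orientation=c.strand,
                    comp_beg=1,
                    comp_end=contig_len[c.query_id],
                )
            )
            placed.add(c.query_id)
        plan.objects[tid] = parts
    plan.validate()
    unplaced = sorted(set(contigs) - placed)
    return plan, unplaced


# ---------------------------------------------------------------------------
# fused reference


def build_fused_reference(
    genome: dict,
    fusion_map: list[tuple[str, ...]] | list[list[str]],
    gap_length: int = 100,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Concatenate chromosome groups into fused pseudo-chromosomes.

    Each fusion group becomes one sequence (members joined in map order
    with an N junction gap); chromosomes not mentioned pass through. The
    returned liftover table maps every old chromosome to its new name and
    additive offset, so old coordinate -> new coordinate is
    ``offset + pos`` exactly.
    """
    used: set[str] = set()
    for group in fusion_map:
        for chrom in group:
            if chrom not in genome:
                raise KeyError(f"fusion map references missing chromosome {chrom}")
            if chrom in used:
                raise ValueError(f"chromosome {chrom} used twice in fusion map")
            used.add(chrom)
    fused: dict[str, np.ndarray] = {}
    rows = []
    for group in fusion_map:
        new_name = "+".join(group)
        pieces = []
        offset = 0
        for i, chrom in enumerate(group):
            arr = as_array(genome[chrom])
            if i > 0:
                pieces.append(np.full(gap_length, GAP_CODE, dtype=np.uint8))
                offset += gap_length
            rows.append(
                {
                    "old_chrom": chrom,
                    "new_chrom": new_name,
                    "offset": offset,
                    "old_length": arr.size,
                }
            )
            pieces.append(arr)
            offset += arr.size
        fused[new_name] = np.concatenate(pieces)
    for chrom in genome:
        if chrom not in used:
            arr = as_array(genome[chrom])
            fused[chrom] = arr
            rows.append(
                {
                    "old_chrom": chrom,
                    "new_chrom": chrom,
                    "offset": 0,
                    "old_length": arr.size,
                }
            )
    liftover = pd.DataFrame(rows, columns=["old_chrom", "new_chrom", "offset", "old_length"])
    return fused, liftover


def liftover_position(liftover: pd.DataFrame, chrom: str, pos: int) -> tuple[str, int]:
    """Map an old (chrom, 0-based pos) to fused coordinates."""
    row = liftover[liftover["old_chrom"] == chrom]
    if row.empty:
        raise KeyError(f"unknown chromosome {chrom}")
    rec = row.iloc[0]
    if not (0 <= pos < rec["old_length"]):
        raise ValueError("position outside chromosome")
    return str(rec["new_chrom"]), int(rec["offset"] + pos)
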