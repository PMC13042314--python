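"""File format helpers: FASTA, FASTQ, PAF, and truth tables.

FASTA/FASTQ go through Biopython's SeqIO; PAF records map onto
:class:`polyphase.align.AnchorAlignment` (0-based half-open coordinates,
as in the format itself).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AnchorAlignment
from .seqs import decode
from .simulate import PolyploidTruth, ReadSet


def _to_str(seq) -> str:
    return decode(np.asarray(seq, dtype=np.uint8)) if not isinstance(seq, str) else seq


def write_fasta(sequences: dict, path: str | Path) -> None:
    records = (
        SeqRecord(Seq(_to_str(s)), id=name, description="") for name, s in sequences.items()
    )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pair(reads: ReadSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write mates as {prefix}_1.fq / {prefix}_2.fq with /1 /2 suffixes."""
    p1, p2 = Path(f"{prefix}_1.fq"), Path(f"{prefix}_2.fq")
    qual = None
    for path, seqs, mate in ((p1, reads.seq1, 1), (p2, reads.seq2, 2)):
        with open(path, "w") as fh:
            for name, seq in zip(reads.names, seqs):
                if qual is None or len(qual) != len(seq):
                    qual = "I" * len(seq)
                fh.write(f"@{name}/{mate}\n{seq}\n+\n{qual}\n")
    return p1, p2


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[tuple[str, str]]:
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    return [(str(a.seq), str(b.seq)) for a, b in zip(it1, it2)]


# ---------------------------------------------------------------------------
# PAF


def write_paf(alignments: list[AnchorAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            block = max(a.q_span, a.t_span)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            a.query_id,
                            a.query_len,
                            a.q_start,
                            a.q_end,
                            a.strand,
                            a.target_id,
                            a.target_len,
                            a.t_start,
                            a.t_end,
                            a.aligned_bases,
                            block,
                            60,
                        ],
                    )
                )
                + "\n"
            )


def read_paf(path: str | Path) -> list[AnchorAlignment]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                AnchorAlignment(
                    query_id=f[0],
                    query_len=int(f[1]),
                    q_start=int(f[2]),
                    q_end=int(f[3]),
                    strand=f[4],
                    target_id=f[5],
                    target_len=int(f[6]),
                    t_start=int(f[7]),
                    t_end=int(f[8]),
                    aligned_bases=int(f[9]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# truth tables


def truth_tables(truth: PolyploidTruth) -> dict[str, pd.DataFrame]:
    """Ground truth as tidy DataFrames (chromosomes, repeats, markers)."""
    chroms = pd.DataFrame(
        [
            {
                "seq_id": r.seq_id,
                "ancestry": r.ancestry,
                "haplotype": r.haplotype,
                "base_chromosome": r.base_index,
                "length": r.length,
            }
            for r in truth.chromosomes
        ]
    )
    repeats = pd.DataFrame(
        [
            {
                "seq_id": seq_id,
                "family": r.family,
                "start": r.start,
                "end": r.end,
                "ltr_length": r.ltr_length,
                "age_myr": r.age_myr,
            }
            for seq_id, recs in truth.repeats_by_seq.items()
            for r in recs
        ]
    )
    markers = pd.DataFrame(
        [
            {"marker_id": mid, "seq_id": p.seq_id, "start": p.start, "length": p.length}
            for mid, places in truth.markers.items()
            for p in places
        ]
    )
    return {"chromosomes": chroms, "repeats": repeats, "markers": markers}
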