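"""Competitive read assignment and subgenome composition inference.

Reads from an accession of unknown ploidy are assigned competitively to
the chromosomes of a phased reference: each pair goes to the single
chromosome sharing the most canonical k-mers with both mates ("top best"
placement). Because reads mainly land in their subgenome of origin, the
per-subgenome share of assigned pairs estimates chromosome dosage, and an
integer chromosome composition (e.g. 12A + 24B = AABBBB for a hexaploid)
is fitted to the observed shares by largest-remainder apportionment.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .kmers import canonical_codes, canonical_codes_batch
from .seqs import as_array
from .simulate import ReadSet


def _chunk_codes(chunk: list[tuple[str, str]], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes + owning pair index for a chunk of pairs.

    Equal-length mates (the common case) take a vectorized 2D path; mixed
    lengths fall back to per-read encoding.
    """
    mates = [m for pair in chunk for m in pair]
    lengths = {len(m) for m in mates}
    if len(lengths) == 1:
        L = lengths.pop()
        mat = (
            np.frombuffer("".join(mates).encode("ascii"), dtype=np.uint8)
            .reshape(len(mates), L)
        )
        from .seqs import _ENCODE

        codes, rows = canonical_codes_batch(_ENCODE[mat], k)
        return codes, rows // 2  # two mates per pair
    parts, owners = [], []
    for i, mate in enumerate(mates):
        c = canonical_codes(as_array(mate), k)
        parts.append(c)
        owners.append(np.full(c.size, i // 2, dtype=np.int64))
    if not parts:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(parts), np.concatenate(owners)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (so 0.005 -> 0.01), matching how printed
    percentage tables are normally rounded."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# competitive assignment


class ChromosomeKmerIndex:
    """Sorted array of distinct (canonical k-mer, chromosome) pairs."""

    def __init__(self, chromosomes: dict, k: int = 21):
        if not chromosomes:
            raise ValueError("empty chromosome index")
        if k % 2 == 0:
            raise ValueError("k must be odd")
        self.k = k
        self.ids = list(chromosomes)
        codes_all = []
        chrom_all = []
        for ci, cid in enumerate(self.ids):
            codes = np.unique(canonical_codes(as_array(chromosomes[cid]), k))
            codes_all.append(codes)
            chrom_all.append(np.full(codes.size, ci, dtype=np.int32))
        codes = np.concatenate(codes_all)
        chrom = np.concatenate(chrom_all)
        order = np.lexsort((chrom, codes))
        self.codes = codes[order]
        self.chrom = chrom[order]

    @property
    def n_chromosomes(self) -> int:
        return len(self.ids)


@dataclass
class AssignmentResult:
    counts: dict[str, int]  # assigned pairs per chromosome
    unassigned: int
    assignments: list[str | None]  # per input pair, chromosome or None

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())


def competitive_assign(
    read_pairs: ReadSet | list[tuple[str, str]],
    chromosomes: dict | ChromosomeKmerIndex,
    k: int = 21,
    min_shared: int = 10,
    tie_policy: str = "random",
    seed: int = 0,
    batch_size: int = 20_000,
) -> AssignmentResult:
    """Assign each read pair to the chromosome sharing the most k-mers.

    Score of a pair against a chromosome = number of canonical k-mer
    positions over both mates whose k-mer occurs in that chromosome. Pairs
    whose top score is below ``min_shared`` are unassigned. Ties for the
    top are broken by a seeded deterministic pseudo-random draw
    (``tie_policy="random"``, the behaviour of a "top best" competitive
    aligner) or discarded (``tie_policy="unassigned"``).
    """
    if tie_policy not in ("random", "unassigned"):
        raise ValueError("tie_policy must be 'random' or 'unassigned'")
    index = (
        chromosomes
        if isinstance(chromosomes, ChromosomeKmerIndex)
        else ChromosomeKmerIndex(chromosomes, k=k)
    )
    if isinstance(read_pairs, ReadSet):
        pairs = list(zip(read_pairs.seq1, read_pairs.seq2))
    else:
        pairs = list(read_pairs)
    n_chrom = index.n_chromosomes
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_chrom, dtype=np.int64)
    assignments: list[str | None] = []
    unassigned = 0

    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        codes, owner = _chunk_codes(chunk, index.k)
        left = np.searchsorted(index.codes, codes, side="left")
        right = np.searchsorted(index.codes, codes, side="right")
        widths = right - left
        total = int(widths.sum())
        scores = np.zeros((len(chunk), n_chrom), dtype=np.int64)
        if total:
            starts = np.repeat(left, widths)
            offs = np.arange(total) - np.repeat(np.cumsum(widths) - widths, widths)
            hit_chrom = index.chrom[starts + offs]
            hit_owner = np.repeat(owner, widths)
            flat = np.bincount(
                hit_owner * n_chrom + hit_chrom, minlength=len(chunk) * n_chrom
            )
            scores = flat.reshape(len(chunk), n_chrom)
        top = scores.max(axis=1)
        is_top = scores == top[:, None]
        n_top = is_top.sum(axis=1)
        ok = top >= min_shared
        if tie_policy == "unassigned":
            ok &= n_top == 1
            choice = scores.argmax(axis=1)
        else:
            # deterministic seeded draw among the tied top chromosomes
            noise = rng.random(scores.shape)
            choice = np.where(is_top, noise, -1.0).argmax(axis=1)
        np.add.at(counts, choice[ok], 1)
        unassigned += int((~ok).sum())
        assignments.extend(
            index.ids[c] if good else None for c, good in zip(choice.tolist(), ok.tolist())
        )
    return AssignmentResult(
        counts={cid: int(c) for cid, c in zip(index.ids, counts) if c > 0},
        unassigned=unassigned,
        assignments=assignments,
    )


# ---------------------------------------------------------------------------
# proportion tables


def coverage_table(
    read_counts: dict[str, int],
    subgenome_map: dict[str, str],
    decimals: int = 2,
) -> pd.DataFrame:
    """Percent of assigned pairs per subgenome (half-up rounding).

    ``read_counts`` is keyed by chromosome (or directly by subgenome when a
    pre-aggregated table is supplied, with an identity map).
    """
    agg: dict[str, int] = {sg: 0 for sg in subgenome_map.values()}
    for cid, n in read_counts.items():
        if cid not in subgenome_map:
            raise KeyError(f"chromosome {cid} missing from subgenome map")
        sg = subgenome_map[cid]
        agg[sg] += int(n)
    total = sum(agg.values())
    if total == 0:
        raise ValueError("no assigned reads")
    rows = [
        {
            "subgenome": sg,
            "reads": agg[sg],
            "percent": round_half_up(100.0 * agg[sg] / total, decimals),
        }
        for sg in sorted(agg)
    ]
    return pd.DataFrame(rows)


def expected_proportions(
    counts: dict[str, int],
    lengths: dict[str, float] | None = None,
    decimals: int = 0,
) -> dict[str, float]:
    """Length-weighted expected read share per subgenome (percent).

    ``counts`` maps subgenome -> chromosome count; ``lengths`` optionally
    maps subgenome -> mean chromosome length (equal lengths when omitted,
    so shares reduce to count/N). Half-up rounded to ``decimals``.
    """
    if any(c < 0 for c in counts.values()) or sum(counts.values()) == 0:
        raise ValueError("counts must be >= 0 and not all zero")
    weights = {
        sg: counts[sg] * (lengths[sg] if lengths else 1.0) for sg in counts
    }
    total = sum(weights.values())
    return {
        sg: round_half_up(100.0 * w / total, decimals) for sg, w in weights.items()
    }


# ---------------------------------------------------------------------------
# integer composition inference


@dataclass
class CompositionEstimate:
    observed_percent: dict[str, float]
    n_chromosomes: int
    counts: dict[str, int]
    residual: float  # L2 distance in percent units
    formula: str
    ratio: str


def largest_remainder(fractions: np.ndarray, n: int) -> np.ndarray:
    """Integer apportionment of ``n`` units proportional to fractions."""
    quota = fractions / fractions.sum() * n
    base = np.floor(quota).astype(int)
    remainder = quota - base
    short = n - int(base.sum())
    if short > 0:
        for i in np.argsort(-remainder)[:short]:
            base[i] += 1
    return base


def _residual(counts: np.ndarray, observed: np.ndarray, n: int) -> float:
    return float(np.linalg.norm(100.0 * counts / n - observed))


def infer_composition(
    observed: dict[str, float],
    N: int,
    base_number: int = 6,
) -> CompositionEstimate:
    """Fit integer chromosome counts summing to N to observed percentages.

    Largest-remainder apportionment, verified L2-optimal by +-1 local
    search between every pair of subgenomes.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    labels = sorted(observed)
    obs = np.array([observed[sg] for sg in labels], dtype=float)
    if not (99.0 <= obs.sum() <= 101.0):
        raise ValueError("observed percentages must sum to 100 +- 1")
    counts = largest_remainder(obs, N)
    improved = True
    while improved:
        improved = False
        best = _residual(counts, obs, N)
        for i in range(len(labels)):
            for j in range(len(labels)):
                if i == j or counts[j] == 0:
                    continue
                trial = counts.copy()
                trial[i] += 1
                trial[j] -= 1
                r = _residual(trial, obs, N)
                if r < best - 1e-12:
                    counts, best, improved = trial, r, True
    count_map = dict(zip(labels, counts.tolist()))
    formula, ratio = format_formula(count_map, base_number)
    return CompositionEstimate(
        observed_percent=dict(observed),
        n_chromosomes=N,
        counts=count_map,
        residual=_residual(counts, obs, N),
        formula=formula,
        ratio=ratio,
    )


def _trim(x: float) -> str:
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def format_formula(counts: dict[str, int], base_number: int = 6) -> tuple[str, str]:
    """Genomic formula and ratio strings for integer subgenome counts.

    Every count divisible by the base number -> letter-run formula (e.g.
    12A+24B with x=6 -> "AABBBB"); otherwise aneuploid notation
    ("14A 22B 12C"). The ratio divides by the smallest nonzero count
    ("1A:2B"), trimming trailing zeros at two decimals.
    """
    labels = sorted(counts)
    values = [counts[sg] for sg in labels]
    if any(v < 0 for v in values):
        raise ValueError("counts must be >= 0")
    if sum(values) == 0:
        raise ValueError("all-zero composition")
    if all(v % base_number == 0 for v in values):
        formula = "".join(sg * (v // base_number) for sg, v in zip(labels, values))
    else:
        formula = " ".join(f"{v}{sg}" for sg, v in zip(labels, values) if v > 0)
    smallest = min(v for v in values if v > 0)
    ratio = ":".join(
        f"{_trim(v / smallest)}{sg}" for sg, v in zip(labels, values) if v > 0
    )
    return formula, ratio


def composition_from_reads(
    read_counts: dict[str, int],
    subgenome_map: dict[str, str],
    N: int,
    base_number: int = 6,
) -> CompositionEstimate:
    """Chromosome-level read counts -> composition call in one step."""
    table = coverage_table(read_counts, subgenome_map)
    observed = dict(zip(table["subgenome"], table["percent"]))
    return infer_composition(observed, N, base_number=base_number)
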