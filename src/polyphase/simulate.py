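"""Synthetic polyploid genome generator with full ground truth.

Emulates the data structure of a complex allopolyploid forage-grass genome:
three ancestral lineages (A and B recently diverged, C distant), base
chromosome number x = 6, per-base-chromosome copy counts such as 2A/4B/2C
(AABBBBCC) or 3A/3B/2C (AAABBBCC), subgenome-specific LTR retrotransposon
families with an age structure, contig fragmentation, paired reads at known
subgenome dosage, and planted single-copy markers (one copy per haplotype
chromosome, the analogue of single-copy BUSCO genes).

Every emitted object carries ground truth (:class:`PolyploidTruth`) so each
downstream stage — k-mer phasing, ploidy estimation, scaffolding, read
composition, LTR dating — can be validated without any real assembly.

Divergence model
----------------
Substitutions are i.i.d. per site with a uniform choice among the three
alternative bases; indels are off by default. That kernel composes
multiplicatively in q = 1 - (4/3) p, so requested pairwise divergences are
realized exactly in expectation by solving per-ancestry branch
probabilities on a star tree (:func:`solve_branch_probs`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .scaffold import AgpComponent, AgpGap, AgpPlan
from .seqs import decode, mutate, p_distance, random_seq

MAX_DIVERGENCE = 0.75  # Jukes-Cantor saturation

#: default substitution rate, substitutions/site/year (typical grass rate)
DEFAULT_MU = 1.3e-8


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class AncestryModel:
    """Ancestral lineages and their pairwise divergences.

    ``divergence`` maps unordered ancestry pairs to expected p-distance
    (substitution proportion per site). The default emulates two recently
    diverged lineages plus a distant one (A-B 3%, A-C = B-C 12%).
    """

    ancestries: tuple[str, ...] = ("A", "B", "C")
    n_base_chromosomes: int = 6
    base_lengths: tuple[int, ...] | None = None
    divergence: dict[tuple[str, str], float] = field(default_factory=dict)
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_base_chromosomes < 1:
            raise ValueError("need at least one base chromosome")
        if self.base_lengths is None:
            self.base_lengths = tuple([100_000] * self.n_base_chromosomes)
        self.base_lengths = tuple(self.base_lengths)
        if len(self.base_lengths) != self.n_base_chromosomes:
            raise ValueError("base_lengths must match n_base_chromosomes")
        if any(length < 10_000 for length in self.base_lengths):
            raise ValueError("base chromosomes must be >= 10 kb")
        # normalize keys to sorted pairs, enforce symmetry and range
        norm: dict[tuple[str, str], float] = {}
        for (a, b), d in self.divergence.items():
            key = _pair(a, b)
            if key in norm and not np.isclose(norm[key], d):
                raise ValueError(f"divergence map not symmetric for {key}")
            if not (0.0 <= d < MAX_DIVERGENCE):
                raise ValueError(
                    f"divergence {d} for {key} outside [0, {MAX_DIVERGENCE}) (saturation)"
                )
            norm[key] = float(d)
        for a, b in itertools.combinations(self.ancestries, 2):
            norm.setdefault(_pair(a, b), 0.0)
        self.divergence = norm
        if not (0.0 <= self.indel_rate < 0.1):
            raise ValueError("indel_rate must be a small proportion")

    def pairwise(self, a: str, b: str) -> float:
        return self.divergence[_pair(a, b)]


def default_model(
    seed: int = 0,
    length: int = 100_000,
    n_base_chromosomes: int = 6,
    d_ab: float = 0.03,
    d_c: float = 0.12,
) -> AncestryModel:
    """Default three-ancestry fixture model (A-B close, C distant)."""
    return AncestryModel(
        ancestries=("A", "B", "C"),
        n_base_chromosomes=n_base_chromosomes,
        base_lengths=tuple([length] * n_base_chromosomes),
        divergence={("A", "B"): d_ab, ("A", "C"): d_c, ("B", "C"): d_c},
        seed=seed,
    )


def solve_branch_probs(
    ancestries: tuple[str, ...], divergence: dict[tuple[str, str], float]
) -> dict[str, float]:
    """Per-ancestry substitution probabilities on a star tree.

    Solves ln q_a + ln q_b = ln(1 - 4 d_ab / 3) in least squares, where
    q = 1 - (4/3) b; composing two branch kernels then yields pairwise
    p-distance d_ab exactly in expectation. Raises if the divergence map
    is infeasible on a star tree (an implied branch would be negative).
    """
    n = len(ancestries)
    if n == 1:
        return {ancestries[0]: 0.0}
    pairs = list(itertools.combinations(range(n), 2))
    rows = np.zeros((len(pairs), n))
    rhs = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        rows[r, i] = rows[r, j] = 1.0
        d = divergence[_pair(ancestries[i], ancestries[j])]
        rhs[r] = np.log1p(-4.0 * d / 3.0)
    logq, *_ = np.linalg.lstsq(rows, rhs, rcond=None)
    if np.any(logq > 1e-9):
        raise ValueError("divergence map infeasible on a star tree (negative branch)")
    logq = np.minimum(logq, 0.0)
    b = (1.0 - np.exp(logq)) * 3.0 / 4.0
    return dict(zip(ancestries, b.tolist()))


def _apply_indels(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Small (1-3 bp) insertions/deletions at the given per-site event rate."""
    if rate <= 0:
        return arr
    n_events = rng.poisson(rate * arr.size)
    if n_events == 0:
        return arr
    pieces: list[np.ndarray] = []
    positions = np.sort(rng.integers(0, arr.size, size=n_events))
    prev = 0
    for pos in positions:
        pieces.append(arr[prev:pos])
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # insertion
            pieces.append(random_seq(size, rng))
            prev = pos
        else:  # deletion
            prev = min(arr.size, pos + size)
    pieces.append(arr[prev:])
    return np.concatenate(pieces)


def simulate_ancestral_genomes(model: AncestryModel) -> dict[str, list[np.ndarray]]:
    """One base-chromosome set per ancestry, at the requested divergences.

    Returns ``{ancestry: [chrom_1, ..., chrom_x]}`` (2-bit arrays).
    Deterministic given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    branch = solve_branch_probs(model.ancestries, model.divergence)
    roots = [random_seq(length, rng) for length in model.base_lengths]
    genomes: dict[str, list[np.ndarray]] = {}
    for anc in model.ancestries:
        seqs = []
        for root in roots:
            s = mutate(root, branch[anc], rng)
            s = _apply_indels(s, model.indel_rate, rng)
            seqs.append(s)
        genomes[anc] = seqs
    return genomes


# ---------------------------------------------------------------------------
# repeat families


@dataclass
class RepeatFamilySpec:
    """An LTR retrotransposon family and the lineage it amplified in.

    ``ancestry`` may be one lineage, a tuple of lineages, or ``None``
    (amplifies everywhere). Ages are
    drawn per copy from a truncated normal (Myr); both LTRs of a copy are
    identical at insertion and then mutated independently at ``mu``
    substitutions/site/year, so the expected LTR pair divergence of a copy
    of age T is ~ 2 mu T.
    """

    name: str
    ancestry: str | tuple[str, ...] | None
    element_length: int = 5000
    ltr_length: int = 500
    copies_per_chromosome: int = 10
    age_mean_myr: float = 1.0
    age_sd_myr: float = 0.2
    mu: float = DEFAULT_MU

    def __post_init__(self) -> None:
        if self.ltr_length * 2 >= self.element_length:
            raise ValueError("two LTRs must fit inside the element")
        if self.copies_per_chromosome < 0:
            raise ValueError("copies must be >= 0")
        if self.mu <= 0:
            raise ValueError("mu must be positive")

    def amplifies_in(self, ancestry: str) -> bool:
        if self.ancestry is None:
            return True
        if isinstance(self.ancestry, str):
            return self.ancestry == ancestry
        return ancestry in self.ancestry


@dataclass
class RepeatInsertion:
    """Ground-truth record of one inserted element (current coordinates)."""

    ancestry: str
    base_index: int  # 1-based
    start: int  # 0-based, in the post-insertion ancestral sequence
    length: int
    ltr_length: int
    family: str
    age_myr: float
    ltr5: str
    ltr3: str

    @property
    def end(self) -> int:
        return self.start + self.length


def insert_repeats(
    genomes: dict[str, list[np.ndarray]],
    families: list[RepeatFamilySpec],
    seed: int = 0,
) -> tuple[dict[str, list[np.ndarray]], list[RepeatInsertion]]:
    """Insert repeat-family copies into ancestral chromosomes.

    Each copy descends from a per-family master element: internal region and
    both LTRs mutated by mu * age (LTRs independently, so their divergence
    dates the copy). Returns new genomes plus truth insertion records in
    the coordinates of the returned sequences.
    """
    rng = np.random.default_rng(seed)
    masters = {}
    for fam in families:
        internal = random_seq(fam.element_length - 2 * fam.ltr_length, rng)
        ltr = random_seq(fam.ltr_length, rng)
        masters[fam.name] = (ltr, internal)

    out: dict[str, list[np.ndarray]] = {}
    insertions: list[RepeatInsertion] = []
    for anc, seqs in genomes.items():
        new_seqs = []
        for ci, seq in enumerate(seqs):
            events: list[tuple[int, RepeatFamilySpec, float]] = []
            for fam in families:
                if not fam.amplifies_in(anc):
                    continue
                if fam.element_length > seq.size:
                    raise ValueError(
                        f"element of family {fam.name} longer than chromosome"
                    )
                ages = np.maximum(
                    0.0, rng.normal(fam.age_mean_myr, fam.age_sd_myr, fam.copies_per_chromosome)
                )
                pos = rng.integers(0, seq.size + 1, size=fam.copies_per_chromosome)
                events.extend((int(p), fam, float(t)) for p, t in zip(pos, ages))
            if not events:
                new_seqs.append(seq)
                continue
            events.sort(key=lambda e: e[0])
            pieces: list[np.ndarray] = []
            prev = 0
            offset = 0
            for pos, fam, age in events:
                ltr_m, internal_m = masters[fam.name]
                b = fam.mu * age * 1e6
                ltr5 = mutate(ltr_m, b, rng)
                ltr3 = mutate(ltr_m, b, rng)
                body = mutate(internal_m, b, rng)
                element = np.concatenate([ltr5, body, ltr3])
                pieces.append(seq[prev:pos])
                pieces.append(element)
                insertions.append(
                    RepeatInsertion(
                        ancestry=anc,
                        base_index=ci + 1,
                        start=pos + offset,
                        length=element.size,
                        ltr_length=fam.ltr_length,
                        family=fam.name,
                        age_myr=age,
                        ltr5=decode(ltr5),
                        ltr3=decode(ltr3),
                    )
                )
                offset += element.size
                prev = pos
            pieces.append(seq[prev:])
            new_seqs.append(np.concatenate(pieces))
        out[anc] = new_seqs
    return out, insertions


# ---------------------------------------------------------------------------
# polyploid composition


@dataclass
class PolyploidSpec:
    """Copy counts per base chromosome and ancestry.

    ``per_chromosome_copies`` maps 1-based base-chromosome index to
    ``{ancestry: copies}``.
    """

    per_chromosome_copies: dict[int, dict[str, int]]

    def __post_init__(self) -> None:
        for base, copies in self.per_chromosome_copies.items():
            for anc, c in copies.items():
                if c < 0:
                    raise ValueError(f"negative copy count for chr{base}{anc}")

    @property
    def totals(self) -> dict[str, int]:
        tot: dict[str, int] = {}
        for copies in self.per_chromosome_copies.values():
            for anc, c in copies.items():
                tot[anc] = tot.get(anc, 0) + c
        return tot

    @property
    def n_chromosomes(self) -> int:
        return sum(self.totals.values())


def tully_spec() -> PolyploidSpec:
    """The aneuploid octoploid fixture: AABBBBCC for base chromosomes 1-4
    and AAABBBCC for 5-6, totalling 14A + 22B + 12C = 48 chromosomes."""
    copies = {i: {"A": 2, "B": 4, "C": 2} for i in range(1, 5)}
    copies.update({i: {"A": 3, "B": 3, "C": 2} for i in range(5, 7)})
    return PolyploidSpec(per_chromosome_copies=copies)


def hexaploid_ab_spec() -> PolyploidSpec:
    """The common C-free hexaploid: AABBBB (12A + 24B = 36 chromosomes)."""
    return PolyploidSpec(
        per_chromosome_copies={i: {"A": 2, "B": 4} for i in range(1, 7)}
    )


@dataclass
class ChromosomeRecord:
    seq_id: str
    ancestry: str
    haplotype: int  # 1-based
    base_index: int  # 1-based
    length: int


@dataclass
class MarkerPlacement:
    seq_id: str
    start: int
    length: int


@dataclass
class PolyploidTruth:
    """Ground truth for every simulated object."""

    chromosomes: list[ChromosomeRecord] = field(default_factory=list)
    repeats: list[RepeatInsertion] = field(default_factory=list)
    repeats_by_seq: dict[str, list[RepeatInsertion]] = field(default_factory=dict)
    markers: dict[str, list[MarkerPlacement]] = field(default_factory=dict)

    def ancestry_map(self) -> dict[str, str]:
        """chromosome id -> true ancestry label (A/B/C)."""
        return {rec.seq_id: rec.ancestry for rec in self.chromosomes}

    def marker_copy_number(self, marker_id: str) -> int:
        return len(self.markers[marker_id])


def compose_polyploid(
    genomes: dict[str, list[np.ndarray]],
    spec: PolyploidSpec,
    haplotype_divergence: float = 0.005,
    seed: int = 0,
    insertions: list[RepeatInsertion] | None = None,
) -> tuple[dict[str, np.ndarray], PolyploidTruth]:
    """Emit one sequence per haplotype copy, named ``chr{base}{anc}{hap}``.

    Each copy is the ancestral chromosome mutated with per-site probability
    ``haplotype_divergence / 2`` (so two copies of the same ancestral
    chromosome differ by ~``haplotype_divergence``). Substitution-only, so
    repeat-insertion coordinates carry over to every copy unchanged.
    """
    rng = np.random.default_rng(seed)
    b = haplotype_divergence / 2.0
    ins_by_chrom: dict[tuple[str, int], list[RepeatInsertion]] = {}
    for ins in insertions or []:
        ins_by_chrom.setdefault((ins.ancestry, ins.base_index), []).append(ins)

    polyploid: dict[str, np.ndarray] = {}
    truth = PolyploidTruth()
    for base in sorted(spec.per_chromosome_copies):
        copies = spec.per_chromosome_copies[base]
        for anc in sorted(copies):
            if copies[anc] == 0:
                continue
            if anc not in genomes or base > len(genomes[anc]):
                raise ValueError(f"no ancestral sequence for chr{base}{anc}")
            ancestral = genomes[anc][base - 1]
            for hap in range(1, copies[anc] + 1):
                seq_id = f"chr{base}{anc}{hap}"
                seq = mutate(ancestral, b, rng)
                polyploid[seq_id] = seq
                truth.chromosomes.append(
                    ChromosomeRecord(seq_id, anc, hap, base, seq.size)
                )
                per_seq = []
                for ins in ins_by_chrom.get((anc, base), []):
                    rec = RepeatInsertion(
                        ancestry=anc,
                        base_index=base,
                        start=ins.start,
                        length=ins.length,
                        ltr_length=ins.ltr_length,
                        family=ins.family,
                        age_myr=ins.age_myr,
                        ltr5=decode(seq[ins.start : ins.start + ins.ltr_length]),
                        ltr3=decode(seq[ins.end - ins.ltr_length : ins.end]),
                    )
                    truth.repeats.append(rec)
                    per_seq.append(rec)
                if per_seq:
                    truth.repeats_by_seq[seq_id] = per_seq
    if len(polyploid) != spec.n_chromosomes:
        raise AssertionError("emitted sequence count != spec total")
    return polyploid, truth


# ---------------------------------------------------------------------------
# contigs, reads, markers


def fragment_to_contigs(
    polyploid: dict[str, np.ndarray],
    mean_contig_length: int,
    length_dispersion: float = 0.3,
    seed: int = 0,
    min_length: int | None = None,
) -> tuple[dict[str, np.ndarray], AgpPlan]:
    """Cut each chromosome into contigs that partition it exactly.

    Contig lengths are gamma-distributed around the mean; fragments shorter
    than ``min_length`` (default mean/4) are merged into their neighbour.
    Returns contigs plus the true AGP plan (gapless, reconstructs each
    chromosome exactly).
    """
    rng = np.random.default_rng(seed)
    if min_length is None:
        min_length = max(1000, mean_contig_length // 4)
    disp = max(length_dispersion, 1e-3)
    shape = 1.0 / disp**2
    scale = mean_contig_length * disp**2
    contigs: dict[str, np.ndarray] = {}
    plan = AgpPlan()
    for chrom, seq in polyploid.items():
        if mean_contig_length >= seq.size:
            cuts = [seq.size]
        else:
            cuts = []
            total = 0
            while total < seq.size:
                ln = max(min_length, int(rng.gamma(shape, scale)))
                total += ln
                cuts.append(min(total, seq.size))
            if len(cuts) > 1 and cuts[-1] - cuts[-2] < min_length:
                cuts.pop(-2)  # merge the short tail into its neighbour
        prev = 0
        components = []
        for i, cut in enumerate(cuts):
            cid = f"{chrom}_ctg{i + 1:03d}"
            contigs[cid] = seq[prev:cut]
            components.append(
                AgpComponent(contig_id=cid, orientation="+", comp_beg=1, comp_end=cut - prev)
            )
            prev = cut
        plan.objects[chrom] = components
    return contigs, plan


@dataclass
class ReadSet:
    """Paired reads with per-pair source-chromosome truth labels."""

    names: list[str]
    seq1: list[str]
    seq2: list[str]
    source: list[str]

    def __len__(self) -> int:
        return len(self.names)

    def source_fractions(self, group_of: dict[str, str]) -> dict[str, float]:
        """True per-group read fractions (e.g. group = subgenome)."""
        counts: dict[str, int] = {}
        for src in self.source:
            g = group_of[src]
            counts[g] = counts.get(g, 0) + 1
        total = len(self.source)
        return {g: c / total for g, c in counts.items()}


def simulate_reads(
    polyploid: dict[str, np.ndarray],
    coverage_per_copy: float = 20.0,
    read_length: int = 150,
    insert_mean: int = 350,
    insert_sd: float = 35.0,
    error_rate: float = 0.002,
    seed: int = 0,
) -> ReadSet:
    """Paired-end reads at uniform depth per chromosome copy.

    Expected pair count per chromosome is length * coverage / (2 * read
    length), so read dosage is proportional to chromosome copy presence.
    Fragments are sampled FR; which physical strand is mate 1 is random.
    """
    if coverage_per_copy <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    names: list[str] = []
    r1: list[str] = []
    r2: list[str] = []
    src: list[str] = []
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, seq in polyploid.items():
        length = seq.size
        if not (read_length < insert_mean < length):
            raise ValueError("need read_length < insert_mean < chromosome length")
        n_pairs = int(round(length * coverage_per_copy / (2 * read_length)))
        if n_pairs == 0:
            continue
        isize = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, n_pairs)).astype(np.int64),
            read_length,
            length,
        )
        start = (rng.random(n_pairs) * (length - isize + 1)).astype(np.int64)
        idx1 = start[:, None] + np.arange(read_length)
        idx2 = (start + isize - read_length)[:, None] + np.arange(read_length)
        fwd = seq[idx1]
        rev = (3 - seq[idx2])[:, ::-1]
        if error_rate > 0:
            for mat in (fwd, rev):
                mask = rng.random(mat.shape) < error_rate
                n = int(mask.sum())
                if n:
                    mat[mask] = (mat[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
        swap = rng.random(n_pairs) < 0.5
        b1 = lut[fwd].tobytes()
        b2 = lut[rev].tobytes()
        for i in range(n_pairs):
            a = b1[i * read_length : (i + 1) * read_length].decode()
            b = b2[i * read_length : (i + 1) * read_length].decode()
            if swap[i]:
                a, b = b, a
            names.append(f"{chrom}_{i + 1:07d}")
            r1.append(a)
            r2.append(b)
            src.append(chrom)
    return ReadSet(names=names, seq1=r1, seq2=r2, source=src)


def plant_markers(
    polyploid: dict[str, np.ndarray],
    truth: PolyploidTruth,
    n_markers: int = 20,
    marker_length: int = 500,
    haplotype_divergence: float = 0.005,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Plant single-copy markers, one copy per haplotype chromosome.

    Marker ``i`` is homed on base chromosome ``(i mod x) + 1`` and written
    (window overwrite, so coordinates stay put) once onto every haplotype
    copy of that base chromosome, with haplotype-level mutations. Placement
    avoids repeat-element intervals and other markers. Truth copy number of
    a marker therefore equals the spec copy count of its home base
    chromosome. Returns the modified genome and the marker sequences.
    """
    rng = np.random.default_rng(seed)
    out = {cid: seq.copy() for cid, seq in polyploid.items()}
    by_base: dict[int, list[ChromosomeRecord]] = {}
    for rec in truth.chromosomes:
        by_base.setdefault(rec.base_index, []).append(rec)
    occupied: dict[str, list[tuple[int, int]]] = {
        cid: [(r.start, r.end) for r in truth.repeats_by_seq.get(cid, [])]
        for cid in out
    }
    bases = sorted(by_base)
    markers: dict[str, str] = {}
    b = haplotype_divergence / 2.0
    for i in range(n_markers):
        home = bases[i % len(bases)]
        mid = f"marker{i + 1:04d}"
        master = random_seq(marker_length, rng)
        markers[mid] = decode(master)
        placements = []
        for rec in by_base[home]:
            seq = out[rec.seq_id]
            for _ in range(1000):
                pos = int(rng.integers(0, seq.size - marker_length + 1))
                if all(
                    pos + marker_length <= s or pos >= e
                    for s, e in occupied[rec.seq_id]
                ):
                    break
            else:  # pragma: no cover - fixture misconfiguration
                raise RuntimeError(f"no free window for {mid} on {rec.seq_id}")
            seq[pos : pos + marker_length] = mutate(master, b, rng)
            occupied[rec.seq_id].append((pos, pos + marker_length))
            placements.append(MarkerPlacement(rec.seq_id, pos, marker_length))
        truth.markers[mid] = placements
    return out, markers


def make_tully_fixture(
    seed: int = 0,
    length: int = 100_000,
    families: list[RepeatFamilySpec] | None | bool = True,
    haplotype_divergence: float = 0.005,
    d_ab: float = 0.03,
    d_c: float = 0.12,
    spec: PolyploidSpec | None = None,
) -> tuple[dict[str, np.ndarray], PolyploidTruth]:
    """Convenience builder for the default 48-chromosome fixture genome.

    Subgenome-specific repeat families are part of the default fixture
    (``families=True`` scales copy numbers to the chromosome length):
    they are what ties different base chromosomes of the same ancestry
    together, the signal subgenome phasing rests on in real polyploids.
    Pass ``families=False``/``None`` for a repeat-free genome, or
    ``spec=`` for a different composition (e.g. ``hexaploid_ab_spec()``).
    """
    model = default_model(seed=seed, length=length, d_ab=d_ab, d_c=d_c)
    genomes = simulate_ancestral_genomes(model)
    if families is True:
        families = default_repeat_families(copies=max(3, length // 20_000))
    insertions = None
    if families:
        genomes, insertions = insert_repeats(genomes, families, seed=seed + 1)
    return compose_polyploid(
        genomes,
        spec if spec is not None else tully_spec(),
        haplotype_divergence=haplotype_divergence,
        seed=seed + 2,
        insertions=insertions,
    )


def default_repeat_families(copies: int = 10, mu: float = DEFAULT_MU) -> list[RepeatFamilySpec]:
    """Subgenome-specific LTR families with the fixture's age structure:
    young shared bursts in A and B, an older independent history in C."""
    return [
        RepeatFamilySpec("gypsy_A", "A", 4000, 400, copies, 1.0, 0.2, mu),
        RepeatFamilySpec("gypsy_B", "B", 4000, 400, copies, 1.0, 0.2, mu),
        RepeatFamilySpec("copia_AB", ("A", "B"), 3000, 300, copies // 2, 0.8, 0.2, mu),
        RepeatFamilySpec("gypsy_C", "C", 4000, 400, copies, 3.0, 0.5, mu),
    ]
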