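"""Canonical k-mer counting.

k-mers are packed into int64 codes (2 bits per base, 5' base in the high
bits), and the canonical form of a k-mer is the lexicographic minimum of
the k-mer and its reverse complement — well defined for odd k, where a
k-mer is never its own reverse complement. Windows containing ambiguous
bases are skipped. Counts are stored raw (occurrences) in a sparse
chromosome x k-mer matrix together with sequence lengths, so both raw and
per-Mb normalized views are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .seqs import encode

MAX_K = 31


def kmer_to_str(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _forward_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed codes of all length-k windows plus a validity mask."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    valid = arr < 4
    safe = np.where(valid, arr, 0).astype(np.int64)
    code = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        code = (code << 2) | safe[j : j + n]
        ok &= valid[j : j + n]
    return code, ok


def canonical_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer codes of every valid window of ``arr``.

    Invalid windows (containing non-ACGT) are dropped; the result is
    positional order with those windows removed.
    """
    if k < 1 or k > MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}]")
    fwd, ok = _forward_codes(arr, k)
    comp = np.where(arr < 4, 3 - arr, arr).astype(np.uint8)
    rc_all, _ = _forward_codes(comp[::-1], k)
    rc = rc_all[::-1]  # rc[i] = code of revcomp(window starting at i)
    canon = np.minimum(fwd, rc)
    return canon[ok]


def canonical_codes_str(seq: str, k: int) -> np.ndarray:
    return canonical_codes(encode(seq), k)


def canonical_codes_batch(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes for a batch of equal-length sequences.

    ``mat`` is (n_seqs, L) uint8. Returns (codes, row) flat arrays covering
    every valid window of every row — the fast path for read batches.
    """
    n, L = mat.shape
    w = L - k + 1
    if w <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    valid = mat < 4
    safe = np.where(valid, mat, 0).astype(np.int64)
    fwd = np.zeros((n, w), dtype=np.int64)
    ok = np.ones((n, w), dtype=bool)
    comp = np.where(valid, 3 - mat, mat).astype(np.int64)[:, ::-1]
    rc = np.zeros((n, w), dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | safe[:, j : j + w]
        rc = (rc << 2) | comp[:, j : j + w]
        ok &= valid[:, j : j + w]
    rc = rc[:, ::-1]
    canon = np.minimum(fwd, rc)
    rows = np.broadcast_to(np.arange(n)[:, None], (n, w))
    flat_ok = ok.ravel()
    return canon.ravel()[flat_ok], rows.ravel()[flat_ok]


@dataclass
class KmerMatrix:
    """Chromosome x canonical-k-mer count matrix.

    ``counts`` holds raw occurrence counts (CSR, one row per chromosome,
    columns ordered by ``kmer_codes``); ``per_mb()`` returns the
    length-normalized view (occurrences per megabase) used by the
    differential-k-mer machinery.
    """

    ids: list[str]
    k: int
    kmer_codes: np.ndarray
    counts: sparse.csr_matrix
    lengths: np.ndarray = field(repr=False)

    @property
    def n_chromosomes(self) -> int:
        return len(self.ids)

    @property
    def n_kmers(self) -> int:
        return self.kmer_codes.size

    def per_mb(self) -> sparse.csr_matrix:
        scale = 1e6 / self.lengths.astype(float)
        return sparse.diags(scale) @ self.counts

    def row(self, chrom: str) -> np.ndarray:
        i = self.ids.index(chrom)
        return np.asarray(self.counts[i].todense()).ravel()


def count_kmers(sequences: dict[str, str] | dict[str, np.ndarray], k: int = 15) -> KmerMatrix:
    """Count canonical k-mers per chromosome.

    Accepts plain strings or pre-encoded uint8 arrays. k must be odd
    (canonicalization is only unambiguous for odd k) and at most 31;
    genome-scale phasing normally uses k in [11, 31].
    """
    if not sequences:
        raise ValueError("empty sequence set")
    if k % 2 == 0 or not (1 <= k <= MAX_K):
        raise ValueError("k must be odd and in [1, 31]")
    ids = list(sequences)
    per_chrom: list[tuple[np.ndarray, np.ndarray]] = []
    lengths = np.zeros(len(ids), dtype=np.int64)
    for i, cid in enumerate(ids):
        s = sequences[cid]
        arr = encode(s) if isinstance(s, str) else s
        lengths[i] = arr.size
        codes = canonical_codes(arr, k)
        uniq, cnt = np.unique(codes, return_counts=True)
        per_chrom.append((uniq, cnt.astype(np.int64)))
    all_codes = np.unique(np.concatenate([u for u, _ in per_chrom]))
    indptr = np.zeros(len(ids) + 1, dtype=np.int64)
    indices = []
    data = []
    for i, (uniq, cnt) in enumerate(per_chrom):
        cols = np.searchsorted(all_codes, uniq)
        indices.append(cols)
        data.append(cnt)
        indptr[i + 1] = indptr[i] + uniq.size
    mat = sparse.csr_matrix(
        (np.concatenate(data), np.concatenate(indices), indptr),
        shape=(len(ids), all_codes.size),
    )
    return KmerMatrix(ids=ids, k=k, kmer_codes=all_codes, counts=mat, lengths=lengths)
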