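"""Low-level nucleotide sequence utilities.

Sequences are handled internally as numpy uint8 arrays with the 2-bit
encoding A=0, C=1, G=2, T=3; any other letter (N, IUPAC ambiguity codes)
is stored as 255 and excluded from k-mer windows. The substitution kernel
used throughout the simulator mutates each site independently with
probability ``b`` and, when a site mutates, replaces the base with one of
the three alternatives chosen uniformly. Two such kernels compose
multiplicatively in the ``q = 1 - (4/3) p`` parameterization, which is what
lets the generator hit requested pairwise divergences exactly in
expectation (see :func:`polyphase.simulate.solve_branch_probs`).
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[ord(chr(_b).lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 array (A=0..T=3, other=255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(arr: np.ndarray) -> str:
    """Decode a 2-bit array back to an upper-case string (255 -> N)."""
    out = np.where(arr < 4, _DECODE[np.minimum(arr, 3)], np.uint8(ord("N")))
    return out.astype(np.uint8).tobytes().decode("ascii")


def as_array(seq) -> np.ndarray:
    """Coerce a str or pre-encoded array to the 2-bit representation."""
    return encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)


def random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random 2-bit sequence of the given length."""
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement in 2-bit space (ambiguous sites stay 255)."""
    out = np.where(arr < 4, 3 - arr, arr).astype(np.uint8)
    return out[::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def mutate(arr: np.ndarray, b: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``b``.

    A mutated site is replaced by one of the other three bases, uniformly.
    Returns a new array; ambiguous (255) sites are left untouched.
    """
    if b < 0:
        raise ValueError("substitution probability must be >= 0")
    out = arr.copy()
    if b == 0:
        return out
    mask = (rng.random(arr.size) < b) & (arr < 4)
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n, dtype=np.uint8)
        out[mask] = (out[mask] + shift) % 4
    return out


def p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Proportion of mismatched sites between two equal-length arrays."""
    if a.size != b.size:
        raise ValueError("p_distance requires equal-length sequences")
    if a.size == 0:
        raise ValueError("empty sequences")
    ok = (a < 4) & (b < 4)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable (unambiguous) sites")
    return float(np.count_nonzero(a[ok] != b[ok])) / n
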