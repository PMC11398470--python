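"""Low-level nucleotide codecs shared across the pipeline.

Sequences travel through the pipeline in two representations:

* ASCII byte arrays (``uint8``, shape ``(n, L)``) for slicing, anchor
  matching and per-base error injection;
* packed 2-bit codes (``uint64``, one integer per sequence, ``L <= 32``)
  for hashing, grouping and fast Hamming distance.

Packing is big-endian in sequence order with A=0, C=1, G=2, T=3, so the
numeric order of packed codes equals the lexicographic order of the
sequences.  ``N`` (or any non-ACGT byte) has no packed representation;
callers must filter ambiguous sequences before packing.
"""

from __future__ import annotations

import numpy as np

BASES = b"ACGT"

_ASCII_TO_2BIT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ASCII_TO_2BIT[_b] = _i
    _ASCII_TO_2BIT[ord(chr(_b).lower())] = _i

_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in [(b"A", b"T"), (b"C", b"G"), (b"G", b"C"), (b"T", b"A"),
               (b"a", b"t"), (b"c", b"g"), (b"g", b"c"), (b"t", b"a")]:
    _COMPLEMENT[ord(_a)] = ord(_b)

# mask selecting the low bit of every 2-bit symbol slot
_ODD_MASK = np.uint64(0x5555555555555555)


def seq_to_bytes(seq: str) -> np.ndarray:
    """Encode a nucleotide string as an ASCII uint8 array."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def bytes_to_str(arr: np.ndarray) -> str:
    """Decode a 1-D ASCII uint8 array back to a string."""
    return arr.tobytes().decode("ascii")


def rows_to_strs(arr: np.ndarray) -> list[str]:
    """Decode each row of a 2-D ASCII array to a string."""
    n, length = arr.shape
    raw = arr.tobytes().decode("ascii")
    return [raw[i * length:(i + 1) * length] for i in range(n)]


def strs_to_rows(seqs: list[str]) -> np.ndarray:
    """Encode equal-length strings as a 2-D ASCII array."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    raw = "".join(seqs).upper().encode("ascii")
    return np.frombuffer(raw, dtype=np.uint8).reshape(len(seqs), length).copy()


def revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    """Reverse-complement along the last axis of an ASCII array."""
    return _COMPLEMENT[arr][..., ::-1]


def revcomp(seq: str) -> str:
    return bytes_to_str(revcomp_bytes(seq_to_bytes(seq)))


def is_acgt(arr: np.ndarray) -> np.ndarray:
    """Boolean mask (same shape) of bytes that are unambiguous A/C/G/T."""
    return _ASCII_TO_2BIT[arr] != 255


def pack(arr: np.ndarray) -> np.ndarray:
    """Pack ASCII rows (n, L), L <= 32, into uint64 codes.

    Raises ValueError on ambiguous bases; filter with :func:`is_acgt` first.
    """
    if arr.ndim == 1:
        arr = arr[None, :]
    n, length = arr.shape
    if length > 32:
        raise ValueError("cannot pack sequences longer than 32 nt")
    codes2 = _ASCII_TO_2BIT[arr]
    if np.any(codes2 == 255):
        raise ValueError("cannot pack sequences containing non-ACGT bases")
    out = np.zeros(n, dtype=np.uint64)
    for j in range(length):
        out = (out << np.uint64(2)) | codes2[:, j].astype(np.uint64)
    return out


def unpack(codes: np.ndarray, length: int) -> np.ndarray:
    """Inverse of :func:`pack`: uint64 codes to ASCII rows (n, length)."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.empty((codes.size, length), dtype=np.uint8)
    base_arr = np.frombuffer(BASES, dtype=np.uint8)
    for j in range(length):
        shift = np.uint64(2 * (length - 1 - j))
        out[:, j] = base_arr[((codes >> shift) & np.uint64(3)).astype(np.intp)]
    return out


def hamming_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamming distance between packed codes (broadcasting)."""
    x = np.bitwise_xor(np.asarray(a, dtype=np.uint64), np.asarray(b, dtype=np.uint64))
    occupied = (x | (x >> np.uint64(1))) & _ODD_MASK
    return np.bitwise_count(occupied).astype(np.int64)


def hamming_bytes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamming distance between ASCII arrays along the last axis."""
    return (np.asarray(a) != np.asarray(b)).sum(axis=-1)


def random_seq_rows(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Uniform random ASCII sequence rows of shape (n, length)."""
    base_arr = np.frombuffer(BASES, dtype=np.uint8)
    return base_arr[rng.integers(0, 4, size=(n, length))]


def apply_substitutions(rng: np.random.Generator, arr: np.ndarray, rate: float) -> None:
    """Inject i.i.d. substitution errors in place at the given per-base rate.

    Each error replaces the base with one of the three other bases uniformly,
    so the realized substitution probability is exactly ``rate``.
    """
    if rate <= 0:
        return
    n_cells = arr.size
    n_err = rng.binomial(n_cells, rate)
    if n_err == 0:
        return
    flat_idx = rng.choice(n_cells, size=n_err, replace=False) if n_err < n_cells // 4 \
        else rng.permutation(n_cells)[:n_err]
    flat = arr.reshape(-1)
    old = _ASCII_TO_2BIT[flat[flat_idx]]
    shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
    base_arr = np.frombuffer(BASES, dtype=np.uint8)
    flat[flat_idx] = base_arr[(old + shift) % 4]
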