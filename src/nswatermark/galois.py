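"""Finite-field arithmetic for barcode codes.

Barcode codewords live in GF(2^p) (GF(16) by default, a hexadecimal
alphabet), while nucleotides are treated as elements of GF(4) so that a
fixed watermark sequence can be added to -- and later removed from -- a
barcode by the self-inverse operator ``⊕``.

All arithmetic is table lookup; tables are built once at field
construction from a primitive polynomial over GF(2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaloisField",
    "NucleotideMap",
    "DEFAULT_NT_MAP",
    "GF16",
    "GF4",
    "nt_add",
]

# Conventional primitive polynomials x^p + ... for small binary extension fields,
# as bitmasks including the leading term.
_DEFAULT_POLYS = {
    2: 0b11,        # x + 1
    4: 0b111,       # x^2 + x + 1
    8: 0b1011,      # x^3 + x + 1
    16: 0b10011,    # x^4 + x + 1
    32: 0b100101,   # x^5 + x^2 + 1
    64: 0b1000011,  # x^6 + x + 1
}


def _carryless_mul_mod(a: int, b: int, poly: int, p: int) -> int:
    """Polynomial multiplication of a*b over GF(2), reduced modulo poly."""
    prod = 0
    while b:
        if b & 1:
            prod ^= a
        b >>= 1
        a <<= 1
        if a >> p & 1:
            a ^= poly
    return prod


@dataclass(frozen=True)
class GaloisField:
    """GF(2^p) with lookup-table arithmetic.

    Parameters
    ----------
    order : int
        Field order q; must be a power of two (q = 2^p, p >= 1).
    primitive_polynomial : int, optional
        Bitmask of an irreducible degree-p polynomial over GF(2),
        including the leading x^p term (e.g. ``0x13`` = x^4+x+1 for
        GF(16)). Defaults to the conventional choice for q <= 64.
    """

    order: int
    primitive_polynomial: int = 0
    add_table: np.ndarray = field(init=False, repr=False, compare=False)
    mul_table: np.ndarray = field(init=False, repr=False, compare=False)
    inv_table: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        q = self.order
        p = q.bit_length() - 1
        if q < 2 or q != 1 << p:
            raise ValueError(f"field order must be a power of two, got {q}")
        poly = self.primitive_polynomial
        if poly == 0:
            if q not in _DEFAULT_POLYS:
                raise ValueError(
                    f"no default primitive polynomial for q={q}; pass one explicitly"
                )
            poly = _DEFAULT_POLYS[q]
            object.__setattr__(self, "primitive_polynomial", poly)
        if poly >> p != 1:
            raise ValueError(
                f"primitive polynomial 0x{poly:x} does not have degree p={p}"
            )
        sym = np.arange(q)
        add = sym[:, None] ^ sym[None, :]
        mul = np.empty((q, q), dtype=np.int64)
        for a in range(q):
            for b in range(q):
                mul[a, b] = _carryless_mul_mod(a, b, poly, p)
        inv = np.zeros(q, dtype=np.int64)
        for a in range(1, q):
            hits = np.nonzero(mul[a] == 1)[0]
            if hits.size != 1:
                raise ValueError(
                    f"0x{poly:x} is not irreducible over GF(2): "
                    f"symbol {a} lacks a unique inverse"
                )
            inv[a] = hits[0]
        object.__setattr__(self, "add_table", add)
        object.__setattr__(self, "mul_table", mul)
        object.__setattr__(self, "inv_table", inv)

    # -- scalar ops -------------------------------------------------------

    def _check(self, *symbols: int) -> None:
        for s in symbols:
            if not 0 <= int(s) < self.order:
                raise ValueError(f"symbol {s} out of range for GF({self.order})")

    def add(self, a: int, b: int) -> int:
        """Carry-free polynomial-basis addition (bitwise XOR)."""
        self._check(a, b)
        return int(self.add_table[a, b])

    def mul(self, a: int, b: int) -> int:
        self._check(a, b)
        return int(self.mul_table[a, b])

    def inv(self, a: int) -> int:
        self._check(a)
        if a == 0:
            raise ZeroDivisionError("0 has no multiplicative inverse")
        return int(self.inv_table[a])

    # -- linear algebra over the field ------------------------------------

    def matvec(self, M: np.ndarray, v: np.ndarray) -> np.ndarray:
        """M @ v over the field (rows of M combined by ⊕)."""
        M = np.asarray(M)
        v = np.asarray(v)
        out = np.zeros(M.shape[0], dtype=np.int64)
        for j in range(M.shape[1]):
            out ^= self.mul_table[M[:, j], v[j]]
        return out

    def matmul(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        A = np.asarray(A)
        B = np.asarray(B)
        out = np.zeros((A.shape[0], B.shape[1]), dtype=np.int64)
        for j in range(B.shape[1]):
            out[:, j] = self.matvec(A, B[:, j])
        return out

    def mat_inv(self, M: np.ndarray) -> np.ndarray:
        """Inverse of a square matrix by Gauss-Jordan elimination.

        Raises ``np.linalg.LinAlgError`` if M is singular over the field.
        """
        M = np.asarray(M)
        n = M.shape[0]
        if M.shape != (n, n):
            raise ValueError("matrix must be square")
        aug = np.concatenate([M.copy(), np.eye(n, dtype=np.int64)], axis=1)
        for col in range(n):
            pivots = np.nonzero(aug[col:, col])[0]
            if pivots.size == 0:
                raise np.linalg.LinAlgError("matrix is singular over the field")
            piv = col + pivots[0]
            if piv != col:
                aug[[col, piv]] = aug[[piv, col]]
            aug[col] = self.mul_table[aug[col], self.inv_table[aug[col, col]]]
            for row in range(n):
                if row != col and aug[row, col]:
                    aug[row] ^= self.mul_table[aug[col], aug[row, col]]
        return aug[:, n:]

    def mat_rank(self, M: np.ndarray) -> int:
        M = np.asarray(M).copy()
        rank = 0
        for col in range(M.shape[1]):
            if rank == M.shape[0]:
                break
            pivots = np.nonzero(M[rank:, col])[0]
            if pivots.size == 0:
                continue
            piv = rank + pivots[0]
            if piv != rank:
                M[[rank, piv]] = M[[piv, rank]]
            M[rank] = self.mul_table[M[rank], self.inv_table[M[rank, rank]]]
            for row in range(M.shape[0]):
                if row != rank and M[row, col]:
                    M[row] ^= self.mul_table[M[rank], M[row, col]]
            rank += 1
        return rank


GF16 = GaloisField(16)
GF4 = GaloisField(4)


@dataclass(frozen=True)
class NucleotideMap:
    """Bijection between {A,C,G,T} and GF(4) elements {0,1,2,3}.

    A maps to 0 (the additive identity), so adding an all-A watermark is
    a no-op and "no watermark" and "all-A watermark" coincide.
    """

    letters: str = "ACGT"

    def __post_init__(self) -> None:
        if sorted(self.letters) != list("ACGT"):
            raise ValueError("letters must be a permutation of ACGT")
        if self.letters[0] != "A":
            raise ValueError("A must map to 0 (the additive identity)")
        lut = np.full(128, -1, dtype=np.int8)
        for i, c in enumerate(self.letters):
            lut[ord(c)] = i
        object.__setattr__(self, "_lut", lut)

    @property
    def letter_to_element(self) -> dict:
        return {c: i for i, c in enumerate(self.letters)}

    @property
    def element_to_letter(self) -> dict:
        return dict(enumerate(self.letters))

    def encode(self, seq: str) -> np.ndarray:
        """ACGT string -> int8 array of GF(4) elements."""
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        out = self._lut[arr]
        if (out < 0).any():
            bad = seq[int(np.nonzero(out < 0)[0][0])]
            raise ValueError(f"non-ACGT character {bad!r} in sequence")
        return out.astype(np.int8)

    def decode(self, elements: np.ndarray) -> str:
        return "".join(self.letters[int(e)] for e in elements)


DEFAULT_NT_MAP = NucleotideMap()


def nt_add(s1: str, s2: str, nt_map: NucleotideMap = DEFAULT_NT_MAP) -> str:
    """Elementwise GF(4) addition ``s1 ⊕ s2`` of two equal-length sequences.

    Self-inverse: ``nt_add(nt_add(s, w), w) == s``. With the default map
    (A=00, C=01, G=10, T=11) the operator is bitwise XOR of the 2-bit
    encodings.
    """
    if len(s1) != len(s2):
        raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
    a = nt_map.encode(s1)
    b = nt_map.encode(s2)
    return nt_map.decode(a ^ b)
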