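"""Barcode code construction: q-ary LDPC + dictionary + watermark.

A barcode identity is a payload ``x`` of k symbols over GF(q) (k=3
hexadecimal digits by default, so 16^3 = 4096 identities). A systematic
LDPC code over GF(q) prepends m = n - k parity symbols, giving a
codeword ``c`` of n symbols (payload last, matching the ``131:4AF``
parity-first layout). A dictionary ``ε`` of q distinct u-mers translates
each symbol to nucleotides, and a fixed watermark ``w`` of length
l = n*u is ⊕-added to give the final 36-nt barcode sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import yaml

from .galois import DEFAULT_NT_MAP, GaloisField, NucleotideMap, nt_add

__all__ = [
    "CodeParams",
    "LDPCCode",
    "SymbolDictionary",
    "BarcodeSpec",
    "Barcode",
    "build_ldpc",
    "encode",
    "to_nucleotides",
    "generate_barcode_set",
    "min_pairwise_distance",
    "default_spec",
]


class CodeConstructionError(RuntimeError):
    pass


@dataclass(frozen=True)
class CodeParams:
    """Code dimensions: q-ary symbols, n per codeword, k of payload,
    u nucleotides per symbol; l = n*u nucleotides per barcode."""

    q: int = 16
    n: int = 6
    k: int = 3
    u: int = 6

    def __post_init__(self) -> None:
        if self.k >= self.n:
            raise CodeConstructionError(
                f"payload size k={self.k} must be smaller than codeword size n={self.n}"
            )
        if self.q < 2 or self.q & (self.q - 1):
            raise CodeConstructionError("q must be a power of two")

    @property
    def m(self) -> int:
        return self.n - self.k

    @property
    def l(self) -> int:
        return self.n * self.u

    @property
    def n_codewords(self) -> int:
        return self.q**self.k


@dataclass(frozen=True)
class LDPCCode:
    """Sparse parity-check matrix H (m x n over GF(q)) with a systematic
    encoder: parity symbols occupy the first m positions, payload the
    last k, and every codeword satisfies H·cᵀ = 0."""

    params: CodeParams
    gf: GaloisField
    H: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        m, n = self.params.m, self.params.n
        if self.H.shape != (m, n):
            raise CodeConstructionError(f"H must be {m}x{n}, got {self.H.shape}")
        if self.gf.mat_rank(self.H) != m:
            raise CodeConstructionError("H is rank deficient over GF(q)")
        Hp = self.H[:, : m]
        Hp_inv = self.gf.mat_inv(Hp)  # raises if not systematic-encodable
        # parity = (Hp^-1 · Hx) · payload
        object.__setattr__(self, "_encoder_mat", self.gf.matmul(Hp_inv, self.H[:, m:]))

    @property
    def parity_positions(self) -> list[int]:
        return list(range(self.params.m))

    @property
    def payload_positions(self) -> list[int]:
        return list(range(self.params.m, self.params.n))

    def encode(self, payload: Sequence[int]) -> np.ndarray:
        return encode(payload, self)

    def syndrome(self, codeword: Sequence[int]) -> np.ndarray:
        return self.gf.matvec(self.H, np.asarray(codeword, dtype=np.int64))

    def codeword_table(self) -> np.ndarray:
        """All q^k codewords, row i = codeword of payload id i. Cached."""
        cached = getattr(self, "_cw_table", None)
        if cached is None:
            p = self.params
            ids = np.arange(p.n_codewords)
            payloads = np.stack(
                [(ids // p.q ** (p.k - 1 - j)) % p.q for j in range(p.k)], axis=1
            )
            cached = np.empty((p.n_codewords, p.n), dtype=np.int64)
            for i in range(p.n_codewords):
                cached[i] = encode(payloads[i], self)
            cached.setflags(write=False)
            object.__setattr__(self, "_cw_table", cached)
        return cached


def build_ldpc(
    params: CodeParams,
    seed: int,
    gf: GaloisField | None = None,
    column_weight: int = 2,
    max_tries: int = 1000,
) -> LDPCCode:
    """Construct a random sparse, full-rank parity-check matrix over GF(q).

    Columns have weight ``column_weight`` (2 by default) with rows filled
    as evenly as possible (weight 4 each for the default 3x6 H); nonzero
    entries are uniform over {1..q-1}. Resamples until the parity-position
    submatrix is invertible, so systematic encoding exists. Deterministic
    given ``seed``.
    """
    gf = gf or GaloisField(params.q)
    m, n = params.m, params.n
    if column_weight > m:
        raise CodeConstructionError("column weight cannot exceed the number of rows")
    rng = np.random.default_rng(seed)
    n_edges = column_weight * n
    base, extra = divmod(n_edges, m)
    row_budget = np.array([base + (1 if r < extra else 0) for r in range(m)])
    for _ in range(max_tries):
        slots = np.repeat(np.arange(m), row_budget)
        rng.shuffle(slots)
        cols = slots.reshape(n, column_weight)
        if any(len(set(c)) != column_weight for c in cols):
            continue
        H = np.zeros((m, n), dtype=np.int64)
        for j in range(n):
            for r in cols[j]:
                H[r, j] = rng.integers(1, params.q)
        try:
            return LDPCCode(params=params, gf=gf, H=H, seed=seed)
        except (CodeConstructionError, np.linalg.LinAlgError):
            continue
    raise CodeConstructionError(
        f"no systematic full-rank H found after {max_tries} tries"
    )


def encode(payload: Sequence[int], code: LDPCCode) -> np.ndarray:
    """Systematic encoding: parity-first codeword whose last k symbols
    equal the payload and whose syndrome is zero."""
    x = np.asarray(payload, dtype=np.int64)
    if x.shape != (code.params.k,):
        raise ValueError(f"payload must have {code.params.k} symbols")
    if (x < 0).any() or (x >= code.params.q).any():
        raise ValueError("payload symbol out of field range")
    parity = code.gf.matvec(code._encoder_mat, x)
    return np.concatenate([parity, x])


@dataclass(frozen=True)
class SymbolDictionary:
    """q distinct nucleotide u-mers ε(0..q-1) with a minimum pairwise
    Hamming distance floor (>=3 by default, so single-base errors inside
    a block never turn one entry into another)."""

    entries: tuple[str, ...]
    min_distance: int = 3

    def __post_init__(self) -> None:
        u = len(self.entries[0])
        if any(len(e) != u for e in self.entries):
            raise ValueError("dictionary entries must all have the same length")
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("dictionary entries must be distinct")
        for e in self.entries:
            if set(e) - set("ACGT"):
                raise ValueError(f"non-ACGT entry {e!r}")
        d = min_pairwise_distance(self.entries, metric="hamming")[0]
        if d < self.min_distance:
            raise ValueError(
                f"dictionary min Hamming distance {d} below floor {self.min_distance}"
            )

    @property
    def u(self) -> int:
        return len(self.entries[0])

    @property
    def inverse(self) -> dict:
        return {e: i for i, e in enumerate(self.entries)}

    def __getitem__(self, symbol: int) -> str:
        return self.entries[symbol]


def _search_dictionary(
    q: int, u: int, rng: np.random.Generator, min_distance: int, gc_bounds: tuple[int, int]
) -> tuple[str, ...]:
    """Greedy seeded search for q distinct u-mers with pairwise Hamming
    distance >= min_distance and GC count within gc_bounds."""
    letters = np.array(list("ACGT"))
    for _ in range(200):
        chosen: list[str] = []
        for _ in range(20000):
            word = "".join(letters[rng.integers(0, 4, size=u)])
            gc = word.count("G") + word.count("C")
            if not gc_bounds[0] <= gc <= gc_bounds[1]:
                continue
            if all(
                sum(a != b for a, b in zip(word, w)) >= min_distance for w in chosen
            ):
                chosen.append(word)
                if len(chosen) == q:
                    return tuple(chosen)
    raise CodeConstructionError(
        f"could not find {q} {u}-mers at Hamming distance {min_distance}"
    )


@dataclass(frozen=True)
class BarcodeSpec:
    """Everything needed to reproduce a barcode set bit-exactly: code
    parameters, parity-check matrix, dictionary ε, watermark w, and the
    design seed."""

    params: CodeParams
    code: LDPCCode
    dictionary: SymbolDictionary
    watermark: str
    design_seed: int
    nt_map: NucleotideMap = DEFAULT_NT_MAP

    def __post_init__(self) -> None:
        if len(self.watermark) != self.params.l:
            raise ValueError(
                f"watermark length {len(self.watermark)} != l={self.params.l}"
            )
        if self.dictionary.u != self.params.u:
            raise ValueError("dictionary word size does not match params.u")
        if len(self.dictionary.entries) != self.params.q:
            raise ValueError("dictionary must have exactly q entries")

    # -- identity <-> symbols ---------------------------------------------

    def id_to_payload(self, barcode_id: int) -> np.ndarray:
        p = self.params
        if not 0 <= barcode_id < p.n_codewords:
            raise ValueError(f"barcode id {barcode_id} out of range")
        return np.array(
            [(barcode_id // p.q ** (p.k - 1 - j)) % p.q for j in range(p.k)],
            dtype=np.int64,
        )

    def payload_to_id(self, payload: Sequence[int]) -> int:
        p = self.params
        return int(sum(int(s) * p.q ** (p.k - 1 - j) for j, s in enumerate(payload)))

    def barcode(self, barcode_id: int) -> "Barcode":
        payload = self.id_to_payload(barcode_id)
        codeword = encode(payload, self.code)
        return Barcode(
            id=barcode_id,
            payload=payload,
            codeword=codeword,
            sequence=to_nucleotides(codeword, self),
        )

    def to_yaml(self) -> str:
        doc = {
            "q": self.params.q,
            "n": self.params.n,
            "k": self.params.k,
            "u": self.params.u,
            "primitive_polynomial": hex(self.code.gf.primitive_polynomial),
            "H": ["".join(f"{v:x}" for v in row) for row in self.code.H],
            "dictionary": list(self.dictionary.entries),
            "dictionary_min_distance": self.dictionary.min_distance,
            "watermark": self.watermark,
            "design_seed": self.design_seed,
            "nucleotide_map": self.nt_map.letters,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "BarcodeSpec":
        doc = yaml.safe_load(text)
        params = CodeParams(q=doc["q"], n=doc["n"], k=doc["k"], u=doc["u"])
        gf = GaloisField(doc["q"], int(doc["primitive_polynomial"], 16))
        H = np.array([[int(c, 16) for c in row] for row in doc["H"]], dtype=np.int64)
        code = LDPCCode(params=params, gf=gf, H=H, seed=doc.get("design_seed", 0))
        dictionary = SymbolDictionary(
            entries=tuple(doc["dictionary"]),
            min_distance=doc.get("dictionary_min_distance", 3),
        )
        return cls(
            params=params,
            code=code,
            dictionary=dictionary,
            watermark=doc["watermark"],
            design_seed=doc.get("design_seed", 0),
            nt_map=NucleotideMap(doc.get("nucleotide_map", "ACGT")),
        )


@dataclass(frozen=True)
class Barcode:
    id: int
    payload: np.ndarray
    codeword: np.ndarray
    sequence: str
    pool: str | None = None  # "A" | "B" | None
    status: str = "synthesized"  # or "negative_control"


def to_nucleotides(codeword: Sequence[int], spec: BarcodeSpec) -> str:
    """ε-translate an n-symbol codeword and ⊕-add the watermark;
    returns the l-nt barcode sequence."""
    cw = np.asarray(codeword, dtype=np.int64)
    if cw.shape != (spec.params.n,):
        raise ValueError(f"codeword must have {spec.params.n} symbols")
    bare = "".join(spec.dictionary[int(s)] for s in cw)
    return nt_add(bare, spec.watermark, spec.nt_map)


def default_spec(seed: int = 20220510) -> BarcodeSpec:
    """Seeded default barcode design with the standard parameters
    (q=16, n=6, k=3, u=6, l=36): random-sparse H, greedy dictionary with
    Hamming floor 3 and 2-4 G/C per 6-mer, pseudo-random watermark."""
    params = CodeParams()
    rng = np.random.default_rng(seed)
    code = build_ldpc(params, seed=int(rng.integers(2**31)))
    entries = _search_dictionary(
        params.q, params.u, rng, min_distance=3, gc_bounds=(2, 4)
    )
    dictionary = SymbolDictionary(entries=entries, min_distance=3)
    watermark = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=params.l)])
    return BarcodeSpec(
        params=params,
        code=code,
        dictionary=dictionary,
        watermark=watermark,
        design_seed=seed,
    )


def generate_barcode_set(
    spec: BarcodeSpec, n_synth: int = 3840, split_seed: int = 0
) -> list[Barcode]:
    """Enumerate all q^k barcodes and split them into synthesized pools.

    ``n_synth`` barcodes are chosen at random as synthesized and divided
    half/half into pools A and B; the remainder are flagged as negative
    controls (designed but never synthesized, so any read decoding to one
    is a known error). Deterministic given ``split_seed``.
    """
    total = spec.params.n_codewords
    if n_synth > total:
        raise ValueError(f"n_synth={n_synth} exceeds the set size {total}")
    if n_synth % 2:
        raise ValueError("n_synth must be even (pools A and B are equal-sized)")
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(total)
    pool_of = {}
    status_of = {}
    for idx in order[: n_synth // 2]:
        pool_of[int(idx)] = "A"
    for idx in order[n_synth // 2 : n_synth]:
        pool_of[int(idx)] = "B"
    for idx in order[n_synth:]:
        status_of[int(idx)] = "negative_control"
    out = []
    for bid in range(total):
        bc = spec.barcode(bid)
        out.append(
            Barcode(
                id=bc.id,
                payload=bc.payload,
                codeword=bc.codeword,
                sequence=bc.sequence,
                pool=pool_of.get(bid),
                status=status_of.get(bid, "synthesized"),
            )
        )
    return out


def min_pairwise_distance(
    sequences: Sequence[str], metric: str = "hamming"
) -> tuple[int, int]:
    """Minimum pairwise distance d of a sequence set and the implied
    guaranteed correction capacity t = floor((d-1)/2) (from d >= 2t+1).

    ``metric`` is "hamming" (equal lengths required) or "levenshtein".
    """
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    best = None
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if metric == "hamming":
                if len(seqs[i]) != len(seqs[j]):
                    raise ValueError("hamming metric requires equal lengths")
                d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
            elif metric == "levenshtein":
                d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")[
                    "editDistance"
                ]
            else:
                raise ValueError(f"unknown metric {metric!r}")
            if best is None or d < best:
                best = d
                if best == 0:
                    return 0, 0
    return int(best), (int(best) - 1) // 2


def write_barcodes_fasta(barcodes: Iterable[Barcode], handle) -> None:
    """FASTA with id, pool and status in the header line."""
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle, "w")
        close = True
    try:
        for bc in barcodes:
            pool = bc.pool or "-"
            handle.write(f">BC{bc.id:04d} pool={pool} status={bc.status}\n")
            handle.write(bc.sequence + "\n")
    finally:
        if close:
            handle.close()
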