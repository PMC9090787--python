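"""Dual-barcoded amplicon construct layout and anchor sequences.

Each amplicon carries one barcode at either end, flanked inboard by a
3-nt pad, a 20-nt pool-specific consensus sequence (CS), a single-A
spacer and the species-specific primer, and outboard by a 20-nt
pool-specific primer annealing site (BPF):

    BPF - bc5 - pad - CS - A - [FP ... rc(RP)] - rc(A) - rc(CS) - rc(pad) - rc(bc3) - rc(BPF)

The ``pad-CS-A-primer`` strings (and their reverse complements) double
as demultiplexing anchors: the barcode sits immediately upstream of a
forward-sense anchor hit.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .code import Barcode

__all__ = [
    "POOLS",
    "PoolConstants",
    "AmpliconTemplate",
    "anchor_strings",
    "build_construct",
    "reverse_complement",
]

# Pool-specific consensus sequences and species-specific primers.
# Pool A tags a 400-nt Bordetella pertussis fragment (IS-481), pool B a
# 538-nt Drosophila mojavensis fragment (Ppr-Y).
CSA = "GCAAGCGGTACACTCAGATC"
CSB = "CAGGAGTTGTCTAGGCGATC"
FPA = "GACTTCGTCTTCGTGGCCAT"
RPA = "GTACAGCGCGCCCGATGCCT"
FPB = "CGAGTATCTTCAAGAAAAAGAAATTCAA"
RPB = "CGTGTAAATGCAATTCCTGAGACAT"
PAD_A = "CGC"
PAD_B = "GCG"


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PoolConstants:
    name: str
    bpf: str  # 20-nt subpool amplification site
    cs: str  # 20-nt consensus sequence
    pad: str  # 3-nt Tm-matching pad between barcode and CS
    fp: str  # species-specific forward primer (starts the insert)
    rp: str  # species-specific reverse primer (insert ends with rc(rp))
    insert_length: int

    @property
    def anchor_fp(self) -> str:
        """pad-CS-A-FP: forward-sense anchor downstream of the 5' barcode."""
        return self.pad + self.cs + "A" + self.fp

    @property
    def anchor_rp(self) -> str:
        """pad-CS-A-RP: anchor adjoining the 3' barcode (hits in reverse
        sense on the canonical strand)."""
        return self.pad + self.cs + "A" + self.rp


def _seeded_sequence(seed: int, length: int) -> str:
    import numpy as np

    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


# BPF sites are 20-mers; seeded stand-ins (synthetic), as are the insert
# interiors between the real primers.
POOLS = {
    "A": PoolConstants(
        name="A",
        bpf=_seeded_sequence(101, 20),
        cs=CSA,
        pad=PAD_A,
        fp=FPA,
        rp=RPA,
        insert_length=400,
    ),
    "B": PoolConstants(
        name="B",
        bpf=_seeded_sequence(102, 20),
        cs=CSB,
        pad=PAD_B,
        fp=FPB,
        rp=RPB,
        insert_length=538,
    ),
}


def default_insert(pool: str, seed: int = 77) -> str:
    """Synthetic insert: real species primers at the ends, seeded random
    interior, at the nominal amplicon length (400 for A, 538 for B)."""
    pc = POOLS[pool]
    interior = pc.insert_length - len(pc.fp) - len(pc.rp)
    return pc.fp + _seeded_sequence(seed + ord(pool), interior) + reverse_complement(pc.rp)


@dataclass(frozen=True)
class AmpliconTemplate:
    """Ordered segments of a dual-barcoded amplicon for one pool."""

    pool: str
    bc5: str
    bc3: str
    insert: str

    @property
    def segments(self) -> list[tuple[str, str]]:
        pc = POOLS[self.pool]
        return [
            ("BPF", pc.bpf),
            ("barcode5", self.bc5),
            ("pad", pc.pad),
            ("CS", pc.cs),
            ("A", "A"),
            ("insert", self.insert),
            ("rcA", "T"),
            ("rcCS", reverse_complement(pc.cs)),
            ("rcpad", reverse_complement(pc.pad)),
            ("rcbarcode3", reverse_complement(self.bc3)),
            ("rcBPF", reverse_complement(pc.bpf)),
        ]

    @property
    def sequence(self) -> str:
        return "".join(s for _, s in self.segments)


def build_construct(
    pool: str, bc5: Barcode, bc3: Barcode, insert: str | None = None
) -> str:
    """Assemble the full dual-barcoded construct for one molecule.

    Both ends carry the same CS (inverted terminal repeats), so total
    length = insert + 2*(20+1) + 2*(20+36+3): 560 bp for the 400-nt pool-A
    insert and 698 bp for the 538-nt pool-B insert.
    """
    if pool not in POOLS:
        raise ValueError(f"unknown pool {pool!r}")
    for bc in (bc5, bc3):
        if bc.pool != pool:
            raise ValueError(
                f"barcode {bc.id} belongs to pool {bc.pool}, not {pool}"
            )
    if insert is None:
        insert = default_insert(pool)
    if not insert:
        raise ValueError("insert must be nonempty")
    return AmpliconTemplate(pool=pool, bc5=bc5.sequence, bc3=bc3.sequence, insert=insert).sequence


def anchor_strings() -> dict[str, str]:
    """The four pad-CS-A-primer anchors aligned to every read.

    Keys are e.g. ``padCSA-A-FPA``; reverse complements are generated at
    alignment time. FP anchors adjoin the 5' barcode, RP anchors the 3'.
    """
    out = {}
    for pool, pc in POOLS.items():
        out[f"padCS{pool}-A-FP{pool}"] = pc.anchor_fp
        out[f"padCS{pool}-A-RP{pool}"] = pc.anchor_rp
    return out
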