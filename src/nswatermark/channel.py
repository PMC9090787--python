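"""IID insertion/deletion/substitution read channel and run simulator.

The channel emulates the error profile of single-pass nanopore reads:
per template base, deletion with probability ``P_d`` and substitution
(uniform over the three alternatives) with ``P_s``; before each template
position and at the end, a geometric run of uniform-random inserted
bases with per-base probability ``P_i``. The demultiplexer's drift
lattice shares this generative model.

``simulate_run`` fabricates a two-species barnyard run: pools A and B
mixed 1:2, dual barcodes drawn per molecule from the pool's synthesized
subset with log-normally skewed abundances, random strand, channel
corruption, FASTQ output plus a ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .code import Barcode, BarcodeSpec, generate_barcode_set
from .constructs import build_construct, default_insert, reverse_complement

__all__ = [
    "ChannelParams",
    "SimulatedRead",
    "SimConfig",
    "corrupt",
    "simulate_run",
    "write_fastq",
]

_LETTERS = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChannelParams:
    """Per-base substitution (P_s), insertion (P_i) and deletion (P_d)
    probabilities."""

    P_s: float = 0.03
    P_i: float = 0.03
    P_d: float = 0.03

    def __post_init__(self) -> None:
        for name in ("P_s", "P_d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if not 0.0 <= self.P_i < 1.0:
            raise ValueError(f"P_i={self.P_i} must be in [0, 1)")
        if self.P_s + self.P_d > 1.0:
            raise ValueError("P_s + P_d must not exceed 1")


def corrupt(sequence: str, params: ChannelParams, rng: np.random.Generator) -> str:
    """Pass one sequence through the IDS channel.

    Insertions occur before each template position and after the last
    one, with a geometric number of inserted bases per slot (each slot
    keeps inserting with probability ``P_i``). Deterministic given the
    generator state.
    """
    if not isinstance(params, ChannelParams):
        params = ChannelParams(*params)
    n = len(sequence)
    out: list[str] = []
    for pos in range(n + 1):
        while rng.random() < params.P_i:
            out.append(_LETTERS[rng.integers(0, 4)])
        if pos == n:
            break
        base = sequence[pos]
        r = rng.random()
        if r < params.P_d:
            continue
        if r < params.P_d + params.P_s:
            alternatives = [c for c in "ACGT" if c != base]
            out.append(alternatives[rng.integers(0, 3)])
        else:
            out.append(base)
    return "".join(out)


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    truth_pool: str
    truth_bc5: int
    truth_bc3: int
    strand: str  # "+" | "-"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated barnyard run.

    Defaults follow the real experiment where the value is reported:
    3840 synthesized barcodes split 1920/1920 into pools A and B, molar
    ratio 1:2, and an abundance skew of about two orders of magnitude
    between the most and least concentrated barcode in a subpool
    (log-normal sigma 0.7 puts the expected max/min ratio near 100 for
    1920 draws). The per-event channel rates are stand-ins at 0.03.
    """

    n_reads: int = 1000
    pool_ratio: tuple[float, float] = (1.0, 2.0)  # A : B
    channel: ChannelParams = field(default_factory=ChannelParams)
    abundance_sigma: float = 0.7
    n_synth: int = 3840
    split_seed: int = 0
    seed: int = 0


def simulate_run(
    spec: BarcodeSpec, config: SimConfig, barcodes: list[Barcode] | None = None
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Fabricate a run of dual-barcoded reads with ground truth.

    Returns the reads and a truth table (read_id, pool, bc5_id, bc3_id,
    strand). Deterministic given ``config.seed``.
    """
    if config.n_reads <= 0:
        raise ValueError("read count must be positive")
    if barcodes is None:
        barcodes = generate_barcode_set(
            spec, n_synth=config.n_synth, split_seed=config.split_seed
        )
    rng = np.random.default_rng(config.seed)
    pools = {
        "A": [bc for bc in barcodes if bc.pool == "A"],
        "B": [bc for bc in barcodes if bc.pool == "B"],
    }
    if not pools["A"] or not pools["B"]:
        raise ValueError("both pools must contain synthesized barcodes")
    inserts = {p: default_insert(p) for p in "AB"}
    # per-barcode abundance weights, skewed log-normally within each pool
    weights = {}
    for p, bcs in pools.items():
        w = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(bcs))
        weights[p] = w / w.sum()
    p_a = config.pool_ratio[0] / sum(config.pool_ratio)
    reads: list[SimulatedRead] = []
    rows = []
    for i in range(config.n_reads):
        pool = "A" if rng.random() < p_a else "B"
        bcs = pools[pool]
        i5, i3 = rng.choice(len(bcs), size=2, p=weights[pool])
        bc5, bc3 = bcs[int(i5)], bcs[int(i3)]
        construct = build_construct(pool, bc5, bc3, insert=inserts[pool])
        strand = "+" if rng.random() < 0.5 else "-"
        template = construct if strand == "+" else reverse_complement(construct)
        seq = corrupt(template, config.channel, rng)
        rid = f"read{i:06d}"
        reads.append(
            SimulatedRead(
                read_id=rid,
                sequence=seq,
                truth_pool=pool,
                truth_bc5=bc5.id,
                truth_bc3=bc3.id,
                strand=strand,
            )
        )
        rows.append((rid, pool, bc5.id, bc3.id, strand))
    truth = pd.DataFrame(
        rows, columns=["read_id", "pool", "bc5_id", "bc3_id", "strand"]
    )
    return reads, truth


def write_fastq(reads: list[SimulatedRead], handle, quality: str = "I") -> None:
    """Standard 4-line FASTQ with a constant quality character (the
    decoder estimates error rates from anchor alignments, not qualities)."""
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle, "w")
        close = True
    try:
        for r in reads:
            handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality * len(r.sequence)}\n")
    finally:
        if close:
            handle.close()
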