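"""End-to-end demultiplexing: length filter, anchor search, subread
extraction, channel-rate estimation, per-read decoding, and
recovery/crosstalk metrics with the negative-control estimator.

Coordinates are 0-based half-open throughout. Reads are processed
as-sequenced; reverse complementation is applied only at subread
extraction, so the decoder always sees a forward-oriented barcode
immediately upstream of its anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .channel import ChannelParams, SimulatedRead
from .code import Barcode, BarcodeSpec
from .constructs import anchor_strings, reverse_complement
from .decoder import DriftModel, WatermarkDecoder

__all__ = [
    "AnchorHit",
    "Subread",
    "DemuxConfig",
    "DemuxMetrics",
    "Demultiplexer",
    "length_filter",
    "bounds_from_peaks",
    "find_anchors",
    "extract_subread",
    "estimate_error_rates",
    "demux_read",
    "compute_metrics",
    "estimate_crosstalk_negative_controls",
    "sweep_thresholds",
    "read_fastq",
]


@dataclass(frozen=True)
class AnchorHit:
    """One semi-global anchor alignment on a read (0-based, half-open)."""

    anchor_name: str
    sense: str  # "forward" | "reverse"
    edit_distance: int
    start: int
    end: int
    cigar: str | None = None  # extended CIGAR (=/X/I/D), query = anchor

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("hit coordinates must satisfy 0 <= start < end")


@dataclass(frozen=True)
class Subread:
    sequence: str
    truncated: bool  # any window clamping at a read boundary
    anchor_side_truncated: bool  # clamping that breaks the anchor offset


@dataclass(frozen=True)
class DemuxConfig:
    """Pipeline parameters.

    The extraction window of -61/+56 around the anchor start leaves
    25 nt of slack upstream of the 36-nt barcode; length bounds default
    to the +-10% window around the 590/740 read-length peaks.
    """

    max_anchor_distance: int = 12
    window_upstream: int = 61
    window_downstream: int = 56
    length_bounds: tuple[int, int] = (531, 814)
    confidence_threshold: float | None = None  # log10 L
    channel_override: ChannelParams | None = None
    max_drift: int = 15
    max_insert_run: int = 2
    min_hit_separation: int = 20  # collapse tie locations closer than this

    def __post_init__(self) -> None:
        if self.length_bounds[0] >= self.length_bounds[1]:
            raise ValueError("length bounds must satisfy min < max")


def bounds_from_peaks(
    low_peak: float, high_peak: float, frac: float = 0.10
) -> tuple[int, int]:
    """Length-filter bounds from read-length histogram peak centers:
    (low*(1-frac), high*(1+frac)), e.g. (590, 740) -> (531, 814)."""
    return int(round(low_peak * (1 - frac))), int(round(high_peak * (1 + frac)))


def _read_tuple(read) -> tuple[str, str]:
    if isinstance(read, SimulatedRead):
        return read.read_id, read.sequence
    if hasattr(read, "seq"):  # Bio.SeqRecord
        return read.id, str(read.seq)
    rid, seq = read
    return rid, seq


def read_fastq(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fastq")]


def length_filter(reads: Iterable, bounds: tuple[int, int]) -> list:
    """Keep reads with min <= length <= max (boundary inclusive)."""
    lo, hi = bounds
    if lo >= hi:
        raise ValueError("length bounds must satisfy min < max")
    return [r for r in reads if lo <= len(_read_tuple(r)[1]) <= hi]


def find_anchors(
    read, anchors: dict[str, str] | None = None, max_distance: int = 12,
    min_separation: int = 20,
) -> list[AnchorHit]:
    """All semi-global (edlib HW: free gaps at read ends) anchor hits
    with edit distance <= ``max_distance``, both senses.

    Tie locations of one alignment closer than ``min_separation`` are
    collapsed to the first.
    """
    _, seq = _read_tuple(read)
    if anchors is None:
        anchors = anchor_strings()
    hits: list[AnchorHit] = []
    for name, anchor in anchors.items():
        for sense, query in (("forward", anchor), ("reverse", reverse_complement(anchor))):
            res = edlib.align(query, seq, mode="HW", task="path", k=max_distance)
            if res["editDistance"] < 0:
                continue
            kept_starts: list[int] = []
            for li, (s, e) in enumerate(res["locations"]):
                if s is None:
                    continue
                if any(abs(s - ks) < min_separation for ks in kept_starts):
                    continue
                kept_starts.append(s)
                hits.append(
                    AnchorHit(
                        anchor_name=name,
                        sense=sense,
                        edit_distance=res["editDistance"],
                        start=s,
                        end=e + 1,  # edlib ends are inclusive
                        cigar=res["cigar"] if li == 0 else None,
                    )
                )
    return hits


def extract_subread(read, hit: AnchorHit, config: DemuxConfig) -> Subread:
    """Extract the decoding window around an anchor hit.

    Forward sense: [start - upstream, start + downstream) in read
    coordinates. Reverse sense: [end - downstream, end + upstream),
    then reverse complemented. The output is always forward-oriented
    (barcode upstream of the anchor, anchor starting ``downstream``
    nucleotides before the subread end). Windows extending past a read
    boundary are truncated and flagged.
    """
    _, seq = _read_tuple(read)
    n = len(seq)
    if not hit.end <= n:
        raise ValueError("hit lies outside the read")
    up, down = config.window_upstream, config.window_downstream
    if hit.sense == "forward":
        lo, hi = hit.start - up, hit.start + down
        anchor_side_cut = hi > n
    else:
        lo, hi = hit.end - down, hit.end + up
        anchor_side_cut = lo < 0
    clo, chi = max(lo, 0), min(hi, n)
    window = seq[clo:chi]
    if hit.sense == "reverse":
        window = reverse_complement(window)
    return Subread(
        sequence=window,
        truncated=(clo != lo or chi != hi),
        anchor_side_truncated=anchor_side_cut,
    )


_CIGAR_OPS = {"=": "match", "X": "sub", "I": "del", "D": "ins"}
# query = anchor (the template): edlib 'I' consumes the anchor only, i.e.
# a template base missing from the read (deletion event); edlib 'D'
# consumes the read only (insertion event).


def _cigar_counts(cigar: str) -> dict[str, int]:
    counts = {"match": 0, "sub": 0, "ins": 0, "del": 0}
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            counts[_CIGAR_OPS[c]] += int(num)
            num = ""
    return counts


def estimate_error_rates(hits: Sequence[AnchorHit]) -> ChannelParams:
    """Channel rates from anchor-alignment CIGAR strings, aggregated
    over all hits. The denominator is template-consuming columns
    (matches + mismatches + deletions)."""
    totals = {"match": 0, "sub": 0, "ins": 0, "del": 0}
    n_used = 0
    for h in hits:
        if h.cigar is None:
            continue
        for k, v in _cigar_counts(h.cigar).items():
            totals[k] += v
        n_used += 1
    if n_used == 0:
        raise ValueError("no hits with an alignment path to estimate rates from")
    denom = totals["match"] + totals["sub"] + totals["del"]
    if denom == 0:
        raise ValueError("alignments consume no template positions")
    return ChannelParams(
        P_s=totals["sub"] / denom,
        P_i=totals["ins"] / denom,
        P_d=totals["del"] / denom,
    )


def collapse_overlapping_hits(
    hits: Sequence[AnchorHit], min_separation: int = 20
) -> list[AnchorHit]:
    """Collapse same-sense hits at one physical site to the best anchor.

    The two anchors of a pool share their first 24 nt (pad-CS-A), so the
    wrong-primer anchor also hits a barcode site, ~10-11 edits away even
    on a clean read -- within the <=12 cutoff. Competing hits whose
    starts are closer than ``min_separation`` are therefore reduced to
    the lowest edit distance, which the primer region does discriminate.
    """
    kept: list[AnchorHit] = []
    for sense in ("forward", "reverse"):
        group: list[AnchorHit] = []
        for h in sorted(
            (h for h in hits if h.sense == sense),
            key=lambda h: (h.start, h.edit_distance, h.anchor_name),
        ):
            if group and h.start - group[0].start >= min_separation:
                kept.append(min(group, key=lambda g: (g.edit_distance, g.anchor_name)))
                group = []
            group.append(h)
        if group:
            kept.append(min(group, key=lambda g: (g.edit_distance, g.anchor_name)))
    return kept


# -- per-read decoding -----------------------------------------------------

# FP anchors adjoin the barcode at the construct 5' end, RP anchors the 3'.
_END_OF_ANCHOR = {"FP": "5p", "RP": "3p"}


def _end_label(anchor_name: str) -> str:
    return _END_OF_ANCHOR["FP" if "FP" in anchor_name else "RP"]


def demux_read(
    read,
    spec: BarcodeSpec,
    config: DemuxConfig,
    channel: ChannelParams,
    anchors: dict[str, str] | None = None,
    negative_control_ids: frozenset | None = None,
    decoders: dict[str, WatermarkDecoder] | None = None,
    hits: Sequence[AnchorHit] | None = None,
) -> list[dict]:
    """Decode one read: for each sense with >= 1 qualifying anchor hit,
    decode every candidate subread and keep the highest-confidence
    result. Yields up to two assignments (5' and 3' barcode)."""
    rid, seq = _read_tuple(read)
    if anchors is None:
        anchors = anchor_strings()
    if decoders is None:
        decoders = {}
    if hits is None:
        hits = collapse_overlapping_hits(
            find_anchors(
                (rid, seq), anchors, config.max_anchor_distance,
                config.min_hit_separation,
            ),
            config.min_hit_separation,
        )
    drift = DriftModel(
        channel=channel,
        max_drift=config.max_drift,
        max_insert_run=config.max_insert_run,
    )
    results = []
    for sense in ("forward", "reverse"):
        sense_hits = [h for h in hits if h.sense == sense]
        if not sense_hits:
            continue
        best = None
        for h in sense_hits:
            sub = extract_subread((rid, seq), h, config)
            dec = decoders.get(h.anchor_name)
            if dec is None:
                dec = WatermarkDecoder(
                    spec,
                    anchors[h.anchor_name],
                    channel,
                    drift,
                    anchor_offset_from_end=config.window_downstream,
                )
                decoders[h.anchor_name] = dec
            try:
                res = dec.decode(sub.sequence, negative_control_ids)
            except ValueError:  # window below decodable minimum
                res = None
            key = (
                res is not None and res.status == "decoded",
                res.log10_confidence if res and res.log10_confidence is not None else -math.inf,
            )
            if best is None or key > best[0]:
                best = (key, h, sub, res)
        _, h, sub, res = best
        row = {
            "read_id": rid,
            "sense": sense,
            "anchor": h.anchor_name,
            "end": _end_label(h.anchor_name),
            "edit_distance": h.edit_distance,
            "n_candidates": len(sense_hits),
            "truncated": sub.truncated,
            "status": "failed" if res is None or res.status == "failed" else "decoded",
            "barcode_id": res.barcode_id if res else None,
            "log10_L": res.log10_confidence if res else None,
            "is_negative_control": bool(res and res.is_negative_control),
        }
        results.append(row)
    return results


class Demultiplexer:
    """Whole-run pipeline bound to one barcode design.

    ``barcodes`` (the generated set with pool labels) supplies the
    negative-control id set and the id -> pool map for reporting.
    """

    def __init__(
        self,
        spec: BarcodeSpec,
        config: DemuxConfig | None = None,
        barcodes: list[Barcode] | None = None,
    ):
        self.spec = spec
        self.config = config or DemuxConfig()
        self.barcodes = barcodes
        self.anchors = anchor_strings()
        if barcodes is not None:
            self.negative_control_ids = frozenset(
                bc.id for bc in barcodes if bc.status == "negative_control"
            )
            self.pool_of = {bc.id: bc.pool for bc in barcodes}
        else:
            self.negative_control_ids = frozenset()
            self.pool_of = {}

    def run(self, reads: Iterable) -> tuple[pd.DataFrame, ChannelParams]:
        """Length-filter, estimate channel rates from anchor alignments
        (unless overridden), decode every read, and return the
        assignments table plus the channel estimate used."""
        cfg = self.config
        kept = length_filter(reads, cfg.length_bounds)
        all_hits: dict[str, list[AnchorHit]] = {}
        for read in kept:
            rid, seq = _read_tuple(read)
            all_hits[rid] = collapse_overlapping_hits(
                find_anchors(
                    (rid, seq), self.anchors, cfg.max_anchor_distance,
                    cfg.min_hit_separation,
                ),
                cfg.min_hit_separation,
            )
        if cfg.channel_override is not None:
            channel = cfg.channel_override
        else:
            flat = [h for hs in all_hits.values() for h in hs]
            channel = estimate_error_rates(flat)
        drift = DriftModel(
            channel=channel, max_drift=cfg.max_drift,
            max_insert_run=cfg.max_insert_run,
        )
        decoders = {
            name: WatermarkDecoder(
                self.spec, a, channel, drift,
                anchor_offset_from_end=cfg.window_downstream,
            )
            for name, a in self.anchors.items()
        }
        rows = []
        for read in kept:
            rid, _ = _read_tuple(read)
            rows.extend(
                demux_read(
                    read, self.spec, cfg, channel, self.anchors,
                    self.negative_control_ids, decoders, hits=all_hits[rid],
                )
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "read_id", "sense", "anchor", "end", "edit_distance",
                "n_candidates", "truncated", "status", "barcode_id",
                "log10_L", "is_negative_control",
            ],
        )
        if len(df):
            df["pool"] = df["barcode_id"].map(self.pool_of)
        else:
            df["pool"] = pd.Series(dtype=object)
        return df, channel


# -- metrics ---------------------------------------------------------------


@dataclass(frozen=True)
class DemuxMetrics:
    """Read recovery and crosstalk at one confidence threshold.

    Conservation holds exactly: considered = recovered + decoder_failed
    + below_threshold + negative_control_hits. The crosstalk rate is
    None (undefined) when nothing is recovered.
    """

    considered_subreads: int
    recovered: int
    recovery_rate: float
    decoder_failed: int
    below_threshold: int
    negative_control_hits: int
    misassigned: int | None = None
    crosstalk_rate: float | None = None
    inter_pool_misassigned: int | None = None
    nc_crosstalk_estimate: float | None = None


def _classify(results: pd.DataFrame, threshold: float | None):
    thr = -math.inf if threshold is None else threshold
    decoded = results["status"] == "decoded"
    logl = results["log10_L"].astype(float)
    below = decoded & (logl < thr)
    nc = decoded & ~below & results["is_negative_control"]
    recovered = decoded & ~below & ~results["is_negative_control"]
    return recovered, below, nc


def compute_metrics(
    results: pd.DataFrame,
    truth: pd.DataFrame | None = None,
    threshold: float | None = None,
    n_synth: int = 3840,
    n_negative_controls: int = 256,
) -> DemuxMetrics:
    """Apply a confidence threshold and count outcomes.

    ``results`` is the assignments table from :class:`Demultiplexer`
    (one row per considered subread); ``truth`` the simulator's table
    keyed by read_id with bc5_id/bc3_id columns. Recovery is the
    percentage of considered subreads not discarded by the decoder,
    the threshold, or a negative-control decode; crosstalk is the
    percentage of recovered subreads assigned to a wrong barcode.
    """
    considered = len(results)
    recovered_m, below_m, nc_m = _classify(results, threshold)
    recovered = int(recovered_m.sum())
    below = int(below_m.sum())
    nc_hits = int(nc_m.sum())
    failed = considered - recovered - below - nc_hits
    recovery = 100.0 * recovered / considered if considered else 0.0
    mis = crosstalk = inter = None
    if truth is not None and considered:
        if not set(results["read_id"]) <= set(truth["read_id"]):
            raise ValueError("truth table does not cover all result read ids")
        t5 = truth.set_index("read_id")["bc5_id"]
        t3 = truth.set_index("read_id")["bc3_id"]
        tpool = truth.set_index("read_id")["pool"]
        rec = results[recovered_m]
        truth_id = np.where(
            rec["end"] == "5p",
            t5.reindex(rec["read_id"]).to_numpy(),
            t3.reindex(rec["read_id"]).to_numpy(),
        )
        wrong = rec["barcode_id"].to_numpy() != truth_id
        mis = int(wrong.sum())
        inter = int(
            (rec["pool"].to_numpy() != tpool.reindex(rec["read_id"]).to_numpy()).sum()
        )
        crosstalk = 100.0 * mis / recovered if recovered else None
    nc_est = None
    if recovered + nc_hits:
        nc_est = estimate_crosstalk_negative_controls(
            results, n_synth=n_synth, n_nc=n_negative_controls, threshold=threshold
        )
    return DemuxMetrics(
        considered_subreads=considered,
        recovered=recovered,
        recovery_rate=recovery,
        decoder_failed=failed,
        below_threshold=below,
        negative_control_hits=nc_hits,
        misassigned=mis,
        crosstalk_rate=crosstalk,
        inter_pool_misassigned=inter,
        nc_crosstalk_estimate=nc_est,
    )


def estimate_crosstalk_negative_controls(
    results: pd.DataFrame,
    n_synth: int = 3840,
    n_nc: int = 256,
    mode: str = "uniform",
    threshold: float | None = None,
    barcodes: list[Barcode] | None = None,
    abundances: dict[int, float] | None = None,
    lam: float = 1.0,
    max_sources: int = 128,
    rng: np.random.Generator | None = None,
) -> float:
    """Crosstalk (%) estimated from negative-control decodes alone.

    Uniform mode multiplies the negative-control fraction among
    confident decodes by the subset-size factor n_synth/n_nc (15 for
    3840/256), exact under the assumption that mistaking any barcode
    for any other is equally likely. Corrected mode replaces the flat
    factor by one that reweights each potential error target by source
    abundance and an edit-distance kernel exp(-lam * Levenshtein);
    this is a documented approximation for non-uniform pools, not an
    exact bias correction.
    """
    if n_nc <= 0:
        raise ValueError("the design must contain negative controls")
    recovered_m, _, nc_m = _classify(results, threshold)
    recovered = int(recovered_m.sum())
    nc_hits = int(nc_m.sum())
    denom = recovered + nc_hits
    if denom == 0:
        return 0.0
    nc_frac = nc_hits / denom
    if mode == "uniform":
        return 100.0 * nc_frac * (n_synth / n_nc)
    if mode != "corrected":
        raise ValueError(f"unknown mode {mode!r}")
    if barcodes is None:
        raise ValueError("corrected mode needs the barcode set")
    import edlib as _edlib

    synth = [bc for bc in barcodes if bc.status == "synthesized"]
    ncs = [bc for bc in barcodes if bc.status == "negative_control"]
    if abundances is None:
        counts = results[recovered_m]["barcode_id"].value_counts()
        abundances = {bc.id: counts.get(bc.id, 0) + 0.5 for bc in synth}
    rng = rng or np.random.default_rng(0)
    sources = synth
    if len(sources) > max_sources:
        idx = rng.choice(len(sources), size=max_sources, replace=False)
        sources = [sources[i] for i in idx]
    weight_to = {"synth": 0.0, "nc": 0.0}
    for src in sources:
        a = abundances.get(src.id, 0.0)
        if a <= 0:
            continue
        for group, targets in (("synth", synth), ("nc", ncs)):
            for tgt in targets:
                if tgt.id == src.id:
                    continue
                d = _edlib.align(src.sequence, tgt.sequence, mode="NW",
                                 task="distance")["editDistance"]
                weight_to[group] += a * math.exp(-lam * d)
    if weight_to["nc"] == 0:
        return 100.0 * nc_frac * (n_synth / n_nc)
    factor = weight_to["synth"] / weight_to["nc"]
    return 100.0 * nc_frac * factor


def sweep_thresholds(
    results: pd.DataFrame,
    truth: pd.DataFrame | None = None,
    max_grid: int = 10_000,
    n_synth: int = 3840,
    n_negative_controls: int = 256,
) -> pd.DataFrame:
    """Recovery/crosstalk trade-off over a grid of confidence thresholds.

    The grid is every distinct observed log10 L (quantiles beyond
    ``max_grid`` values), preceded by an unthresholded point; recovery
    is monotone non-increasing along the sweep.
    """
    logl = results.loc[results["status"] == "decoded", "log10_L"].astype(float)
    values = np.unique(logl.to_numpy())
    if values.size > max_grid:
        values = np.unique(np.quantile(values, np.linspace(0, 1, 1000)))
    grid = [None] + list(values)
    rows = []
    for thr in grid:
        m = compute_metrics(
            results, truth, thr, n_synth=n_synth,
            n_negative_controls=n_negative_controls,
        )
        rows.append(
            {
                "threshold": -math.inf if thr is None else thr,
                "recovery_rate": m.recovery_rate,
                "crosstalk_rate": m.crosstalk_rate,
                "nc_crosstalk_estimate": m.nc_crosstalk_estimate,
                "recovered": m.recovered,
                "misassigned": m.misassigned,
            }
        )
    return pd.DataFrame(rows)
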