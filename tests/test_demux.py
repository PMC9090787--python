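"""Demultiplexing pipeline: filtering, anchors, windows, rates, metrics."""

import math

import edlib
import numpy as np
import pandas as pd
import pytest

from nswatermark.channel import ChannelParams, SimConfig, simulate_run
from nswatermark.constructs import anchor_strings, reverse_complement
from nswatermark.demux import (
    AnchorHit,
    DemuxConfig,
    Demultiplexer,
    bounds_from_peaks,
    collapse_overlapping_hits,
    compute_metrics,
    demux_read,
    estimate_crosstalk_negative_controls,
    estimate_error_rates,
    extract_subread,
    find_anchors,
    length_filter,
    sweep_thresholds,
)


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# -- length filter ---------------------------------------------------------


def test_length_filter_boundaries_inclusive():
    reads = [("a", "A" * 530), ("b", "A" * 531), ("c", "A" * 814), ("d", "A" * 815)]
    kept = {r[0] for r in length_filter(reads, (531, 814))}
    assert kept == {"b", "c"}
    assert length_filter([], (531, 814)) == []


def test_bounds_from_read_length_peaks():
    assert bounds_from_peaks(590, 740) == (531, 814)


# -- anchor search ---------------------------------------------------------


def test_find_anchors_exact_copy(anchor_a):
    read = _random_seq(200, 1) + anchor_a + _random_seq(100, 2)
    hits = [h for h in find_anchors(("r", read)) if h.edit_distance == 0]
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end) == (200, 200 + len(anchor_a))
    assert h.sense == "forward"
    assert read[h.start : h.end] == anchor_a


def test_find_anchors_respects_distance_cutoff(anchor_a):
    """An anchor copy 13 edits away is not reported at threshold 12."""
    mutated = list(anchor_a)
    for i in range(13):
        pos = 3 * i + 1
        mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
    mutated = "".join(mutated)
    assert edlib.align(anchor_a, mutated, mode="NW", task="distance")["editDistance"] == 13
    read = _random_seq(150, 3) + mutated + _random_seq(150, 4)
    hits = find_anchors(("r", read), {"a": anchor_a}, max_distance=12)
    assert all(
        not (140 < h.start < 220) for h in hits
    )  # nothing at the mutated site


def test_find_anchors_reverse_complement_symmetry(anchor_a):
    read = _random_seq(120, 5) + anchor_a + _random_seq(80, 6)
    fwd = [h for h in find_anchors(("r", read), {"a": anchor_a}) if h.edit_distance == 0]
    rc_hits = [
        h
        for h in find_anchors(("r", reverse_complement(read)), {"a": anchor_a})
        if h.edit_distance == 0
    ]
    assert len(fwd) == 1 and len(rc_hits) == 1
    assert fwd[0].sense == "forward" and rc_hits[0].sense == "reverse"
    assert rc_hits[0].edit_distance == fwd[0].edit_distance
    n = len(read)
    assert (rc_hits[0].start, rc_hits[0].end) == (n - fwd[0].end, n - fwd[0].start)


def test_collapse_overlapping_hits_prefers_lower_distance():
    a = AnchorHit("padCSA-A-FPA", "forward", 2, 100, 144)
    b = AnchorHit("padCSA-A-RPA", "forward", 11, 100, 141)
    c = AnchorHit("padCSA-A-RPA", "forward", 3, 400, 444)
    kept = collapse_overlapping_hits([a, b, c])
    assert {(h.anchor_name, h.start) for h in kept} == {
        ("padCSA-A-FPA", 100),
        ("padCSA-A-RPA", 400),
    }


# -- subread extraction ----------------------------------------------------


def test_extract_subread_forward_window():
    read = ("r", _random_seq(500, 7))
    hit = AnchorHit("padCSA-A-FPA", "forward", 0, 200, 244)
    sub = extract_subread(read, hit, DemuxConfig())
    assert len(sub.sequence) == 117  # 61 + 56, half-open
    assert sub.sequence == read[1][139:256]
    assert not sub.truncated


def test_extract_subread_reverse_window_contains_anchor(anchor_a, spec):
    bc = spec.barcode(99).sequence
    segment = bc + anchor_a
    read_seq = _random_seq(150, 8) + reverse_complement(segment) + _random_seq(150, 9)
    hits = [h for h in find_anchors(("r", read_seq), {"a": anchor_a})
            if h.sense == "reverse" and h.edit_distance == 0]
    assert len(hits) == 1
    sub = extract_subread(("r", read_seq), hits[0], DemuxConfig())
    # forward-oriented: barcode immediately upstream of the anchor,
    # anchor starting 56 nt before the subread end
    pos = len(sub.sequence) - 56
    assert sub.sequence[pos : pos + len(anchor_a)] == anchor_a
    assert sub.sequence[pos - 36 : pos] == bc


def test_extract_subread_truncation_flagged():
    read = ("r", _random_seq(300, 10))
    hit = AnchorHit("padCSA-A-FPA", "forward", 0, 10, 54)
    sub = extract_subread(read, hit, DemuxConfig())
    assert sub.truncated
    assert len(sub.sequence) == 10 + 56


# -- channel-rate estimation ----------------------------------------------


def test_estimate_error_rates_counting_convention():
    perfect = AnchorHit("a", "forward", 0, 0, 44, cigar="44=")
    est = estimate_error_rates([perfect])
    assert (est.P_s, est.P_i, est.P_d) == (0, 0, 0)
    # 16 matches, 1 mismatch, 2 read insertions (edlib D), 1 template
    # deletion (edlib I): template-consuming denominator = 18
    mixed = AnchorHit("a", "forward", 4, 0, 19, cigar="16=1X2D1I")
    est = estimate_error_rates([mixed])
    assert est.P_s == pytest.approx(1 / 18)
    assert est.P_i == pytest.approx(2 / 18)
    assert est.P_d == pytest.approx(1 / 18)
    with pytest.raises(ValueError):
        estimate_error_rates([])


def test_estimate_error_rates_recovers_simulated_channel(validation_run):
    """Aggregated CIGAR estimates land near the simulated 5% rates.

    Alignment-derived rates are biased slightly low (boundary indels are
    absorbed by the free end gaps and adjacent ins+del pairs collapse
    into substitutions), so the tolerance is wider than sampling noise.
    """
    est = validation_run["channel_estimate"]
    for got in (est.P_s, est.P_i, est.P_d):
        assert abs(got - 0.05) < 0.012


# -- per-read decoding and metrics ----------------------------------------


def test_demux_read_noiseless_matches_truth(spec, barcode_set):
    config = SimConfig(n_reads=6, channel=ChannelParams(0, 0, 0), seed=21)
    reads, truth = simulate_run(spec, config, barcodes=barcode_set)
    ch = ChannelParams(0, 0, 0)
    for read, row in zip(reads, truth.itertuples()):
        results = demux_read(read, spec, DemuxConfig(), ch)
        assert len(results) == 2
        by_end = {r["end"]: r for r in results}
        assert by_end["5p"]["barcode_id"] == row.bc5_id
        assert by_end["3p"]["barcode_id"] == row.bc3_id


def test_demux_read_without_anchors_reports_nothing(spec):
    assert demux_read(("r", _random_seq(600, 22)), spec, DemuxConfig(),
                      ChannelParams(0.03, 0.03, 0.03)) == []


def _toy_results(considered, recovered, misassigned=0, nc=0, failed=None):
    """Assignments table with prescribed outcome counts."""
    failed = considered - recovered - nc if failed is None else failed
    rows = []
    for i in range(considered):
        if i < recovered:
            status, bid, is_nc = "decoded", (1 if i < misassigned else 0), False
        elif i < recovered + nc:
            status, bid, is_nc = "decoded", 4000, True
        else:
            status, bid, is_nc = "failed", None, False
        rows.append(
            {
                "read_id": f"r{i}",
                "end": "5p",
                "status": status,
                "barcode_id": bid,
                "log10_L": -1.0 if status == "decoded" else None,
                "is_negative_control": is_nc,
                "pool": "A" if bid == 0 else "B",
            }
        )
    truth = pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(considered)],
            "pool": "A",
            "bc5_id": 0,
            "bc3_id": 0,
            "strand": "+",
        }
    )
    return pd.DataFrame(rows), truth


def test_compute_metrics_headline_arithmetic():
    results, truth = _toy_results(1000, 864)
    m = compute_metrics(results, truth)
    assert m.recovery_rate == pytest.approx(86.4)
    results, truth = _toy_results(600, 584, misassigned=1)
    m = compute_metrics(results, truth)
    assert m.crosstalk_rate == pytest.approx(100 / 584)  # ~0.17%


def test_compute_metrics_zero_recovered_undefined_crosstalk():
    results, truth = _toy_results(10, 0)
    m = compute_metrics(results, truth)
    assert m.recovered == 0
    assert m.crosstalk_rate is None


def test_negative_control_estimator_arithmetic():
    results, _ = _toy_results(1100, 998, nc=2)
    est = estimate_crosstalk_negative_controls(results, n_synth=3840, n_nc=256)
    assert est == pytest.approx(0.2 * 15)  # 2/1000 x 3840/256
    results, _ = _toy_results(1100, 1000, nc=0)
    assert estimate_crosstalk_negative_controls(results) == 0.0
    with pytest.raises(ValueError):
        estimate_crosstalk_negative_controls(results, n_nc=0)


def test_negative_control_estimator_corrected_mode(barcode_set):
    """With a flat distance kernel and uniform abundances the corrected
    factor collapses to the uniform subset-size factor."""
    results, _ = _toy_results(1100, 998, nc=2)
    uniform_ab = {b.id: 1.0 for b in barcode_set if b.status == "synthesized"}
    est = estimate_crosstalk_negative_controls(
        results, mode="corrected", barcodes=barcode_set,
        abundances=uniform_ab, lam=0.0, max_sources=32,
    )
    assert est == pytest.approx(0.2 * (3839 / 256), rel=0.02)


def test_conservation_is_exact(validation_run):
    """considered = recovered + failed + below-threshold + nc, exactly,
    at any threshold."""
    results = validation_run["results"]
    for thr in (None, -3.0, -1.5, -0.5, 0.0):
        m = compute_metrics(results, validation_run["truth"], thr)
        assert (
            m.considered_subreads
            == m.recovered + m.decoder_failed + m.below_threshold
            + m.negative_control_hits
        )


def test_sweep_reproduces_unthresholded_point_and_improves_crosstalk(
    validation_run,
):
    results, truth = validation_run["results"], validation_run["truth"]
    curve = sweep_thresholds(results, truth)
    m0 = compute_metrics(results, truth)
    first = curve.iloc[0]
    assert first["threshold"] == -math.inf
    assert first["recovery_rate"] == pytest.approx(m0.recovery_rate)
    assert first["crosstalk_rate"] == pytest.approx(m0.crosstalk_rate)
    # confidence is informative: some threshold strictly reduces crosstalk
    valid = curve["crosstalk_rate"].notna()
    assert (curve.loc[valid, "crosstalk_rate"] < m0.crosstalk_rate).any()


def test_anchor_set_has_four_anchors_both_pools():
    anchors = anchor_strings()
    assert len(anchors) == 4
    assert {n[-3:] for n in anchors} == {"FPA", "RPA", "FPB", "RPB"}
    assert all(a.startswith(("CGC", "GCG")) for a in anchors.values())
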