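import numpy as np
import pytest

from nswatermark.channel import ChannelParams, SimConfig, simulate_run
from nswatermark.code import default_spec, generate_barcode_set
from nswatermark.constructs import POOLS
from nswatermark.demux import Demultiplexer, DemuxConfig


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def barcode_set(spec):
    return generate_barcode_set(spec, n_synth=3840, split_seed=0)


@pytest.fixture(scope="session")
def anchor_a():
    return POOLS["A"].anchor_fp


@pytest.fixture(scope="session")
def window_factory(spec, anchor_a):
    """Build a clean decoding window for a barcode id: 25 nt of upstream
    slack, the 36-nt barcode, the pool-A FP anchor, and 12 nt of insert,
    mirroring the -61/+56 extraction geometry."""

    def make(barcode_id: int, slack: str = "A" * 25, tail: str = "ACGTACGTACGT"):
        return slack + spec.barcode(barcode_id).sequence + anchor_a + tail

    return make


@pytest.fixture(scope="session")
def validation_run(spec, barcode_set):
    """Simulated validation run for estimator and threshold checks:
    2500 reads at 5% substitution/insertion/deletion rates with uniform
    barcode abundances (the uniformity assumption behind the
    negative-control estimator), demultiplexed end to end."""
    config = SimConfig(
        n_reads=2500,
        channel=ChannelParams(0.05, 0.05, 0.05),
        abundance_sigma=0.0,
        seed=11,
    )
    reads, truth = simulate_run(spec, config, barcodes=barcode_set)
    dm = Demultiplexer(spec, DemuxConfig(), barcode_set)
    results, channel = dm.run(reads)
    return {
        "reads": reads,
        "truth": truth,
        "results": results,
        "channel_estimate": channel,
        "config": config,
    }
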