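import numpy as np
import pytest

from turf.features import TISSUE_MARKS, AnnotationBundle
from turf.genomic import GenomicInterval, IntervalIndex, SignalTrack, Variant


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_bundle():
    """Hand-built biosample bundle with one active window on chr1:[1000, 2000)."""
    b = AnnotationBundle(biosample="bs1")
    b.tf_peaks["CTCF"] = IntervalIndex([GenomicInterval("chr1", 1000, 2000, "CTCF")])
    b.dnase_peaks = IntervalIndex([GenomicInterval("chr1", 1000, 2000, "DNase")])
    b.footprints = IntervalIndex([GenomicInterval("chr1", 1400, 1450, "fp")])
    for mark in TISSUE_MARKS:
        b.histone_peaks[mark] = IntervalIndex([GenomicInterval("chr1", 1000, 2000, mark)])
    b.chip_signals = [SignalTrack([("chr1", 1000, 2000, 3.0)], dataset="chip1")]
    b.dnase_signals = [SignalTrack([("chr1", 1000, 2000, 1.5)], dataset="dnase1")]
    return b


@pytest.fixture
def inside_variant():
    return Variant("chr1", 1420, "A", "G", "rs_in")


@pytest.fixture
def outside_variant():
    return Variant("chr1", 5000, "C", "T", "rs_out")
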