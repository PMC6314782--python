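import numpy as np
import pytest

from oriterm.genomic_io import (
    GenomeLayout,
    Interval,
    StrandedTrack,
    bundled_origin_table,
    read_origin_table,
)
from oriterm.origin_model import OriginRecord


@pytest.fixture(scope="session")
def fixture_records():
    """The bundled 228-origin ACS coordinate table."""
    return read_origin_table(bundled_origin_table())


@pytest.fixture
def toy_layout():
    return GenomeLayout.from_dict({"chrT": 1000})


def make_origin(anchor, strand="+", chrom="chrT", length=17, oid="o1",
                secondary_anchor=None):
    """Build an origin record from its 5' anchor (0-based)."""
    if strand == "+":
        primary = Interval(chrom, anchor, anchor + length, "+")
    else:
        primary = Interval(chrom, anchor - length + 1, anchor + 1, "-")
    secondary = None
    if secondary_anchor is not None:
        if strand == "+":
            secondary = Interval(chrom, secondary_anchor - length + 1,
                                 secondary_anchor + 1, "-")
        else:
            secondary = Interval(chrom, secondary_anchor,
                                 secondary_anchor + length, "+")
    return OriginRecord(id=oid, primary_acs=primary, secondary_acs=secondary)


def random_track(layout, rng, rate=1.0, integer=True):
    track = StrandedTrack.zeros(layout)
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        for strand in "+-":
            vals = rng.poisson(rate, size=length).astype(float)
            track.data[chrom][strand] = vals
    return track
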