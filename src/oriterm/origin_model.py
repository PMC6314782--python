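"""Oriented origin records and origin-relative coordinate mapping.

An origin is oriented by the T-rich strand of its primary ACS.  Relative
position 0 is the first (5'-most) base of the ACS match on its own strand;
"upstream of the ACS" means negative relative positions.  Transcription along
the T-rich strand is *sense*; transcription on the opposite strand is
*antisense*.  A secondary, oppositely oriented ACS may be attached; its
anchor lies at a positive relative position (the "protected length" between
the two 5' ends).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genomic_io import Interval, StrandedTrack

__all__ = ["OriginRecord", "RelativeWindow", "orient", "to_genomic", "extract_window"]

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class OriginRecord:
    """An oriented replication origin anchored at its primary ACS 5' end."""

    id: str
    primary_acs: Interval
    primary_match: Optional[str] = None
    primary_score: Optional[float] = None
    secondary_acs: Optional[Interval] = None
    secondary_match: Optional[str] = None
    secondary_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.secondary_acs is not None:
            if self.secondary_acs.strand == self.primary_acs.strand:
                raise ValueError(
                    f"origin {self.id}: secondary ACS must lie on the strand "
                    "opposite the primary ACS"
                )
            if self.distance <= 0:
                raise ValueError(f"origin {self.id}: non-positive ACS distance")

    @property
    def chrom(self) -> str:
        return self.primary_acs.chrom

    @property
    def strand(self) -> str:
        return self.primary_acs.strand

    @property
    def anchor(self) -> int:
        """0-based genomic position of the primary ACS 5' end (rel_pos 0)."""
        return self.primary_acs.five_prime()

    @property
    def secondary_anchor(self) -> Optional[int]:
        if self.secondary_acs is None:
            return None
        return self.secondary_acs.five_prime()

    @property
    def distance(self) -> Optional[int]:
        """5'-to-5' distance between primary and secondary ACS (bp)."""
        if self.secondary_acs is None:
            return None
        return abs(self.anchor - self.secondary_acs.five_prime())


@dataclass(frozen=True)
class RelativeWindow:
    """Origin-relative window: positions -upstream .. downstream-1."""

    upstream: int
    downstream: int

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 1:
            raise ValueError("need upstream >= 0 and downstream >= 1")

    def __len__(self) -> int:
        return self.upstream + self.downstream

    def rel_positions(self) -> np.ndarray:
        return np.arange(-self.upstream, self.downstream)


def orient(
    record: OriginRecord,
    genomic_pos: int,
    genomic_strand: str,
    chrom: Optional[str] = None,
) -> tuple[int, str]:
    """Map a genomic (position, strand) into origin-relative coordinates.

    Returns ``(rel_pos, direction)`` where direction is ``"sense"`` when the
    genomic strand matches the origin's T-rich strand.
    """
    if chrom is not None and chrom != record.chrom:
        raise ValueError(
            f"chromosome mismatch: {chrom!r} vs origin on {record.chrom!r}"
        )
    if record.strand == "+":
        rel = genomic_pos - record.anchor
    else:
        rel = record.anchor - genomic_pos
    direction = SENSE if genomic_strand == record.strand else ANTISENSE
    return rel, direction


def to_genomic(record: OriginRecord, rel_pos: int, direction: str) -> tuple[int, str]:
    """Inverse of :func:`orient`."""
    if record.strand == "+":
        pos = record.anchor + rel_pos
        strand = "+" if direction == SENSE else "-"
    else:
        pos = record.anchor - rel_pos
        strand = "-" if direction == SENSE else "+"
    return pos, strand


def extract_window(
    track: StrandedTrack, record: OriginRecord, window: RelativeWindow
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the origin-relative (sense, antisense) signal vectors.

    Vectors are indexed by rel_pos (-upstream .. downstream-1).  Positions
    overhanging a chromosome end are NaN so that downstream aggregation can
    exclude them rather than treat them as zero signal.
    """
    chrom_len = track.layout.length(record.chrom)
    width = len(window)
    sense = np.full(width, np.nan)
    antisense = np.full(width, np.nan)

    if record.strand == "+":
        g_lo = record.anchor - window.upstream
        g_hi = record.anchor + window.downstream
        lo, hi = max(g_lo, 0), min(g_hi, chrom_len)
        if lo < hi:
            sl = slice(lo - g_lo, hi - g_lo)
            sense[sl] = track.values(record.chrom, "+")[lo:hi]
            antisense[sl] = track.values(record.chrom, "-")[lo:hi]
    else:
        # rel r maps to genomic anchor - r; window occupies
        # [anchor - downstream + 1, anchor + upstream] and is reversed.
        g_lo = record.anchor - window.downstream + 1
        g_hi = record.anchor + window.upstream + 1
        lo, hi = max(g_lo, 0), min(g_hi, chrom_len)
        if lo < hi:
            # genomic index p -> rel = anchor - p -> array index upstream + rel
            plus = track.values(record.chrom, "+")[lo:hi][::-1]
            minus = track.values(record.chrom, "-")[lo:hi][::-1]
            i_lo = window.upstream + (record.anchor - (hi - 1))
            sl = slice(i_lo, i_lo + (hi - lo))
            sense[sl] = minus
            antisense[sl] = plus
    return sense, antisense
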