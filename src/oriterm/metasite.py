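"""Metasite aggregation and positional termination statistics.

Two aggregates over origin-aligned windows are supported:

* ``median_occupancy`` — the per-position median of polymerase occupancy
  across origins, the robust summary used for RNAPII metaprofiles.
* ``endsite_origin_count`` — the per-position number of origins showing at
  least one polyadenylated RNA 3'-end, i.e. presence/absence of a
  termination event scored independently of read depth.  This keeps a few
  heavily transcribed loci from dominating the aggregate and makes the
  profile invariant under rescaling of the counts.

The positional test asks, for each position, whether termination events are
observed at more origins than expected under a null in which termination
occurs at a uniform baseline frequency.  The baseline is estimated from a
100-nt window far upstream of the anchor (default centred start at -500).
For an observed count k out of n informative origins the raw p-value is the
inclusive upper binomial tail P[Bin(n, p0) >= k]; Bonferroni correction
multiplies by the number of positions tested in that direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genomic_io import StrandedTrack
from .origin_model import OriginRecord, RelativeWindow, extract_window

__all__ = [
    "MetaProfile",
    "TerminationTest",
    "median_profile",
    "endsite_profile",
    "termination_significance",
]

MEDIAN_OCCUPANCY = "median_occupancy"
ENDSITE_ORIGIN_COUNT = "endsite_origin_count"


@dataclass
class MetaProfile:
    """Per-relative-position aggregate for sense and antisense directions."""

    rel_positions: np.ndarray
    sense_values: np.ndarray
    antisense_values: np.ndarray
    n_origins: np.ndarray  # informative (non-missing) origins per position
    statistic: str

    def __post_init__(self) -> None:
        n = len(self.rel_positions)
        for arr in (self.sense_values, self.antisense_values, self.n_origins):
            if len(arr) != n:
                raise ValueError("profile arrays must share one length")
        if self.statistic == ENDSITE_ORIGIN_COUNT:
            for vals in (self.sense_values, self.antisense_values):
                ok = np.isnan(vals) | (
                    (vals >= 0) & (vals <= self.n_origins) & (vals == np.floor(vals))
                )
                if not ok.all():
                    raise ValueError("end-site counts must be integers in [0, n]")

    def index_of(self, rel_pos: int) -> int:
        idx = np.flatnonzero(self.rel_positions == rel_pos)
        if idx.size != 1:
            raise KeyError(f"relative position {rel_pos} not in profile")
        return int(idx[0])

    def direction_values(self, direction: str) -> np.ndarray:
        if direction == "sense":
            return self.sense_values
        if direction == "antisense":
            return self.antisense_values
        raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class TerminationTest:
    """Binomial enrichment test of termination events at one position."""

    rel_pos: int
    direction: str
    k: int          # origins with >= 1 end at this position
    n: int          # informative origins at this position
    p0: float       # baseline per-position termination frequency
    p_raw: float
    p_corrected: float
    n_tests: int
    degenerate: bool = False


def _stacked_windows(
    track: StrandedTrack, origins: list[OriginRecord], window: RelativeWindow
) -> tuple[np.ndarray, np.ndarray]:
    if not origins:
        raise ValueError("need at least one origin")
    sense = np.empty((len(origins), len(window)))
    anti = np.empty((len(origins), len(window)))
    for i, rec in enumerate(origins):
        sense[i], anti[i] = extract_window(track, rec, window)
    return sense, anti


def median_profile(
    track: StrandedTrack, origins: list[OriginRecord], window: RelativeWindow
) -> MetaProfile:
    """Median occupancy across origins at every relative position."""
    sense, anti = _stacked_windows(track, origins, window)
    n = np.sum(~np.isnan(sense), axis=0)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "All-NaN slice")
        med_s = np.nanmedian(sense, axis=0)
        med_a = np.nanmedian(anti, axis=0)
    return MetaProfile(window.rel_positions(), med_s, med_a, n, MEDIAN_OCCUPANCY)


def endsite_profile(
    ends: StrandedTrack, origins: list[OriginRecord], window: RelativeWindow
) -> MetaProfile:
    """Number of origins with at least one RNA 3'-end at every position.

    Scale-invariant: multiplying all counts by any positive factor leaves
    the profile unchanged.
    """
    sense, anti = _stacked_windows(ends, origins, window)
    n = np.sum(~np.isnan(sense), axis=0)
    cnt_s = np.nansum(sense > 0, axis=0).astype(float)
    cnt_a = np.nansum(anti > 0, axis=0).astype(float)
    return MetaProfile(window.rel_positions(), cnt_s, cnt_a, n, ENDSITE_ORIGIN_COUNT)


def termination_significance(
    profile: MetaProfile,
    direction: str = "sense",
    null_window_center: int = -500,
    null_window_width: int = 100,
    test_positions: np.ndarray | None = None,
) -> list[TerminationTest]:
    """Test every position for termination-event enrichment over a flat null.

    The null frequency p0 is the aggregate event frequency in the
    ``null_window_width`` positions starting at ``null_window_center``.
    Tested positions default to the whole profile minus the null window;
    each direction is tested separately with its own multiple-testing factor.
    """
    if profile.statistic != ENDSITE_ORIGIN_COUNT:
        raise ValueError("termination test requires an end-site count profile")
    values = profile.direction_values(direction)
    rel = profile.rel_positions

    null_lo = null_window_center
    null_hi = null_window_center + null_window_width
    in_null = (rel >= null_lo) & (rel < null_hi)
    if in_null.sum() != null_window_width:
        raise ValueError(
            f"null window [{null_lo}, {null_hi}) not fully inside profile"
        )
    null_k = np.nansum(values[in_null])
    null_n = profile.n_origins[in_null].sum()
    if null_n == 0:
        raise ValueError("no informative origins in the null window")
    p0 = float(null_k / null_n)

    if test_positions is None:
        tested_mask = ~in_null
    else:
        tested_mask = np.isin(rel, np.asarray(test_positions))
    tested_idx = np.flatnonzero(tested_mask & (profile.n_origins > 0))
    m = int(tested_idx.size)

    k_arr = values[tested_idx].astype(int)
    n_arr = profile.n_origins[tested_idx].astype(int)
    if p0 > 0.0:
        # inclusive upper tail: P[Bin(n, p0) >= k]
        p_raw_arr = stats.binom.sf(k_arr - 1, n_arr, p0)
    else:
        p_raw_arr = np.where(k_arr == 0, 1.0, 0.0)

    results = []
    for i, k, n, p_raw in zip(tested_idx, k_arr, n_arr, p_raw_arr):
        k, n, p_raw = int(k), int(n), float(p_raw)
        degenerate = p0 == 0.0 and k > 0
        if k == 0:
            p_raw = 1.0
        results.append(
            TerminationTest(
                rel_pos=int(rel[i]), direction=direction, k=k, n=n, p0=p0,
                p_raw=p_raw, p_corrected=min(1.0, p_raw * m), n_tests=m,
                degenerate=degenerate,
            )
        )
    return results
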