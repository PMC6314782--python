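"""Relating intra-origin pervasive transcription to licensing and firing.

Per origin, transcription is quantified over named origin-relative regions:

* region B — the "area of origin activity", by default the protected span
  between the primary and secondary ACS 5' ends (relative positions 0..d
  inclusive), summed separately along the sense (B_a) and antisense (B_as)
  strands; region_B = B_a + B_as.
* region A — the 200 bp immediately 5' of B, summed on the sense strand
  (transcription incoming toward the primary ACS).
* region C — the 200 bp immediately 3' of B, summed on the antisense strand
  (transcription incoming toward the secondary ACS).
* ACS-start window — both-strand sum over the first 100 nt starting at the
  primary ACS 5' end, used for ranking origins by internal transcription.

Replication metrics are per-origin probabilities of licensing (P_L) and
firing (P_F) plus the median firing time T_half; the conditional firing
probability is P_F|L = P_F / P_L.  Group comparisons use the classical
pooled-variance two-sample t-test; trend tests use ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import StrandedTrack
from .origin_model import OriginRecord, RelativeWindow, extract_window

__all__ = [
    "TranscriptionQuant",
    "GroupComparison",
    "RegressionResult",
    "quantify",
    "quants_frame",
    "rank_and_compare",
    "conditional_firing",
    "partition_classes",
    "regress",
    "select_high_incoming",
    "read_metrics_table",
    "write_metrics_table",
]

logger = logging.getLogger(__name__)

FLANK = 200        # bp of regions A and C
ACS_WINDOW = 100  # bp of the ranking window


@dataclass(frozen=True)
class TranscriptionQuant:
    """Summed reads over the origin-relative regions of one origin."""

    origin_id: str
    region_A: float
    region_C: float
    region_Ba: float
    region_Bas: float
    acs_window: float
    b_length: int

    def __post_init__(self) -> None:
        for name in ("region_A", "region_C", "region_Ba", "region_Bas",
                     "acs_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def region_B(self) -> float:
        return self.region_Ba + self.region_Bas


@dataclass(frozen=True)
class GroupComparison:
    """Pooled-variance two-sample t-test between two origin groups."""

    n_top: int
    n_rest: int
    median_top: float
    median_rest: float
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares of a replication metric on transcription."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def quantify(
    track: StrandedTrack,
    origins: Sequence[OriginRecord],
    activity_area: Union[str, int] = "protected",
) -> list[TranscriptionQuant]:
    """Sum reads over regions A, B (Ba/Bas), C and the ACS-start window.

    ``activity_area="protected"`` takes region B as the span between the two
    ACS anchors inclusive (origins lacking a secondary ACS are skipped with a
    warning); an integer takes a fixed B length from the primary anchor.
    """
    out = []
    for rec in origins:
        if activity_area == "protected":
            if rec.secondary_acs is None:
                logger.warning(
                    "origin %s has no secondary ACS; skipped in protected mode",
                    rec.id,
                )
                continue
            b_len = rec.distance + 1  # anchors inclusive
        else:
            b_len = int(activity_area)
            if b_len < 1:
                raise ValueError("fixed activity area must be >= 1 bp")
        window = RelativeWindow(upstream=FLANK, downstream=b_len + FLANK)
        sense, anti = extract_window(track, rec, window)
        idx0 = FLANK  # array index of rel_pos 0
        a_sum = np.nansum(sense[:idx0])
        ba = np.nansum(sense[idx0 : idx0 + b_len])
        bas = np.nansum(anti[idx0 : idx0 + b_len])
        c_sum = np.nansum(anti[idx0 + b_len : idx0 + b_len + FLANK])
        acs_win = np.nansum(sense[idx0 : idx0 + ACS_WINDOW]) + np.nansum(
            anti[idx0 : idx0 + ACS_WINDOW]
        )
        out.append(
            TranscriptionQuant(
                origin_id=rec.id,
                region_A=float(a_sum),
                region_C=float(c_sum),
                region_Ba=float(ba),
                region_Bas=float(bas),
                acs_window=float(acs_win),
                b_length=b_len,
            )
        )
    return out


def quants_frame(quants: Sequence[TranscriptionQuant]) -> pd.DataFrame:
    """Tabulate quantifications (one row per origin)."""
    return pd.DataFrame(
        {
            "origin_id": [q.origin_id for q in quants],
            "region_A": [q.region_A for q in quants],
            "region_C": [q.region_C for q in quants],
            "region_Ba": [q.region_Ba for q in quants],
            "region_Bas": [q.region_Bas for q in quants],
            "region_B": [q.region_B for q in quants],
            "acs_window": [q.acs_window for q in quants],
            "b_length": [q.b_length for q in quants],
        }
    )


def rank_and_compare(
    quants: Sequence[TranscriptionQuant],
    metrics: pd.DataFrame,
    key: str = "acs_window",
    top_n: int = 30,
    metric: str = "P_L",
) -> GroupComparison:
    """Compare a replication metric between the most-transcribed origins and
    the rest of the population.

    Origins are ranked by ``key`` descending (ties broken by origin id); the
    ``top_n`` most transcribed form one group, the remainder the other, and
    the two metric distributions are compared by an unpaired, equal-variance,
    two-tailed t-test.  Origins missing from either table are dropped.
    """
    qdf = quants_frame(quants)
    joined = qdf.merge(metrics, on="origin_id", how="inner")
    dropped = len(qdf) - len(joined)
    if dropped:
        logger.info("rank_and_compare: %d origins lacked metrics", dropped)
    if top_n >= len(joined):
        raise ValueError(
            f"top_n={top_n} must be smaller than the joined population "
            f"({len(joined)})"
        )
    joined = joined.sort_values([key, "origin_id"], ascending=[False, True])
    top = joined[metric].to_numpy()[:top_n]
    rest = joined[metric].to_numpy()[top_n:]
    t, p = stats.ttest_ind(top, rest, equal_var=True)
    if np.isnan(t):  # zero pooled variance: identical constant groups
        t, p = 0.0, 1.0
    return GroupComparison(
        n_top=len(top), n_rest=len(rest),
        median_top=float(np.median(top)), median_rest=float(np.median(rest)),
        t_statistic=float(t), p_value=float(p),
    )


def conditional_firing(metrics: pd.DataFrame) -> pd.DataFrame:
    """Append the conditional firing probability P_F|L = P_F / P_L.

    Origins with P_L = 0 are excluded with a warning; ratios above 1 are
    flagged as inconsistent (column ``pfl_inconsistent``) but returned.
    """
    zero = metrics["P_L"] == 0
    if zero.any():
        for oid in metrics.loc[zero, "origin_id"]:
            logger.warning("origin %s: P_L = 0, P_F|L undefined; excluded", oid)
    out = metrics.loc[~zero].copy()
    out["P_F_L"] = out["P_F"] / out["P_L"]
    out["pfl_inconsistent"] = out["P_F_L"] > 1.0
    return out


def partition_classes(
    metrics: pd.DataFrame, threshold: float = 0.9
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split origins into high- and low-P_F|L classes at a threshold.

    The high class fires near-deterministically once licensed; the low class
    fires inefficiently even when licensed.
    """
    if "P_F_L" not in metrics.columns:
        metrics = conditional_firing(metrics)
    high = metrics[metrics["P_F_L"] >= threshold]
    low = metrics[metrics["P_F_L"] < threshold]
    return high, low


def regress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on x with the slope's two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )


def select_high_incoming(
    quants: Sequence[TranscriptionQuant], min_reads: float = 10
) -> list[TranscriptionQuant]:
    """Keep origins exposed to incoming transcription on both flanks.

    The filter is strict: region_A > min_reads AND region_C > min_reads.
    """
    return [
        q for q in quants if q.region_A > min_reads and q.region_C > min_reads
    ]


def read_metrics_table(path) -> pd.DataFrame:
    """Read a per-origin replication-metrics TSV (origin_id, P_L, P_F, T_half)."""
    df = pd.read_csv(path, sep="\t", dtype={"origin_id": str})
    required = {"origin_id", "P_L", "P_F", "T_half"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metric columns {sorted(missing)}")
    for col in ("P_L", "P_F"):
        vals = df[col].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{path}: column {col} outside [0, 1]")
    return df


def write_metrics_table(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, sep="\t", index=False)
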