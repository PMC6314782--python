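"""Position-weight-matrix construction, scoring, and secondary-ACS scanning.

The ORC-binding ACS motif is summarised by a base-frequency matrix (4 rows
A,C,G,T by L columns).  The PWM stores per-base log2 odds against a uniform
background with a small pseudocount:

    weight(b, j) = log2( (freq(b, j) + pc * bg) / (1 + pc) / bg )

Raw scores are sums of weights over a window; they are min-max normalised to
[0, 1] using the column-wise attainable extremes, so 1.0 is the consensus
(column-wise argmax) sequence and 0.0 the anti-consensus.

A secondary ACS is predicted per origin as the best-scoring window on the
strand opposite the primary ACS whose own-strand 5' end lies 10-400 bp
downstream (in the sense direction) of the primary anchor; ties go to the
nearest window.  Distances below 70 or above 200 bp can be filtered before
meta-analysis, since such spacings are unlikely to accommodate the licensing
machinery.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .genomic_io import Interval
from .origin_model import OriginRecord

__all__ = [
    "FrequencyMatrix",
    "PwmModel",
    "AcsHit",
    "DistanceStats",
    "build_pwm",
    "score",
    "scan_secondary",
    "distance_stats",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class FrequencyMatrix:
    """4 x L matrix of per-column base probabilities (rows A, C, G, T)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError("frequency matrix must be 4 x L")
        if (probs < 0).any():
            raise ValueError("frequencies must be non-negative")
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("every column must sum to 1 (within 1e-9)")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


@dataclass(frozen=True)
class PwmModel:
    """Log2-odds weights plus attainable raw-score bounds for normalisation."""

    weights: np.ndarray  # 4 x L
    raw_min: float
    raw_max: float

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def degenerate(self) -> bool:
        return self.raw_max - self.raw_min <= 0.0


@dataclass(frozen=True)
class AcsHit:
    """Best secondary-ACS match for one origin."""

    origin_id: str
    interval: Interval          # opposite strand to the primary ACS
    anchor: int                 # 0-based own-strand 5' end
    norm_score: float
    distance: int               # primary anchor -> hit anchor (bp, > 0)
    match: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.norm_score <= 1.0:
            raise ValueError("normalised score outside [0, 1]")
        if self.distance <= 0:
            raise ValueError("hit distance must be positive")


def build_pwm(
    freq: FrequencyMatrix,
    pseudocount: float = 0.0025,
    background: float = 0.25,
) -> PwmModel:
    """Turn a frequency matrix into a log2-odds PWM with score bounds."""
    probs = freq.probs
    if np.any(probs.sum(axis=0) == 0):
        raise ValueError("zero column in frequency matrix")
    adjusted = (probs + pseudocount * background) / (1.0 + pseudocount)
    weights = np.log2(adjusted / background)
    raw_min = float(weights.min(axis=0).sum())
    raw_max = float(weights.max(axis=0).sum())
    return PwmModel(weights=weights, raw_min=raw_min, raw_max=raw_max)


def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3; any other symbol (e.g. N) to 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def score(model: PwmModel, seq: str, on_ambiguous: str = "error") -> Optional[float]:
    """Normalised [0, 1] PWM score of an L-length sequence.

    ``on_ambiguous="skip"`` returns None for windows containing non-ACGT
    symbols instead of raising.
    """
    seq = seq.upper()
    if len(seq) != model.length:
        raise ValueError(f"sequence length {len(seq)} != matrix length {model.length}")
    if model.degenerate:
        raise ValueError("degenerate model: raw_max equals raw_min")
    codes = _encode(seq)
    if (codes > 3).any():
        if on_ambiguous == "skip":
            return None
        raise ValueError(f"ambiguous base in {seq!r}")
    raw = float(model.weights[codes, np.arange(model.length)].sum())
    return (raw - model.raw_min) / (model.raw_max - model.raw_min)


def _window_scores(model: PwmModel, codes: np.ndarray) -> np.ndarray:
    """Normalised scores of every L-window of an encoded sequence (NaN if N)."""
    L = model.length
    if len(codes) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows <= 3).all(axis=1)
    raw = np.full(len(windows), np.nan)
    if valid.any():
        w = np.vstack((model.weights, np.zeros(L)))  # row 4 absorbs N codes
        raw[valid] = w[windows[valid], np.arange(L)].sum(axis=1)
    return (raw - model.raw_min) / (model.raw_max - model.raw_min)


def scan_secondary(
    model: PwmModel,
    genome: Mapping[str, str],
    origin: OriginRecord,
    range_start: int = 10,
    range_end: int = 400,
) -> Optional[AcsHit]:
    """Best opposite-strand ACS match 10-400 bp downstream of the primary.

    Candidate windows are those whose own-strand 5' end lies at relative
    positions ``range_start..range_end`` (sense direction downstream of the
    primary anchor).  Ties on score are broken by smallest distance; windows
    truncated by a chromosome end are skipped.  Returns None when no valid
    window exists.
    """
    if model.degenerate:
        raise ValueError("degenerate model: raw_max equals raw_min")
    chrom_seq = genome[origin.chrom]
    L = model.length
    anchor = origin.anchor
    n = len(chrom_seq)

    distances = np.arange(range_start, range_end + 1)
    if origin.strand == "+":
        # candidate on '-' strand, 5' end at genomic anchor + d,
        # occupying [p - L + 1, p + 1)
        p = anchor + distances
        starts = p - L + 1
        valid = (starts >= 0) & (p + 1 <= n)
    else:
        # candidate on '+' strand, 5' end at genomic anchor - d
        p = anchor - distances
        starts = p
        valid = (starts >= 0) & (starts + L <= n)
    if not valid.any():
        return None

    lo, hi = int(starts[valid].min()), int(starts[valid].max()) + L
    region = chrom_seq[lo:hi].upper()
    scores_fwd = _window_scores(model, _encode(region))
    if origin.strand == "+":
        scores_rev = _window_scores(model, _encode(reverse_complement(region)))

    best: Optional[tuple[float, int]] = None
    for d, pos, start, ok in zip(distances, p, starts, valid):
        if not ok:
            continue
        if origin.strand == "+":
            # forward window [start, start+L); its reverse complement starts at
            # index (len(region) - (start - lo) - L) of the reversed region
            idx = len(region) - (start - lo) - L
            s = scores_rev[idx]
        else:
            s = scores_fwd[start - lo]
        if np.isnan(s):
            continue
        if best is None or s > best[0]:
            best = (float(s), int(d))
    if best is None:
        return None

    norm, d = best
    if origin.strand == "+":
        pos = anchor + d
        iv = Interval(origin.chrom, pos - L + 1, pos + 1, "-")
        match = reverse_complement(chrom_seq[pos - L + 1 : pos + 1].upper())
    else:
        pos = anchor - d
        iv = Interval(origin.chrom, pos, pos + L, "+")
        match = chrom_seq[pos : pos + L].upper()
    # clamp tiny float error at the normalisation endpoints
    norm = min(1.0, max(0.0, norm))
    return AcsHit(
        origin_id=origin.id, interval=iv, anchor=pos,
        norm_score=norm, distance=d, match=match,
    )


@dataclass(frozen=True)
class DistanceStats:
    """Summary of primary-to-secondary distances and match scores."""

    n: int
    median: float
    mode: int
    distances: np.ndarray
    scores: Optional[np.ndarray]


def distance_stats(
    hits: Sequence,
    restrict: Optional[tuple[int, int]] = None,
) -> DistanceStats:
    """Median/mode/distributions of hit distances.

    ``hits`` may be AcsHit objects, OriginRecord objects with a secondary
    ACS, or bare integers.  ``restrict=(70, 200)`` drops hits outside the
    biologically plausible spacing before summarising.  Mode ties resolve to
    the smallest distance.
    """
    dists, scores = [], []
    for h in hits:
        if isinstance(h, (int, np.integer)):
            dists.append(int(h))
            scores.append(np.nan)
        else:
            d = h.distance
            if d is None:
                continue
            dists.append(int(d))
            s = getattr(h, "norm_score", None)
            if s is None:
                s = getattr(h, "secondary_score", None)
            scores.append(np.nan if s is None else float(s))
    if restrict is not None:
        lo, hi = restrict
        kept = [(d, s) for d, s in zip(dists, scores) if lo <= d <= hi]
        dists = [d for d, _ in kept]
        scores = [s for _, s in kept]
    if not dists:
        raise ValueError("no hits left to summarise")
    counts = Counter(dists)
    top = max(counts.values())
    mode = min(d for d, c in counts.items() if c == top)
    return DistanceStats(
        n=len(dists),
        median=float(np.median(dists)),
        mode=int(mode),
        distances=np.array(sorted(dists)),
        scores=np.array(scores),
    )
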