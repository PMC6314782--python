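"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the data layout of nucleotide-resolution RNAPII
occupancy and poly(A)+ 3'-end maps around budding-yeast replication origins,
with known ground truth:

* a toy genome with non-overlapping origins, each carrying a planted T-rich
  primary ACS motif and an oppositely oriented secondary ACS motif at a
  ground-truth spacing drawn from a discretised gamma (mode 110 bp,
  support 70-200 bp);
* roadblock-shaped polymerase occupancy: signal builds up linearly over
  ~200 nt before the primary ACS, drops sharply within the last ~25 nt, and
  only a small fraction of elongating events crosses into the origin;
  antisense transcription shows the mirrored construction at the secondary
  ACS with its own pause gain;
* 3'-end (termination) counts enriched over the sense drop span immediately
  upstream of the primary ACS and, antisense, ~50 nt past the secondary
  anchor; an "exosome-depleted" condition multiplies the roadblock-proximal
  end rates, mimicking stabilisation of degraded termination products;
* per-origin replication metrics in which the licensing probability
  decreases logistically with the realised intra-origin transcription sum,
  and a two-class conditional-firing structure (high P_F|L insensitive to
  transcription; low P_F|L and firing time transcription-dependent).

All counts are Poisson; one seed fixes every output byte-for-byte.
Sub-streams for genome, placement, occupancy, end sites and metrics are
spawned deterministically from the seed so adding an output never perturbs
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import replication_corr
from .acs_scan import BASES, FrequencyMatrix, build_pwm, reverse_complement, score
from .genomic_io import (
    GenomeLayout,
    Interval,
    StrandedTrack,
    write_fasta,
    write_frequency_matrix,
    write_origin_table,
    write_stranded_track,
)
from .replication_corr import write_metrics_table
from .origin_model import OriginRecord

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "default_frequency_matrix",
    "simulate_cohort",
    "write_cohort",
]

CONDITIONS = ("wt", "depleted")

# 17-nt T-rich consensus used to parameterise the default ACS matrix; the
# core matches the WTTTATRTTTW degenerate ORC-binding consensus.
_DEFAULT_CONSENSUS = "TTTTTTATGTTTTAGTT"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cohort (defaults are the study conditions)."""

    seed: int = 0
    n_origins: int = 190
    chrom_length: int | None = None       # default: 1600 bp per origin
    # occupancy shape
    background_rate: float = 2.0          # reads/base of incoming transcription
    buildup_span: int = 200               # bp of RNAPII accumulation before ACS
    buildup_gain: float = 4.0             # fold occupancy at the pause peak
    drop_span: int = 25                   # bp of sharp signal loss before ACS
    crossing_fraction: float = 0.1        # fraction of events passing the roadblock
    antisense_pause_at_secondary: float = 3.0
    origin_intensity_sd: float = 0.5      # lognormal sd of per-origin load
    # 3'-end (termination) rates
    endsite_background_rate: float = 0.05  # Poisson mean per base, genome-wide
    endsite_rate_at_rb: float = 0.45       # Poisson mean per base at roadblocks
    exosome_gain: float = 3.0              # depleted-condition multiplier
    antisense_end_offset: int = 50         # nt past the secondary anchor
    antisense_end_halfwidth: int = 5
    # ACS spacing distribution (discretised gamma)
    distance_shape: float = 12.0
    distance_scale: float = 10.0           # mode = (shape - 1) * scale = 110
    distance_min: int = 70
    distance_max: int = 200
    # replication metrics
    licensing_intercept: float = 2.0       # P_L = logistic(a - b * region_B)
    licensing_slope: float = 0.04
    class_mix: float = 0.5                 # fraction of high-P_F|L origins
    high_pfl_mean: float = 0.97
    high_pfl_sd: float = 0.02
    low_pfl_mean: float = 0.55
    low_pfl_sd: float = 0.08
    low_pfl_txn_slope: float = 0.004        # P_F|L loss per region_B read (low class)
    t_half_base: float = 20.0              # minutes
    t_half_sd: float = 2.0
    low_thalf_txn_slope: float = 0.12       # minutes per region_B read (low class)
    # motif model
    matrix_length: int = 17

    def __post_init__(self) -> None:
        if self.n_origins < 1:
            raise ValueError("need at least one origin")
        for name in ("background_rate", "endsite_background_rate",
                     "endsite_rate_at_rb", "crossing_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.class_mix <= 1:
            raise ValueError("class_mix must be a probability")

    @property
    def effective_chrom_length(self) -> int:
        return self.chrom_length or self.n_origins * 1600


@dataclass
class SimulatedCohort:
    """Everything one simulation produced, plus its ground truth."""

    config: SimConfig
    layout: GenomeLayout
    genome: dict[str, str]
    freq_matrix: FrequencyMatrix
    origins: list[OriginRecord]
    occupancy: dict[str, StrandedTrack] = field(default_factory=dict)
    endsites: dict[str, StrandedTrack] = field(default_factory=dict)
    metrics: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def default_frequency_matrix(length: int = 17) -> FrequencyMatrix:
    """A peaked T-rich ACS frequency matrix (0.85 consensus / 0.05 others)."""
    consensus = (_DEFAULT_CONSENSUS * (length // 17 + 1))[:length]
    probs = np.full((4, length), 0.05)
    for j, base in enumerate(consensus):
        probs[BASES.index(base), j] = 0.85
    return FrequencyMatrix(probs)


def _sample_motif(freq: FrequencyMatrix, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=freq.probs[:, j]) for j in range(freq.length)]
    return "".join(BASES[i] for i in cols)


def _sample_distances(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample integer ACS spacings from a truncated gamma."""
    out = np.empty(config.n_origins, dtype=int)
    filled = 0
    while filled < config.n_origins:
        draws = np.rint(
            rng.gamma(config.distance_shape, config.distance_scale,
                      size=2 * (config.n_origins - filled))
        ).astype(int)
        ok = draws[(draws >= config.distance_min) & (draws <= config.distance_max)]
        take = min(len(ok), config.n_origins - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _pause_factor(rel: np.ndarray, gain: float, cf: float, config: SimConfig,
                  span: int) -> np.ndarray:
    """Roadblock shape in the frame of one ACS (0 = its 5' anchor).

    Flat incoming level 1 far upstream, linear build-up to ``gain`` over
    the buildup span, sharp linear drop to ``cf`` over the drop span, then
    flat at ``cf`` over ``span`` bases downstream (the origin interior).
    """
    b, d = config.buildup_span, config.drop_span
    f = np.ones_like(rel, dtype=float)
    ramp = (rel >= -b) & (rel < -d)
    f[ramp] = 1.0 + (gain - 1.0) * (rel[ramp] + b) / (b - d)
    drop = (rel >= -d) & (rel < 0)
    f[drop] = gain + (cf - gain) * (rel[drop] + d) / d
    inside = (rel >= 0) & (rel <= span)
    f[inside] = cf
    f[rel > span] = np.nan  # caller masks: beyond the origin interior
    return f


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate one cohort: genome, origins, tracks, metrics, ground truth."""
    chrom = "chrS"
    n_bases = config.effective_chrom_length
    spacing = n_bases // config.n_origins
    L = config.matrix_length
    margin = (config.buildup_span + config.drop_span
              + config.distance_max + replication_corr.FLANK + 200)
    if spacing < 2 * (L + 20) + config.distance_max or n_bases < 2 * margin:
        raise ValueError(
            f"infeasible placement: {config.n_origins} origins do not fit in "
            f"{n_bases} bp"
        )

    seq_rng, place_rng, occ_rng, end_rng, met_rng = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(5)
    )

    freq = default_frequency_matrix(L)
    pwm = build_pwm(freq)

    # --- genome background and origin placement -------------------------
    genome_arr = np.frombuffer(
        bytes(seq_rng.choice([65, 67, 71, 84], size=n_bases).astype(np.uint8)),
        dtype=np.uint8,
    ).copy()
    distances = _sample_distances(config, place_rng)
    strands = np.where(place_rng.random(config.n_origins) < 0.5, "+", "-")
    jitter_span = max(1, spacing // 20)
    anchors = np.empty(config.n_origins, dtype=int)
    for i in range(config.n_origins):
        center = i * spacing + spacing // 2
        a = center + int(place_rng.integers(-jitter_span, jitter_span + 1))
        anchors[i] = int(np.clip(a, margin, n_bases - margin))

    origins: list[OriginRecord] = []
    for i in range(config.n_origins):
        a, d, strand = int(anchors[i]), int(distances[i]), strands[i]
        p_motif = _sample_motif(freq, place_rng)
        s_motif = _sample_motif(freq, place_rng)
        if strand == "+":
            genome_arr[a : a + L] = np.frombuffer(p_motif.encode(), np.uint8)
            sp = a + d  # secondary 5' end on '-' strand
            genome_arr[sp - L + 1 : sp + 1] = np.frombuffer(
                reverse_complement(s_motif).encode(), np.uint8
            )
            primary = Interval(chrom, a, a + L, "+")
            secondary = Interval(chrom, sp - L + 1, sp + 1, "-")
        else:
            genome_arr[a - L + 1 : a + 1] = np.frombuffer(
                reverse_complement(p_motif).encode(), np.uint8
            )
            sp = a - d
            genome_arr[sp : sp + L] = np.frombuffer(s_motif.encode(), np.uint8)
            primary = Interval(chrom, a - L + 1, a + 1, "-")
            secondary = Interval(chrom, sp, sp + L, "+")
        origins.append(
            OriginRecord(
                id=str(i + 1),
                primary_acs=primary,
                primary_match=p_motif,
                primary_score=score(pwm, p_motif),
                secondary_acs=secondary,
                secondary_match=s_motif,
                secondary_score=score(pwm, s_motif),
            )
        )
    genome = {chrom: genome_arr.tobytes().decode("ascii")}
    layout = GenomeLayout.from_sequences(genome)

    # --- occupancy and 3'-end mean tracks --------------------------------
    b0 = config.background_rate
    kappa = np.exp(occ_rng.normal(0.0, config.origin_intensity_sd,
                                  size=config.n_origins))
    ext = config.buildup_span + 300  # incoming-transcription extent upstream

    occ_mean = {s: np.full(n_bases, b0) for s in ("+", "-")}
    end_mean_wt = {s: np.full(n_bases, config.endsite_background_rate)
                   for s in ("+", "-")}
    end_mean_dep = {s: arr.copy() for s, arr in end_mean_wt.items()}

    for i, rec in enumerate(origins):
        a, d, k = rec.anchor, rec.distance, float(kappa[i])
        rel = np.arange(-ext, d + ext + 1)
        sense_f = _pause_factor(rel, config.buildup_gain,
                                config.crossing_fraction, config, span=d)
        anti_f = _pause_factor(d - rel, config.antisense_pause_at_secondary,
                               config.crossing_fraction, config, span=d)
        sense_mean = np.where(np.isnan(sense_f), 1.0, sense_f) * k * b0
        anti_mean = np.where(np.isnan(anti_f), 1.0, anti_f) * k * b0
        if rec.strand == "+":
            sl = slice(a - ext, a + d + ext + 1)
            occ_mean["+"][sl] = sense_mean
            occ_mean["-"][sl] = anti_mean
        else:
            sl = slice(a - d - ext, a + ext + 1)
            occ_mean["-"][sl] = sense_mean[::-1]
            occ_mean["+"][sl] = anti_mean[::-1]

        # termination events: sense over the drop span, antisense ~offset nt
        # past the secondary anchor (in the antisense travel direction)
        rb_rate = config.endsite_rate_at_rb * k
        hw = config.antisense_end_halfwidth
        as_lo = d - config.antisense_end_offset - hw
        as_hi = d - config.antisense_end_offset + hw + 1
        for mean_map, gain in ((end_mean_wt, 1.0),
                               (end_mean_dep, config.exosome_gain)):
            if rec.strand == "+":
                mean_map["+"][a - config.drop_span : a] = rb_rate * gain
                mean_map["-"][a + as_lo : a + as_hi] = rb_rate * gain
            else:
                mean_map["-"][a + 1 : a + config.drop_span + 1] = rb_rate * gain
                mean_map["+"][a - as_hi + 1 : a - as_lo + 1] = rb_rate * gain

    def _poisson_track(mean_map, rng) -> StrandedTrack:
        track = StrandedTrack.zeros(layout)
        for s in ("+", "-"):
            track.data[chrom][s] = rng.poisson(mean_map[s]).astype(float)
        return track

    occupancy = {c: _poisson_track(occ_mean, occ_rng) for c in CONDITIONS}
    endsites = {
        "wt": _poisson_track(end_mean_wt, end_rng),
        "depleted": _poisson_track(end_mean_dep, end_rng),
    }

    # --- replication metrics from realised transcription ------------------
    quants = replication_corr.quantify(occupancy["wt"], origins, "protected")
    region_b = np.array([q.region_B for q in quants])
    p_l = 1.0 / (1.0 + np.exp(-(config.licensing_intercept
                                - config.licensing_slope * region_b)))
    high_class = met_rng.random(config.n_origins) < config.class_mix
    b_centered = region_b - region_b.mean()
    pfl = np.where(
        high_class,
        met_rng.normal(config.high_pfl_mean, config.high_pfl_sd,
                       config.n_origins),
        config.low_pfl_mean
        - config.low_pfl_txn_slope * b_centered
        + met_rng.normal(0.0, config.low_pfl_sd, config.n_origins),
    )
    pfl = np.clip(pfl, 0.02, 1.0)
    p_f = p_l * pfl
    t_half = np.where(
        high_class,
        config.t_half_base + met_rng.normal(0.0, config.t_half_sd,
                                            config.n_origins),
        config.t_half_base + 5.0
        + config.low_thalf_txn_slope * b_centered
        + met_rng.normal(0.0, config.t_half_sd, config.n_origins),
    )

    ids = [rec.id for rec in origins]
    metrics = pd.DataFrame(
        {"origin_id": ids, "P_L": p_l, "P_F": p_f, "T_half": t_half}
    )
    truth = pd.DataFrame(
        {
            "origin_id": ids,
            "strand": strands,
            "anchor": [rec.anchor for rec in origins],
            "distance": distances,
            "intensity": kappa,
            "high_class": high_class,
            "region_B": region_b,
            "P_L": p_l,
            "P_F_L": pfl,
            "P_F": p_f,
            "T_half": t_half,
        }
    )
    return SimulatedCohort(
        config=config, layout=layout, genome=genome, freq_matrix=freq,
        origins=origins, occupancy=occupancy, endsites=endsites,
        metrics=metrics, truth=truth,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write every simulated artifact in the formats the analysis reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(cohort.genome, paths["genome"])

    paths["matrix"] = outdir / "acs_frequency_matrix.txt"
    write_frequency_matrix(cohort.freq_matrix.probs, paths["matrix"])

    paths["origins"] = outdir / "origins.tsv"
    write_origin_table(cohort.origins, paths["origins"])

    for kind, tracks in (("occupancy", cohort.occupancy),
                         ("endsites", cohort.endsites)):
        for cond, track in tracks.items():
            plus = outdir / f"{kind}_{cond}_plus.bedgraph"
            minus = outdir / f"{kind}_{cond}_minus.bedgraph"
            write_stranded_track(track, plus, minus)
            paths[f"{kind}_{cond}_plus"] = plus
            paths[f"{kind}_{cond}_minus"] = minus

    paths["metrics"] = outdir / "metrics.tsv"
    write_metrics_table(cohort.metrics, paths["metrics"])

    paths["truth"] = outdir / "ground_truth.tsv"
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
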