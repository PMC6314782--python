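"""Readers and writers for the external data formats.

Internal coordinate convention
------------------------------
All internal coordinates are 0-based half-open intervals with an explicit
strand.  The origin table dialect used by the bundled ACS fixture encodes
coordinates 1-based and strand-aware: ``Start`` is the 5' end of the match on
its own strand, so ``Start > End`` on the minus strand, and ``End`` lies one
match-length away from ``Start`` in the strand direction.  Conversion between
the two conventions is centralised here so that no other module ever touches
1-based coordinates.

Coverage interchange is bedGraph, one file per strand (bedGraph has no strand
column).  Dense per-base vectors are used in memory.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeLayout",
    "Interval",
    "StrandedTrack",
    "bundled_origin_table",
    "read_origin_table",
    "write_origin_table",
    "read_stranded_track",
    "write_stranded_track",
    "read_metaprofile",
    "write_metaprofile",
    "read_frequency_matrix",
    "write_frequency_matrix",
    "read_fasta",
    "write_fasta",
]

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths of a (possibly toy) genome."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, lengths: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), tuple(lengths.values()))

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str]) -> "GenomeLayout":
        return cls(tuple(seqs), tuple(len(s) for s in seqs.values()))

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


@dataclass(frozen=True)
class Interval:
    """0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """0-based position of the 5'-most base on the interval's own strand."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class StrandedTrack:
    """Per-base, per-strand non-negative counts over a genome."""

    layout: GenomeLayout
    data: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def zeros(cls, layout: GenomeLayout) -> "StrandedTrack":
        data = {
            name: {s: np.zeros(length, dtype=float) for s in STRANDS}
            for name, length in zip(layout.chrom_names, layout.chrom_lengths)
        }
        return cls(layout, data)

    def values(self, chrom: str, strand: str) -> np.ndarray:
        if strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {strand!r}")
        return self.data[chrom][strand]

    def add_interval(
        self, chrom: str, start: int, end: int, strand: str, value: float
    ) -> None:
        if value < 0:
            raise ValueError(f"negative track value {value} at {chrom}:{start}-{end}")
        length = self.layout.length(chrom)
        if start < 0 or end > length:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome (length {length})"
            )
        if start >= end:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        self.values(chrom, strand)[start:end] += value

    def total(self) -> float:
        return float(
            sum(v.sum() for per in self.data.values() for v in per.values())
        )


# ---------------------------------------------------------------------------
# Origin tables


def bundled_origin_table() -> Path:
    """Path of the ACS coordinate table shipped with the package (228 origins)."""
    return Path(
        importlib.resources.files("oriterm.data") / "origins_acs_table.tsv"
    )


_TABLE_COLUMNS = [
    "ID", "Chromosome", "Strand", "Start", "End", "Match", "Score",
    "Chromosome", "Strand", "Start", "End", "Match", "Score",
    "Protected length (nt)",
]


def _interval_from_5prime(chrom: str, start1: int, end1: int, row: int) -> Interval:
    """Convert 1-based strand-aware (Start, End) to an internal Interval.

    Start is the 5' end of the match on its own strand; End = Start +/- L.
    """
    if start1 == end1:
        raise ValueError(f"row {row}: Start == End ({start1})")
    if end1 > start1:  # plus strand
        return Interval(chrom, start1 - 1, end1 - 1, "+")
    return Interval(chrom, end1, start1, "-")


def _interval_to_5prime(iv: Interval) -> tuple[int, int]:
    """Inverse of :func:`_interval_from_5prime`: 1-based (Start, End)."""
    if iv.strand == "+":
        return iv.start + 1, iv.end + 1
    return iv.end, iv.start


def read_origin_table(path, dialect: str = "table2"):
    """Read an origin/ACS coordinate table into oriented origin records.

    ``table2`` is the bundled fixture dialect (primary + secondary ACS blocks
    and a "Protected length (nt)" column); ``bed6`` reads generic BED with a
    strand column, yielding records without a secondary ACS.
    """
    from .origin_model import OriginRecord  # deferred: avoids import cycle

    path = Path(path)
    if dialect == "bed6":
        return _read_bed6(path, OriginRecord)
    if dialect != "table2":
        raise ValueError(f"unknown dialect {dialect!r}")

    records = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if [h.strip() for h in header] != _TABLE_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 14:
                raise ValueError(
                    f"{path} row {lineno}: expected 14 columns, got {len(parts)}"
                )
            (oid, p_chrom, p_strand, p_start, p_end, p_match, p_score,
             s_chrom, s_strand, s_start, s_end, s_match, s_score,
             protected) = parts
            try:
                p_start_i, p_end_i = int(p_start), int(p_end)
                s_start_i, s_end_i = int(s_start), int(s_end)
                protected_i = int(protected)
            except ValueError as exc:
                raise ValueError(
                    f"{path} row {lineno}: non-integer coordinate ({exc})"
                ) from None
            for sym, col in ((p_strand, "Strand"), (s_strand, "Strand")):
                if sym not in STRANDS:
                    raise ValueError(
                        f"{path} row {lineno}, column {col}: "
                        f"unknown strand symbol {sym!r}"
                    )
            primary = _interval_from_5prime(p_chrom, p_start_i, p_end_i, lineno)
            secondary = _interval_from_5prime(s_chrom, s_start_i, s_end_i, lineno)
            if len(primary) != len(p_match):
                raise ValueError(
                    f"{path} row {lineno}: primary span {len(primary)} != "
                    f"match length {len(p_match)}"
                )
            if secondary.strand == primary.strand:
                raise ValueError(
                    f"{path} row {lineno}: secondary strand must oppose primary"
                )
            distance = abs(primary.five_prime() - secondary.five_prime())
            if distance != protected_i:
                raise ValueError(
                    f"{path} row {lineno}, column 'Protected length (nt)': "
                    f"5'-to-5' distance {distance} != printed {protected_i}"
                )
            records.append(
                OriginRecord(
                    id=oid,
                    primary_acs=primary,
                    primary_match=p_match,
                    primary_score=float(p_score),
                    secondary_acs=secondary,
                    secondary_match=s_match,
                    secondary_score=float(s_score),
                )
            )
    return records


def _read_bed6(path: Path, OriginRecord):
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path} row {lineno}: BED6 needs 6 columns")
            chrom, start, end, name, score, strand = parts[:6]
            if strand not in STRANDS:
                raise ValueError(
                    f"{path} row {lineno}, column strand: unknown symbol {strand!r}"
                )
            iv = Interval(chrom, int(start), int(end), strand)
            try:
                norm_score = float(score)
            except ValueError:
                norm_score = None
            records.append(
                OriginRecord(id=name, primary_acs=iv, primary_score=norm_score)
            )
    return records


def _format_score(score) -> str:
    return "" if score is None else repr(float(score))


def write_origin_table(records: Iterable, path) -> None:
    """Write records back in the table dialect (round-trips the fixture)."""
    with open(path, "w") as handle:
        handle.write("\t".join(_TABLE_COLUMNS) + "\n")
        for rec in records:
            if rec.secondary_acs is None:
                raise ValueError(
                    f"origin {rec.id}: table dialect requires a secondary ACS"
                )
            p_start, p_end = _interval_to_5prime(rec.primary_acs)
            s_start, s_end = _interval_to_5prime(rec.secondary_acs)
            handle.write(
                "\t".join(
                    [
                        str(rec.id),
                        rec.primary_acs.chrom, rec.primary_acs.strand,
                        str(p_start), str(p_end),
                        rec.primary_match or "",
                        _format_score(rec.primary_score),
                        rec.secondary_acs.chrom, rec.secondary_acs.strand,
                        str(s_start), str(s_end),
                        rec.secondary_match or "",
                        _format_score(rec.secondary_score),
                        str(rec.distance),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph coverage tracks


def _read_bedgraph_into(path, track: StrandedTrack, strand: str) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path} row {lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = parts
            try:
                track.add_interval(chrom, int(start), int(end), strand, float(value))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path} row {lineno}: {exc}") from None


def read_stranded_track(plus_path, minus_path, layout: GenomeLayout) -> StrandedTrack:
    """Read a strand-split bedGraph pair into dense per-base vectors.

    Unspecified positions are 0; overlapping bedGraph lines are summed.
    """
    track = StrandedTrack.zeros(layout)
    _read_bedgraph_into(plus_path, track, "+")
    _read_bedgraph_into(minus_path, track, "-")
    return track


def _format_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _write_bedgraph(values_by_chrom, path) -> None:
    with open(path, "w") as handle:
        for chrom, values in values_by_chrom:
            # run-length encode maximal constant nonzero runs
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    handle.write(f"{chrom}\t{s}\t{e}\t{_format_value(v)}\n")


def write_stranded_track(track: StrandedTrack, plus_path, minus_path) -> None:
    names = track.layout.chrom_names
    _write_bedgraph(((c, track.values(c, "+")) for c in names), plus_path)
    _write_bedgraph(((c, track.values(c, "-")) for c in names), minus_path)


# ---------------------------------------------------------------------------
# Metaprofiles


def write_metaprofile(profile, path) -> None:
    """Write a metasite profile as TSV; round-trip preserves exact values."""
    with open(path, "w") as handle:
        handle.write(f"# statistic={profile.statistic}\n")
        handle.write("rel_pos\tsense_value\tantisense_value\tn_origins_covered\n")
        for pos, s, a, n in zip(
            profile.rel_positions, profile.sense_values,
            profile.antisense_values, profile.n_origins,
        ):
            handle.write(f"{pos}\t{float(s)!r}\t{float(a)!r}\t{n}\n")


def read_metaprofile(path):
    from .metasite import MetaProfile  # deferred: avoids import cycle

    statistic = None
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line.startswith("# statistic="):
                statistic = line.split("=", 1)[1]
                continue
            if not line or line.startswith("rel_pos"):
                continue
            pos, s, a, n = line.split("\t")
            rows.append((int(pos), float(s), float(a), int(n)))
    if statistic is None:
        raise ValueError(f"{path}: missing '# statistic=' header")
    pos, s, a, n = (np.array(col) for col in zip(*rows))
    return MetaProfile(
        rel_positions=pos.astype(int), sense_values=s.astype(float),
        antisense_values=a.astype(float), n_origins=n.astype(int),
        statistic=statistic,
    )


# ---------------------------------------------------------------------------
# Nucleotide frequency matrices (rows A, C, G, T)

_BASES = "ACGT"


def read_frequency_matrix(path) -> np.ndarray:
    """Read a plain-text 4 x L base-frequency matrix (rows labelled A,C,G,T)."""
    rows: dict[str, list[float]] = {}
    with open(path) as handle:
        for line in handle:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            base, values = parts[0].upper(), parts[1:]
            if base not in _BASES:
                raise ValueError(f"{path}: unexpected row label {base!r}")
            rows[base] = [float(v) for v in values]
    if sorted(rows) != sorted(_BASES):
        raise ValueError(f"{path}: need exactly one row per base A,C,G,T")
    matrix = np.array([rows[b] for b in _BASES], dtype=float)
    if matrix.ndim != 2 or len({len(rows[b]) for b in _BASES}) != 1:
        raise ValueError(f"{path}: ragged matrix rows")
    return matrix


def write_frequency_matrix(matrix: np.ndarray, path) -> None:
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as handle:
        for base, row in zip(_BASES, matrix):
            handle.write(
                base + "\t" + "\t".join(repr(float(v)) for v in row) + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
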