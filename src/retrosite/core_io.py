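"""Shared domain types, file I/O and configuration.

Coordinates are 0-based half-open everywhere inside the package; conversion
to the 1-based inclusive convention used in genome-browser style output
happens only at the presentation layer (:func:`to_one_based`,
:func:`from_one_based`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger("retrosite")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open genomic interval, 0-based.

    ``start`` is inclusive, ``end`` exclusive.  ``start < end`` and the
    chromosome name must be non-empty.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def padded(self, pad: int) -> "GenomeInterval":
        return GenomeInterval(self.chrom, max(0, self.start - pad), self.end + pad)


def to_one_based(iv: GenomeInterval) -> tuple[str, int, int]:
    """Convert to 1-based inclusive coordinates (presentation layer)."""
    return iv.chrom, iv.start + 1, iv.end


def from_one_based(chrom: str, start1: int, end1: int) -> GenomeInterval:
    """Inverse of :func:`to_one_based`."""
    return GenomeInterval(chrom, start1 - 1, end1)


@dataclass
class MateInfo:
    """Mapping evidence for one read of a pair.

    ``chrom is None`` means the read is unmapped (or was demoted because its
    mapping quality fell below the filter).  ``pos`` is the leftmost aligned
    reference base, ``aligned_len`` the number of reference bases covered by
    the alignment, ``mapped_fraction`` the fraction of read bases aligned.
    ``clip_side`` records which end of the read was soft-clipped ("left",
    "right" or None) and ``seq`` the read sequence in original (as sequenced)
    orientation.
    """

    chrom: Optional[str] = None
    pos: int = -1
    strand: str = "+"
    mapq: int = 0
    read_len: int = 0
    aligned_len: int = 0
    mapped_fraction: float = 0.0
    clip_side: Optional[str] = None
    seq: Optional[str] = None

    @property
    def is_mapped(self) -> bool:
        return self.chrom is not None

    @property
    def end(self) -> int:
        return self.pos + self.aligned_len


@dataclass
class AlignedPair:
    """One mate pair's mapping evidence (both reads)."""

    name: str
    a: MateInfo
    b: MateInfo

    @property
    def n_mapped(self) -> int:
        return int(self.a.is_mapped) + int(self.b.is_mapped)

    @property
    def span(self) -> Optional[int]:
        """Outer distance between the two mates.

        Defined only when both mates map to the same chromosome.
        """
        if self.a.is_mapped and self.b.is_mapped and self.a.chrom == self.b.chrom:
            return max(self.a.end, self.b.end) - min(self.a.pos, self.b.pos)
        return None

    @property
    def mates(self) -> tuple[MateInfo, MateInfo]:
        return (self.a, self.b)


@dataclass
class InsertSizeModel:
    """Expected mate-pair insert (outer fragment span) distribution.

    Defaults describe an 8 kbp long-insert library whose fragment sizes fall
    in the 5-12 kbp range.
    """

    expected_low: int = 5000
    expected_high: int = 12000
    mean: int = 8000
    sd: float = 1500.0

    def __post_init__(self) -> None:
        if not (self.expected_low < self.mean < self.expected_high):
            raise ValueError("require expected_low < mean < expected_high")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass
class RunConfig:
    """All tunables of the insertion-call pipeline and genotyper.

    Track vote thresholds are raw per-window counts; a track threshold of
    ``None`` disables voting for that track (it is still computed and
    reported as evidence).  Defaults were calibrated with the built-in
    mate-pair simulator at 20x physical coverage.
    """

    window_size: int = 500
    min_mapq: int = 20
    min_clipped_fraction: float = 0.2
    # per-track vote thresholds (counts per window)
    threshold_short_insert: Optional[int] = 2
    threshold_discordant: Optional[int] = 3
    threshold_orphan: Optional[int] = 2
    threshold_clipped: Optional[int] = 2
    threshold_depth: Optional[int] = None
    min_tracks_agreeing: int = 1
    # windows with votes closer than this many gap windows merge into one call
    merge_gap_windows: int = 24
    flank_bp: int = 12000
    # assembler
    min_overlap: int = 30
    min_identity: float = 0.95
    # classification
    min_aligned_len: int = 100
    min_hit_identity: float = 0.80
    # k-mer genotyper
    k: int = 25
    t_provirus: float = 0.5
    t_solo_ltr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not (1 <= self.min_tracks_agreeing <= 5):
            raise ValueError("min_tracks_agreeing must be in 1..5")
        if self.k < 11 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 11")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a config from a ``key=value`` or ``key: value`` (YAML) file."""
        import yaml

        text = Path(path).read_text()
        values: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                key, _, val = line.partition("=")
                values[key.strip()] = yaml.safe_load(val.strip())
        if not values:
            loaded = yaml.safe_load(text) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"cannot parse config file {path}")
            values = loaded
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**values)
        return replace(cfg, **overrides) if overrides else cfg

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an order-preserving ``{name: sequence}`` map.

    Sequence names are truncated at the first whitespace and sequences are
    uppercased.  Content before the first header is a parse error reported
    with its line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA, expected '>' header at line {lineno}"
                )
            break
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(name, sequence)`` from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write ``(name, sequence)`` reads with uniform qualities; returns count."""
    n = 0
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def _mate_from_record(rec: "pysam.AlignedSegment", min_mapq: int) -> MateInfo:
    seq = rec.query_sequence
    read_len = rec.infer_read_length() or (len(seq) if seq else 0)
    if seq is not None and rec.is_reverse:
        seq = revcomp(seq)  # store in original sequenced orientation
    if rec.is_unmapped or rec.mapping_quality < min_mapq:
        return MateInfo(read_len=read_len, mapq=rec.mapping_quality if not rec.is_unmapped else 0, seq=seq)
    aligned_len = rec.reference_length or 0
    qlen = rec.query_alignment_length
    frac = qlen / read_len if read_len else 0.0
    clip_side = None
    cig = rec.cigartuples or []
    left_clip = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
    right_clip = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
    if left_clip or right_clip:
        clip_side = "left" if left_clip >= right_clip else "right"
    return MateInfo(
        chrom=rec.reference_name,
        pos=rec.reference_start,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
        read_len=read_len,
        aligned_len=aligned_len,
        mapped_fraction=frac,
        clip_side=clip_side,
        seq=seq,
    )


def read_alignments(path: str | Path, min_mapq: int = 20) -> Iterator[AlignedPair]:
    """Stream :class:`AlignedPair` records from a SAM/BAM file.

    One pair is emitted per template name; secondary and supplementary
    records are ignored.  Mates mapped below ``min_mapq`` are demoted to
    unmapped (rather than dropped) so they still contribute to the orphan
    signal.  Names left unpaired at EOF are counted and logged.
    """
    pending: dict[str, MateInfo] = {}
    n_pairs = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = _mate_from_record(rec, min_mapq)
            name = rec.query_name
            if name in pending:
                first = pending.pop(name)
                if rec.is_read1:
                    first, mate = mate, first
                n_pairs += 1
                yield AlignedPair(name=name, a=first, b=mate)
            else:
                pending[name] = mate
    if pending:
        logger.warning("read_alignments: %d unpaired record(s) skipped at EOF", len(pending))
    logger.info("read_alignments: %d pairs read from %s", n_pairs, path)


# ---------------------------------------------------------------------------
# pair TSV (mapper-free interchange produced by the simulator)
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = [
    "name",
    "chromA", "posA", "strandA", "mapqA", "readLenA", "alignedLenA", "fracA", "clipA", "seqA",
    "chromB", "posB", "strandB", "mapqB", "readLenB", "alignedLenB", "fracB", "clipB", "seqB",
]


def _mate_row(m: MateInfo) -> list:
    return [
        m.chrom or ".", m.pos, m.strand, m.mapq, m.read_len, m.aligned_len,
        round(m.mapped_fraction, 4), m.clip_side or ".", m.seq or ".",
    ]


def write_pairs_tsv(pairs: Iterable[AlignedPair], path: str | Path) -> None:
    rows = [[p.name, *_mate_row(p.a), *_mate_row(p.b)] for p in pairs]
    pd.DataFrame(rows, columns=_PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def _mate_from_row(row: pd.Series, suffix: str) -> MateInfo:
    chrom = row[f"chrom{suffix}"]
    chrom = None if chrom in (".", None) or pd.isna(chrom) else str(chrom)
    clip = row[f"clip{suffix}"]
    seq = row[f"seq{suffix}"]
    return MateInfo(
        chrom=chrom,
        pos=int(row[f"pos{suffix}"]),
        strand=str(row[f"strand{suffix}"]),
        mapq=int(row[f"mapq{suffix}"]),
        read_len=int(row[f"readLen{suffix}"]),
        aligned_len=int(row[f"alignedLen{suffix}"]),
        mapped_fraction=float(row[f"frac{suffix}"]),
        clip_side=None if clip in (".",) or pd.isna(clip) else str(clip),
        seq=None if seq in (".",) or pd.isna(seq) else str(seq),
    )


def read_pairs_tsv(path: str | Path) -> list[AlignedPair]:
    df = pd.read_csv(path, sep="\t", dtype={"chromA": str, "chromB": str})
    return [
        AlignedPair(name=str(row["name"]), a=_mate_from_row(row, "A"), b=_mate_from_row(row, "B"))
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------


def write_bed(calls: Iterable, path: str | Path) -> None:
    """Write scored intervals as BED (0-based half-open), sorted by (chrom, start).

    ``calls`` may be :class:`GenomeInterval` objects or anything exposing an
    ``interval`` attribute plus an optional ``score``.
    """
    rows = []
    for i, call in enumerate(calls):
        iv = call.interval if hasattr(call, "interval") else call
        score = getattr(call, "score", getattr(call, "n_tracks_agreeing", 0))
        rows.append((iv.chrom, iv.start, iv.end, f"call_{i}", score))
    rows.sort(key=lambda r: (r[0], r[1], -r[4]))
    with open(path, "w") as fh:
        for j, (chrom, start, end, _, score) in enumerate(rows):
            fh.write(f"{chrom}\t{start}\t{end}\tcall_{j}\t{score}\n")


def read_bed(path: str | Path) -> list[GenomeInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(GenomeInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_tsv(table: pd.DataFrame, path: str | Path, sort_by: Optional[list[str]] = None) -> None:
    """Write a DataFrame as a TSV with header, deterministic row order."""
    if sort_by:
        table = table.sort_values(sort_by, kind="mergesort")
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
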