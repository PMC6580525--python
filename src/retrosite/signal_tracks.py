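"""Per-window genome signal tracks computed from mate-pair alignments.

An insertion that is present in the sample but absent from the reference
betrays itself through several mapping anomalies of a long-insert mate-pair
library: pairs that span the whole inserted element map at a shorter than
expected distance; pairs with one read inside the element leave an orphan
(one mapped, one unmapped read); reads crossing an insertion junction map
only partially; and read depth is perturbed around the breakpoints.  Each
anomaly class is accumulated into a per-window count vector ("track") over
the genome; the caller integrates the five tracks.

Track values are raw integer counts, which keeps them exact and directly
testable; any normalisation happens downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import AlignedPair, InsertSizeModel, RunConfig

TRACKS = ("SHORT_INSERT", "DISCORDANT", "ORPHAN", "CLIPPED", "DEPTH")


@dataclass
class SignalTrackSet:
    """The five per-window genome tracks.

    ``counts[track][chrom]`` is an integer array of length
    ``ceil(chrom_length / window_size)``.
    """

    window_size: int
    chrom_lengths: dict[str, int]
    counts: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    total_pairs: int = 0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for track in TRACKS:
            self.counts.setdefault(track, {})
            for chrom in self.chrom_lengths:
                self.counts[track].setdefault(
                    chrom, np.zeros(self.n_windows(chrom), dtype=np.int64)
                )

    def n_windows(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[chrom] / self.window_size)

    def window_of(self, pos: int) -> int:
        return pos // self.window_size

    def get(self, track: str, chrom: str) -> np.ndarray:
        return self.counts[track][chrom]

    def _add_interval(self, track: str, chrom: str, start: int, end: int) -> None:
        """Increment every window overlapping [start, end)."""
        if chrom not in self.chrom_lengths or end <= start:
            return
        arr = self.counts[track][chrom]
        w0 = max(0, start // self.window_size)
        w1 = min(len(arr) - 1, (end - 1) // self.window_size)
        if w1 >= w0:
            arr[w0 : w1 + 1] += 1

    def _add_point(self, track: str, chrom: str, pos: int) -> None:
        if chrom not in self.chrom_lengths:
            return
        arr = self.counts[track][chrom]
        w = pos // self.window_size
        if 0 <= w < len(arr):
            arr[w] += 1

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chrom_lengths:
            n = self.n_windows(chrom)
            starts = np.arange(n) * self.window_size
            data = {"chrom": chrom, "windowStart": starts}
            for track in TRACKS:
                data[track] = self.counts[track][chrom]
            rows.append(pd.DataFrame(data))
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, window_size: int) -> "SignalTrackSet":
        chrom_lengths = {
            str(chrom): int(sub["windowStart"].max()) + window_size
            for chrom, sub in df.groupby("chrom", sort=False)
        }
        ts = cls(window_size=window_size, chrom_lengths=chrom_lengths)
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("windowStart")
            for track in TRACKS:
                ts.counts[track][str(chrom)] = sub[track].to_numpy(dtype=np.int64)
        return ts

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SignalTrackSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        starts = np.sort(df["windowStart"].unique())
        window_size = int(starts[1] - starts[0]) if len(starts) > 1 else int(starts[0]) or 500
        return cls.from_dataframe(df, window_size)

    def write_bedgraph(self, track: str, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chrom_lengths:
                arr = self.counts[track][chrom]
                for w, v in enumerate(arr):
                    if v:
                        s = w * self.window_size
                        e = min(s + self.window_size, self.chrom_lengths[chrom])
                        fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def _dedupe(pairs: Iterable[AlignedPair]) -> list[AlignedPair]:
    """Count each pair name once; distinct names at identical coordinates all count."""
    seen: set[str] = set()
    out = []
    for p in pairs:
        if p.name in seen:
            continue
        seen.add(p.name)
        out.append(p)
    return out


def compute_short_insert_track(
    pairs: Sequence[AlignedPair],
    insert_model: InsertSizeModel,
    track_set: SignalTrackSet,
) -> None:
    """Pairs whose mates map to the same chromosome at a span shorter than
    the expected insert range increment every window between the mates.

    Spanning the inserted element shortens the apparent (reference) span by
    the element's length, so these pairs localise the insertion interior.
    """
    for p in pairs:
        span = p.span
        if span is not None and span < insert_model.expected_low:
            lo = min(p.a.pos, p.b.pos)
            hi = max(p.a.end, p.b.end)
            track_set._add_interval("SHORT_INSERT", p.a.chrom, lo, hi)


def compute_discordant_track(
    pairs: Sequence[AlignedPair],
    insert_model: InsertSizeModel,
    track_set: SignalTrackSet,
) -> None:
    """Inter-chromosomal pairs and pairs with a longer than expected span
    increment the window containing each mapped mate."""
    for p in pairs:
        if p.n_mapped != 2:
            continue
        span = p.span
        discordant = (p.a.chrom != p.b.chrom) or (span is not None and span > insert_model.expected_high)
        if discordant:
            track_set._add_point("DISCORDANT", p.a.chrom, p.a.pos)
            track_set._add_point("DISCORDANT", p.b.chrom, p.b.pos)


def compute_orphan_track(pairs: Sequence[AlignedPair], track_set: SignalTrackSet) -> None:
    """Pairs with exactly one mappable read increment the mapped mate's window."""
    for p in pairs:
        if p.n_mapped == 1:
            m = p.a if p.a.is_mapped else p.b
            track_set._add_point("ORPHAN", m.chrom, m.pos)


def compute_clipped_track(
    pairs: Sequence[AlignedPair],
    min_clipped_fraction: float,
    track_set: SignalTrackSet,
) -> None:
    """Partially mapped reads (mapped fraction <= 1 - min_clipped_fraction)
    increment the window of their leftmost aligned base."""
    cutoff = 1.0 - min_clipped_fraction
    for p in pairs:
        for m in p.mates:
            if m.is_mapped and m.mapped_fraction <= cutoff:
                track_set._add_point("CLIPPED", m.chrom, m.pos)


def compute_depth_track(pairs: Sequence[AlignedPair], track_set: SignalTrackSet) -> None:
    """Each mapped read increments every window overlapped by its aligned bases."""
    for p in pairs:
        for m in p.mates:
            if m.is_mapped:
                track_set._add_interval("DEPTH", m.chrom, m.pos, m.end)


def compute_tracks(
    pairs: Iterable[AlignedPair],
    chrom_lengths: dict[str, int],
    insert_model: InsertSizeModel | None = None,
    config: RunConfig | None = None,
) -> SignalTrackSet:
    """Compute all five signal tracks from a stream of mate pairs."""
    insert_model = insert_model or InsertSizeModel()
    config = config or RunConfig()
    unique = _dedupe(pairs)
    ts = SignalTrackSet(window_size=config.window_size, chrom_lengths=dict(chrom_lengths))
    ts.total_pairs = len(unique)
    compute_short_insert_track(unique, insert_model, ts)
    compute_discordant_track(unique, insert_model, ts)
    compute_orphan_track(unique, ts)
    compute_clipped_track(unique, config.min_clipped_fraction, ts)
    compute_depth_track(unique, ts)
    import logging

    logging.getLogger("retrosite").info(
        "compute_tracks: %d pairs in; per-track totals: %s",
        len(unique),
        {t: int(sum(a.sum() for a in ts.counts[t].values())) for t in TRACKS},
    )
    return ts
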