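"""Integrate the five signal tracks into candidate insertion calls.

The first step of the two-step pipeline is deliberately permissive to false
positives: any window in which enough tracks show anomalous counts becomes
part of a candidate call, and candidates are only resolved in the second
step by assembling and classifying the discordant mates collected at each
call.  Voting is per window on raw track counts; voting windows that fall
within ``merge_gap_windows`` of each other merge into a single call, which
bridges the two breakpoint flanks of one insertion (orphan and clipped
anchors accumulate on both sides of the true insertion point, spread over
roughly one insert length).

A refined breakpoint estimate is attached to each call when the supporting
pairs are available: clipped-read junction positions when present, otherwise
the innermost orphan anchors on each strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core_io import AlignedPair, GenomeInterval, InsertSizeModel, RunConfig, revcomp
from .signal_tracks import TRACKS, SignalTrackSet, compute_tracks

logger = logging.getLogger("retrosite")


@dataclass
class InsertionCall:
    """A candidate insertion interval with per-track evidence.

    ``per_track_evidence`` maps each track name to ``(peak_count, z_score)``
    where the z-like score compares the in-call peak with the genome-wide
    window background.  ``breakpoint`` is the refined insertion-point
    estimate (set by :func:`refine_breakpoint`); it defaults to the interval
    midpoint.
    """

    interval: GenomeInterval
    per_track_evidence: dict[str, tuple[int, float]] = field(default_factory=dict)
    n_tracks_agreeing: int = 0
    supporting_pair_names: list[str] = field(default_factory=list)
    breakpoint: Optional[float] = None

    @property
    def score(self) -> int:
        return self.n_tracks_agreeing

    @property
    def position_estimate(self) -> float:
        return self.breakpoint if self.breakpoint is not None else self.interval.midpoint


def _thresholds(config: RunConfig) -> dict[str, Optional[int]]:
    return {
        "SHORT_INSERT": config.threshold_short_insert,
        "DISCORDANT": config.threshold_discordant,
        "ORPHAN": config.threshold_orphan,
        "CLIPPED": config.threshold_clipped,
        "DEPTH": config.threshold_depth,
    }


def integrate_tracks(track_set: SignalTrackSet, config: RunConfig | None = None) -> list[InsertionCall]:
    """Scan the windows of every chromosome and emit merged candidate calls.

    A track votes in a window when its count reaches its threshold
    (SHORT_INSERT, DISCORDANT, ORPHAN, CLIPPED) or, for DEPTH, when the
    count deviates from the genome-wide median by at least its threshold in
    either direction (insertion interiors lose uniquely mapped depth while
    breakpoints gain clipped pile-ups).  Windows with at least
    ``min_tracks_agreeing`` votes are merged (gap <= ``merge_gap_windows``)
    into calls sorted by (chrom, start); ties order by evidence descending.
    """
    config = config or RunConfig()
    for track in TRACKS:
        if track not in track_set.counts:
            raise ValueError(f"track {track} missing from track set")
    thresholds = _thresholds(config)

    depth_all = np.concatenate(
        [track_set.counts["DEPTH"][c] for c in track_set.chrom_lengths]
    ) if track_set.chrom_lengths else np.array([0])
    depth_median = float(np.median(depth_all)) if depth_all.size else 0.0

    background = {}
    for track in TRACKS:
        allv = np.concatenate([track_set.counts[track][c] for c in track_set.chrom_lengths])
        background[track] = (float(allv.mean()), float(allv.std()) or 1.0)

    calls: list[InsertionCall] = []
    for chrom in track_set.chrom_lengths:
        n = track_set.n_windows(chrom)
        votes = np.zeros(n, dtype=np.int64)
        voting = {}
        for track in TRACKS:
            thr = thresholds[track]
            if thr is None:
                voting[track] = np.zeros(n, dtype=bool)
                continue
            arr = track_set.counts[track][chrom]
            if track == "DEPTH":
                mask = np.abs(arr - depth_median) >= thr
            else:
                mask = arr >= thr
            voting[track] = mask
            votes += mask
        hot = np.flatnonzero(votes >= config.min_tracks_agreeing)
        if hot.size == 0:
            continue
        # merge voting windows separated by <= merge_gap_windows
        runs: list[tuple[int, int]] = []
        start = prev = int(hot[0])
        for w in hot[1:]:
            w = int(w)
            if w - prev - 1 <= config.merge_gap_windows:
                prev = w
            else:
                runs.append((start, prev))
                start = prev = w
        runs.append((start, prev))
        ws = track_set.window_size
        for w0, w1 in runs:
            iv = GenomeInterval(chrom, w0 * ws, min((w1 + 1) * ws, track_set.chrom_lengths[chrom]))
            evidence = {}
            agreeing = 0
            for track in TRACKS:
                seg = track_set.counts[track][chrom][w0 : w1 + 1]
                peak = int(seg.max()) if seg.size else 0
                mu, sd = background[track]
                evidence[track] = (peak, (peak - mu) / sd)
                if voting[track][w0 : w1 + 1].any():
                    agreeing += 1
            calls.append(
                InsertionCall(interval=iv, per_track_evidence=evidence, n_tracks_agreeing=agreeing)
            )
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start, -c.n_tracks_agreeing))
    logger.info("integrate_tracks: %d candidate call(s)", len(calls))
    return calls


def _anchored(pair: AlignedPair, call: InsertionCall, flank_bp: int) -> Optional[tuple]:
    """Return (anchor, other) if the pair has a mapped mate anchored within
    the call interval +- flank_bp whose partner is unmapped or heavily clipped."""
    iv = call.interval
    lo, hi = iv.start - flank_bp, iv.end + flank_bp
    for anchor, other in ((pair.a, pair.b), (pair.b, pair.a)):
        if not anchor.is_mapped or anchor.chrom != iv.chrom:
            continue
        if not (lo <= anchor.pos < hi):
            continue
        if (not other.is_mapped) or other.mapped_fraction <= 0.5:
            return anchor, other
    return None


def collect_discordant_mates(
    call: InsertionCall, pairs: Iterable[AlignedPair], flank_bp: int = 12000
) -> list[str]:
    """Gather the unmapped/heavily-clipped mate sequences of pairs anchored
    near the call, orientation-normalised to the forward strand of the
    inserted element as implied by the anchor.

    For a forward-strand anchor the partner read was sequenced from the
    opposite strand (innie orientation), so its sequence is
    reverse-complemented; reverse-strand anchors contribute their partner
    as sequenced.  Pairs contributing are recorded in
    ``call.supporting_pair_names``.
    """
    out: list[str] = []
    names: list[str] = []
    for pair in pairs:
        hit = _anchored(pair, call, flank_bp)
        if hit is None:
            continue
        anchor, other = hit
        if other.seq is None:
            continue
        seq = revcomp(other.seq) if anchor.strand == "+" else other.seq
        out.append(seq)
        names.append(pair.name)
    call.supporting_pair_names = names
    return out


def refine_breakpoint(
    call: InsertionCall,
    pairs: Sequence[AlignedPair],
    insert_model: InsertSizeModel | None = None,
    config: RunConfig | None = None,
) -> Optional[float]:
    """Estimate the insertion point within a call.

    Clipped reads place the junction exactly (at the boundary between their
    aligned and clipped portions); when none are available the innermost
    orphan anchors bracket the insertion: forward-strand anchors lie to its
    left, reverse-strand anchors to its right.  The estimate is stored on
    ``call.breakpoint`` and returned (None when no informative pair exists).
    """
    config = config or RunConfig()
    iv = call.interval
    lo, hi = iv.start - config.flank_bp, iv.end + config.flank_bp
    clip_points: list[float] = []
    left_bounds: list[int] = []
    right_bounds: list[int] = []
    cutoff = 1.0 - config.min_clipped_fraction
    for pair in pairs:
        for m, other in ((pair.a, pair.b), (pair.b, pair.a)):
            if not m.is_mapped or m.chrom != iv.chrom or not (lo <= m.pos < hi):
                continue
            if m.mapped_fraction < 1.0 and m.mapped_fraction <= cutoff:
                clip_points.append(float(m.pos if m.clip_side == "left" else m.end))
            elif not other.is_mapped:
                if m.strand == "+":
                    left_bounds.append(m.end)
                else:
                    right_bounds.append(m.pos)
    estimate: Optional[float] = None
    if clip_points:
        estimate = float(np.median(clip_points))
    elif left_bounds and right_bounds:
        estimate = (max(left_bounds) + min(right_bounds)) / 2
    elif left_bounds:
        estimate = float(max(left_bounds))
    elif right_bounds:
        estimate = float(min(right_bounds))
    call.breakpoint = estimate
    return estimate


def call_insertions(
    pairs: Sequence[AlignedPair],
    chrom_lengths: dict[str, int],
    insert_model: InsertSizeModel | None = None,
    config: RunConfig | None = None,
) -> list[InsertionCall]:
    """Full first-step pipeline: tracks, integration, breakpoint refinement."""
    insert_model = insert_model or InsertSizeModel()
    config = config or RunConfig()
    track_set = compute_tracks(pairs, chrom_lengths, insert_model, config)
    calls = integrate_tracks(track_set, config)
    for call in calls:
        refine_breakpoint(call, pairs, insert_model, config)
    return calls
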