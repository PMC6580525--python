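"""Second pipeline step: assemble discordant mates, classify the contigs.

The mates collected at each candidate insertion are assembled with a greedy
overlap-layout assembler; the resulting contigs — which contain the sequence
of the inserted element — are classified by local alignment against a panel
of annotated sequences (retrovirus / endogenous retrovirus / human / other)
standing in for a taxonomy-annotated nucleotide database.  Endogenous
retrovirus hits are confirmed by placing the contig's host flanks back onto
the reference near the call, and alleles at a known locus can be
reconstructed and compared base-by-base to a reference allele.

Alignment scoring is fixed (match +1, mismatch -2, gap open -4, gap extend
-1) so identity computations are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .core_io import GenomeInterval, RunConfig, revcomp
from .insertion_caller import InsertionCall, collect_discordant_mates

logger = logging.getLogger("retrosite")

CATEGORIES = ("retrovirus", "endogenous_retrovirus", "human", "other")

VERDICTS = (
    "novel_retrovirus",
    "known_polymorphic_ERV",
    "human_structural_variant",
    "unresolved",
)


def make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


# ---------------------------------------------------------------------------
# greedy overlap-layout assembly
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    sequence: str
    n_reads: int
    source_call: Optional[InsertionCall] = None

    def __len__(self) -> int:
        return len(self.sequence)


def _hamming_identity(a: str, b: str) -> float:
    if not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> int:
    """Longest suffix(a)/prefix(b) overlap at the required identity.

    Candidate overlaps are anchored on exact occurrences of b's leading
    ``min_overlap``-mer inside a (seed-and-extend; a mismatch inside the
    seed hides the overlap, acceptable for low error rates).  Returns the
    overlap length, ``len(b)`` when b is contained in a, or 0.
    """
    if len(a) < min_overlap or len(b) < min_overlap:
        return 0
    seed = b[:min_overlap]
    pos = a.find(seed)
    best = 0
    while pos != -1:
        o = len(a) - pos
        if o >= len(b):
            # potential containment of b inside a
            if _hamming_identity(b, a[pos : pos + len(b)]) >= min_identity:
                return len(b)
        elif o > best and _hamming_identity(a[pos:], b[:o]) >= min_identity:
            best = o
        pos = a.find(seed, pos + 1)
    return best


def assemble_contigs(
    reads: Sequence[str],
    min_overlap: int = 30,
    min_identity: float = 0.95,
    source_call: Optional[InsertionCall] = None,
) -> list[Contig]:
    """Greedy overlap-layout assembly of orientation-mixed reads.

    Repeatedly merges the pair of sequences with the longest suffix-prefix
    overlap (>= ``min_overlap`` at identity >= ``min_identity``; both
    orientations tried) until no merge is possible.  Contigs are returned
    sorted by length descending, then lexicographically, so the output is
    deterministic.
    """
    items: dict[int, tuple[str, int]] = {
        i: (r.upper(), 1) for i, r in enumerate(reads) if r
    }
    next_id = len(items)

    def candidates_for(i: int, j: int):
        """Best merge between items i and j over the four distinct
        orientation pairings (a->b, b->a, a->rc(b), rc(a)->b; the remaining
        combinations are reverse complements of these)."""
        out = []
        for left, right, flip_l, flip_r in (
            (i, j, False, False),
            (j, i, False, False),
            (i, j, False, True),
            (i, j, True, False),
        ):
            l_seq = items[left][0]
            r_seq = items[right][0]
            if flip_l:
                l_seq = revcomp(l_seq)
            if flip_r:
                r_seq = revcomp(r_seq)
            o = _best_overlap(l_seq, r_seq, min_overlap, min_identity)
            if o >= min_overlap:
                out.append((o, left, right, flip_l, flip_r))
        return out

    pool: list[tuple[int, int, int, bool, bool]] = []
    ids = sorted(items)
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            pool.extend(candidates_for(ids[x], ids[y]))

    while pool:
        pool.sort(key=lambda c: (-c[0], c[1], c[2], c[3], c[4]))
        o, left, right, flip_l, flip_r = pool[0]
        if left not in items or right not in items:
            pool = [c for c in pool if c[1] in items and c[2] in items]
            continue
        l_seq, l_n = items[left]
        r_seq, r_n = items[right]
        if flip_l:
            l_seq = revcomp(l_seq)
        if flip_r:
            r_seq = revcomp(r_seq)
        merged = l_seq if o >= len(r_seq) else l_seq + r_seq[o:]
        del items[left], items[right]
        pool = [c for c in pool if c[1] in items and c[2] in items]
        new_id = next_id
        next_id += 1
        items[new_id] = (merged, l_n + r_n)
        for other in sorted(items):
            if other != new_id:
                pool.extend(candidates_for(new_id, other))

    contigs = [
        Contig(sequence=seq, n_reads=n, source_call=source_call)
        for seq, n in items.values()
    ]
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return contigs


# ---------------------------------------------------------------------------
# panel classification
# ---------------------------------------------------------------------------


@dataclass
class PanelSequence:
    name: str
    sequence: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown panel category {self.category!r}")


def read_panel_fasta(path) -> list[PanelSequence]:
    """Panel FASTA whose description lines carry a ``category=`` tag."""
    from Bio import SeqIO

    panel = []
    for rec in SeqIO.parse(str(path), "fasta"):
        category = "other"
        for token in rec.description.split():
            if token.startswith("category="):
                category = token.split("=", 1)[1]
        panel.append(PanelSequence(rec.id, str(rec.seq).upper(), category))
    return panel


def write_panel_fasta(panel: Sequence[PanelSequence], path) -> None:
    with open(path, "w") as fh:
        for p in panel:
            fh.write(f">{p.name} category={p.category}\n")
            for i in range(0, len(p.sequence), 80):
                fh.write(p.sequence[i : i + 80] + "\n")


@dataclass
class PanelHit:
    contig: Contig
    panel_sequence_name: str
    category: str
    aligned_length: int
    identity: float
    score: float
    strand: str
    contig_span: tuple[int, int]
    contig_flanks: list[str] = field(default_factory=list)
    #: panel-entry bases outside the matched region — the host context a
    #: database entry for a polymorphic insertion carries around the element
    panel_flanks: list[str] = field(default_factory=list)

    @property
    def flanks(self) -> list[str]:
        return self.contig_flanks + self.panel_flanks

    @property
    def rank_key(self) -> float:
        return self.identity * self.aligned_length


def _align_stats(alignment) -> tuple[int, int, int]:
    counts = alignment.counts()
    return counts.identities, counts.mismatches, counts.gaps


def classify_contig(
    contig: Contig,
    panel: Sequence[PanelSequence],
    min_aligned_len: int = 100,
    min_identity: float = 0.80,
) -> list[PanelHit]:
    """Local-align the contig against every panel sequence (both strands).

    Hits with aligned length >= ``min_aligned_len`` and identity >=
    ``min_identity`` are returned best-first by identity x aligned length.
    ``contig_flanks`` holds the contig bases outside the best local
    alignment (the putative host flanks of an inserted element).
    """
    if not panel:
        raise ValueError("classification panel is empty")
    aligner = make_aligner("local")
    hits: list[PanelHit] = []
    for entry in panel:
        for strand, query in (("+", entry.sequence), ("-", revcomp(entry.sequence))):
            try:
                alignments = aligner.align(contig.sequence, query)
                aln = alignments[0]
            except (ValueError, IndexError, OverflowError):
                continue
            if aln.score <= 0:
                continue
            ident, mism, gaps = _align_stats(aln)
            columns = ident + mism + gaps
            if columns == 0:
                continue
            identity = ident / columns
            t_segments = aln.aligned[0]
            t_start = int(t_segments[0][0])
            t_end = int(t_segments[-1][1])
            aligned_length = t_end - t_start
            if aligned_length < min_aligned_len or identity < min_identity:
                continue
            flanks = []
            if t_start > 0:
                flanks.append(contig.sequence[:t_start])
            if t_end < len(contig.sequence):
                flanks.append(contig.sequence[t_end:])
            q_segments = aln.aligned[1]
            q_start = int(q_segments[0][0])
            q_end = int(q_segments[-1][1])
            panel_flanks = []
            if q_start > 0:
                panel_flanks.append(query[:q_start])
            if q_end < len(query):
                panel_flanks.append(query[q_end:])
            hits.append(
                PanelHit(
                    contig=contig,
                    panel_sequence_name=entry.name,
                    category=entry.category,
                    aligned_length=aligned_length,
                    identity=identity,
                    score=float(aln.score),
                    strand=strand,
                    contig_span=(t_start, t_end),
                    contig_flanks=flanks,
                    panel_flanks=panel_flanks,
                )
            )
    # keep the better strand per panel entry, then best-first overall
    best: dict[str, PanelHit] = {}
    for h in hits:
        if h.panel_sequence_name not in best or h.rank_key > best[h.panel_sequence_name].rank_key:
            best[h.panel_sequence_name] = h
    out = sorted(best.values(), key=lambda h: (-h.rank_key, h.panel_sequence_name))
    return out


def confirm_flank_placement(
    hit: PanelHit,
    reference: str | dict[str, str],
    call: InsertionCall,
    max_distance: int = 5000,
    min_flank_len: int = 50,
    min_flank_identity: float = 0.95,
) -> bool:
    """True iff one of the hit's contig flanks aligns (identity >= 0.95 over
    >= 50 bp) to the reference within ``call.interval`` +- ``max_distance``.

    This is the placement check that ties an ERV-matching contig back to the
    called insertion site via its host flanking sequence.
    """
    if not hit.flanks:
        return False
    iv = call.interval
    ref_seq = reference[iv.chrom] if isinstance(reference, dict) else reference
    lo = max(0, iv.start - max_distance)
    hi = min(len(ref_seq), iv.end + max_distance)
    region = ref_seq[lo:hi]
    if not region:
        return False
    aligner = make_aligner("local")
    for flank in hit.flanks:
        if len(flank) < min_flank_len:
            continue
        for query in (flank, revcomp(flank)):
            try:
                aln = aligner.align(region, query)[0]
            except (ValueError, IndexError, OverflowError):
                continue
            ident, mism, gaps = _align_stats(aln)
            columns = ident + mism + gaps
            if columns >= min_flank_len and ident / columns >= min_flank_identity:
                return True
    return False


# ---------------------------------------------------------------------------
# allele reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AlleleReconstruction:
    sequence: str
    substitutions: list[tuple[int, str, str]]
    covered_fraction: float
    partial: bool
    n_reads: int


def _edlib_substitutions(contig: str, allele: str) -> tuple[list[tuple[int, str, str]], float]:
    """Substitution list (allele position, ref base, alt base) and covered
    fraction, from an edlib alignment of the allele within the contig."""
    mode = "NW" if abs(len(contig) - len(allele)) <= 0.1 * len(allele) else "HW"
    res = edlib.align(allele, contig, mode=mode, task="path")
    nice = edlib.getNiceAlignment(res, allele, contig)
    q, t = nice["query_aligned"], nice["target_aligned"]
    subs: list[tuple[int, str, str]] = []
    qpos = 0  # position on the allele
    covered = 0
    for qb, tb in zip(q, t):
        if qb != "-" and tb != "-":
            covered += 1
            if qb != tb:
                subs.append((qpos, qb, tb))
        if qb != "-":
            qpos += 1
    return subs, covered / len(allele)


def reconstruct_locus_allele(
    locus,
    pairs: Sequence,
    reference_allele: str,
    config: RunConfig | None = None,
) -> AlleleReconstruction:
    """Assemble the non-anchored mates of pairs flanking a locus and compare
    the assembly to a reference allele.

    Pairs qualify when one mate is anchored in the locus flank (within
    ``config.flank_bp`` outside the locus interval) and the other is
    unmapped or maps inside the locus.  Substitutions are reported as
    ``(allele position, reference base, observed base)``.  When the
    assembly covers less than 95% of the allele the result is flagged
    partial with its covered fraction.
    """
    config = config or RunConfig()
    iv: GenomeInterval = locus.interval if hasattr(locus, "interval") else locus
    lo, hi = iv.start - config.flank_bp, iv.end + config.flank_bp
    seqs: list[str] = []
    for pair in pairs:
        for anchor, other in ((pair.a, pair.b), (pair.b, pair.a)):
            if not anchor.is_mapped or anchor.chrom != iv.chrom:
                continue
            in_flank = (lo <= anchor.pos < iv.start) or (iv.end <= anchor.pos < hi)
            if not in_flank:
                continue
            other_in_locus = (
                other.is_mapped
                and other.chrom == iv.chrom
                and iv.start <= other.pos < iv.end
            )
            if not (other_in_locus or not other.is_mapped):
                continue
            if other.seq is None:
                continue
            if other.is_mapped:
                seqs.append(other.seq if other.strand == "+" else revcomp(other.seq))
            else:
                seqs.append(revcomp(other.seq) if anchor.strand == "+" else other.seq)
            break
    if not seqs:
        return AlleleReconstruction("", [], 0.0, True, 0)
    contigs = assemble_contigs(seqs, config.min_overlap, config.min_identity)
    contig = contigs[0]
    fwd = edlib.align(reference_allele, contig.sequence, mode="HW")["editDistance"]
    rev = edlib.align(reference_allele, revcomp(contig.sequence), mode="HW")["editDistance"]
    seq = contig.sequence if fwd <= rev else revcomp(contig.sequence)
    subs, covered = _edlib_substitutions(seq, reference_allele)
    return AlleleReconstruction(
        sequence=seq,
        substitutions=subs,
        covered_fraction=covered,
        partial=covered < 0.95,
        n_reads=contig.n_reads,
    )


# ---------------------------------------------------------------------------
# call screening
# ---------------------------------------------------------------------------


def screen_calls(
    calls: Sequence[InsertionCall],
    pairs: Sequence,
    panel: Sequence[PanelSequence],
    reference: str | dict[str, str] | None = None,
    config: RunConfig | None = None,
    max_contigs: int = 3,
) -> pd.DataFrame:
    """Assemble, classify and flank-confirm every call; assign a verdict.

    Verdicts follow the precedence human > endogenous retrovirus >
    retrovirus > unresolved: a best hit in the human category short-circuits
    to ``human_structural_variant`` before the retrovirus keyword pass, so
    human structural variation is never mistaken for a viral insertion.
    """
    config = config or RunConfig()
    rows = []
    for call in calls:
        mates = collect_discordant_mates(call, pairs, config.flank_bp)
        verdict = "unresolved"
        best_hit_name = "."
        best_identity = np.nan
        best_aligned = 0
        flank_confirmed = False
        n_contigs = 0
        if mates:
            contigs = assemble_contigs(
                mates, config.min_overlap, config.min_identity, source_call=call
            )
            contigs = [c for c in contigs if c.n_reads >= 1][:max_contigs]
            n_contigs = len(contigs)
            all_hits: list[PanelHit] = []
            for contig in contigs:
                all_hits.extend(
                    classify_contig(
                        contig, panel, config.min_aligned_len, config.min_hit_identity
                    )
                )
            all_hits.sort(key=lambda h: -h.rank_key)
            if all_hits:
                top = all_hits[0]
                best_hit_name = top.panel_sequence_name
                best_identity = round(top.identity, 4)
                best_aligned = top.aligned_length
                if top.category == "human":
                    verdict = "human_structural_variant"
                else:
                    erv_hits = [h for h in all_hits if h.category == "endogenous_retrovirus"]
                    rv_hits = [h for h in all_hits if h.category == "retrovirus"]
                    if erv_hits:
                        verdict = "known_polymorphic_ERV"
                        hit = erv_hits[0]
                        best_hit_name = hit.panel_sequence_name
                        best_identity = round(hit.identity, 4)
                        best_aligned = hit.aligned_length
                        if reference is not None:
                            flank_confirmed = confirm_flank_placement(
                                hit, reference, call, config.flank_bp
                            )
                    elif rv_hits:
                        verdict = "novel_retrovirus"
                        hit = rv_hits[0]
                        best_hit_name = hit.panel_sequence_name
                        best_identity = round(hit.identity, 4)
                        best_aligned = hit.aligned_length
        rows.append(
            {
                "chrom": call.interval.chrom,
                "start": call.interval.start,
                "end": call.interval.end,
                "verdict": verdict,
                "bestHit": best_hit_name,
                "identity": best_identity,
                "alignedLength": best_aligned,
                "flankConfirmed": flank_confirmed,
                "nContigs": n_contigs,
                "nSupportingReads": len(mates),
            }
        )
    logger.info("screen_calls: %d call(s) screened", len(rows))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "verdict", "bestHit", "identity",
            "alignedLength", "flankConfirmed", "nContigs", "nSupportingReads",
        ],
    )
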