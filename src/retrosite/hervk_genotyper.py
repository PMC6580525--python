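"""HERV-K provirus genotyping from unique k-mers and from mate-pair evidence.

Each HERV-K locus is characterised by the set ``T`` of k-mers that occur in
its known allele sequence(s) but nowhere else — not in the reference genome
with the locus masked out and not in any other locus's alleles.  ``T`` is
partitioned into LTR-only and internal k-mers using the LTR annotations of
each allele.  For an individual, ``n`` counts the distinct members of ``T``
observed as exact (canonical-form) matches anywhere in the reads; the ratio
``n/T`` is 1 when the reference allele is present and drops below 1 when
the individual carries a divergent allele, a solo LTR, or lacks the
provirus, because any polymorphism inside a k-mer excludes it from the
count.  The locus state (absence / solo LTR / provirus) is called from the
partition ratios.

A second, independent path calls the same states from mate-pair mapping
evidence (read occupancy across the locus for proviruses present in the
reference, anchored orphan mates for proviruses absent from it), which is
how k-mer calls are cross-validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    AlignedPair,
    GenomeInterval,
    InsertSizeModel,
    RunConfig,
    read_fasta,
    read_fastq,
    revcomp,
)

logger = logging.getLogger("retrosite")

STATES = ("absence", "solo_LTR", "provirus")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def canonical_kmers(seq: str, k: int) -> Iterable[int]:
    """Yield 2-bit-encoded canonical k-mers (min of k-mer and its reverse
    complement) over ``seq``; windows containing non-ACGT bases are skipped.

    Encoding is rolling, so the scan is linear in ``len(seq)``.
    """
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = rev = 0
    valid = 0
    for ch in seq:
        code = _CODE.get(ch)
        if code is None:
            valid = 0
            continue
        fwd = ((fwd << 2) | code) & mask
        rev = (rev >> 2) | ((3 - code) << shift)
        valid += 1
        if valid >= k:
            yield fwd if fwd <= rev else rev


def canonical_kmer_positions(seq: str, k: int) -> Iterable[tuple[int, int]]:
    """Like :func:`canonical_kmers` but yields ``(start_position, code)``."""
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = rev = 0
    valid = 0
    for i, ch in enumerate(seq):
        code = _CODE.get(ch)
        if code is None:
            valid = 0
            continue
        fwd = ((fwd << 2) | code) & mask
        rev = (rev >> 2) | ((3 - code) << shift)
        valid += 1
        if valid >= k:
            yield i - k + 1, (fwd if fwd <= rev else rev)


@dataclass
class HervKLocus:
    """One HERV-K locus: reference placement, known alleles, unique k-mers.

    ``interval`` is the provirus span for loci represented in the reference,
    or a 1 bp pre-integration point for loci absent from it
    (``in_reference=False``).  ``ltr_annotations[i]`` lists the LTR
    intervals on ``allele_seqs[i]``.
    """

    id: str
    interval: GenomeInterval
    allele_seqs: list[str]
    ltr_annotations: list[list[tuple[int, int]]]
    in_reference: bool = True
    kmers_internal: frozenset[int] = frozenset()
    kmers_ltr: frozenset[int] = frozenset()
    k: int = 0
    flagged_unusable: bool = False

    @property
    def T(self) -> int:
        return len(self.kmers_internal) + len(self.kmers_ltr)

    @property
    def ltr_length(self) -> int:
        s, e = self.ltr_annotations[0][0]
        return e - s


@dataclass
class HervKGenotype:
    """n/T evidence and called state for one locus in one individual."""

    locus_id: str
    n: int
    T: int
    n_internal: int
    T_internal: int
    n_ltr: int
    T_ltr: int
    state: Optional[str] = None
    warning: Optional[str] = None

    @property
    def ratio(self) -> float:
        return self.n / self.T if self.T else 0.0

    @property
    def internal_ratio(self) -> Optional[float]:
        return self.n_internal / self.T_internal if self.T_internal else None

    @property
    def ltr_ratio(self) -> Optional[float]:
        return self.n_ltr / self.T_ltr if self.T_ltr else None


# ---------------------------------------------------------------------------
# unique k-mer construction and counting
# ---------------------------------------------------------------------------


def _mask_reference(reference: str, loci: Sequence[HervKLocus]) -> str:
    chars = list(reference)
    for locus in loci:
        if locus.in_reference:
            iv = locus.interval
            chars[iv.start : iv.end] = "N" * (iv.end - iv.start)
    return "".join(chars)


def build_unique_kmers(
    loci: Sequence[HervKLocus], reference_genome: str, k: int = 25
) -> list[HervKLocus]:
    """Populate each locus's unique k-mer set ``T`` (in place; also returned).

    A k-mer belongs to a locus's ``T`` when it occurs in at least one of the
    locus's alleles, does not occur in the reference genome with the locus
    intervals masked, and does not occur in any other locus's alleles.  It
    is assigned to the LTR-only partition when every allele occurrence lies
    fully inside an LTR annotation, and to the internal partition otherwise
    (so LTR/internal junction k-mers witness the proviral interior).  A
    locus whose ``T`` comes out empty is flagged unusable.
    """
    if k < 11 or k % 2 == 0:
        raise ValueError("k must be odd and >= 11")
    masked = _mask_reference(reference_genome, loci)
    ref_kmers = set(canonical_kmers(masked, k))

    per_locus: list[dict[int, bool]] = []  # code -> ltr_only over all alleles
    for locus in loci:
        table: dict[int, bool] = {}
        for allele, ltrs in zip(locus.allele_seqs, locus.ltr_annotations):
            for pos, code in canonical_kmer_positions(allele, k):
                inside_ltr = any(s <= pos and pos + k <= e for s, e in ltrs)
                table[code] = table.get(code, True) and inside_ltr
        per_locus.append(table)

    occurrences: dict[int, int] = {}
    for table in per_locus:
        for code in table:
            occurrences[code] = occurrences.get(code, 0) + 1

    for locus, table in zip(loci, per_locus):
        ltr = set()
        internal = set()
        for code, ltr_only in table.items():
            if code in ref_kmers or occurrences[code] > 1:
                continue
            (ltr if ltr_only else internal).add(code)
        locus.kmers_internal = frozenset(internal)
        locus.kmers_ltr = frozenset(ltr)
        locus.k = k
        locus.flagged_unusable = locus.T == 0
        if locus.flagged_unusable:
            logger.warning("locus %s has no unique k-mers; flagged unusable", locus.id)
    return list(loci)


def count_matches(
    reads: Iterable[str] | str | Path,
    loci: Sequence[HervKLocus],
    k: int = 25,
) -> dict[str, HervKGenotype]:
    """Count, per locus, the distinct unique k-mers observed in the reads.

    ``reads`` may be an iterable of sequences or a FASTQ path.  Matching is
    exact on canonical k-mers: a read k-mer carrying an error or a
    polymorphism at any position does not count, which is what pushes n/T
    below 1 for divergent alleles.
    """
    lookup: dict[int, tuple[int, bool]] = {}  # code -> (locus index, is_ltr)
    for idx, locus in enumerate(loci):
        for code in locus.kmers_internal:
            lookup[code] = (idx, False)
        for code in locus.kmers_ltr:
            lookup[code] = (idx, True)
    observed_int: list[set[int]] = [set() for _ in loci]
    observed_ltr: list[set[int]] = [set() for _ in loci]
    if isinstance(reads, (str, Path)):
        reads = (seq for _, seq in read_fastq(reads))
    for seq in reads:
        for code in canonical_kmers(seq, k):
            hit = lookup.get(code)
            if hit is None:
                continue
            idx, is_ltr = hit
            (observed_ltr if is_ltr else observed_int)[idx].add(code)
    out = {}
    for idx, locus in enumerate(loci):
        n_int = len(observed_int[idx])
        n_ltr = len(observed_ltr[idx])
        out[locus.id] = HervKGenotype(
            locus_id=locus.id,
            n=n_int + n_ltr,
            T=locus.T,
            n_internal=n_int,
            T_internal=len(locus.kmers_internal),
            n_ltr=n_ltr,
            T_ltr=len(locus.kmers_ltr),
        )
    return out


def call_state(
    genotype: HervKGenotype, t_provirus: float = 0.5, t_solo_ltr: float = 0.5
) -> str:
    """Three-state call from the partition ratios.

    ``provirus`` when the internal-partition ratio reaches ``t_provirus``;
    otherwise ``solo_LTR`` when the LTR-only ratio reaches ``t_solo_ltr``;
    otherwise ``absence``.  When a partition is empty the call is made from
    the available partition and a warning is recorded on the genotype.
    """
    internal = genotype.internal_ratio
    ltr = genotype.ltr_ratio
    if internal is None and ltr is None:
        genotype.warning = "no usable k-mers"
        genotype.state = "absence"
        return genotype.state
    if internal is None:
        genotype.warning = "internal partition empty"
        genotype.state = "provirus" if ltr >= t_provirus else "absence"
        return genotype.state
    if ltr is None and internal < t_provirus:
        genotype.warning = "LTR partition empty"
    if internal >= t_provirus:
        genotype.state = "provirus"
    elif ltr is not None and ltr >= t_solo_ltr:
        genotype.state = "solo_LTR"
    else:
        genotype.state = "absence"
    return genotype.state


def genotype_individual(
    reads: Iterable[str] | str | Path,
    loci: Sequence[HervKLocus],
    config: RunConfig | None = None,
) -> dict[str, HervKGenotype]:
    """k-mer path end to end: count matches and call a state per locus."""
    config = config or RunConfig()
    genotypes = count_matches(reads, loci, config.k)
    for g in genotypes.values():
        call_state(g, config.t_provirus, config.t_solo_ltr)
    return genotypes


def genotypes_to_frame(per_individual: dict[str, dict[str, HervKGenotype]]) -> pd.DataFrame:
    """Long-format table (individual, locus, n, T, ratio, state)."""
    rows = []
    for individual, genos in per_individual.items():
        for locus_id, g in genos.items():
            rows.append(
                {
                    "individual": individual,
                    "locus": locus_id,
                    "n": g.n,
                    "T": g.T,
                    "ratio": round(g.ratio, 6),
                    "state": g.state,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mate-pair evidence path
# ---------------------------------------------------------------------------


def anchor_discovery(
    pairs: Iterable[AlignedPair],
    hervk_reference_seq: str,
    cluster_window: int = 10000,
    min_anchors: int = 3,
    max_divergence: float = 0.05,
) -> list[dict]:
    """Cluster the reference positions of mates whose partner looks like
    HERV-K, to find candidate (possibly low-frequency) insertion sites.

    The unmapped read of each orphan pair is matched against the provided
    full-length HERV-K sequence (exact substring first, then a banded
    edit-distance alignment allowing ``max_divergence``).  Anchors within
    ``cluster_window`` of each other on a chromosome merge; clusters with at
    least ``min_anchors`` members are reported.
    """
    import edlib

    anchors: dict[str, list[int]] = {}
    target = hervk_reference_seq
    for pair in pairs:
        if pair.n_mapped != 1:
            continue
        mapped = pair.a if pair.a.is_mapped else pair.b
        other = pair.b if pair.a.is_mapped else pair.a
        seq = other.seq
        if not seq:
            continue
        is_hervk = seq in target or revcomp(seq) in target
        if not is_hervk and max_divergence > 0:
            limit = int(max_divergence * len(seq))
            for q in (seq, revcomp(seq)):
                if edlib.align(q, target, mode="HW", k=limit)["editDistance"] != -1:
                    is_hervk = True
                    break
        if is_hervk:
            anchors.setdefault(mapped.chrom, []).append(mapped.pos)
    sites = []
    for chrom in sorted(anchors):
        positions = sorted(anchors[chrom])
        cluster = [positions[0]]
        for pos in positions[1:] + [None]:
            if pos is not None and pos - cluster[-1] <= cluster_window:
                cluster.append(pos)
            else:
                if len(cluster) >= min_anchors:
                    sites.append(
                        {
                            "chrom": chrom,
                            "start": cluster[0],
                            "end": cluster[-1] + 1,
                            "position": float(np.median(cluster)),
                            "n_anchors": len(cluster),
                        }
                    )
                if pos is not None:
                    cluster = [pos]
    return sites


def _region_occupancy(pairs: Sequence[AlignedPair], iv: GenomeInterval) -> np.ndarray:
    cov = np.zeros(iv.length, dtype=bool)
    for pair in pairs:
        for m in pair.mates:
            if m.is_mapped and m.chrom == iv.chrom and m.pos < iv.end and m.end > iv.start:
                lo = max(m.pos, iv.start) - iv.start
                hi = min(m.end, iv.end) - iv.start
                cov[lo:hi] = True
    return cov


def genotype_locus_matepair(
    locus: HervKLocus,
    pairs: Sequence[AlignedPair],
    insert_model: InsertSizeModel | None = None,
    min_occupancy: float = 0.2,
    min_reads: int = 3,
) -> str:
    """Call the locus state from mate-pair mapping evidence alone.

    For a locus whose reference allele is the provirus, the state follows
    from read occupancy: reads covering the proviral interior imply the
    provirus, reads confined to the 5' LTR imply a solo LTR, and an
    uncovered locus implies absence (the deletion is corroborated by
    longer-than-expected spans but occupancy alone separates the states).
    For a locus absent from the reference, orphan mates anchored within one
    insert length of the pre-integration site are located on the provirus
    allele: any mate touching the proviral interior implies the provirus,
    LTR-only mates a solo LTR, and no anchored mates absence.
    """
    insert_model = insert_model or InsertSizeModel()
    allele = locus.allele_seqs[0]
    ltr_intervals = locus.ltr_annotations[0]
    ltr_len = ltr_intervals[0][1] - ltr_intervals[0][0]
    iv = locus.interval
    if locus.in_reference:
        ltr_region = GenomeInterval(iv.chrom, iv.start, iv.start + ltr_len)
        interior = GenomeInterval(iv.chrom, iv.start + ltr_len, iv.end)
        interior_occ = _region_occupancy(pairs, interior).mean()
        ltr_occ = _region_occupancy(pairs, ltr_region).mean()
        if interior_occ >= min_occupancy:
            return "provirus"
        if ltr_occ >= min_occupancy:
            return "solo_LTR"
        return "absence"
    # non-reference locus: classify the content of anchored orphan mates
    flank = insert_model.expected_high
    internal_lo, internal_hi = ltr_len, len(allele) - ltr_len
    n_internal = 0
    n_ltr = 0
    for pair in pairs:
        if pair.n_mapped != 1:
            continue
        mapped = pair.a if pair.a.is_mapped else pair.b
        other = pair.b if pair.a.is_mapped else pair.a
        if mapped.chrom != iv.chrom or not (iv.start - flank <= mapped.pos < iv.end + flank):
            continue
        seq = other.seq
        if not seq:
            continue
        pos = allele.find(seq)
        if pos == -1:
            pos = allele.find(revcomp(seq))
        if pos == -1:
            continue
        if pos < internal_hi and pos + len(seq) > internal_lo:
            n_internal += 1
        else:
            n_ltr += 1
    if n_internal >= min_reads:
        return "provirus"
    if n_ltr >= min_reads:
        return "solo_LTR"
    return "absence"


def genotype_matrix_matepair(
    per_individual_pairs: dict[str, Sequence[AlignedPair]],
    loci: Sequence[HervKLocus],
    insert_model: InsertSizeModel | None = None,
) -> pd.DataFrame:
    """States from the mate-pair path for all individuals x loci."""
    rows = {
        individual: {
            locus.id: genotype_locus_matepair(locus, pairs, insert_model)
            for locus in loci
        }
        for individual, pairs in per_individual_pairs.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[[l.id for l in loci]]


def genotype_matrix_kmer(
    per_individual_reads: dict[str, Iterable[str]],
    loci: Sequence[HervKLocus],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """States from the k-mer path for all individuals x loci."""
    rows = {}
    for individual, reads in per_individual_reads.items():
        genos = genotype_individual(reads, loci, config)
        rows[individual] = {lid: g.state for lid, g in genos.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[[l.id for l in loci]]


def concordance(states_a: pd.DataFrame, states_b: pd.DataFrame) -> float:
    """Fraction of (individual, locus) cells with identical state calls."""
    if states_a.shape != states_b.shape:
        raise ValueError("state matrices have different shapes")
    b = states_b.loc[states_a.index, states_a.columns]
    return float((states_a.values == b.values).mean())


# ---------------------------------------------------------------------------
# locus panel I/O
# ---------------------------------------------------------------------------


def read_locus_panel(panel_tsv: str | Path) -> list[HervKLocus]:
    """Locus panel TSV: id, chrom, start, end, inReference, alleleFasta, ltrBed.

    Paths are resolved relative to the TSV.  The LTR BED holds one line per
    LTR interval per allele, named ``<alleleName>`` in column 4.
    """
    base = Path(panel_tsv).parent
    df = pd.read_csv(panel_tsv, sep="\t", dtype={"chrom": str})
    loci = []
    for _, row in df.iterrows():
        alleles = read_fasta(base / row["alleleFasta"])
        ltrs: dict[str, list[tuple[int, int]]] = {name: [] for name in alleles}
        with open(base / row["ltrBed"]) as fh:
            for line in fh:
                if not line.strip():
                    continue
                parts = line.split("\t")
                ltrs[parts[3].strip()].append((int(parts[1]), int(parts[2])))
        loci.append(
            HervKLocus(
                id=str(row["id"]),
                interval=GenomeInterval(str(row["chrom"]), int(row["start"]), int(row["end"])),
                allele_seqs=list(alleles.values()),
                ltr_annotations=[sorted(ltrs[name]) for name in alleles],
                in_reference=bool(row["inReference"]),
            )
        )
    return loci


def write_locus_panel(loci: Sequence[HervKLocus], out_dir: str | Path, chrom_field: bool = True) -> Path:
    """Write a locus panel (TSV + per-locus allele FASTA and LTR BED)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for locus in loci:
        fasta = out / f"{locus.id}_alleles.fa"
        bed = out / f"{locus.id}_ltrs.bed"
        with open(fasta, "w") as fh:
            for i, seq in enumerate(locus.allele_seqs):
                fh.write(f">{locus.id}_allele{i}\n")
                for j in range(0, len(seq), 80):
                    fh.write(seq[j : j + 80] + "\n")
        with open(bed, "w") as fh:
            for i, ltrs in enumerate(locus.ltr_annotations):
                for s, e in ltrs:
                    fh.write(f"{locus.id}\t{s}\t{e}\t{locus.id}_allele{i}\n")
        rows.append(
            {
                "id": locus.id,
                "chrom": locus.interval.chrom,
                "start": locus.interval.start,
                "end": locus.interval.end,
                "inReference": locus.in_reference,
                "alleleFasta": fasta.name,
                "ltrBed": bed.name,
            }
        )
    tsv = out / "loci.tsv"
    pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)
    return tsv
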