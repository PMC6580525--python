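"""Long-insert mate-pair simulator with truth records.

Generates synthetic references, plants insertions (or more general edits) at
a chosen cell prevalence, and draws mate pairs from the resulting mixture of
carrier and reference haplotypes.  Cell prevalence is modelled per fragment:
each fragment is drawn from the carrier haplotype with probability
``prevalence`` and from the unedited reference otherwise, which mirrors a
clonal cell fraction.

Reads carry their true placement, so the signal tracks can be computed
without an external mapper ("oracle alignment"): a read is mapped at the
reference coordinates of its dominant reference-derived segment, partially
mapped (soft-clip semantics) when it straddles an edit junction, and
unmapped when fewer than ``MIN_MAPPABLE_BASES`` of it derive from the
reference.  A real mapper's BAM is the production input path; the oracle
path exists so simulation experiments are deterministic and fast.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    AlignedPair,
    GenomeInterval,
    InsertSizeModel,
    MateInfo,
    RunConfig,
    revcomp,
)

BASES = np.array(list("ACGT"))

#: a read must derive at least this many bases from the reference to be
#: considered mappable by the oracle aligner (roughly a mapper seed length)
MIN_MAPPABLE_BASES = 32

DEFAULT_CHROM = "chrSim"


def make_reference(length: int, seed: int) -> str:
    """Pseudo-random i.i.d. ACGT sequence, reproducible by seed."""
    if length <= 0:
        raise ValueError("reference length must be positive")
    rng = np.random.default_rng(seed)
    return "".join(BASES[rng.integers(0, 4, size=length)])


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# carrier genome model
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    kind: str  # "ref" or "ins"
    ref_start: int = 0
    ref_end: int = 0
    seq: str = ""

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start if self.kind == "ref" else len(self.seq)


class CarrierGenome:
    """A haplotype expressed as a sequence of reference blocks and novel
    insertions, supporting liftover of read positions back to the reference."""

    def __init__(self, reference: str, segments: list[_Segment], chrom: str = DEFAULT_CHROM):
        self.reference = reference
        self.chrom = chrom
        self.segments = [s for s in segments if s.length > 0]
        self._starts: list[int] = []
        pos = 0
        parts = []
        for seg in self.segments:
            self._starts.append(pos)
            pos += seg.length
            parts.append(
                reference[seg.ref_start : seg.ref_end] if seg.kind == "ref" else seg.seq
            )
        self._length = pos
        self.sequence = "".join(parts)

    def __len__(self) -> int:
        return self._length

    @classmethod
    def identity(cls, reference: str, chrom: str = DEFAULT_CHROM) -> "CarrierGenome":
        return cls(reference, [_Segment("ref", 0, len(reference))], chrom)

    @classmethod
    def from_edits(
        cls,
        reference: str,
        edits: Sequence[tuple[int, int, str]],
        chrom: str = DEFAULT_CHROM,
    ) -> "CarrierGenome":
        """Apply non-overlapping edits ``(start, end, replacement)`` to the
        reference: the region [start, end) is replaced by ``replacement``
        (empty string = deletion; start == end = pure insertion)."""
        segs: list[_Segment] = []
        cursor = 0
        for start, end, ins in sorted(edits):
            if start < cursor or end > len(reference) or start > end:
                raise ValueError(f"invalid or overlapping edit ({start}, {end})")
            if start > cursor:
                segs.append(_Segment("ref", cursor, start))
            if ins:
                segs.append(_Segment("ins", seq=ins))
            cursor = end
        if cursor < len(reference):
            segs.append(_Segment("ref", cursor, len(reference)))
        return cls(reference, segs, chrom)

    def locate(self, x: int, length: int) -> Optional[tuple[int, int, float, Optional[str]]]:
        """Oracle-align the carrier interval [x, x+length).

        Returns ``(ref_pos, aligned_len, mapped_fraction, clip_side)`` for
        the dominant reference-derived block of the read, or ``None`` when
        fewer than ``MIN_MAPPABLE_BASES`` derive from the reference.
        """
        end = x + length
        i = bisect_right(self._starts, x) - 1
        best: Optional[tuple[int, int, int]] = None  # (overlap, ref_pos, read_off)
        while i < len(self.segments) and self._starts[i] < end:
            seg = self.segments[i]
            s0 = self._starts[i]
            lo, hi = max(x, s0), min(end, s0 + seg.length)
            if seg.kind == "ref" and hi > lo:
                overlap = hi - lo
                if best is None or overlap > best[0]:
                    best = (overlap, seg.ref_start + (lo - s0), lo - x)
            i += 1
        if best is None or best[0] < min(MIN_MAPPABLE_BASES, length):
            return None
        overlap, ref_pos, read_off = best
        frac = overlap / length
        clip_side: Optional[str] = None
        if frac < 1.0:
            left_clip = read_off
            right_clip = length - read_off - overlap
            clip_side = "left" if left_clip >= right_clip else "right"
        return ref_pos, overlap, frac, clip_side


def plant_insertion(reference: str, insert_seq: str, point: int, chrom: str = DEFAULT_CHROM) -> CarrierGenome:
    """Splice ``insert_seq`` into the reference at ``point`` (0 < point < len)."""
    if not (0 < point < len(reference)):
        raise ValueError(f"insertion point {point} out of range")
    return CarrierGenome.from_edits(reference, [(point, point, insert_seq)], chrom)


# ---------------------------------------------------------------------------
# simulation config / truth
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Conditions for one mate-pair simulation.

    Defaults mirror the tuning conditions of the insertion caller: a 1 Mbp
    reference, an 8 kbp insertion, 20x physical coverage of an 8 kbp-insert
    library (fragment sizes truncated to 5-12 kbp), 125 bp reads, and a
    0.1% substitution error rate.
    """

    reference_length: int = 1_000_000
    insert_length: int = 8000
    prevalence: float = 1.0
    physical_coverage: float = 20.0
    read_length: int = 125
    insert_model: InsertSizeModel = field(default_factory=InsertSizeModel)
    substitution_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if self.insert_length <= 0:
            raise ValueError("insert_length must be positive")
        if self.read_length >= self.insert_model.expected_low:
            raise ValueError("read_length must be below the expected insert range")


@dataclass
class TruthRecord:
    """Ground truth for one planted insertion."""

    insertion_point: GenomeInterval
    inserted_sequence: str
    prevalence: float

    @property
    def point(self) -> int:
        return self.insertion_point.start


@dataclass
class SimulatedReads:
    """Output of :func:`generate_mate_pairs`."""

    pairs: list[AlignedPair]
    reads: list[tuple[str, str]]  # FASTQ emission order: r1, r2 per fragment
    n_fragments: int
    config: SimulationConfig


def _truncated_normal(rng: np.random.Generator, model: InsertSizeModel) -> int:
    while True:
        v = rng.normal(model.mean, model.sd)
        if model.expected_low <= v <= model.expected_high:
            return int(round(v))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def generate_mate_pairs(
    reference: str,
    carrier: CarrierGenome,
    config: SimulationConfig,
) -> SimulatedReads:
    """Draw mate pairs from the carrier/reference haplotype mixture.

    The number of fragments is ``physical_coverage * len(reference) /
    insert_model.mean``.  Each fragment comes from the carrier with
    probability ``prevalence``; its length is a truncated normal within the
    expected insert range, and the two ``read_length`` reads are taken from
    its ends in forward/reverse (innie) orientation.  Substitution errors
    are i.i.d. per base.  Identical configs produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    model = config.insert_model
    n_frags = int(round(config.physical_coverage * len(reference) / model.mean))
    ref_genome = CarrierGenome.identity(reference, carrier.chrom)
    rl = config.read_length
    pairs: list[AlignedPair] = []
    reads: list[tuple[str, str]] = []
    for i in range(n_frags):
        from_carrier = rng.random() < config.prevalence
        genome = carrier if from_carrier else ref_genome
        frag_len = _truncated_normal(rng, model)
        if frag_len >= len(genome):
            frag_len = len(genome) - 1
        start = int(rng.integers(0, len(genome) - frag_len + 1))
        name = f"frag{i:07d}"
        # read 1: forward from the left end; read 2: reverse from the right end
        s1 = genome.sequence[start : start + rl]
        s2_fwd = genome.sequence[start + frag_len - rl : start + frag_len]
        r1 = _mutate(s1, config.substitution_error_rate, rng)
        r2 = _mutate(revcomp(s2_fwd), config.substitution_error_rate, rng)
        mates = []
        for read_seq, gstart, strand in (
            (r1, start, "+"),
            (r2, start + frag_len - rl, "-"),
        ):
            loc = genome.locate(gstart, rl)
            if loc is None:
                mates.append(MateInfo(read_len=rl, seq=read_seq))
            else:
                ref_pos, aligned_len, frac, clip_side = loc
                mates.append(
                    MateInfo(
                        chrom=genome.chrom,
                        pos=ref_pos,
                        strand=strand,
                        mapq=60,
                        read_len=rl,
                        aligned_len=aligned_len,
                        mapped_fraction=frac,
                        clip_side=clip_side,
                        seq=read_seq,
                    )
                )
        pairs.append(AlignedPair(name=name, a=mates[0], b=mates[1]))
        reads.append((f"{name}/1", r1))
        reads.append((f"{name}/2", r2))
    return SimulatedReads(pairs=pairs, reads=reads, n_fragments=n_frags, config=config)


# ---------------------------------------------------------------------------
# detection evaluation
# ---------------------------------------------------------------------------


def evaluate_detection(calls: Sequence, truth: TruthRecord, tolerance: int = 1000) -> dict:
    """Detected iff any call's position estimate lies within ``tolerance``
    of the true insertion point (on the right chromosome)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    best = float("inf")
    for call in calls:
        if call.interval.chrom != truth.insertion_point.chrom:
            continue
        best = min(best, abs(call.position_estimate - truth.point))
    return {"detected": best <= tolerance, "distance": best}


def simulate_insertion_replicate(
    config: SimulationConfig,
) -> tuple[str, CarrierGenome, TruthRecord, SimulatedReads]:
    """One complete replicate: reference, planted insertion, reads."""
    rng = np.random.default_rng(config.seed)
    ref_seed = int(rng.integers(0, 2**31 - 1))
    reference = make_reference(config.reference_length, ref_seed)
    insert_seq = random_sequence(config.insert_length, rng)
    margin = max(config.insert_model.expected_high, config.reference_length // 10)
    margin = min(margin, config.reference_length // 3)
    point = int(rng.integers(margin, config.reference_length - margin))
    carrier = plant_insertion(reference, insert_seq, point)
    sim = generate_mate_pairs(reference, carrier, config)
    truth = TruthRecord(
        insertion_point=GenomeInterval(carrier.chrom, point, point + 1),
        inserted_sequence=insert_seq,
        prevalence=config.prevalence,
    )
    return reference, carrier, truth, sim


def run_detection_replicate(
    config: SimulationConfig,
    run_config: RunConfig | None = None,
    tolerance: int = 1000,
) -> dict:
    """Simulate one replicate and run the caller on the oracle alignments."""
    from .insertion_caller import call_insertions

    run_config = run_config or RunConfig()
    reference, carrier, truth, sim = simulate_insertion_replicate(config)
    calls = call_insertions(
        sim.pairs,
        {carrier.chrom: len(reference)},
        config.insert_model,
        run_config,
    )
    result = evaluate_detection(calls, truth, tolerance)
    result["n_calls"] = len(calls)
    return result


def sensitivity_sweep(
    prevalences: Sequence[float],
    insert_lengths: Sequence[int] = (8000,),
    replicates: int = 20,
    base_config: SimulationConfig | None = None,
    run_config: RunConfig | None = None,
    seed: int = 0,
    tolerance: int = 1000,
) -> pd.DataFrame:
    """Detection rate over a grid of insertion length and cell prevalence.

    Returns a table with columns ``insertLength, prevalence, detectionRate,
    nReplicates``, reproducible by ``seed``.
    """
    base = base_config or SimulationConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for L in insert_lengths:
        for p in prevalences:
            detected = 0
            for _ in range(replicates):
                rep_seed = int(rng.integers(0, 2**31 - 1))
                cfg = replace(base, insert_length=int(L), prevalence=float(p), seed=rep_seed)
                if run_detection_replicate(cfg, run_config, tolerance)["detected"]:
                    detected += 1
            rows.append(
                {
                    "insertLength": int(L),
                    "prevalence": float(p),
                    "detectionRate": detected / replicates,
                    "nReplicates": replicates,
                }
            )
    return pd.DataFrame(rows)


def minimum_detectable_prevalence(sweep: pd.DataFrame, min_rate: float = 0.9) -> Optional[float]:
    """Smallest prevalence whose detection rate reaches ``min_rate``."""
    ok = sweep[sweep["detectionRate"] >= min_rate].sort_values("prevalence")
    return float(ok["prevalence"].iloc[0]) if len(ok) else None


# ---------------------------------------------------------------------------
# synthetic HERV-K material
# ---------------------------------------------------------------------------

LTR_LENGTH = 968  # length of a HERV-K(HML-2) long terminal repeat


def make_hervk_allele(
    rng: np.random.Generator,
    internal_length: int = 7064,
    ltr_length: int = LTR_LENGTH,
) -> tuple[str, list[tuple[int, int]]]:
    """A synthetic full-length provirus allele: LTR + internal + identical LTR.

    Returns the allele sequence and its LTR annotation intervals.  The
    default total length (~9 kbp) matches a full-length HERV-K provirus.
    """
    ltr = random_sequence(ltr_length, rng)
    internal = random_sequence(internal_length, rng)
    allele = ltr + internal + ltr
    annotations = [(0, ltr_length), (ltr_length + internal_length, len(allele))]
    return allele, annotations


def solo_ltr_of(allele: str, ltr_annotations: Sequence[tuple[int, int]]) -> str:
    """The recombination remnant of a provirus: its (5') LTR alone."""
    s, e = ltr_annotations[0]
    return allele[s:e]


def build_hervk_panel(
    n_loci: int = 8,
    n_in_reference: int = 5,
    seed: int = 0,
    internal_length: int = 7064,
    ltr_length: int = LTR_LENGTH,
    inter_locus_gap: int = 25000,
    chrom: str = DEFAULT_CHROM,
) -> tuple[str, list]:
    """Synthetic reference plus a panel of HERV-K loci.

    The first ``n_in_reference`` loci carry the full provirus in the
    reference (reference allele = provirus); the remaining loci are empty
    pre-integration sites in the reference whose provirus allele is known
    only from the panel.  Returns ``(reference, loci)`` where loci are
    :class:`retrosite.hervk_genotyper.HervKLocus` records.
    """
    from .hervk_genotyper import HervKLocus

    rng = np.random.default_rng(seed)
    allele_len = internal_length + 2 * ltr_length
    parts = []
    loci = []
    cursor = 0
    for i in range(n_loci):
        gap = random_sequence(inter_locus_gap, rng)
        parts.append(gap)
        cursor += inter_locus_gap
        allele, annotations = make_hervk_allele(rng, internal_length, ltr_length)
        in_ref = i < n_in_reference
        if in_ref:
            parts.append(allele)
            interval = GenomeInterval(chrom, cursor, cursor + allele_len)
            cursor += allele_len
        else:
            interval = GenomeInterval(chrom, cursor, cursor + 1)
        loci.append(
            HervKLocus(
                id=f"HK{i + 1:02d}",
                interval=interval,
                allele_seqs=[allele],
                ltr_annotations=[list(annotations)],
                in_reference=in_ref,
            )
        )
    parts.append(random_sequence(inter_locus_gap, rng))
    return "".join(parts), loci


def simulate_hervk_cohort(
    n_individuals: int = 5,
    n_loci: int = 8,
    n_in_reference: int = 5,
    read_coverage: float = 20.0,
    seed: int = 0,
    substitution_error_rate: float = 0.0,
) -> dict:
    """Cohort with randomly assigned locus states and mate-pair reads.

    States are drawn uniformly from absence / solo LTR / provirus per
    (individual, locus).  ``read_coverage`` is sequence coverage; the
    corresponding physical coverage of the 8 kbp-insert library is
    ``read_coverage * mean_insert / (2 * read_length)``.  Returns a dict
    with the reference, loci (k-mers not yet built), true state table, and
    per-individual pairs and reads.
    """
    rng = np.random.default_rng(seed)
    reference, loci = build_hervk_panel(
        n_loci=n_loci, n_in_reference=n_in_reference, seed=int(rng.integers(2**31 - 1))
    )
    states_true = pd.DataFrame(
        {
            locus.id: [
                ("absence", "solo_LTR", "provirus")[rng.integers(0, 3)]
                for _ in range(n_individuals)
            ]
            for locus in loci
        },
        index=[f"ind{i + 1:02d}" for i in range(n_individuals)],
    )
    model = InsertSizeModel()
    per_individual: dict[str, SimulatedReads] = {}
    for individual in states_true.index:
        genome = build_individual_genome(reference, loci, states_true.loc[individual].to_dict())
        cfg = SimulationConfig(
            reference_length=len(reference),
            prevalence=1.0,
            physical_coverage=read_coverage * model.mean / (2 * 125),
            insert_model=model,
            substitution_error_rate=substitution_error_rate,
            seed=int(rng.integers(2**31 - 1)),
        )
        per_individual[individual] = generate_mate_pairs(reference, genome, cfg)
    return {
        "reference": reference,
        "loci": loci,
        "states_true": states_true,
        "simulations": per_individual,
    }


def build_individual_genome(
    reference: str,
    loci: Sequence,
    states: dict[str, str],
    chrom: str = DEFAULT_CHROM,
) -> CarrierGenome:
    """Germline genome of one individual given a state per HERV-K locus.

    For loci whose reference allele is the provirus: ``provirus`` keeps the
    reference, ``solo_LTR`` deletes the proviral interior leaving the 5'
    LTR, ``absence`` deletes the whole locus.  For non-reference loci:
    ``provirus`` inserts the panel allele at the pre-integration site,
    ``solo_LTR`` inserts its LTR, ``absence`` keeps the reference.
    """
    edits: list[tuple[int, int, str]] = []
    for locus in loci:
        state = states[locus.id]
        allele = locus.allele_seqs[0]
        ltr = solo_ltr_of(allele, locus.ltr_annotations[0])
        iv = locus.interval
        if locus.in_reference:
            if state == "provirus":
                continue
            elif state == "solo_LTR":
                edits.append((iv.start + len(ltr), iv.end, ""))
            elif state == "absence":
                edits.append((iv.start, iv.end, ""))
            else:
                raise ValueError(f"unknown state {state!r}")
        else:
            point = iv.start
            if state == "provirus":
                edits.append((point, point, allele))
            elif state == "solo_LTR":
                edits.append((point, point, ltr))
            elif state == "absence":
                continue
            else:
                raise ValueError(f"unknown state {state!r}")
    return CarrierGenome.from_edits(reference, edits, chrom)
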