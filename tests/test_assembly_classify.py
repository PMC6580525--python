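"""Assembler reconstruction, panel classification (with a brute-force
affine-gap Smith-Waterman oracle), flank confirmation, allele
reconstruction, and call screening verdicts."""

import numpy as np
import pytest

from retrosite.assembly_classify import (
    AlleleReconstruction,
    Contig,
    PanelSequence,
    assemble_contigs,
    classify_contig,
    confirm_flank_placement,
    make_aligner,
    read_panel_fasta,
    reconstruct_locus_allele,
    screen_calls,
    write_panel_fasta,
)
from retrosite.core_io import AlignedPair, GenomeInterval, MateInfo, RunConfig, revcomp
from retrosite.insertion_caller import InsertionCall, call_insertions
from retrosite.mp_simulator import make_reference, random_sequence


def tiling_reads(seq, read_len=125, step=50):
    reads = [seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)]
    reads.append(seq[-read_len:])
    return reads


class TestAssembleContigs:
    def test_single_read_is_its_own_contig(self):
        (c,) = assemble_contigs(["ACGT" * 40])
        assert c.sequence == "ACGT" * 40 and c.n_reads == 1

    def test_error_free_tiling_reads_reconstruct_exactly(self, rng):
        seq = random_sequence(2000, rng)
        contigs = assemble_contigs(tiling_reads(seq), min_overlap=30)
        assert len(contigs) == 1
        assert contigs[0].sequence == seq

    def test_two_disjoint_sequences_give_two_contigs(self, rng):
        s1, s2 = random_sequence(1500, rng), random_sequence(1200, rng)
        contigs = assemble_contigs(tiling_reads(s1) + tiling_reads(s2), min_overlap=30)
        assert sorted(len(c.sequence) for c in contigs) == [1200, 1500]

    def test_orientation_invariance_up_to_reverse_complement(self, rng):
        seq = random_sequence(1000, rng)
        reads = tiling_reads(seq)
        fwd = {c.sequence for c in assemble_contigs(reads)}
        rev = {c.sequence for c in assemble_contigs([revcomp(r) for r in reads])}
        assert {min(s, revcomp(s)) for s in fwd} == {min(s, revcomp(s)) for s in rev}

    def test_mixed_orientation_reads_assemble(self, rng):
        seq = random_sequence(1000, rng)
        reads = [r if i % 2 else revcomp(r) for i, r in enumerate(tiling_reads(seq))]
        contigs = assemble_contigs(reads)
        assert len(contigs) == 1
        assert contigs[0].sequence in (seq, revcomp(seq))


# --- brute-force affine-gap Smith-Waterman oracle (match +1, mismatch -2,
# gap open -4, gap extend -1; open cost includes the first extension) ------


def sw_affine_score(a: str, b: str, match=1, mismatch=-2, gap_open=-4, gap_extend=-1) -> float:
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(0.0, max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s)
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            best = max(best, M[i, j])
    return best


@pytest.fixture(scope="module")
def panel():
    rng = np.random.default_rng(21)
    return [
        PanelSequence("XRV-1", random_sequence(8000, rng), "retrovirus"),
        PanelSequence("HERVK-ref", random_sequence(9000, rng), "endogenous_retrovirus"),
        PanelSequence("BAC-human", random_sequence(6000, rng), "human"),
    ]


class TestClassifyContig:
    def test_exact_substring_hit(self, panel):
        contig = Contig(panel[0].sequence[1000:1500], 5)
        hits = classify_contig(contig, panel)
        assert hits[0].panel_sequence_name == "XRV-1"
        assert hits[0].identity == 1.0
        assert hits[0].aligned_length == 500

    def test_reverse_strand_hit(self, panel):
        contig = Contig(revcomp(panel[1].sequence[2000:2600]), 3)
        hits = classify_contig(contig, panel)
        assert hits[0].panel_sequence_name == "HERVK-ref"
        assert hits[0].strand == "-"
        assert hits[0].identity == 1.0

    def test_random_contig_no_hit(self, rng):
        panel = [PanelSequence("X", random_sequence(5000, rng), "other")]
        contig = Contig(random_sequence(300, rng), 1)
        assert classify_contig(contig, panel) == []

    def test_chimeric_contig_yields_flank(self, panel, rng):
        flank = random_sequence(200, rng)
        contig = Contig(flank + panel[1].sequence[3000:3400], 4)
        hits = classify_contig(contig, panel)
        assert hits[0].category == "endogenous_retrovirus"
        assert len(hits[0].contig_flanks) == 1
        # local alignment may absorb a chance-matching base or two at the edge
        assert abs(len(hits[0].contig_flanks[0]) - 200) <= 3

    def test_empty_panel_is_configuration_error(self):
        with pytest.raises(ValueError):
            classify_contig(Contig("ACGT" * 50, 1), [])

    def test_agrees_with_brute_force_dp(self, rng):
        """Alignment scores from the classifier equal a from-scratch affine
        Smith-Waterman on small contig/panel combinations."""
        aligner = make_aligner("local")
        for trial in range(5):
            target = random_sequence(300, rng)
            query = random_sequence(120, rng)
            if trial >= 3:  # make some related pairs
                query = target[50:170]
            expected = sw_affine_score(target, query)
            got = aligner.align(target, query).score if expected > 0 else 0.0
            assert got == pytest.approx(expected)

    def test_panel_fasta_round_trip(self, panel, tmp_path):
        p = tmp_path / "panel.fa"
        write_panel_fasta(panel, p)
        back = read_panel_fasta(p)
        assert [(x.name, x.category, x.sequence) for x in back] == [
            (x.name, x.category, x.sequence) for x in panel
        ]


class TestConfirmFlankPlacement:
    def _setup(self, rng):
        reference = random_sequence(50_000, rng)
        call = InsertionCall(interval=GenomeInterval("chrSim", 20_000, 22_000))
        return reference, call

    def _hit_with_flanks(self, flanks):
        return classify_stub(flanks)

    def test_flank_copied_from_reference_confirms(self, rng):
        reference, call = self._setup(rng)
        flank = reference[20_500:20_700]
        hit = classify_stub([flank])
        assert confirm_flank_placement(hit, reference, call, max_distance=5000)

    def test_foreign_flank_rejected(self, rng):
        reference, call = self._setup(rng)
        hit = classify_stub([random_sequence(200, rng)])
        assert not confirm_flank_placement(hit, reference, call, max_distance=5000)

    def test_hit_without_flanks_rejected(self, rng):
        reference, call = self._setup(rng)
        assert not confirm_flank_placement(classify_stub([]), reference, call)

    def test_flank_outside_window_rejected(self, rng):
        reference, call = self._setup(rng)
        hit = classify_stub([reference[40_000:40_200]])
        assert not confirm_flank_placement(hit, reference, call, max_distance=5000)


def classify_stub(flanks):
    from retrosite.assembly_classify import PanelHit

    return PanelHit(
        contig=Contig("A" * 200, 1),
        panel_sequence_name="X",
        category="endogenous_retrovirus",
        aligned_length=100,
        identity=1.0,
        score=100,
        strand="+",
        contig_span=(0, 100),
        contig_flanks=flanks,
    )


class TestReconstructLocusAllele:
    def _locus_pairs(self, rng, n_subs):
        """In-reference locus whose individual allele carries n_subs planted
        substitutions; far mates tile the individual allele, anchors flank it."""
        reference = random_sequence(30_000, rng)
        locus_iv = GenomeInterval("chrSim", 12_000, 14_500)
        ref_allele = reference[12_000:14_500]
        allele = list(ref_allele)
        positions = sorted(rng.choice(np.arange(100, 2400), size=n_subs, replace=False))
        truth = []
        for p in positions:
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[allele[p]]
            truth.append((int(p), allele[p], alt))
            allele[p] = alt
        allele = "".join(allele)
        pairs = []
        for i, read in enumerate(tiling_reads(allele, 125, 25)):
            anchor = MateInfo(
                chrom="chrSim", pos=11_000 - (i % 7) * 10, strand="+", mapq=60,
                read_len=125, aligned_len=125, mapped_fraction=1.0, seq="A" * 125,
            )
            other = MateInfo(read_len=125, seq=revcomp(read))  # unmapped, as sequenced
            pairs.append(AlignedPair(f"m{i}", anchor, other))
        locus = type("L", (), {"interval": locus_iv})()
        return locus, pairs, ref_allele, truth

    def test_reference_allele_gives_empty_substitution_list(self, rng):
        locus, pairs, ref_allele, _ = self._locus_pairs(rng, 0)
        res = reconstruct_locus_allele(locus, pairs, ref_allele)
        assert res.substitutions == []
        assert not res.partial and res.covered_fraction == 1.0

    @pytest.mark.parametrize("n_subs", [1, 5])
    def test_planted_substitutions_recovered_exactly(self, rng, n_subs):
        locus, pairs, ref_allele, truth = self._locus_pairs(rng, n_subs)
        res = reconstruct_locus_allele(locus, pairs, ref_allele)
        assert res.substitutions == truth

    def test_insufficient_reads_flagged_partial(self, rng):
        locus, pairs, ref_allele, _ = self._locus_pairs(rng, 0)
        res = reconstruct_locus_allele(locus, pairs[:5], ref_allele)
        assert res.partial and res.covered_fraction < 0.95

    def test_no_reads_empty_result(self, rng):
        locus, _, ref_allele, _ = self._locus_pairs(rng, 0)
        res = reconstruct_locus_allele(locus, [], ref_allele)
        assert res == AlleleReconstruction("", [], 0.0, True, 0)


@pytest.fixture(scope="module")
def scenario():
    """End-to-end screening setup: a simulated genome plus a panel holding a
    retrovirus, an ERV entry with host flanks (as an nt database entry for a
    polymorphic insertion would), and a human BAC segment."""
    rng = np.random.default_rng(31)
    reference = make_reference(150_000, 881)
    retrovirus = random_sequence(8000, rng)
    hervk = random_sequence(9000, rng)
    screen_panel = [
        PanelSequence("XRV-1", retrovirus, "retrovirus"),
        PanelSequence("HERVK-locus", reference[69_500:70_000] + hervk + reference[70_000:70_500], "endogenous_retrovirus"),
        PanelSequence("BAC-human", reference[100_000:106_000], "human"),
    ]
    return {"reference": reference, "retrovirus": retrovirus, "hervk": hervk, "panel": screen_panel, "rng": rng}


class TestScreenCalls:
    def _simulate_and_screen(self, scenario, insert_seq, point):
        from retrosite.mp_simulator import SimulationConfig, generate_mate_pairs, plant_insertion

        reference = scenario["reference"]
        carrier = plant_insertion(reference, insert_seq, point)
        cfg = SimulationConfig(
            reference_length=len(reference), prevalence=1.0, physical_coverage=60,
            substitution_error_rate=0.0, seed=55,
        )
        sim = generate_mate_pairs(reference, carrier, cfg)
        calls = call_insertions(sim.pairs, {"chrSim": len(reference)})
        report = screen_calls(calls, sim.pairs, scenario["panel"], reference)
        return calls, report

    def test_novel_retrovirus_verdict(self, scenario):
        calls, report = self._simulate_and_screen(scenario, scenario["retrovirus"], 40_000)
        assert len(report) >= 1
        best = report.iloc[(report["start"] - 40_000).abs().argmin()]
        assert best["verdict"] == "novel_retrovirus"
        assert best["bestHit"] == "XRV-1"

    def test_known_polymorphic_erv_with_flank_confirmation(self, scenario):
        calls, report = self._simulate_and_screen(scenario, scenario["hervk"], 70_000)
        best = report.iloc[(report["start"] - 70_000).abs().argmin()]
        assert best["verdict"] == "known_polymorphic_ERV"
        assert bool(best["flankConfirmed"])

    def test_human_hit_short_circuits_to_structural_variant(self, scenario):
        human_insert = scenario["reference"][101_000:107_000]  # overlaps BAC entry
        calls, report = self._simulate_and_screen(scenario, human_insert, 30_000)
        best = report.iloc[(report["start"] - 30_000).abs().argmin()]
        assert best["verdict"] == "human_structural_variant"
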