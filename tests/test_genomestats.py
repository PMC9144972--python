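import numpy as np
import pytest
from hypothesis import given, strategies as st

from phagekit.genomestats import (
    boundary_codon_usage,
    coding_density,
    find_att_overlap,
    frame_preservation_check,
    gc_content,
    trim_terminal_repeat,
)
from phagekit.io_tables import AnnotatedGenome, GeneRecord
from phagekit.simulate import simulate_genome

DNA = st.text(alphabet="ACGT", min_size=1)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------- trimming


class TestTerminalRepeat:
    def test_hand_checked_repeat(self):
        seq = "ACGTACGTTTTACGTACGT"  # 8 bp prefix repeated as suffix
        trimmed, rep = trim_terminal_repeat(seq, max_repeat=9)
        assert rep == 8
        assert trimmed == "ACGTACGTTTT"
        assert len(trimmed) == 11

    def test_no_shared_ends_returns_unchanged(self):
        rng = np.random.default_rng(0)
        core = "AAC" + _random_seq(rng, 100) + "GTT"  # distinct ends
        trimmed, rep = trim_terminal_repeat(core, max_repeat=20)
        assert rep == 0 and trimmed == core

    @given(st.integers(0, 40))
    def test_exact_for_planted_repeats_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        rep_len = int(rng.integers(4, 25))
        core = _random_seq(rng, 400)
        seq = core + core[:rep_len]
        trimmed, rep = trim_terminal_repeat(seq, max_repeat=50)
        assert rep == rep_len
        assert trimmed == core
        # second application removes nothing unless the core itself happens
        # to end with a copy of its start (checked independently)
        accidental = max(
            (k for k in range(4, 51) if core[:k] == core[-k:]), default=0
        )
        again, rep2 = trim_terminal_repeat(trimmed, max_repeat=50)
        assert rep2 == accidental
        if accidental == 0:
            assert again == trimmed

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            trim_terminal_repeat("ACGT" * 10, max_repeat=50)


# ------------------------------------------------------------------ density


def _density_oracle(genome: AnnotatedGenome) -> float:
    mask = np.zeros(genome.length, dtype=bool)
    for g in genome.genes:
        lo, hi = g.interval()
        mask[lo - 1 : hi] = True
    return 100.0 * mask.sum() / genome.length


class TestCodingDensity:
    def test_single_full_length_gene(self):
        g = AnnotatedGenome(length=300, genes=[GeneRecord(1, 1, 300, "+", 99)])
        assert coding_density(g) == 100.0

    def test_overlapping_genes_counted_once(self):
        genes = [GeneRecord(1, 1, 9, "+", 2), GeneRecord(2, 7, 15, "+", 2)]
        # union covers 1..15 = 15 bp of 20
        assert coding_density(AnnotatedGenome(length=20, genes=genes)) \
            == pytest.approx(75.0)

    def test_no_genes_rejected(self):
        with pytest.raises(ValueError):
            coding_density(AnnotatedGenome(length=100))

    @given(st.integers(0, 30))
    def test_matches_per_base_oracle(self, seed):
        genome, _ = simulate_genome(seed, length=8000,
                                    n_genes=int(3 + seed % 6), gc=0.5)
        assert coding_density(genome) == pytest.approx(_density_oracle(genome),
                                                       abs=1e-12)

    def test_oracle_agreement_with_nested_and_abutting_genes(self):
        genes = [
            GeneRecord(1, 1, 60, "+", 19),
            GeneRecord(2, 69, 10, "-", 19),   # nested/overlapping, minus strand
            GeneRecord(3, 61, 90, "+", 9),    # abuts gene 1
        ]
        genome = AnnotatedGenome(length=120, genes=genes)
        assert coding_density(genome) == pytest.approx(_density_oracle(genome))


# ----------------------------------------------------------------------- GC


class TestGcContent:
    def test_all_gc(self):
        assert gc_content("GCGC") == 100.0

    def test_no_gc(self):
        assert gc_content("ATAT") == 0.0

    def test_ambiguity_codes_excluded(self):
        assert gc_content("GCGCNNNN") == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")

    @given(DNA)
    def test_strand_invariance(self, seq):
        comp = seq.translate(str.maketrans("ACGT", "TGCA"))
        assert gc_content(seq) == pytest.approx(gc_content(comp))


# -------------------------------------------------------------- codon usage


class TestBoundaryCodons:
    def test_plus_strand_gene(self):
        g = AnnotatedGenome(length=9, sequence="ATGAAATAA",
                            genes=[GeneRecord(1, 1, 9, "+", 2)])
        starts, stops = boundary_codon_usage(g)
        assert starts["ATG"] == 1 and stops["TAA"] == 1

    def test_minus_strand_gene_gives_identical_tallies(self):
        # reverse complement of ATGAAATAA, with printed coordinates 9..1
        g = AnnotatedGenome(length=9, sequence="TTATTTCAT",
                            genes=[GeneRecord(1, 9, 1, "-", 2)])
        starts, stops = boundary_codon_usage(g)
        assert starts["ATG"] == 1 and stops["TAA"] == 1

    def test_totals_equal_gene_count_and_match_planted_truth(self):
        genome, truth = simulate_genome(21, length=25000, n_genes=14, gc=0.654)
        starts, stops = boundary_codon_usage(genome)
        assert sum(starts.values()) == sum(stops.values()) == 14
        for codon, n in truth["start_counts"].items():
            assert starts[codon] == n
        for codon, n in truth["stop_counts"].items():
            assert stops[codon] == n

    def test_requires_sequence(self):
        g = AnnotatedGenome(length=9, genes=[GeneRecord(1, 1, 9, "+", 2)])
        with pytest.raises(ValueError, match="sequence"):
            boundary_codon_usage(g)


# -------------------------------------------------------------- att overlap


def att_overlap_oracle(a, b, min_len, max_mismatch):
    """Exhaustive enumeration of all substring pairs, same tie-breaking:
    longest, then fewest mismatches, then smallest offsets."""
    best = None
    for i in range(len(a)):
        for j in range(len(b)):
            mism = 0
            for k in range(min(len(a) - i, len(b) - j)):
                if a[i + k] != b[j + k]:
                    mism += 1
                    if mism > max_mismatch:
                        break
                length = k + 1
                if length >= min_len:
                    cand = (-length, mism, i, j)
                    if best is None or cand < best:
                        best = cand
    if best is None:
        return None
    return (best[2], best[3], -best[0], best[1])


class TestAttOverlap:
    def test_planted_identical_segment(self):
        rng = np.random.default_rng(1)
        core = _random_seq(rng, 18)
        a = _random_seq(rng, 90) + core + _random_seq(rng, 92)
        b = _random_seq(rng, 40) + core + _random_seq(rng, 142)
        hit = find_att_overlap(a, b, min_len=12, max_mismatch=1)
        assert hit is not None and hit.length >= 18
        # the found segment covers the planted core positions
        assert hit.offset_a <= 90 and hit.offset_a + hit.length >= 108
        assert a[hit.offset_a : hit.offset_a + hit.length].count("") \
            is not None  # sanity
        exact = find_att_overlap(a, b, min_len=12, max_mismatch=0)
        assert exact.length >= 18

    def test_planted_segment_with_one_substitution(self):
        rng = np.random.default_rng(2)
        core = _random_seq(rng, 18)
        mutated = list(core)
        mutated[9] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[9]]
        a = _random_seq(rng, 50) + core + _random_seq(rng, 50)
        b = _random_seq(rng, 30) + "".join(mutated) + _random_seq(rng, 70)
        hit = find_att_overlap(a, b, min_len=12, max_mismatch=1)
        assert hit.length >= 18 and hit.mismatches == 1
        exact = find_att_overlap(a, b, min_len=5, max_mismatch=0)
        assert exact.length == 9  # only the longer exact flank survives

    def test_unrelated_sequences_yield_nothing(self):
        rng = np.random.default_rng(3)
        a, b = _random_seq(rng, 50), _random_seq(rng, 50)
        assert find_att_overlap(a, b, min_len=12, max_mismatch=1) is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_att_overlap("", "ACGT")

    @given(st.integers(0, 24))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(15, 45)), int(rng.integers(15, 45))
        a, b = _random_seq(rng, na), _random_seq(rng, nb)
        if seed % 2:  # plant a shared segment in half the cases
            core = _random_seq(rng, int(rng.integers(8, 14)))
            ia = int(rng.integers(0, na - len(core) + 1))
            ib = int(rng.integers(0, nb - len(core) + 1))
            a = a[:ia] + core + a[ia + len(core):]
            b = b[:ib] + core + b[ib + len(core):]
        min_len, max_mm = int(rng.integers(4, 10)), int(rng.integers(0, 3))
        hit = find_att_overlap(a, b, min_len=min_len, max_mismatch=max_mm)
        oracle = att_overlap_oracle(a, b, min_len, max_mm)
        got = None if hit is None else tuple(hit)
        assert got == oracle


# -------------------------------------------------------------- frame check


class TestFramePreservation:
    REF = "ATGGCTGAAACCGTTAAAGACCTGATCGAACGTTGGCAGTCTGCT"  # 15 codons

    def test_identical_hybrid_preserves_frame(self):
        res = frame_preservation_check(self.REF, self.REF)
        assert res.in_frame and res.aa_changes == 0

    def test_phage_replacing_first_codons(self):
        """Junction swaps the first 5 codons for phage codons; 3 of the
        first 5 amino acids change, frame preserved."""
        # ref first 5 codons: ATG GCT GAA ACC GTT -> M A E T V
        # phage codons:       ATG TCT GAT ACG CTG -> M S D T L (3 changes)
        hybrid = "ATGTCTGATACGCTG" + self.REF[15:]
        res = frame_preservation_check(hybrid, self.REF, n_compare=10)
        assert res.in_frame
        assert res.aa_changes == 3
        assert res.alt_start_offset == 15

    def test_upstream_alternative_start(self):
        """An in-frame ATG upstream of the junction rescues the gene."""
        # hybrid: phage leader with ATG 6 nt before the junction into codon 3
        downstream = self.REF[6:]  # reference from codon 3 on
        hybrid = "CCC" + "ATGCAC" + downstream
        res = frame_preservation_check(hybrid, self.REF, n_compare=10)
        assert res.in_frame
        assert res.alt_start_offset == 6

    def test_frameshifting_junction_without_rescue(self):
        hybrid = "CCCCCC" + self.REF[7:]  # downstream remainder shifted by 1
        res = frame_preservation_check(hybrid, self.REF)
        assert not res.in_frame and res.aa_changes is None

    def test_reference_must_start_with_start_codon(self):
        with pytest.raises(ValueError):
            frame_preservation_check("ACGT", "CCCGGG")
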