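"""Primer thermodynamics, pair design with an exhaustive penalty oracle,
and strand-inclusive occurrence counting."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as BioMT

from satellite_miner.primerdesign import (
    CompositionError,
    PrimerParams,
    count_occurrences,
    design_primer_pair,
    gc_percent,
    has_self_complementary_suffix,
    melting_temperature,
    tm_nearest_neighbor,
    tm_wallace,
)
from satellite_miner.seqio import Read, reverse_complement
from satellite_miner.ssrfind import SsrLocus, SsrRun, canonical_motif


def random_oligo(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ------------------------------------------------------------------- Tm

class TestMeltingTemperature:
    def test_wallace_direct_arithmetic(self):
        assert tm_wallace("ACGT") == pytest.approx(12.0)  # 2x2 + 4x2

    def test_wallace_strand_symmetric(self, rng):
        for _ in range(20):
            seq = random_oligo(rng, int(rng.integers(10, 30)))
            assert tm_wallace(seq) == pytest.approx(tm_wallace(reverse_complement(seq)))

    def test_n_rejected(self):
        with pytest.raises(CompositionError):
            melting_temperature("ACGNT", "wallace")
        with pytest.raises(CompositionError):
            melting_temperature("ACGNTACGTACGTACGTACG", "nearest_neighbor")

    def test_nearest_neighbor_agrees_with_independent_implementation(self, rng):
        """Cross-check against Biopython's SantaLucia unified-parameter model
        at matching salt (50 mM Na+) and primer (250 nM) conditions."""
        for _ in range(50):
            seq = random_oligo(rng, int(rng.integers(15, 31)))
            ours = tm_nearest_neighbor(seq, na_mM=50.0, primer_nM=250.0)
            theirs = BioMT.Tm_NN(
                seq, nn_table=BioMT.DNA_NN3, Na=50, dnac1=250, dnac2=0, saltcorr=5
            )
            assert ours == pytest.approx(theirs, abs=0.5)


def test_self_complementary_suffix_detection():
    assert has_self_complementary_suffix("TTTTGAATTC", 6)  # GAATTC is palindromic
    assert not has_self_complementary_suffix("TTTTGAATTG", 6)
    assert not has_self_complementary_suffix("ACGT", 6)


# ----------------------------------------------------------------- design

def make_locus(left, right, motif="AT", copies=8):
    target = motif * copies
    seq = left + target + right
    run = SsrRun(
        read_id="r", motif=motif, canonical=canonical_motif(motif), copies=copies,
        start=len(left), end=len(left) + len(target),
    )
    return SsrLocus(
        read_id="r", runs=[run], target_start=run.start, target_end=run.end,
        left_flank=left, right_flank=right, purity="perfect",
    )


def oracle_best_pair(locus, params):
    """Brute-force enumeration of all admissible (forward, reverse) windows."""

    def admissible(primer):
        if "N" in primer or not params.length_min <= len(primer) <= params.length_max:
            return None
        gc = gc_percent(primer)
        if not params.gc_min <= gc <= params.gc_max:
            return None
        tm = melting_temperature(primer, params.tm_method)
        if not params.tm_min <= tm <= params.tm_max:
            return None
        if params.self_comp_suffix and has_self_complementary_suffix(
            primer, params.self_comp_suffix
        ):
            return None
        return tm

    best = None
    for flen in range(params.length_min, params.length_max + 1):
        for fstart in range(len(locus.left_flank) - flen + 1):
            fseq = locus.left_flank[fstart : fstart + flen]
            ftm = admissible(fseq)
            if ftm is None:
                continue
            for rlen in range(params.length_min, params.length_max + 1):
                for rstart in range(len(locus.right_flank) - rlen + 1):
                    window = locus.right_flank[rstart : rstart + rlen]
                    rseq = reverse_complement(window)
                    rtm = admissible(rseq)
                    if rtm is None:
                        continue
                    product = locus.target_end + rstart + rlen - fstart
                    if not params.product_min <= product <= params.product_max:
                        continue
                    if abs(ftm - rtm) > params.max_tm_diff:
                        continue
                    penalty = (
                        abs(ftm - params.tm_opt) + abs(rtm - params.tm_opt)
                        + abs(flen - params.length_opt) + abs(rlen - params.length_opt)
                        + abs(ftm - rtm)
                    )
                    key = (penalty, fstart, product)
                    if best is None or key < best[0]:
                        best = (key, fseq, rseq)
    return best


class TestDesignPrimerPair:
    def test_short_flank_yields_none(self):
        locus = make_locus("ACGTACGT", "ACGTACGT")  # both flanks < length_min
        assert design_primer_pair(locus, PrimerParams()) is None

    def test_planted_balanced_flanks_yield_admissible_pair(self, rng):
        from satellite_miner.simdata import SimConfig, _sample_primer_site

        cfg = SimConfig()
        fwd_site = _sample_primer_site(rng, cfg)
        rev_site = _sample_primer_site(rng, cfg)
        left = random_oligo(rng, 20) + fwd_site + "CTTGGC"
        right = "GGCTTC" + reverse_complement(rev_site) + random_oligo(rng, 20)
        locus = make_locus(left, right, "CAG", 8)
        params = PrimerParams()
        pair = design_primer_pair(locus, params)
        assert pair is not None
        # soundness: every constraint holds on the returned pair
        for seq, tm in ((pair.fwd_seq, pair.fwd_tm), (pair.rev_seq, pair.rev_tm)):
            assert params.length_min <= len(seq) <= params.length_max
            assert params.tm_min <= tm <= params.tm_max
            assert params.gc_min <= gc_percent(seq) <= params.gc_max
        assert abs(pair.fwd_tm - pair.rev_tm) <= params.max_tm_diff
        assert params.product_min <= pair.product_size <= params.product_max
        # the product spans the repeat target region
        assert pair.fwd_start <= locus.target_start
        assert pair.fwd_start + pair.product_size >= locus.target_end

    def test_matches_exhaustive_oracle_on_small_flanks(self, rng):
        params = PrimerParams(
            length_min=18, length_opt=20, length_max=22, product_min=40, product_max=200
        )
        n_with_pair = 0
        for _ in range(30):
            locus = make_locus(random_oligo(rng, 40), random_oligo(rng, 40))
            got = design_primer_pair(locus, params)
            expected = oracle_best_pair(locus, params)
            if expected is None:
                assert got is None
                continue
            n_with_pair += 1
            (penalty, fstart, product), fseq, rseq = expected
            assert got.fwd_seq == fseq
            assert got.rev_seq == rseq
            assert got.product_size == product
        assert n_with_pair >= 3  # the comparison actually exercised real pairs

    def test_design_is_deterministic(self, rng):
        locus = make_locus(random_oligo(rng, 60), random_oligo(rng, 60))
        params = PrimerParams(product_min=40)
        first = design_primer_pair(locus, params)
        second = design_primer_pair(locus, params)
        assert first == second


# ---------------------------------------------------------------- counting

def oracle_count(pattern, reads):
    patterns = {pattern, reverse_complement(pattern)}
    total = 0
    for read in reads:
        for p in patterns:
            total += sum(
                1
                for i in range(len(read.seq) - len(p) + 1)
                if read.seq[i : i + len(p)] == p
            )
    return total


class TestCountOccurrences:
    def test_single_forward_occurrence(self):
        reads = [Read("a", "TTTGATTACATTT", [30] * 13), Read("b", "C" * 13, [30] * 13)]
        assert count_occurrences("GATTACA", reads) == 1

    def test_forward_plus_reverse_complement(self):
        reads = [
            Read("a", "TTGATTACATT", [30] * 11),
            Read("b", "TTTGTAATCTT", [30] * 11),  # contains revcomp(GATTACA)
        ]
        assert count_occurrences("GATTACA", reads) == 2
        assert count_occurrences("GATTACA", reads, include_reverse_complement=False) == 1

    def test_overlapping_occurrences_counted(self):
        reads = [Read("a", "CACACACA", [30] * 8)]
        # CACACA at offsets 0 and 2, plus revcomp TGTGTG absent
        assert count_occurrences("CACACA", reads) == 2

    def test_palindrome_counted_once_per_site(self):
        reads = [Read("a", "TTGAATTCTT", [30] * 10)]
        assert count_occurrences("GAATTC", reads) == 1

    def test_matches_naive_oracle(self, rng):
        reads = [
            Read(f"r{i}", "".join(rng.choice(list("ACGTN"), size=80, p=[0.245] * 4 + [0.02])), [30] * 80)
            for i in range(40)
        ]
        for _ in range(300):
            length = int(rng.integers(2, 8))  # short patterns: matches actually occur
            pattern = random_oligo(rng, length)
            assert count_occurrences(pattern, reads) == oracle_count(pattern, reads)

    def test_counting_is_additive_over_read_subsets(self, rng):
        reads = [Read(f"r{i}", random_oligo(rng, 60), [30] * 60) for i in range(30)]
        pattern = "ACGT"
        total = count_occurrences(pattern, reads)
        assert total == count_occurrences(pattern, reads[:11]) + count_occurrences(
            pattern, reads[11:]
        )
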