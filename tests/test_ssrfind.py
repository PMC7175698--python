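"""SSR detection: canonicalization, exhaustive run-finding oracle, locus
grouping, and planted-run recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from satellite_miner.seqio import Read, reverse_complement
from satellite_miner.ssrfind import (
    COMPOUND,
    INTERRUPTED,
    PERFECT,
    PrimitivityError,
    canonical_motif,
    find_loci,
    find_perfect_runs,
    group_runs_to_locus,
    is_primitive,
)
from satellite_miner.simdata import SimConfig, simulate_templates


# ---------------------------------------------------------------- oracles

def oracle_canonical(motif):
    """Brute force over all rotations of the motif and its reverse complement."""
    candidates = []
    for m in (motif, reverse_complement(motif)):
        candidates += [m[i:] + m[:i] for i in range(len(m))]
    return min(candidates)


def oracle_runs(seq, min_copies):
    """Exhaustive (start, motif-length) scan for maximal perfect tandem runs."""
    out = []
    n = len(seq)
    for k in range(2, 7):
        for a in range(n - 2 * k + 1):
            motif = seq[a : a + k]
            if set(motif) - set("ACGT") or not is_primitive(motif):
                continue
            # left-maximal: the k-periodicity must not extend one base left
            if a > 0 and seq[a - 1] in "ACGT" and seq[a - 1] == seq[a - 1 + k]:
                continue
            copies = 1
            while seq[a + copies * k : a + (copies + 1) * k] == motif:
                copies += 1
            if copies >= min_copies:
                out.append((motif, copies, a, a + copies * k))
    return sorted(out, key=lambda r: (r[2], r[3]))


def random_seq(rng, n, n_frac=0.0):
    bases = list("ACGT") + (["N"] if n_frac else [])
    p = [0.25 * (1 - n_frac)] * 4 + ([n_frac] if n_frac else [])
    return "".join(rng.choice(bases, size=n, p=p))


def seed_with_repeats(rng, n):
    """Random sequence with tandem repeats spliced in, so runs actually occur."""
    seq = list(random_seq(rng, n, n_frac=0.01))
    for _ in range(rng.integers(1, 4)):
        k = int(rng.integers(2, 7))
        motif = "".join(rng.choice(list("ACGT"), size=k))
        copies = int(rng.integers(2, 12))
        pos = int(rng.integers(0, max(1, n - copies * k)))
        seq[pos : pos + copies * k] = motif * copies
    return "".join(seq[:n])


# ------------------------------------------------------- canonical motifs

class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,expected",
        [
            ("TA", "AT"),
            ("GAA", "AAG"),  # min over {GAA,AAG,AGA} ∪ {TTC,TCT,CTT}
            ("AT", "AT"),
            ("CAG", "AGC"),
        ],
    )
    def test_known_keys(self, motif, expected):
        assert oracle_canonical(motif) == expected  # oracle agrees with frozen value
        assert canonical_motif(motif) == expected

    def test_non_primitive_rejected(self):
        with pytest.raises(PrimitivityError):
            canonical_motif("ATAT")
        with pytest.raises(PrimitivityError):
            canonical_motif("AA")

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=6))
    def test_rotation_and_strand_invariance(self, motif):
        if not is_primitive(motif):
            return
        key = canonical_motif(motif)
        assert key == oracle_canonical(motif)
        assert key == canonical_motif(reverse_complement(motif))
        for i in range(len(motif)):
            rotation = motif[i:] + motif[:i]
            if is_primitive(rotation):
                assert canonical_motif(rotation) == key


# ------------------------------------------------------------ run finding

class TestFindPerfectRuns:
    def test_single_planted_run_exact_span(self):
        seq = "CC" + "AT" * 8 + "GG"
        (run,) = find_perfect_runs(seq, 8)
        assert (run.motif, run.copies, run.start, run.end) == ("AT", 8, 2, 18)

    def test_below_threshold_not_reported(self):
        assert find_perfect_runs("AT" * 7, 8) == []

    def test_n_splits_runs(self):
        seq = "AT" * 5 + "N" + "AT" * 5
        runs = find_perfect_runs(seq, 4)
        assert [(r.copies, r.start) for r in runs] == [(5, 0), (5, 11)]

    def test_partial_trailing_copy_is_flank(self):
        seq = "T" + "CAG" * 9 + "CA" + "TTT"
        (run,) = find_perfect_runs(seq, 8)
        assert (run.motif, run.copies) == ("CAG", 9)
        assert (run.start, run.end) == (1, 28)

    def test_per_motif_size_thresholds(self):
        seq = "AT" * 6 + "CCCCC" + "CAG" * 6
        by_size = {2: 5, 3: 8, 4: 8, 5: 8, 6: 8}
        runs = find_perfect_runs(seq, by_size)
        assert [r.motif for r in runs] == ["AT"]

    def test_matches_exhaustive_oracle_on_random_strings(self, rng):
        mismatches = 0
        for i in range(400):
            n = int(rng.integers(30, 300))
            seq = seed_with_repeats(rng, n) if i % 2 else random_seq(rng, n, 0.02)
            min_copies = int(rng.integers(2, 9))
            got = [(r.motif, r.copies, r.start, r.end) for r in find_perfect_runs(seq, min_copies)]
            expected = oracle_runs(seq, min_copies)
            if got != expected:
                mismatches += 1
        assert mismatches == 0

    def test_planted_truth_runs_recovered_exactly(self):
        cfg = SimConfig(n_perfect=20, n_templates=4, seed=3)
        templates = simulate_templates(cfg)
        for planted in templates.truth:
            runs = find_perfect_runs(templates.sequences[planted.template_id], 8)
            spans = {(r.motif, r.copies, r.start, r.end) for r in runs}
            assert (planted.motif, planted.copies, planted.start, planted.end) in spans


# ---------------------------------------------------------- locus grouping

def run(motif, copies, start, read_id="r"):
    from satellite_miner.ssrfind import SsrRun

    return SsrRun(
        read_id=read_id,
        motif=motif,
        canonical=canonical_motif(motif),
        copies=copies,
        start=start,
        end=start + copies * len(motif),
    )


class TestGroupRuns:
    def test_single_run_is_perfect_locus(self):
        (locus,) = group_runs_to_locus([run("AT", 8, 10)], max_gap=10)
        assert locus.purity == PERFECT
        assert (locus.target_start, locus.target_end) == (10, 26)

    def test_same_motif_with_gap_is_interrupted(self):
        (locus,) = group_runs_to_locus([run("AT", 8, 0), run("TA", 8, 18)], max_gap=10)
        assert locus.purity == INTERRUPTED
        assert (locus.target_start, locus.target_end) == (0, 34)

    def test_different_motifs_with_gap_is_compound(self):
        (locus,) = group_runs_to_locus([run("AT", 8, 0), run("CAG", 8, 18)], max_gap=10)
        assert locus.purity == COMPOUND

    def test_distant_runs_stay_separate(self):
        loci = group_runs_to_locus([run("AT", 8, 0), run("AT", 8, 100)], max_gap=10)
        assert [l.purity for l in loci] == [PERFECT, PERFECT]

    def test_flank_reconstruction(self):
        seq = "GGCC" + "AT" * 8 + "TTGG"
        read = Read("r", seq, [30] * len(seq))
        (locus,) = find_loci(read, min_copies=8)
        assert locus.left_flank == "GGCC"
        assert locus.right_flank == "TTGG"
        assert (
            locus.left_flank + seq[locus.target_start : locus.target_end] + locus.right_flank
            == seq
        )
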