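"""Microsatellite (SSR) detection in reads.

Finds maximal perfect tandem runs of primitive 2-6 base motifs, groups
nearby runs on a read into loci classified as perfect, interrupted
(same repeat unit resuming after a short gap) or compound (different
repeat units adjacent), and extracts the flanking sequences that primer
design will search.

A run must reach a minimum number of complete tandem copies (8 by default,
for every motif size) to be reported; partial trailing copies count as
flank, not repeat, so copy numbers are always integers.  Uncalled bases (N)
terminate runs: an N can never confirm a repeat unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .seqio import Read, reverse_complement

MOTIF_MIN = 2
MOTIF_MAX = 6
DEFAULT_MIN_COPIES = 8
DEFAULT_MAX_GAP = 10

_ACGT = frozenset("ACGT")

PERFECT = "perfect"
INTERRUPTED = "interrupted"
COMPOUND = "compound"


class PrimitivityError(ValueError):
    """Motif is a whole-number repetition of a shorter unit."""


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a repetition of a shorter unit (e.g. ATAT is not)."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Strand- and rotation-invariant normal form of a repeat motif.

    The canonical key is the lexicographically smallest string among all
    cyclic rotations of the motif and of its reverse complement, so that
    e.g. TA, AT, and their complements all summarize as AT.
    """
    if not MOTIF_MIN <= len(motif) <= MOTIF_MAX:
        raise ValueError(f"motif length must be in [{MOTIF_MIN}, {MOTIF_MAX}]: {motif!r}")
    if not is_primitive(motif):
        raise PrimitivityError(f"motif {motif!r} is a repetition of a shorter unit")
    candidates = []
    for m in (motif, reverse_complement(motif)):
        doubled = m + m
        candidates.extend(doubled[i : i + len(m)] for i in range(len(m)))
    return min(candidates)


@dataclass
class SsrRun:
    """One maximal perfect tandem repeat run within a read."""

    read_id: str
    motif: str
    canonical: str
    copies: int
    start: int  # 0-based half-open span in the read
    end: int
    purity: str = PERFECT

    def __post_init__(self) -> None:
        if self.end - self.start != self.copies * len(self.motif):
            raise ValueError("run span inconsistent with copies x motif length")


@dataclass
class SsrLocus:
    """One or more runs on a read, with the flanks primer design will search."""

    read_id: str
    runs: list[SsrRun]
    target_start: int
    target_end: int
    left_flank: str
    right_flank: str
    purity: str

    @property
    def primary_run(self) -> SsrRun:
        """The longest run (ties to the earliest); carries the locus motif."""
        return max(self.runs, key=lambda r: (r.end - r.start, -r.start))


def find_perfect_runs(
    seq: str,
    min_copies: int | Mapping[int, int] = DEFAULT_MIN_COPIES,
    read_id: str = "",
) -> list[SsrRun]:
    """All maximal perfect tandem runs of primitive 2-6-mer motifs.

    ``min_copies`` may be a single threshold or a {motif_size: threshold}
    mapping.  For each motif size k, the sequence is scanned for maximal
    k-periodic stretches (positions where ``seq[i] == seq[i+k]``, both called
    bases); each stretch long enough to hold the required complete copies
    yields one run, anchored at the stretch start.  Non-primitive motifs are
    skipped — their runs are reported at their true (shorter) period.
    """
    runs: list[SsrRun] = []
    n = len(seq)
    for k in range(MOTIF_MIN, MOTIF_MAX + 1):
        threshold = min_copies[k] if isinstance(min_copies, Mapping) else min_copies
        if threshold < 2:
            raise ValueError("min_copies must be >= 2")
        i = 0
        limit = n - k
        while i < limit:
            if seq[i] in _ACGT and seq[i] == seq[i + k]:
                # extend the k-periodic match stretch
                j = i
                while j < limit and seq[j] in _ACGT and seq[j] == seq[j + k]:
                    j += 1
                # periodic region is seq[i : j + k)
                copies = (j + k - i) // k
                motif = seq[i : i + k]
                if copies >= threshold and is_primitive(motif):
                    runs.append(
                        SsrRun(
                            read_id=read_id,
                            motif=motif,
                            canonical=canonical_motif(motif),
                            copies=copies,
                            start=i,
                            end=i + copies * k,
                        )
                    )
                i = j + 1
            else:
                i += 1
    runs.sort(key=lambda r: (r.start, r.end))
    return runs


def group_runs_to_locus(
    runs: Sequence[SsrRun],
    max_gap: int = DEFAULT_MAX_GAP,
    seq: str | None = None,
) -> list[SsrLocus]:
    """Merge runs on one read separated by <= ``max_gap`` bases into loci.

    A single isolated run yields a perfect locus; merged runs sharing one
    canonical motif form an interrupted locus; runs with different canonical
    motifs form a compound locus.  When ``seq`` is given, flanks are sliced
    from it so that ``left_flank + read[target] + right_flank`` reconstructs
    the read.
    """
    runs = sorted(runs, key=lambda r: (r.start, r.end))
    loci: list[SsrLocus] = []
    cluster: list[SsrRun] = []

    def flush() -> None:
        if not cluster:
            return
        start = min(r.start for r in cluster)
        end = max(r.end for r in cluster)
        canonicals = {r.canonical for r in cluster}
        if len(cluster) == 1:
            purity = PERFECT
        elif len(canonicals) == 1:
            purity = INTERRUPTED
        else:
            purity = COMPOUND
        loci.append(
            SsrLocus(
                read_id=cluster[0].read_id,
                runs=list(cluster),
                target_start=start,
                target_end=end,
                left_flank=seq[:start] if seq is not None else "",
                right_flank=seq[end:] if seq is not None else "",
                purity=purity,
            )
        )

    for run in runs:
        if cluster and run.start - max(r.end for r in cluster) <= max_gap:
            cluster.append(run)
        else:
            flush()
            cluster = [run]
    flush()
    return loci


def find_loci(
    read: Read,
    min_copies: int | Mapping[int, int] = DEFAULT_MIN_COPIES,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[SsrLocus]:
    """Detect SSR loci (runs grouped, flanks attached) on one read."""
    runs = find_perfect_runs(read.seq, min_copies, read_id=read.id)
    return group_runs_to_locus(runs, max_gap=max_gap, seq=read.seq)
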