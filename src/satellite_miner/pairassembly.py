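"""Read-pair overlap assembly and on-template primer confirmation.

Overlapping 2x250 bp mates from sub-500 bp fragments are merged into a
single consensus template; a designed primer pair is then confirmed by
requiring both priming sites on that one template in the correct
orientation and at an admissible product size.  Confirming both sites on a
single physical molecule is what raises downstream PCR success: each primer
was otherwise only ever observed on its own mate.

The overlap scorer is quality-aware and deterministic: every candidate
overlap length is scored by summing +min(q1,q2) at agreements and
-min(q1,q2) at disagreements, the best-scoring overlap wins (ties go to the
longer overlap, which carries more evidence), and the merge is accepted only
if its fractional identity reaches ``min_identity``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import Read, ReadPair, reverse_complement
from .primerdesign import PrimerPair

DEFAULT_MIN_OVERLAP = 15
DEFAULT_MIN_IDENTITY = 0.9


@dataclass
class MergedRead:
    """Consensus of an overlapped mate pair."""

    seq: str
    quals: list[int]
    overlap_len: int
    mismatches_in_overlap: int
    source_pair_id: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("consensus sequence/quality length mismatch")


@dataclass
class Confirmation:
    """Outcome of checking a primer pair against a merged template."""

    found: bool
    product_size: int | None = None


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> MergedRead | None:
    """Merge a mate pair by 3' overlap, or return None if no acceptable overlap.

    Mate 2 is reverse-complemented (with reversed qualities) onto mate 1's
    strand; every overlap length in [min_overlap, min(len1, len2)] is scored.
    At disagreeing overlap positions the consensus takes the higher-quality
    base with quality |q1 - q2| (q1 wins exact ties); agreements keep the
    base with quality max(q1, q2).
    """
    r1, r2rc = pair.r1, pair.r2.reverse_complement()
    len1, len2 = len(r1), len(r2rc)
    max_overlap = min(len1, len2)
    if max_overlap < min_overlap:
        return None

    s1 = np.frombuffer(r1.seq.encode(), dtype=np.uint8)
    s2 = np.frombuffer(r2rc.seq.encode(), dtype=np.uint8)
    q1 = np.asarray(r1.quals, dtype=np.int64)
    q2 = np.asarray(r2rc.quals, dtype=np.int64)

    best_score = -np.inf
    best_len = 0
    for olen in range(min_overlap, max_overlap + 1):
        a = slice(len1 - olen, len1)
        b = slice(0, olen)
        agree = s1[a] == s2[b]
        weight = np.minimum(q1[a], q2[b])
        score = int(weight[agree].sum()) - int(weight[~agree].sum())
        if score >= best_score:  # >= breaks ties toward the longer overlap
            best_score = score
            best_len = olen

    a = slice(len1 - best_len, len1)
    b = slice(0, best_len)
    agree = s1[a] == s2[b]
    identity = float(agree.mean())
    if identity < min_identity:
        return None

    take1 = q1[a] >= q2[b]  # mate 1 wins quality ties
    cons = np.where(agree | take1, s1[a], s2[b])
    cons_q = np.where(agree, np.maximum(q1[a], q2[b]), np.abs(q1[a] - q2[b]))
    seq = r1.seq[: len1 - best_len] + cons.tobytes().decode() + r2rc.seq[best_len:]
    quals = list(q1[: len1 - best_len]) + [int(q) for q in cons_q] + list(q2[best_len:])
    return MergedRead(
        seq=seq,
        quals=quals,
        overlap_len=best_len,
        mismatches_in_overlap=int((~agree).sum()),
        source_pair_id=pair.pair_id,
    )


def _find_with_mismatches(seq: str, pattern: str, start: int, max_mismatches: int) -> list[int]:
    """Start positions of matches of ``pattern`` in ``seq[start:]`` with at
    most ``max_mismatches`` substitutions."""
    if max_mismatches == 0:
        hits = []
        idx = seq.find(pattern, start)
        while idx != -1:
            hits.append(idx)
            idx = seq.find(pattern, idx + 1)
        return hits
    m = len(pattern)
    hits = []
    for i in range(start, len(seq) - m + 1):
        mismatches = 0
        for a, b in zip(seq[i : i + m], pattern):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            hits.append(i)
    return hits


def confirm_primers_on_template(
    merged: MergedRead,
    primer_pair: PrimerPair,
    product_bounds: tuple[int, int],
    max_mismatches: int = 0,
) -> Confirmation:
    """Check that both primers sit on one merged template in PCR orientation.

    The forward primer must occur on the template, the reverse primer's
    binding site (its reverse complement) must occur downstream of the
    forward match end, and the implied product size — forward match start to
    reverse-site end — must lie within ``product_bounds`` (inclusive).
    Matching is exact by default; ``max_mismatches=1`` relaxes it.
    """
    lo, hi = product_bounds
    rev_site = reverse_complement(primer_pair.rev_seq)
    fwd_hits = _find_with_mismatches(merged.seq, primer_pair.fwd_seq, 0, max_mismatches)
    for fwd_start in fwd_hits:
        fwd_end = fwd_start + len(primer_pair.fwd_seq)
        for rev_start in _find_with_mismatches(merged.seq, rev_site, fwd_end, max_mismatches):
            product = rev_start + len(rev_site) - fwd_start
            if lo <= product <= hi:
                return Confirmation(found=True, product_size=product)
    return Confirmation(found=False)
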