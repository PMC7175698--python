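"""PCR primer design in SSR flanks and primer-occurrence counting.

The designer enumerates every candidate window in the left flank (forward
primer) and right flank (reverse primer, taken as the reverse complement of
the window so it is reported 5'->3' on the opposite strand), rejects
candidates violating length, melting-temperature, GC-content and
self-complementarity constraints, and returns the admissible pair minimizing
a Primer3-style penalty.  Ties break deterministically toward the leftmost
forward start, then the shortest product.

Melting temperatures come from either the Wallace 2+4 rule or a
nearest-neighbor model using the SantaLucia (1998) unified ΔH/ΔS parameters
with monovalent-salt entropy correction.

Occurrence counting is strand-inclusive by default: a primer site present on
either strand of a shotgun read is the same genomic site, so occurrences of
the pattern and of its reverse complement are summed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import Read, reverse_complement
from .ssrfind import SsrLocus


@dataclass
class PrimerParams:
    """Primer design constraints (lengths in bases, temperatures in °C, GC in %)."""

    length_min: int = 18
    length_opt: int = 20
    length_max: int = 27
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 30.0
    gc_max: float = 70.0
    max_tm_diff: float = 3.0
    product_min: int = 60
    product_max: int = 500
    self_comp_suffix: int = 6  # reject palindromic 3' suffixes of this length or more; 0 = off
    tm_method: str = "nearest_neighbor"

    def __post_init__(self) -> None:
        for lo, opt, hi, name in (
            (self.length_min, self.length_opt, self.length_max, "length"),
            (self.tm_min, self.tm_opt, self.tm_max, "tm"),
        ):
            if not lo <= opt <= hi:
                raise ValueError(f"{name} triple must satisfy min <= opt <= max")
        if not self.gc_min <= self.gc_max:
            raise ValueError("gc_min must be <= gc_max")
        if not self.product_min <= self.product_max:
            raise ValueError("product_min must be <= product_max")


@dataclass
class PrimerPair:
    """A designed forward/reverse primer pair for one SSR locus.

    ``rev_seq`` is given 5'->3' on the opposite strand; ``rev_start`` is the
    0-based start of its binding site (the site's reverse complement) on the
    source read.  Occurrence counts are filled in by a later pipeline stage.
    """

    fwd_seq: str
    rev_seq: str
    fwd_tm: float
    rev_tm: float
    fwd_start: int
    rev_start: int
    product_size: int
    fwd_count: int = 0
    rev_count: int = 0


class CompositionError(ValueError):
    """Sequence contains bases a thermodynamic model cannot score (N)."""


def gc_percent(seq: str) -> float:
    """GC content of a sequence as a percentage."""
    if not seq:
        return 0.0
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def tm_wallace(seq: str) -> float:
    """Wallace rule: Tm = 2(A+T) + 4(G+C) °C.  Adequate only for short oligos."""
    _check_composition(seq)
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


# SantaLucia (1998) unified nearest-neighbor parameters.
# dH in kcal/mol, dS in cal/(mol*K); keys are the 5'->3' top-strand dimers.
_NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_NN_INIT_AT = (2.3, 4.1)  # duplex initiation with a terminal A·T
_NN_INIT_GC = (0.1, -2.8)  # duplex initiation with a terminal G·C
_GAS_CONSTANT = 1.987  # cal/(mol*K)


def _check_composition(seq: str) -> None:
    if not seq:
        raise CompositionError("empty sequence")
    if set(seq) - set("ACGT"):
        raise CompositionError(f"sequence contains non-ACGT bases: {seq!r}")


def tm_nearest_neighbor(
    seq: str, na_mM: float = 50.0, primer_nM: float = 250.0
) -> float:
    """Nearest-neighbor duplex melting temperature in °C.

    Sums the SantaLucia (1998) unified dimer ΔH/ΔS with terminal-base
    initiation terms, applies the entropic salt correction
    ``ΔS += 0.368 (N-1) ln[Na+]``, and evaluates
    ``Tm = ΔH / (ΔS + R ln C) - 273.15`` with C the excess primer
    concentration (primer in excess over template).
    """
    _check_composition(seq)
    if len(seq) < 2:
        raise CompositionError("nearest-neighbor model needs at least 2 bases")
    dh = 0.0  # kcal/mol
    ds = 0.0  # cal/(mol*K)
    for end in (seq[0], seq[-1]):
        init = _NN_INIT_GC if end in "GC" else _NN_INIT_AT
        dh += init[0]
        ds += init[1]
    for i in range(len(seq) - 1):
        dimer = seq[i : i + 2]
        if dimer not in _NN_PARAMS:
            dimer = reverse_complement(dimer)
        h, s = _NN_PARAMS[dimer]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    conc = primer_nM * 1e-9
    return (dh * 1000.0) / (ds + _GAS_CONSTANT * math.log(conc)) - 273.15


def melting_temperature(seq: str, method: str = "nearest_neighbor") -> float:
    """Primer melting temperature by the requested model."""
    if method == "wallace":
        return tm_wallace(seq)
    if method == "nearest_neighbor":
        return tm_nearest_neighbor(seq)
    raise ValueError(f"unknown Tm method: {method!r}")


def has_self_complementary_suffix(seq: str, min_len: int = 6) -> bool:
    """True if some 3' suffix of length >= ``min_len`` is its own reverse
    complement (a hairpin/dimer-prone palindrome)."""
    if min_len <= 0:
        return False
    start = min_len + (min_len % 2)  # palindromes have even length
    for length in range(start, len(seq) + 1, 2):
        suffix = seq[-length:]
        if suffix == reverse_complement(suffix):
            return True
    return False


def _candidate_windows(
    flank: str, params: PrimerParams, reverse: bool
) -> list[tuple[int, int, str, float, float]]:
    """Admissible single-primer candidates in one flank.

    Returns (window_start, window_end, primer_seq, tm, gc) tuples; for the
    right flank the primer is the reverse complement of the window.
    """
    out = []
    n = len(flank)
    for length in range(params.length_min, min(params.length_max, n) + 1):
        for start in range(0, n - length + 1):
            window = flank[start : start + length]
            if "N" in window:
                continue
            primer = reverse_complement(window) if reverse else window
            gc = gc_percent(primer)
            if not params.gc_min <= gc <= params.gc_max:
                continue
            try:
                tm = melting_temperature(primer, params.tm_method)
            except CompositionError:
                continue
            if not params.tm_min <= tm <= params.tm_max:
                continue
            if params.self_comp_suffix and has_self_complementary_suffix(
                primer, params.self_comp_suffix
            ):
                continue
            out.append((start, start + length, primer, tm, gc))
    return out


def design_primer_pair(locus: SsrLocus, params: PrimerParams) -> PrimerPair | None:
    """Best admissible primer pair for a locus, or None if no pair satisfies
    all constraints (which triggers the "no primers" filter downstream).

    Penalty = |Tm - Tm_opt| + |len - len_opt| summed over both mates,
    plus the pair's Tm difference.  Ties break by leftmost forward start,
    then shortest product.
    """
    fwd = _candidate_windows(locus.left_flank, params, reverse=False)
    rev = _candidate_windows(locus.right_flank, params, reverse=True)
    if not fwd or not rev:
        return None

    right_offset = locus.target_end  # right flank coordinates -> read coordinates
    fwd_start = np.array([c[0] for c in fwd])
    fwd_len = np.array([c[1] - c[0] for c in fwd])
    fwd_tm = np.array([c[3] for c in fwd])
    rev_end = np.array([c[1] for c in rev]) + right_offset
    rev_len = np.array([c[1] - c[0] for c in rev])
    rev_tm = np.array([c[3] for c in rev])

    # pairwise (fwd x rev) constraint masks and penalties
    product = rev_end[None, :] - fwd_start[:, None]
    tm_diff = np.abs(fwd_tm[:, None] - rev_tm[None, :])
    ok = (
        (product >= params.product_min)
        & (product <= params.product_max)
        & (tm_diff <= params.max_tm_diff)
    )
    if not ok.any():
        return None
    penalty = (
        np.abs(fwd_tm[:, None] - params.tm_opt)
        + np.abs(rev_tm[None, :] - params.tm_opt)
        + np.abs(fwd_len[:, None] - params.length_opt)
        + np.abs(rev_len[None, :] - params.length_opt)
        + tm_diff
    )
    penalty = np.where(ok, penalty, np.inf)
    best = penalty.min()
    # deterministic tie-break: leftmost forward start, then shortest product
    ii, jj = np.nonzero(np.isclose(penalty, best, rtol=0.0, atol=1e-9))
    order = np.lexsort((product[ii, jj], fwd_start[ii]))
    i, j = int(ii[order[0]]), int(jj[order[0]])

    f = fwd[i]
    r = rev[j]
    return PrimerPair(
        fwd_seq=f[2],
        rev_seq=r[2],
        fwd_tm=float(fwd_tm[i]),
        rev_tm=float(rev_tm[j]),
        fwd_start=int(fwd_start[i]),
        rev_start=int(r[0] + right_offset),
        product_size=int(product[i, j]),
    )


def count_in_sequence(pattern: str, seq: str) -> int:
    """Overlapping occurrences of ``pattern`` in ``seq``."""
    count = 0
    idx = seq.find(pattern)
    while idx != -1:
        count += 1
        idx = seq.find(pattern, idx + 1)
    return count


def count_occurrences(
    pattern: str, reads: Iterable[Read], include_reverse_complement: bool = True
) -> int:
    """Total occurrences of a primer sequence across a read set.

    Counts exact, overlapping matches of the pattern and (by default) of its
    reverse complement; a palindromic pattern is counted once per site.
    """
    if not pattern:
        raise ValueError("pattern must be nonempty")
    rc = reverse_complement(pattern) if include_reverse_complement else None
    if rc == pattern:
        rc = None  # palindrome: forward scan already counts every site
    total = 0
    for read in reads:
        total += count_in_sequence(pattern, read.seq)
        if rc is not None:
            total += count_in_sequence(rc, read.seq)
    return total
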