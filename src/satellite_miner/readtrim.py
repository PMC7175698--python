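"""Pair-aware quality trimming.

Implements the four classic Trimmomatic-style operators — LEADING, TRAILING,
SLIDINGWINDOW, and MINLEN — with pair-aware semantics: if either mate of a
pair falls below the minimum length after trimming, the whole pair is
discarded, so the surviving output always consists of complete pairs.

Defaults follow common MiSeq practice for 2x250 bp shotgun libraries:
a 4-base sliding window at mean Q20 (99% per-base accuracy), leading and
trailing hard-clip at Q3, and a 50 bp minimum surviving length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .seqio import Read, ReadPair

#: Operator names accepted in :attr:`TrimConfig.step_order`.
KNOWN_STEPS = ("SLIDINGWINDOW", "LEADING", "TRAILING", "MINLEN", "ADAPTERS")

DEFAULT_STEP_ORDER = ("SLIDINGWINDOW", "LEADING", "TRAILING", "MINLEN")


@dataclass
class TrimConfig:
    """Trimming parameters.

    ``step_order`` lists the per-read operators in application order; MINLEN
    may appear anywhere (or be omitted) — the pair-drop decision is always
    taken on the final length of each mate.
    """

    window_size: int = 4
    window_quality: float = 20.0
    leading_quality: int = 3
    trailing_quality: int = 3
    min_length: int = 50
    step_order: tuple[str, ...] = DEFAULT_STEP_ORDER
    adapters: tuple[str, ...] = ()  # adapter clipping off unless sequences given
    adapter_max_mismatches: int = 1
    adapter_min_overlap: int = 6

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.window_quality < 0 or self.leading_quality < 0 or self.trailing_quality < 0:
            raise ValueError("quality thresholds must be >= 0")
        self.step_order = tuple(s.upper() for s in self.step_order)
        unknown = set(self.step_order) - set(KNOWN_STEPS)
        if unknown:
            raise ValueError(f"unknown trimming steps: {sorted(unknown)}")


def trim_leading(read: Read, q: int) -> Read:
    """Remove 5' bases while their quality is below ``q`` (a suffix survives)."""
    start = 0
    while start < len(read) and read.quals[start] < q:
        start += 1
    return read.slice(start, len(read))


def trim_trailing(read: Read, q: int) -> Read:
    """Remove 3' bases while their quality is below ``q`` (a prefix survives)."""
    end = len(read)
    while end > 0 and read.quals[end - 1] < q:
        end -= 1
    return read.slice(0, end)


def sliding_window_trim(read: Read, w: int, q: float) -> Read:
    """Truncate at the first w-base window whose mean quality drops below ``q``.

    Windows are evaluated at every offset from the 5' end.  A read shorter
    than the window is kept whole iff its overall mean quality is >= ``q``.
    Every scanned window wholly inside the surviving read has mean >= ``q``.
    """
    n = len(read)
    if n == 0:
        return read
    quals = read.quals
    if n < w:
        mean = sum(quals) / n
        return read if mean >= q else read.slice(0, 0)
    threshold = q * w  # compare window sums to avoid float division per window
    window_sum = sum(quals[:w])
    if window_sum < threshold:
        return read.slice(0, 0)
    for start in range(1, n - w + 1):
        window_sum += quals[start + w - 1] - quals[start - 1]
        if window_sum < threshold:
            return read.slice(0, start)
    return read


def _clip_adapter(read: Read, cfg: TrimConfig) -> Read:
    """Clip the 3' end where a read suffix matches an adapter prefix.

    For each adapter, every read suffix of length >= ``adapter_min_overlap``
    is compared to the adapter prefix of the same length; at the leftmost
    position matching with <= ``adapter_max_mismatches`` mismatches, the read
    is truncated there.
    """
    if not cfg.adapters:
        return read
    seq = read.seq
    n = len(seq)
    for start in range(0, n - cfg.adapter_min_overlap + 1):
        span = n - start
        for adapter in cfg.adapters:
            m = min(span, len(adapter))
            if m < cfg.adapter_min_overlap:
                continue
            mismatches = sum(1 for a, b in zip(seq[start : start + m], adapter[:m]) if a != b)
            if mismatches <= cfg.adapter_max_mismatches:
                return read.slice(0, start)
    return read


def _apply_steps(read: Read, cfg: TrimConfig) -> Read:
    for step in cfg.step_order:
        if step == "SLIDINGWINDOW":
            read = sliding_window_trim(read, cfg.window_size, cfg.window_quality)
        elif step == "LEADING":
            read = trim_leading(read, cfg.leading_quality)
        elif step == "TRAILING":
            read = trim_trailing(read, cfg.trailing_quality)
        elif step == "ADAPTERS":
            read = _clip_adapter(read, cfg)
        # MINLEN is a length gate, not a transform; enforced in process_pair
    return read


def process_pair(pair: ReadPair, cfg: TrimConfig) -> ReadPair | None:
    """Trim both mates; drop the pair if either mate ends below min_length.

    Pair-awareness maintains mate-file parity: downstream stages only ever
    see complete pairs.
    """
    r1 = _apply_steps(pair.r1, cfg)
    r2 = _apply_steps(pair.r2, cfg)
    if len(r1) < cfg.min_length or len(r2) < cfg.min_length:
        return None
    return ReadPair(r1, r2, pair.pair_id)


@dataclass
class TrimStats:
    pairs_in: int = 0
    pairs_out: int = 0
    bases_in: int = 0
    bases_out: int = 0

    @property
    def percent_removed(self) -> float:
        return 100.0 * (1 - self.pairs_out / self.pairs_in) if self.pairs_in else 0.0


def trim_pairs(
    pairs: Iterable[ReadPair], cfg: TrimConfig, stats: TrimStats | None = None
) -> Iterator[ReadPair]:
    """Stream pairs through :func:`process_pair`, accumulating statistics."""
    for pair in pairs:
        if stats is not None:
            stats.pairs_in += 1
            stats.bases_in += len(pair.r1) + len(pair.r2)
        trimmed = process_pair(pair, cfg)
        if trimmed is not None:
            if stats is not None:
                stats.pairs_out += 1
                stats.bases_out += len(trimmed.r1) + len(trimmed.r2)
            yield trimmed
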