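"""Per-library read quality reports.

Produces FastQC-style summaries — read counts, length distribution,
per-cycle quality statistics, GC content, exact sequence duplication levels,
and adapter content — as plain dataclasses plus tab-delimited serializations.
Duplication is counted exactly over the whole library rather than estimated
from a subsample; at desk scale this is cheap and exactly testable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import Read

#: Common Illumina adapter read-through sequences (TruSeq universal, Nextera).
DEFAULT_ADAPTERS: dict[str, str] = {
    "truseq": "AGATCGGAAGAGC",
    "nextera": "CTGTCTCTTATACACATCT",
}


class EmptyLibraryError(ValueError):
    """A QC report requires at least one read."""


def phred_accuracy(q: float) -> float:
    """Percent base-call accuracy implied by a Phred score.

    A Phred score Q corresponds to an error probability of 10^(-Q/10), so the
    accuracy is ``100 * (1 - 10^(-q/10))`` — e.g. Q20 means 99.0% accuracy.
    """
    if q < 0:
        raise ValueError(f"Phred score must be non-negative, got {q}")
    return 100.0 * (1.0 - 10.0 ** (-q / 10.0))


@dataclass
class QcReport:
    """Summary statistics for one read library."""

    n_reads: int
    length_distribution: dict[int, int]
    per_cycle_quality: pd.DataFrame  # columns: cycle, n, mean, q25, median, q75
    gc_percent: float
    duplication_fraction: float
    adapter_hits: dict[str, int]

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_percent <= 100.0:
            raise ValueError("gc_percent outside [0, 100]")
        if not 0.0 <= self.duplication_fraction <= 1.0:
            raise ValueError("duplication_fraction outside [0, 1]")
        if sum(self.length_distribution.values()) != self.n_reads:
            raise ValueError("length histogram total != n_reads")


def build_report(
    reads: Sequence[Read], adapters: dict[str, str] | None = None
) -> QcReport:
    """Compute a :class:`QcReport` over a library of reads.

    Per-cycle statistics at cycle *i* are computed over the reads long enough
    to cover that cycle.
    """
    if adapters is None:
        adapters = DEFAULT_ADAPTERS
    reads = list(reads)
    if not reads:
        raise EmptyLibraryError("cannot build a QC report from zero reads")

    lengths = Counter(len(r) for r in reads)
    max_len = max(lengths)

    # Ragged per-cycle matrix: NaN-padded so short reads drop out of cycles
    # they do not cover.
    qual_matrix = np.full((len(reads), max_len), np.nan)
    for i, read in enumerate(reads):
        qual_matrix[i, : len(read)] = read.quals
    with np.errstate(invalid="ignore"):
        per_cycle = pd.DataFrame(
            {
                "cycle": np.arange(1, max_len + 1),
                "n": np.sum(~np.isnan(qual_matrix), axis=0),
                "mean": np.nanmean(qual_matrix, axis=0),
                "q25": np.nanpercentile(qual_matrix, 25, axis=0),
                "median": np.nanpercentile(qual_matrix, 50, axis=0),
                "q75": np.nanpercentile(qual_matrix, 75, axis=0),
            }
        )

    total_bases = sum(lengths[k] * k for k in lengths)
    gc_bases = sum(r.seq.count("G") + r.seq.count("C") for r in reads)
    gc_percent = 100.0 * gc_bases / total_bases if total_bases else 0.0

    seq_counts = Counter(r.seq for r in reads)
    duplicated = sum(c for c in seq_counts.values() if c > 1)
    duplication_fraction = duplicated / len(reads)

    adapter_hits = {
        name: sum(1 for r in reads if adapter in r.seq)
        for name, adapter in adapters.items()
    }

    return QcReport(
        n_reads=len(reads),
        length_distribution=dict(sorted(lengths.items())),
        per_cycle_quality=per_cycle,
        gc_percent=gc_percent,
        duplication_fraction=duplication_fraction,
        adapter_hits=adapter_hits,
    )


def write_report(report: QcReport, path: str | Path) -> None:
    """Serialize a report as a tab-delimited file with sectioned key/value rows."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("section\tkey\tvalue\n")
        fh.write(f"basic\tn_reads\t{report.n_reads}\n")
        fh.write(f"basic\tgc_percent\t{report.gc_percent:.4f}\n")
        fh.write(f"basic\tduplication_fraction\t{report.duplication_fraction:.6f}\n")
        for length, count in report.length_distribution.items():
            fh.write(f"length\t{length}\t{count}\n")
        for name, hits in sorted(report.adapter_hits.items()):
            fh.write(f"adapter\t{name}\t{hits}\n")
        for row in report.per_cycle_quality.itertuples(index=False):
            fh.write(
                f"cycle\t{int(row.cycle)}\t"
                f"{int(row.n)},{row.mean:.3f},{row.q25:.1f},{row.median:.1f},{row.q75:.1f}\n"
            )


def summary_text(report: QcReport, title: str = "library") -> str:
    """Short plain-text summary suitable for logs."""
    lengths = report.length_distribution
    lo, hi = min(lengths), max(lengths)
    mean_q = float(
        np.average(report.per_cycle_quality["mean"], weights=report.per_cycle_quality["n"])
    )
    return (
        f"QC {title}: {report.n_reads} reads, lengths {lo}-{hi}, "
        f"GC {report.gc_percent:.1f}%, duplication {100 * report.duplication_fraction:.1f}%, "
        f"mean quality Q{mean_q:.1f}"
    )


def plot_per_cycle_quality(report: QcReport, path: str | Path, title: str = "") -> None:
    """Write a per-cycle quality plot (mean with interquartile band)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.per_cycle_quality
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.fill_between(df["cycle"], df["q25"], df["q75"], alpha=0.3, label="IQR")
    ax.plot(df["cycle"], df["mean"], lw=1.5, label="mean")
    ax.set_xlabel("cycle")
    ax.set_ylabel("Phred quality")
    ax.set_ylim(0, None)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
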