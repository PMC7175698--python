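"""Marker-table construction, the locus filter cascade, and table writers.

A :class:`MarkerRecord` is one candidate microsatellite locus: the repeat,
its designed primer pair (if any), each primer's occurrence count in the
total read set, and the outcome of pair-assembly confirmation.  The filter
cascade removes, per enabled toggle:

1. loci for which no primer pair could be designed;
2. loci whose motif structure is not a single perfect run (compound or
   interrupted repeats do not follow the stepwise mutation model most
   microsatellite population-genetics methods assume) — when this filter is
   enabled the survivors are also ranked by motif size, largest first;
3. loci whose primer sequences occur more than once in the total reads
   (multi-copy priming sites risk amplifying duplicated regions);
4. loci whose primers could not be confirmed on a single merged template.

Each additional toggle can only shrink the surviving set, so enabling
filters reproduces the nested raw >= filtered >= assembly-confirmed
structure of a marker development run.  All tables are tab-delimited and
round-trip through the bundled reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .primerdesign import PrimerPair
from .ssrfind import PERFECT


class FilterConfigurationError(ValueError):
    """A filter was requested whose inputs were never computed."""


@dataclass
class MarkerRecord:
    """One candidate locus row of the marker table."""

    locus_id: str
    fwd_read_id: str
    rev_read_id: str
    motif: str
    canonical_motif: str
    motif_size: int
    copies: int
    purity: str
    primer_pair: PrimerPair | None = None
    assembly_confirmed: bool | None = None  # None = assembly never evaluated

    def __post_init__(self) -> None:
        if self.primer_pair is not None:
            if self.primer_pair.fwd_count < 1 or self.primer_pair.rev_count < 1:
                raise ValueError(
                    f"{self.locus_id}: a designed primer must occur at least once "
                    f"(in its own source read)"
                )

    @property
    def fwd_count(self) -> int:
        return self.primer_pair.fwd_count if self.primer_pair else 0

    @property
    def rev_count(self) -> int:
        return self.primer_pair.rev_count if self.primer_pair else 0


@dataclass
class FilterToggles:
    """Independent on/off switches of the filter cascade."""

    require_primers: bool = False
    perfect_only: bool = False
    unique_primers_only: bool = False
    require_assembly: bool = False


def apply_filters(
    records: Sequence[MarkerRecord], toggles: FilterToggles
) -> list[MarkerRecord]:
    """Apply the enabled filters; rank by motif size when ``perfect_only`` is on.

    With every toggle off the input is returned unchanged (same order).
    Ranking ties break by copies descending, then locus_id ascending, so the
    output is a total order and the operation is idempotent.
    """
    if toggles.require_assembly and records and all(
        r.assembly_confirmed is None for r in records
    ):
        raise FilterConfigurationError(
            "require_assembly is enabled but assembly was never evaluated"
        )
    out = list(records)
    if toggles.require_primers:
        out = [r for r in out if r.primer_pair is not None]
    if toggles.perfect_only:
        out = [r for r in out if r.purity == PERFECT]
    if toggles.unique_primers_only:
        out = [
            r
            for r in out
            if r.primer_pair is not None
            and r.fwd_count <= 1
            and r.rev_count <= 1
        ]
    if toggles.require_assembly:
        out = [r for r in out if r.assembly_confirmed is True]
    if toggles.perfect_only:
        out.sort(key=lambda r: (-r.motif_size, -r.copies, r.locus_id))
    return out


def summarize_motif_types(records: Sequence[MarkerRecord]) -> pd.DataFrame:
    """Count loci per (canonical motif, purity) — the repeat-type summary table."""
    if not records:
        return pd.DataFrame(columns=["canonical_motif", "purity", "n_loci"])
    df = pd.DataFrame(
        {
            "canonical_motif": [r.canonical_motif for r in records],
            "purity": [r.purity for r in records],
        }
    )
    summary = (
        df.groupby(["canonical_motif", "purity"], sort=True)
        .size()
        .reset_index(name="n_loci")
    )
    return summary


_NA = "NA"

_COLUMNS = [
    "locus_id",
    "fwd_read_id",
    "rev_read_id",
    "motif",
    "canonical_motif",
    "motif_size",
    "copies",
    "purity",
    "fwd_primer",
    "rev_primer",
    "fwd_tm",
    "rev_tm",
    "fwd_start",
    "rev_start",
    "product_size",
    "fwd_count",
    "rev_count",
    "assembly_confirmed",
]


def _record_to_row(r: MarkerRecord) -> dict[str, object]:
    p = r.primer_pair
    return {
        "locus_id": r.locus_id,
        "fwd_read_id": r.fwd_read_id,
        "rev_read_id": r.rev_read_id,
        "motif": r.motif,
        "canonical_motif": r.canonical_motif,
        "motif_size": r.motif_size,
        "copies": r.copies,
        "purity": r.purity,
        "fwd_primer": p.fwd_seq if p else _NA,
        "rev_primer": p.rev_seq if p else _NA,
        "fwd_tm": f"{p.fwd_tm:.4f}" if p else _NA,
        "rev_tm": f"{p.rev_tm:.4f}" if p else _NA,
        "fwd_start": p.fwd_start if p else _NA,
        "rev_start": p.rev_start if p else _NA,
        "product_size": p.product_size if p else _NA,
        "fwd_count": p.fwd_count if p else _NA,
        "rev_count": p.rev_count if p else _NA,
        "assembly_confirmed": _NA if r.assembly_confirmed is None else str(r.assembly_confirmed),
    }


def write_marker_table(records: Sequence[MarkerRecord], path: str | Path) -> int:
    """Write the tab-delimited marker table (header always present); returns row count."""
    df = pd.DataFrame([_record_to_row(r) for r in records], columns=_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def read_marker_table(path: str | Path) -> list[MarkerRecord]:
    """Re-read a marker table written by :func:`write_marker_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        if row.fwd_primer == _NA:
            pair = None
        else:
            pair = PrimerPair(
                fwd_seq=row.fwd_primer,
                rev_seq=row.rev_primer,
                fwd_tm=float(row.fwd_tm),
                rev_tm=float(row.rev_tm),
                fwd_start=int(row.fwd_start),
                rev_start=int(row.rev_start),
                product_size=int(row.product_size),
                fwd_count=int(row.fwd_count),
                rev_count=int(row.rev_count),
            )
        confirmed = None if row.assembly_confirmed == _NA else row.assembly_confirmed == "True"
        records.append(
            MarkerRecord(
                locus_id=row.locus_id,
                fwd_read_id=row.fwd_read_id,
                rev_read_id=row.rev_read_id,
                motif=row.motif,
                canonical_motif=row.canonical_motif,
                motif_size=int(row.motif_size),
                copies=int(row.copies),
                purity=row.purity,
                primer_pair=pair,
                assembly_confirmed=confirmed,
            )
        )
    return records


def write_motif_summary(records: Sequence[MarkerRecord], path: str | Path) -> int:
    """Write the repeat-type summary table; returns row count."""
    summary = summarize_motif_types(records)
    summary.to_csv(path, sep="\t", index=False)
    return len(summary)
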