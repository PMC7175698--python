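"""Synthetic templates and Illumina-like paired-end reads with truth tables.

The simulator emulates, at desk scale, a 2x250 bp MiSeq shotgun library from
a genome carrying microsatellites: synthetic templates receive planted SSR
constructs — a known-good forward priming site, a spacer, the repeat, a
spacer, and the reverse-complemented reverse priming site — and paired
reads are drawn from fragments with Phred-calibrated substitution errors
and linear 3' quality decay (Q38 at cycle 1 down to Q18 at the last cycle),
so that trimming, detection, design, counting, assembly, and filtering all
have real work to do.

Negative plants exercise every filter: repeats below the copy threshold
(invisible to detection), interrupted and compound repeats (filter 2),
loci flanked by low-complexity poly-A so no primer is designable
(filter 1), and loci whose forward priming region is duplicated elsewhere
and sequenced, so its primer occurs more than once in the reads (filter 3).

Each planted locus is covered by a deterministic number of targeted
fragments (one by default, mirroring low shotgun coverage where a priming
site is typically observed once); background fragments come from a
repeat-free tail region of each template.  All randomness flows from one
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import Read, ReadPair, reverse_complement
from .ssrfind import COMPOUND, INTERRUPTED, PERFECT, canonical_motif
from .primerdesign import (
    gc_percent,
    has_self_complementary_suffix,
    tm_nearest_neighbor,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationConfigError(ValueError):
    """Inconsistent simulation parameters (e.g. loci too dense to space out)."""


@dataclass
class SimConfig:
    """Study conditions for one simulated library."""

    # planted locus classes
    n_perfect: int = 50
    n_interrupted: int = 0
    n_compound: int = 0
    n_below_min: int = 0          # copies below threshold: must stay undetected
    n_bad_flank: int = 0          # poly-A flanks: detectable, but no primer designable
    n_dup_primer: int = 0         # forward priming region duplicated and sequenced
    # repeat geometry
    motif_size_weights: dict[int, float] = field(
        default_factory=lambda: {2: 0.40, 3: 0.30, 4: 0.15, 5: 0.10, 6: 0.05}
    )
    copies_min: int = 8
    copies_max: int = 14
    below_min_copies: tuple[int, int] = (4, 6)
    # template / library geometry (2 x 250 bp MiSeq-like)
    n_templates: int = 10
    template_length: int | None = None  # None: sized automatically from the loci
    read_length: int = 250
    fragment_mean: float = 410.0
    fragment_sd: float = 25.0
    pairs_per_locus: int = 1
    n_background_pairs: int = 100
    background_tail: int = 1200
    # primer-site planting
    primer_length: int = 20
    pad: int = 8
    #: low-complexity spacer planted downstream of each priming construct so
    #: that the mate-overlap region offers no alternative primer windows
    desert_len: int = 190
    primer_tm_range: tuple[float, float] = (58.5, 61.5)
    primer_gc_range: tuple[float, float] = (40.0, 60.0)
    # error model: per-base substitution probability 10^(-q/10)
    quality_start: int = 38
    quality_end: int = 18
    sequencing_errors: bool = True
    seed: int = 0

    @property
    def n_loci(self) -> int:
        return (
            self.n_perfect
            + self.n_interrupted
            + self.n_compound
            + self.n_below_min
            + self.n_bad_flank
            + self.n_dup_primer
        )

    @property
    def locus_spacing(self) -> int:
        # planted loci are separated by at least two read lengths, with margin
        # so a targeted fragment can never reach the next construct
        return 2 * self.read_length + 120


@dataclass
class PlantedLocus:
    """Ground truth for one planted repeat."""

    locus_id: str
    template_id: str
    motif: str
    canonical: str
    copies: int
    purity: str
    start: int  # target span on the template (repeat region incl. interruptions)
    end: int
    fwd_primer: str | None
    rev_primer: str | None
    primer_unique: bool = True

    @property
    def has_primer_sites(self) -> bool:
        return self.fwd_primer is not None

    def eligible(self, min_copies: int) -> bool:
        """Recoverable by a run of the full filter cascade: a perfect repeat
        above the detection threshold with unique planted priming sites."""
        return (
            self.purity == PERFECT
            and self.has_primer_sites
            and self.primer_unique
            and self.copies >= min_copies
        )


@dataclass
class SimulatedTemplates:
    sequences: dict[str, str]
    truth: list[PlantedLocus]
    #: regions duplicated from dup-primer loci, each needing sequencing coverage
    decoy_spans: list[tuple[str, int, int]]


@dataclass
class RecoveryReport:
    """Planted-truth evaluation of a marker table."""

    n_eligible: int
    n_recovered: int
    n_markers: int
    n_true_markers: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_eligible if self.n_eligible else 0.0

    @property
    def precision(self) -> float:
        return self.n_true_markers / self.n_markers if self.n_markers else 0.0


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _sample_motif(rng: np.random.Generator, cfg: SimConfig) -> str:
    sizes = sorted(cfg.motif_size_weights)
    weights = np.array([cfg.motif_size_weights[s] for s in sizes], dtype=float)
    weights /= weights.sum()
    k = int(rng.choice(sizes, p=weights))
    while True:
        motif = _random_bases(rng, k)
        try:
            canonical_motif(motif)  # validates primitivity
        except ValueError:
            continue
        return motif


def _sample_primer_site(rng: np.random.Generator, cfg: SimConfig) -> str:
    """A priming site with MiSeq-panel-friendly thermodynamics."""
    tm_lo, tm_hi = cfg.primer_tm_range
    gc_lo, gc_hi = cfg.primer_gc_range
    for _ in range(10_000):
        site = _random_bases(rng, cfg.primer_length)
        if not gc_lo <= gc_percent(site) <= gc_hi:
            continue
        if not tm_lo <= tm_nearest_neighbor(site) <= tm_hi:
            continue
        if has_self_complementary_suffix(site, 6):
            continue
        return site
    raise SimulationConfigError("could not sample an admissible priming site")


def _pad_bases(rng: np.random.Generator, n: int, not_first: str, not_last: str) -> str:
    """Spacer bases whose junction characters cannot extend an adjacent repeat."""
    pad = list(_random_bases(rng, n))
    choices = [b for b in "ACGT" if b != not_first]
    pad[0] = choices[rng.integers(len(choices))]
    choices = [b for b in "ACGT" if b != not_last]
    pad[-1] = choices[rng.integers(len(choices))]
    return "".join(pad)


def _build_construct(
    rng: np.random.Generator, cfg: SimConfig, kind: str
) -> tuple[str, dict]:
    """One planted construct and its truth metadata.

    Layout (coordinates relative to the construct):
    ``fwd_site + padL + repeat_region + padR + revcomp(rev_site)`` for
    primer-bearing classes; bad-flank loci replace sites and pads by poly-A.
    """
    motif = _sample_motif(rng, cfg)
    k = len(motif)
    copies = int(rng.integers(cfg.copies_min, cfg.copies_max + 1))

    last_motif = motif  # motif of the last run; pads must not extend it
    if kind == "below_min":
        lo, hi = cfg.below_min_copies
        copies = int(rng.integers(lo, hi + 1))
        repeat = motif * copies
        purity = PERFECT
    elif kind == "interrupted":
        copies = min(copies, 10)  # keep two-run constructs within one read
        gap = _pad_bases(rng, 3, not_first=motif[0], not_last=motif[-1])
        repeat = motif * copies + gap + motif * copies
        purity = INTERRUPTED
    elif kind == "compound":
        copies = min(copies, 10)
        other = _sample_motif(rng, cfg)
        while canonical_motif(other) == canonical_motif(motif):
            other = _sample_motif(rng, cfg)
        gap = _pad_bases(rng, 3, not_first=motif[0], not_last=other[-1])
        repeat = motif * copies + gap + other * copies
        purity = COMPOUND
        last_motif = other
    else:  # perfect, bad_flank, dup_primer
        repeat = motif * copies
        purity = PERFECT

    if kind == "bad_flank":
        # low-complexity flanks long enough that a 250 bp read covering the
        # repeat sees nothing but poly-A: no admissible primer window exists
        flank = "A" * 110
        construct = flank + repeat + flank
        meta = {
            "motif": motif,
            "copies": copies,
            "purity": purity,
            "target_offset": len(flank),
            "target_len": len(repeat),
            "fwd_primer": None,
            "rev_primer": None,
        }
        return construct, meta

    fwd = _sample_primer_site(rng, cfg)
    rev = _sample_primer_site(rng, cfg)
    # junction constraints keep the detected run span exactly the planted span
    pad_l = _pad_bases(rng, cfg.pad, not_first="", not_last=motif[-1])
    pad_r = _pad_bases(rng, cfg.pad, not_first=last_motif[0], not_last="")
    construct = (
        fwd + pad_l + repeat + pad_r + reverse_complement(rev) + "A" * cfg.desert_len
    )
    meta = {
        "motif": motif,
        "copies": copies,
        "purity": purity,
        "target_offset": len(fwd) + len(pad_l),
        "target_len": len(repeat),
        "fwd_primer": fwd,
        "rev_primer": rev,
    }
    return construct, meta


def simulate_templates(cfg: SimConfig) -> SimulatedTemplates:
    """Build templates with planted loci; deterministic for a given seed."""
    rng = np.random.default_rng(cfg.seed)
    kinds = (
        ["perfect"] * cfg.n_perfect
        + ["interrupted"] * cfg.n_interrupted
        + ["compound"] * cfg.n_compound
        + ["below_min"] * cfg.n_below_min
        + ["bad_flank"] * cfg.n_bad_flank
        + ["dup_primer"] * cfg.n_dup_primer
    )
    per_template = -(-len(kinds) // cfg.n_templates) if kinds else 0  # ceil
    margin = 80
    needed = margin + per_template * cfg.locus_spacing + cfg.background_tail + margin
    length = cfg.template_length if cfg.template_length is not None else needed
    if length < needed:
        raise SimulationConfigError(
            f"template_length {length} too short for {per_template} loci per "
            f"template at spacing {cfg.locus_spacing} (need >= {needed})"
        )

    sequences: dict[str, str] = {}
    truth: list[PlantedLocus] = []
    decoys: list[tuple[str, int, int]] = []
    pending_dups: list[str] = []  # left-flank regions awaiting decoy placement

    for t in range(cfg.n_templates):
        template_id = f"tpl{t:03d}"
        seq = list(_random_bases(rng, length))
        my_kinds = kinds[t::cfg.n_templates]
        for slot, kind in enumerate(my_kinds):
            construct, meta = _build_construct(rng, cfg, kind)
            pos = margin + slot * cfg.locus_spacing
            seq[pos : pos + len(construct)] = construct
            locus_id = f"planted{len(truth):04d}"
            start = pos + meta["target_offset"]
            truth.append(
                PlantedLocus(
                    locus_id=locus_id,
                    template_id=template_id,
                    motif=meta["motif"],
                    canonical=canonical_motif(meta["motif"]),
                    copies=meta["copies"],
                    purity=meta["purity"],
                    start=start,
                    end=start + meta["target_len"],
                    fwd_primer=meta["fwd_primer"],
                    rev_primer=meta["rev_primer"],
                    primer_unique=kind != "dup_primer",
                )
            )
            if kind == "dup_primer":
                # duplicate everything any designed forward primer could use:
                # 60 bases of upstream context, the priming site, and the pad
                dup_start = max(0, pos - 60)
                pending_dups.append("".join(seq[dup_start:start]))
        sequences[template_id] = "".join(seq)

    # place duplicated left-flank regions in other templates' tail regions
    template_ids = list(sequences)
    for i, region in enumerate(pending_dups):
        target = template_ids[(i + 1) % len(template_ids)]
        seq = list(sequences[target])
        pos = length - cfg.background_tail + 40 + i * (len(region) + 40)
        if pos + len(region) > length - margin:
            raise SimulationConfigError("too many duplicated priming regions for the tail")
        seq[pos : pos + len(region)] = region
        sequences[target] = "".join(seq)
        decoys.append((target, pos, pos + len(region)))

    return SimulatedTemplates(sequences=sequences, truth=truth, decoy_spans=decoys)


def _quality_curve(cfg: SimConfig) -> np.ndarray:
    return np.rint(
        np.linspace(cfg.quality_start, cfg.quality_end, cfg.read_length)
    ).astype(int)


def _apply_errors(
    seq: str, quals: np.ndarray, rng: np.random.Generator
) -> str:
    """Substitute each base with probability 10^(-q/10)."""
    p = 10.0 ** (-quals / 10.0)
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[rng.integers(3)]
    return "".join(out)


def _fragment_length(
    rng: np.random.Generator, cfg: SimConfig, lo: int, hi: int
) -> int:
    if lo > hi:
        raise SimulationConfigError(f"no admissible fragment length in [{lo}, {hi}]")
    for _ in range(100):
        length = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
        if lo <= length <= hi:
            return length
    raise SimulationConfigError(
        f"could not draw a fragment length in [{lo}, {hi}] after 100 tries"
    )


def simulate_paired_reads(
    templates: SimulatedTemplates, cfg: SimConfig
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw fragments and sequence 2 x read_length mates with the error model.

    Mate 1 is the fragment prefix; mate 2 the reverse complement of the
    fragment suffix.  Each planted locus (and each duplicated priming-region
    decoy) receives ``pairs_per_locus`` targeted fragments placed so the
    whole construct lies within mate 1; background fragments are drawn from
    each template's repeat-free tail.  Provenance records every fragment's
    template and coordinates.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    curve = _quality_curve(cfg)
    rl = cfg.read_length
    # cap insert sizes so mates still overlap after 3'-quality trimming
    frag_hi = 2 * rl - 60
    pairs: list[ReadPair] = []
    rows: list[dict] = []

    def sequence_fragment(template_id: str, start: int, length: int, locus_id: str) -> None:
        frag = templates.sequences[template_id][start : start + length]
        m1 = frag[:rl]
        m2 = reverse_complement(frag[-rl:])
        if cfg.sequencing_errors:
            m1 = _apply_errors(m1, curve, rng)
            m2 = _apply_errors(m2, curve, rng)
        pair_id = f"sim{len(pairs):06d}"
        quals = [int(q) for q in curve]
        pairs.append(
            ReadPair(Read(pair_id, m1, quals), Read(pair_id, m2, list(quals)), pair_id)
        )
        rows.append(
            {
                "pair_id": pair_id,
                "template_id": template_id,
                "frag_start": start,
                "frag_end": start + length,
                "locus_id": locus_id,
            }
        )

    site_len = cfg.primer_length + cfg.pad  # pad + priming site beyond the repeat
    targeted: list[tuple[str, int, int, str, bool]] = [
        (p.template_id, p.start, p.end, p.locus_id, p.has_primer_sites and p.purity == PERFECT)
        for p in templates.truth
    ]
    targeted += [
        (tid, s, e, f"decoy{i:03d}", False)
        for i, (tid, s, e) in enumerate(templates.decoy_spans)
    ]
    for template_id, span_start, span_end, locus_id, primer_bearing in targeted:
        tlen = len(templates.sequences[template_id])
        for _ in range(cfg.pairs_per_locus):
            # place the fragment so mate 1 covers the whole priming construct;
            # the upstream context (<= 60 bases) is what dup-primer decoys copy
            offset = int(rng.integers(40, 56))
            start = max(0, span_start - offset)
            if primer_bearing:
                # mate 2 must start beyond the reverse priming site, keeping
                # every designed primer out of the mate-overlap region; the
                # overlap then falls in the construct's low-complexity spacer
                lo = rl + (span_end - start) + site_len + 2
            else:
                lo = max(rl, span_end - start + 40)
            hi = min(frag_hi, tlen - start)
            length = _fragment_length(rng, cfg, lo, hi)
            sequence_fragment(template_id, start, length, locus_id)

    template_ids = list(templates.sequences)
    for _ in range(cfg.n_background_pairs):
        template_id = template_ids[int(rng.integers(len(template_ids)))]
        tlen = len(templates.sequences[template_id])
        tail_start = tlen - cfg.background_tail
        decoy_free = [
            (s, e) for (tid, s, e) in templates.decoy_spans if tid == template_id
        ]
        for _attempt in range(100):
            length = _fragment_length(rng, cfg, rl, min(frag_hi, cfg.background_tail))
            start = int(rng.integers(tail_start, tlen - length + 1))
            if all(start + length <= s or start >= e for s, e in decoy_free):
                break
        else:
            raise SimulationConfigError("could not place a background fragment")
        sequence_fragment(template_id, start, length, "")

    provenance = pd.DataFrame(
        rows, columns=["pair_id", "template_id", "frag_start", "frag_end", "locus_id"]
    )
    return pairs, provenance


def evaluate_recovery(
    truth: Sequence[PlantedLocus],
    markers: Sequence,
    provenance: pd.DataFrame,
    min_copies: int = 8,
) -> RecoveryReport:
    """Score a marker table against the planted truth.

    A marker counts as recovering a planted locus when its source read's
    fragment overlaps the locus target span on the same template and the
    canonical motifs agree.  Recall is taken over eligible planted loci
    (perfect with >= ``min_copies`` copies, planted priming sites, unique);
    precision over all reported markers.
    """
    prov = provenance.set_index("pair_id")
    by_template: dict[str, list[PlantedLocus]] = {}
    for locus in truth:
        by_template.setdefault(locus.template_id, []).append(locus)

    def planted_match(marker) -> PlantedLocus | None:
        pair_id = marker.fwd_read_id.rsplit("/", 1)[0]
        if pair_id not in prov.index:
            return None
        row = prov.loc[pair_id]
        for locus in by_template.get(row["template_id"], []):
            if (
                locus.start < row["frag_end"]
                and row["frag_start"] < locus.end
                and locus.canonical == marker.canonical_motif
            ):
                return locus
        return None

    eligible = {p.locus_id for p in truth if p.eligible(min_copies)}
    recovered: set[str] = set()
    n_true = 0
    for marker in markers:
        locus = planted_match(marker)
        if locus is not None:
            n_true += 1
            if locus.locus_id in eligible:
                recovered.add(locus.locus_id)
    return RecoveryReport(
        n_eligible=len(eligible),
        n_recovered=len(recovered),
        n_markers=len(markers),
        n_true_markers=n_true,
    )


def write_truth_table(truth: Sequence[PlantedLocus], path: str | Path) -> int:
    df = pd.DataFrame([asdict(p) for p in truth])
    df.to_csv(path, sep="\t", index=False)
    return len(df)
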