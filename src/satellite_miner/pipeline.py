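"""End-to-end orchestration: trim -> QC -> SSR find -> primer design ->
occurrence counting -> pair assembly -> filter -> write.

Every intermediate is persisted in the output directory (trimmed FASTQ, raw
and trimmed QC reports, the full candidate table, the filtered table, the
repeat-type summary, merged reads) so each stage can be inspected or
re-filtered without recomputation; the run manifest records per-stage counts
and every effective parameter.  The pipeline itself is deterministic:
identical inputs and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import palfilter, readqc, readtrim, seqio, ssrfind
from .config import PipelineConfig, config_to_dict, dump_config
from .pairassembly import confirm_primers_on_template, merge_pair
from .palfilter import FilterToggles, MarkerRecord
from .primerdesign import count_occurrences, design_primer_pair
from .seqio import Read, ReadPair

log = logging.getLogger("satellite_miner")


@dataclass
class RunManifest:
    """Per-stage counts and output locations of one pipeline run."""

    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    parameters: dict[str, object] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def write(self, tsv_path: str | Path, text_path: str | Path) -> None:
        with open(tsv_path, "w") as fh:
            fh.write("section\tkey\tvalue\n")
            for key, value in self.counts.items():
                fh.write(f"count\t{key}\t{value}\n")
            for key, value in self.outputs.items():
                fh.write(f"output\t{key}\t{value}\n")
            for key, value in self.parameters.items():
                fh.write(f"parameter\t{key}\t{value}\n")
        with open(text_path, "w") as fh:
            fh.write("satellite-miner run summary\n")
            fh.write("===========================\n")
            for key, value in self.counts.items():
                fh.write(f"{key:40s} {value}\n")
            fh.write("\noutputs:\n")
            for key, value in self.outputs.items():
                fh.write(f"  {key}: {value}\n")


def _flatten_params(cfg: PipelineConfig) -> dict[str, object]:
    flat: dict[str, object] = {}
    for key, value in config_to_dict(cfg).items():
        if isinstance(value, dict):
            for sub, subval in value.items():
                flat[f"{key}.{sub}"] = subval
        else:
            flat[key] = value
    return flat


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _detect_records(
    survivors: list[ReadPair], cfg: PipelineConfig, all_reads: list[Read]
) -> tuple[list[MarkerRecord], dict[str, ReadPair]]:
    """SSR detection + primer design + occurrence counting over trimmed pairs."""
    min_copies = cfg.ssr.copies_by_size()
    records: list[MarkerRecord] = []
    source_pairs: dict[str, ReadPair] = {}
    for pair in survivors:
        for mate, read in ((1, pair.r1), (2, pair.r2)):
            for locus in ssrfind.find_loci(read, min_copies, cfg.ssr.max_gap):
                locus_id = f"L{len(records):05d}"
                primer_pair = design_primer_pair(locus, cfg.primer)
                if primer_pair is not None:
                    primer_pair.fwd_count = count_occurrences(
                        primer_pair.fwd_seq, all_reads, cfg.count_reverse_complement
                    )
                    primer_pair.rev_count = count_occurrences(
                        primer_pair.rev_seq, all_reads, cfg.count_reverse_complement
                    )
                run = locus.primary_run
                records.append(
                    MarkerRecord(
                        locus_id=locus_id,
                        fwd_read_id=f"{pair.pair_id}/1",
                        rev_read_id=f"{pair.pair_id}/2",
                        motif=run.motif,
                        canonical_motif=run.canonical,
                        motif_size=len(run.motif),
                        copies=run.copies,
                        purity=locus.purity,
                        primer_pair=primer_pair,
                    )
                )
                source_pairs[locus_id] = pair
    return records, source_pairs


def _incremental_filter_counts(
    records: list[MarkerRecord], toggles: FilterToggles
) -> dict[str, int]:
    """Survivor counts as each enabled filter is added, in cascade order."""
    counts: dict[str, int] = {}
    partial = FilterToggles()
    stages = (
        ("require_primers", "after_primer_filter"),
        ("perfect_only", "after_purity_filter"),
        ("unique_primers_only", "after_uniqueness_filter"),
        ("require_assembly", "after_assembly_filter"),
    )
    for attr, label in stages:
        if getattr(toggles, attr):
            partial = replace(partial, **{attr: True})
            counts[label] = len(palfilter.apply_filters(records, partial))
    return counts


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the full marker-development pipeline; returns the run manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(parameters=_flatten_params(cfg))

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest.timings_s[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    log.error("stage %s: failed (%s)", name, exc)
                    raise StageError(name, exc) from exc
                log.info("stage %s: done in %.2fs", name, manifest.timings_s[name])

        return _Timer()

    with stage("read_input"):
        pairs = list(seqio.read_paired_fastq(cfg.in1, cfg.in2, cfg.quality_offset))
        manifest.counts["pairs_in"] = len(pairs)

    with stage("trim"):
        stats = readtrim.TrimStats()
        survivors = list(readtrim.trim_pairs(pairs, cfg.trim, stats))
        out1 = outdir / "trimmed_1.fastq"
        out2 = outdir / "trimmed_2.fastq"
        seqio.write_paired_fastq(survivors, out1, out2, cfg.quality_offset)
        manifest.counts["pairs_surviving_trim"] = stats.pairs_out
        manifest.outputs["trimmed_1"] = str(out1)
        manifest.outputs["trimmed_2"] = str(out2)
        log.info(
            "trim: %d pairs in, %d surviving (%.1f%% removed)",
            stats.pairs_in, stats.pairs_out, stats.percent_removed,
        )

    with stage("qc"):
        libraries = {
            "qc_raw_1": [p.r1 for p in pairs],
            "qc_raw_2": [p.r2 for p in pairs],
            "qc_trimmed_1": [p.r1 for p in survivors],
            "qc_trimmed_2": [p.r2 for p in survivors],
        }
        for name, reads in libraries.items():
            if not reads:
                continue
            report = readqc.build_report(reads)
            path = outdir / f"{name}.tsv"
            readqc.write_report(report, path)
            manifest.outputs[name] = str(path)
            log.info("%s", readqc.summary_text(report, name))

    with stage("ssr_and_primers"):
        all_reads = [r for p in survivors for r in (p.r1, p.r2)]
        records, source_pairs = _detect_records(survivors, cfg, all_reads)
        manifest.counts["loci_found"] = len(records)
        manifest.counts["loci_with_primers"] = sum(
            1 for r in records if r.primer_pair is not None
        )

    with stage("assembly"):
        merged_out: list[Read] = []
        if cfg.assembly.enabled:
            n_confirmed = 0
            merged_cache: dict[str, object] = {}
            for record in records:
                if record.primer_pair is None:
                    continue
                pair = source_pairs[record.locus_id]
                if pair.pair_id not in merged_cache:
                    merged_cache[pair.pair_id] = merge_pair(
                        pair, cfg.assembly.min_overlap, cfg.assembly.min_identity
                    )
                merged = merged_cache[pair.pair_id]
                if merged is None:
                    record.assembly_confirmed = False
                    continue
                confirmation = confirm_primers_on_template(
                    merged,
                    record.primer_pair,
                    (cfg.primer.product_min, cfg.primer.product_max),
                    cfg.assembly.max_primer_mismatches,
                )
                record.assembly_confirmed = confirmation.found
                n_confirmed += confirmation.found
            manifest.counts["pairs_merged"] = sum(
                1 for m in merged_cache.values() if m is not None
            )
            manifest.counts["loci_assembly_confirmed"] = n_confirmed
            if cfg.write_merged_reads:
                merged_path = outdir / "merged.fastq"
                with open(merged_path, "w") as fh:
                    for pair_id in sorted(merged_cache):
                        m = merged_cache[pair_id]
                        if m is None:
                            continue
                        quals = "".join(chr(min(q, 93) + 33) for q in m.quals)
                        fh.write(f"@{pair_id} merged\n{m.seq}\n+\n{quals}\n")
                manifest.outputs["merged_reads"] = str(merged_path)

    with stage("filter_and_write"):
        all_path = outdir / "pal_all.tsv"
        palfilter.write_marker_table(records, all_path)
        manifest.outputs["pal_all"] = str(all_path)

        summary_path = outdir / "motif_summary.tsv"
        palfilter.write_motif_summary(records, summary_path)
        manifest.outputs["motif_summary"] = str(summary_path)

        manifest.counts.update(_incremental_filter_counts(records, cfg.filters))
        filtered = palfilter.apply_filters(records, cfg.filters)
        filtered_path = outdir / "pal_filtered.tsv"
        palfilter.write_marker_table(filtered, filtered_path)
        manifest.outputs["pal_filtered"] = str(filtered_path)
        manifest.counts["loci_after_filters"] = len(filtered)

    config_path = outdir / "effective_config.yaml"
    dump_config(cfg, config_path)
    manifest.outputs["effective_config"] = str(config_path)
    manifest.write(outdir / "manifest.tsv", outdir / "manifest.txt")
    manifest.outputs["manifest"] = str(outdir / "manifest.tsv")
    return manifest
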