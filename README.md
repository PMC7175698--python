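# satellite-miner

Microsatellite (SSR) marker development from Illumina paired-end shotgun
reads, in one self-contained toolkit: pair-aware quality trimming, library
QC reports, detection of 2–6 bp tandem repeats, PCR primer design in repeat
flanks, primer-occurrence counting, overlap assembly of mate pairs with
on-template primer confirmation, and a filter cascade that selects optimal,
PCR-ready loci. A bundled simulator generates 2 × 250 bp MiSeq-like
libraries with planted repeats and truth tables, so the whole pipeline is
testable without any sequencing data.

**Who it is for.** Ecologists and conservation geneticists developing
de-novo microsatellite panels for a new species from a single shotgun
paired-end library, and anyone who wants a small, deterministic, fully
tested reference implementation of the Seq-SSR workflow.

## The method

From a library of mate pairs (r₁, r₂):

1. **Trim** (per pair): truncate each read at the first 4-base window with
   mean Phred < 20 (so survivors have ≥ 99% expected base-call accuracy per
   window, via P_err = 10^(−Q/10)), hard-clip ends below Q3, and drop the
   *pair* if either mate ends below 50 bp — parity of the two files is
   always maintained.
2. **Detect**: find maximal perfect tandem runs of primitive motifs
   (2 ≤ |m| ≤ 6) with ≥ 8 complete copies; group nearby runs into loci
   classified perfect / interrupted / compound; summarize repeat types by
   the canonical motif (lexicographic minimum over rotations and reverse
   complement).
3. **Design**: in each locus's flanks, pick the primer pair minimizing
   |Tm−60| + |len−20| (summed over mates) + |ΔTm|, subject to length
   18–27, Tm 57–63 °C (SantaLucia 1998 nearest-neighbor model), GC 30–70%,
   ΔTm ≤ 3 °C, product 60–500 bp.
4. **Count**: exact, overlapping, strand-inclusive occurrences of each
   primer across all reads — a single-copy genomic site should count once.
5. **Assemble**: merge each candidate's mate pair by quality-weighted 3'
   overlap and confirm both priming sites on the single merged template at
   an admissible product size.
6. **Filter** (each optional): require primers; require a perfect motif
   (then rank by motif size, largest first); require single-copy primers;
   require assembly confirmation. Each added filter yields a subset —
   candidate counts are nested, raw ≥ filtered ≥ assembly-confirmed.

See `docs/methods.md` for the full model, parameter, and limitation notes.

## Worked example

Simulate a small library (30 clean planted loci plus negative classes that
exercise each filter), run the pipeline, then apply the full cascade:

```sh
$ satellite-miner simulate --out-dir sim --seed 11 --n-perfect 30 \
      --n-bad-flank 4 --n-dup-primer 4 --n-below-min 4 --n-background-pairs 60
templates: 10   planted loci: 42        read pairs: 106

$ satellite-miner run --in1 sim/reads_1.fastq --in2 sim/reads_2.fastq --out-dir out
pairs_in        106
pairs_surviving_trim    106
loci_found      38
loci_with_primers       34
pairs_merged    32
loci_assembly_confirmed 32
loci_after_filters      38

$ satellite-miner filter --in out/pal_all.tsv --out filtered.tsv \
      --require-primers --perfect-only --unique-primers --require-assembly
records in: 38  surviving: 28
```

Reading the numbers: of 42 planted loci, the 4 below-threshold repeats are
(correctly) never detected, leaving 38 candidates; the 4 poly-A-flanked loci
admit no primers (38 → 34 with primers); 2 loci fail assembly confirmation
(34 → 32); and the cascade also removes the 4 duplicated-primer loci
(counts > 1), yielding 28 optimal loci. The filtered table is ranked by
motif size, largest first:

```
locus_id  motif   motif_size  copies  purity   fwd_count  rev_count  assembly_confirmed
L00022    ATCTAT  6           14      perfect  1          1          True
L00000    TTCGGA  6           10      perfect  1          1          True
...
```

`out/` also keeps every intermediate: trimmed FASTQ, QC reports for raw and
trimmed reads, the unfiltered candidate table (`pal_all.tsv`), the
repeat-type summary (`motif_summary.tsv`), merged reads, the effective
configuration, and a run manifest with per-stage counts.

The same operations are available as a library:

```python
from satellite_miner import SimConfig, simulate_templates, find_perfect_runs

templates = simulate_templates(SimConfig(n_perfect=5, seed=1))
runs = find_perfect_runs(next(iter(templates.sequences.values())), min_copies=8)
```

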