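# Methods

`satellite-miner` is a desk-scale implementation of the standard
microsatellite (SSR) marker-development workflow for Illumina paired-end
shotgun data: quality-trim reads pair-aware, report library quality, detect
2–6 bp tandem repeats in individual reads, design a PCR primer pair in each
repeat's flanks, count each primer sequence's occurrences in the total read
set, merge overlapping mate pairs to confirm both priming sites on one
physical template, and finally apply a cascade of optional filters that
selects PCR-ready loci. This note records the models, parameters, numerical
choices, and limitations.

## Read trimming

Four operators are applied per read, in configurable order (default:
sliding window, leading, trailing, then the length gate):

- **SLIDINGWINDOW (w = 4, Q = 20).** Windows of width *w* are evaluated at
  every offset from the 5' end; the read is truncated at the start of the
  first window whose mean Phred score falls below Q. A surviving read
  therefore has mean quality ≥ 20 across every four bases — i.e. ≥ 99%
  expected base-call accuracy per window, since a Phred score Q implies an
  error probability of 10^(−Q/10). Reads shorter than the window are kept
  iff their overall mean passes.
- **LEADING / TRAILING (Q = 3).** Hard-clip terminal bases below Q3 (the
  near-random-call level).
- **MINLEN (50).** Applied to the final length of each mate. Pair-awareness
  is strict: if either mate ends below the minimum, both are discarded, so
  the output files always keep positional parity. Orphan reads are never
  emitted.
- **Adapter clipping** (off by default) removes a 3' suffix matching an
  adapter prefix with ≤ 1 mismatch at ≥ 6 bases overlap.

Every survivor is a contiguous substring of its input, trimming is
idempotent, and raising any threshold can only shrink the surviving set —
all three are enforced by property tests.

## SSR detection

For each motif size k = 2…6 the read is scanned for maximal k-periodic
stretches (`seq[i] == seq[i+k]`, both bases called; N never matches, so
uncalled bases split runs). Each stretch anchored at its leftmost position
yields one run; the copy number counts complete motif units only (partial
trailing copies are flank, keeping copy numbers integral), and the motif
must be primitive — a non-primitive unit (e.g. ATAT) is reported at its true
shorter period. The default threshold is **8 complete copies for every
motif size**, configurable per size. With ≥ 2 copies per run, a region
cannot carry two distinct primitive periods (Fine–Wilf), so runs are
reported exactly once; an exhaustive brute-force oracle over every (start,
motif-size) pair confirms exact agreement on thousands of random sequences.

Runs on one read separated by ≤ 10 bases (`max_gap`, configurable; chosen to
keep interrupted motifs detectable without merging unrelated repeats) are
grouped into one locus: a single run is *perfect*, multiple runs sharing a
canonical motif are *interrupted*, and runs with different canonical motifs
are *compound*. The canonical motif — the lexicographic minimum over all
rotations of the motif and of its reverse complement — makes the repeat-type
summary strand- and phase-invariant.

Reads are scanned on the sequenced strand only (primers are designed on the
read as observed); both mates of every surviving pair are scanned.

## Primer design

Candidate forward primers are all windows of the left flank, reverse primers
the reverse complements of right-flank windows (reported 5'→3' on the
opposite strand). Constraints (defaults chosen as typical microsatellite-PCR
kit settings, all configurable): length 18/20/27 (min/opt/max), melting
temperature 57/60/63 °C, GC 30–70%, pair Tm difference ≤ 3 °C, product size
60–500 bp, and no self-reverse-complementary 3' suffix of ≥ 6 bases (a cheap
hairpin/dimer proxy). Melting temperatures use the nearest-neighbor model
with the SantaLucia (1998) unified ΔH/ΔS parameters, entropic salt
correction 0.368·(N−1)·ln[Na⁺] at 50 mM monovalent salt and 250 nM primer
(the Wallace 2+4 rule is available as a cheap alternative). The admissible
pair minimizing

penalty = |Tm_f − Tm_opt| + |Tm_r − Tm_opt| + |len_f − len_opt| + |len_r − len_opt| + |Tm_f − Tm_r|

is returned; ties break deterministically by leftmost forward start, then
shortest product. A locus with no admissible pair is recorded with an empty
primer slot — that is what the first filter removes. The selection equals an
exhaustive enumeration oracle on small flanks, and the nearest-neighbor Tm
is cross-checked against an independent published-parameter implementation
to within 0.5 °C.

**Occurrence counting** is exact, overlapping, and strand-inclusive by
default: shotgun reads sample both strands, so occurrences of the primer and
of its reverse complement across all reads are summed (a palindromic primer
counts once per site; a switch restores forward-only counting). A designed
primer always counts at least once — its own source read contains it.

## Pair assembly and primer confirmation

Mate 2 is reverse-complemented (qualities reversed) and every overlap length
ℓ ∈ [15, min(len₁, len₂)] is scored by Σ ±min(q₁,q₂) (+ at agreements, − at
disagreements); the best score wins, ties going to the longer overlap, and
the merge is accepted iff its identity (agreements/ℓ) ≥ 0.9. Consensus
bases: agreements keep the base with quality max(q₁,q₂); disagreements take
the higher-quality base with quality |q₁−q₂| (mate 1 wins exact ties). The
merged length always equals len₁ + len₂ − ℓ.

A primer pair is *confirmed* when the forward primer occurs on the merged
template, the reverse primer's binding site occurs downstream of it, and the
implied product size lies within the configured bounds. Matching is exact by
default (the conservative choice for maximizing PCR success); a switch
allows one mismatch. Unmerged pairs are not discarded — their loci simply
fail the assembly filter when it is enabled.

## The filter cascade

Four independent toggles remove, in order: (1) loci without a designed
primer pair; (2) loci that are not a single perfect run — compound and
interrupted repeats violate the stepwise mutation model assumed by most
microsatellite analyses — with survivors then ranked by motif size, largest
first (ties by copies descending, then locus id, so output order is total
and deterministic); (3) loci where either primer occurs more than once in
the total reads (both priming sites must be single-copy); (4) loci whose
primers were not confirmed on one merged template. Each added toggle yields
a subset of the previous survivors, so enabled cascades reproduce the nested
raw ≥ filtered ≥ assembly-confirmed structure of a marker-development run.
The unfiltered table is always retained on disk alongside the filtered one.

## Synthetic data generator

The simulator emulates a 2 × 250 bp MiSeq shotgun library from a genome with
planted microsatellites, at desk scale. Templates receive constructs of the
form

    [fwd priming site 20 bp][pad 8][repeat][pad 8][revcomp(rev site) 20 bp][poly-A spacer 190 bp]

with priming sites rejection-sampled to Tm 58.5–61.5 °C and GC 40–60%
(comfortably inside the design window), pads whose junction bases cannot
extend the repeat's periodicity (so detected spans equal planted spans
exactly), and loci spaced ≥ 2 read lengths apart. Planted classes cover
every filter's positive and negative case: perfect repeats of 8–14 copies;
interrupted and compound repeats (two runs split by a 3-base gap);
below-threshold repeats (4–6 copies) that must stay undetected; poly-A
flanked repeats where no primer is designable; and loci whose forward
priming region is duplicated into another template *and sequenced*, so its
primer genuinely occurs twice in the reads.

Reads: each planted locus receives one targeted fragment (low-coverage
shotgun regime — each priming site is typically observed once, the situation
the uniqueness filter presumes) placed so that mate 1 covers the whole
priming construct; background fragments are drawn from a repeat-free tail
region. Fragment lengths are Normal(410, 25) truncated to [250, 440] — an
insert distribution chosen, as in overlap-merging library designs, so mates
still overlap after 3'-quality trimming; for primer-bearing loci the lower
truncation additionally keeps mate 2 clear of the priming sites, and the
poly-A spacer keeps the mate-overlap region free of alternative primer
windows, so a single-copy locus really does yield single-copy primer counts.
Qualities follow a deterministic linear decay from Q38 (cycle 1) to Q18
(last cycle), giving the trimmer real work; substitutions are injected per
base with probability 10^(−q/10) (verified binomially: Q20 ⇒ 1% observed
rate). Indels, PCR duplicates, optical artifacts, quality jitter between
reads, and platform-specific error spectra are not modeled. All randomness
derives from one seed; outputs are byte-reproducible.

Because the generator plants clean, well-spaced, fully-covered loci,
passing recovery tests demonstrate the pipeline's correctness on data
matching its assumptions — not its yield on real libraries, where coverage
variance, repeat-dense regions, and indel errors reduce both detection and
confirmation rates.

## Evaluation

`evaluate_recovery` maps each reported marker back through read provenance
to its template fragment; a marker recovers a planted locus when the
fragment overlaps the planted span and canonical motifs agree. Recall is
computed over eligible planted loci (perfect, ≥ threshold copies, unique
planted priming sites); precision over all reported markers. Under the
error-free 50-locus condition the full cascade attains ≥ 95% recall at 100%
precision; the rare misses are pairs whose overlap falls in the
low-complexity spacer, where quality-weighted overlap scoring can settle on
an alignment whose identity fails the 0.9 threshold — an inherent ambiguity
of merging low-complexity overlaps.

## Numerical and degenerate-input choices

- Phred+33 encoding by default; +64 selectable. Scores are validated to
  [0, 93].
- Empty reads are legal throughout trimming; empty libraries are rejected
  by QC with a dedicated error.
- The run detector requires ≥ 2 copies even when configured lower; locus
  grouping tolerates overlapping runs (gap may be negative).
- Filtering with `require_assembly` raises a configuration error when
  assembly was never evaluated, rather than silently removing everything.
- All tables are plain TSV with `NA` sentinels and round-trip through the
  bundled readers; the pipeline contains no randomness, so reruns are
  byte-identical.

## Problem sizes

Default verification sizes — 10^4 reads for trimming invariants, 10^3
instances per brute-force oracle, 10^3 merged fragments, 220-record filter
fixtures, and a 50-locus end-to-end library (150 read pairs) — were chosen
so the whole suite completes in well under a minute on one CPU while still
exercising every code path at scales where the oracles remain exhaustive.
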