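# Methods

## Background and scope

OTTR (ordered two-template relay) builds a sequencing-ready cDNA in a single
reverse-transcription reaction. An input RNA is first 3'-labeled with a
dideoxypurine (ddA, optionally chased with ddG; collectively "ddR"). A primer
duplex carrying a single pyrimidine 3' overhang (the "+1 Y" base: T pairs a
ddA label, C pairs ddG) base-pairs that label and primes cDNA synthesis
across the input; after copying the input, the enzyme jumps to an adapter
template, appending the second sequencing adapter. Each raw read is
therefore

```
[UMI prefix][insert][+1 base][Read2 adapter sequence]...
```

This package models the *read-level* consequences of that chemistry and
implements the evaluation machinery around it: sequential adapter trimming
with header metadata, a cascade mapper, end-precision and bias metrics,
contamination extrapolation, adapter-dimer junction classification, and the
comparison statistics. The physical chemistry itself (enzyme kinetics,
buffer effects) is out of scope; only its observable consequences on reads
are modeled.

## The capture model

Each simulated molecule is assigned one of five 3'-end capture mechanisms:

| code | event | 3' offset |
|------|-------|-----------|
| I_precise | labeled molecule primed on its ddR | 0 |
| II_overcapture | unlabeled 3'-purine captured by direct +1 Y pairing | 1 |
| III_plus2_apparent_precise | unlabeled 3'-pyrimidine captured via a nontemplated purine (+2 YR overhang) pairing the terminal base | 0 |
| IV_plus2_internal | the same +2 YR capture initiating at the penultimate base | 1 |
| V_plus1_penultimate | +1 Y pairing of an internal (penultimate) purine | 2 |

The offset is the number of 3' nucleotides missing from the insert after
trimming (mechanism II loses its terminal base to the trimming of the +1
position, so it *appears* one nucleotide short; mechanism III is
observationally indistinguishable from precise capture). A 1-nt 5'
truncation is drawn independently (the second template jump occasionally
loses the input's 5'-terminal base). Adapter dimers (no insert) and
contaminant molecules complete the model.

Sampling is renormalised over emitted reads: molecules that are neither
labeled nor rescued by an alternative mechanism drop out, because read
count, not molecule count, is the observable. Consequently, per-miRNA
expected counts are proportional to `lognormal(0, sigma^2) x P(capture)`,
which is what couples labeling efficiency to both representation bias
(CV, terminal-nucleotide skew) and 3' precision.

### Default parameters

| parameter | default | rationale |
|-----------|---------|-----------|
| `p_label` | 0.85 | incomplete-but-good labeling; may be a per-base table |
| `p_overcapture_R` | 0.5 | unlabeled 3'-purines are captured efficiently |
| `p_nta` | 0.3 | +2 YR rescue of unlabeled 3'-pyrimidines is weaker |
| `p_internal_minus1` | 0.25 | fraction of +2 events initiating internally |
| `p_penultimate_plus1` | 0.05 | internal +1 capture is inefficient |
| `p_5p_truncation` | 0.05 | single-nucleotide 5' losses are detectable but rare |
| `capture_dispersion` (sigma) | 0.55 | lognormal per-miRNA efficiency; implies a library CV near 0.6, the scale observed for well-optimised equimolar-pool libraries |
| `dimer_rate` | 0.05 | minor adapter-dimer carry-through |
| `sequencing_error_rate` | 0 | errors off by default so classification is exact in tests; configurable |
| read length | 75 | single-end short-read run |
| quality | constant Q37 | no published error model; quality trimming is still exercised via synthetic low-quality tails in tests |

The relative rates of mechanisms III/IV/V are not biologically established;
they are exposed as parameters, not asserted as truth. The +1 base records
the labeling chemistry: drawn from the primer-duplex mix (default T:C = 4:1)
for labeled/NTA captures, and forced to the Watson-Crick partner of the
captured purine for mechanisms II and V.

## Synthetic references

`make_synthetic_references` builds a 962-entry pool spanning 16-28 nt with
943 entries in the 19-24 nt mapping range (the composition of the
commercial equimolar benchmarking pool the metrics are defined around),
with an exactly balanced 3'-terminal nucleotide composition by default.
Contaminant surrogates are a 2.5 kb expression-plasmid and a 6 kb genome
sequence with annotated tRNA/rRNA intervals, plus the adapter oligos.
Pool and contaminants share no canonical 15-mer (enforced by rejection
sampling), so category assignment by alignment is unambiguous and the
cascade's recall can be validated against simulator truth.

What the generator does *not* emulate: real miRNA pools contain homologous
families, so the "reliable subset" (entries whose 3+3 end-trimmed core still
maps uniquely) retains essentially the whole synthetic pool, whereas a real
pool loses about a third of entries to cross-homology. Passing tests
therefore validate the *procedure*, not the real pool's membership. Likewise
the absence of sequencing errors and indels by default means round-trip and
recall figures of 100% bound the real-data behaviour from above.

## Trimming

Four sequential passes, matching the library architecture: (1) remove the
best occurrence of the 33-nt Read2 adapter and everything 3' of it,
tolerating partial occurrences at the read 3' end (error rate 0.1, minimum
overlap 3 — the conventional defaults of read trimmers); (2) cut the first
X bases as the UMI; (3) cut the final base as the +1 ("PD") position; (4)
3'-quality-trim at Q10 and drop reads shorter than 15 nt. Passes 2 and 3
record their cuts verbatim in the header as `{id}_UMI={umi}_PD={base}`.
The PD cut is applied unconditionally (as a fixed `-1` cut would be);
adapter-absent reads are kept and flagged rather than discarded, since the
original behaviour is unstated — a filter flag is exposed via
`TrimmedRead.adapter_found`. Reads with nothing left after the fixed cuts
are discarded and counted separately from minimum-length discards;
conservation (`reads_in == reads_out + discards`) is asserted in tests.

Quality trimming uses the BWA-style running-sum rule: scanning from the 3'
end, accumulate `cutoff - Q_i` and cut at the running-sum maximum (no cut
if the sum never exceeds zero).

## Mapping

Alignment is ungapped and end-to-end: a read is placed wherever a
same-length reference window matches with the minimum number of
mismatches, up to 2; all tied placements are reported and flagged
multi-mapping. Indels are out of model because inserts are short and
simulated without them. Two equivalent search paths are implemented — an
exhaustive per-length window-matrix scan and a pigeonhole seed-and-verify
path (a read within tolerance k must match one of k+1 disjoint segments
exactly) — and their equivalence is asserted in tests; the exhaustive scan
is also the independent oracle for the aligner acceptance check.

The cascade assigns each read to the first stage with any placement:
adapter oligos, then expression plasmid, then genome, then the miRNA pool.
Adapter and miRNA stages search the sense strand only (the library is
stranded by construction); plasmid and genome search both strands. Genome
hits are subcategorised by >= 1 nt overlap with annotation intervals,
ties broken tRNA > rRNA > other. Mapped records are emitted as BED6
(0-based half-open, score = mismatch count).

## Metrics

* **Counts/CPM** — per-miRNA single-mapping alignment counts;
  CPM = count x 1e6 / total mapped miRNA reads; zero-count miRNAs kept.
* **Median filter** — miRNAs with median raw count below 50 across the
  libraries under comparison are excluded, to address depth differences.
* **CV** — sample standard deviation (n-1) over mean of per-miRNA counts.
  The convention is ours; at ~900 miRNAs the n vs n-1 difference is
  negligible.
* **End precision** — mean over miRNAs of the per-miRNA fraction of
  alignments covering the terminal reference nucleotide
  (`(1/m) sum_j b_j/T_j`). An alignment covers the first nucleotide iff
  start == 0 and the final nucleotide iff end == L_j. A literal
  double-normalisation form `(1/T)(1/m) sum_j b_j` exists behind
  `per_mirna=False` for comparison; the per-miRNA mean is the default
  because the defining prose averages per-miRNA fractions.
* **End-coverage profiles** — histograms of alignment endpoints in
  end-anchored coordinates (offset 0 = the miRNA 3' end).
* **Composition** — category fractions over reads strictly longer than
  17 nt (18 nt and longer), summing to 1, with per-category length
  histograms.
* **Terminal-nucleotide stratification** — log2 CPM grouped by 3' purine
  vs pyrimidine (or per base); zero-count entries use CPM of count + 0.5
  and are flagged.
* **Mechanism classification** — observed (offset, terminal base, +1 base)
  maps to the *set* of compatible mechanisms, never a point guess, because
  offsets do not identify mechanisms uniquely.
* **Junction classification** — an adapter-dimer junction
  `<+1 base>|<observed prefix>` is compared against the expected cDNA
  prefix `G + N*(X-1) + AGATCGG`; leading dashes count the
  internal-initiation offset; Read1 detectability requires the complete
  constant prefix. For UMI-less templates, primer-duplex dependence equals
  Watson-Crick pairing of the +1 base at the initiation-adjacent template
  position and NTA dependence is its complement; internal initiation within
  a degenerate UMI segment is assigned both dependencies by rule (no
  mechanical rule is derivable for those rows). The classifier reproduces
  all 43 curated clone observations.

## Statistics

Library pairs are compared by a paired two-sided Student's t-test on
per-miRNA precision fractions, restricted to miRNAs with >= 30 alignments
in both libraries; the mean difference is reported in percent with a 95%
t-based CI; p-values are Bonferroni-adjusted with the number of paired
miRNAs as the default factor (a per-comparison factor is available — the
convention is ambiguous, so both are supported). The unpaired one-sided
test uses Welch's unequal-variance form; the degenerate zero-variance
equal-mean case returns p = 0.5 by definition. Rank agreement between
libraries uses Spearman's rho with average ranks on ties.

The contamination model (fixed contaminant load competing with input)
forces the miRNA:contaminant read ratio through the origin as input goes to
zero, so the titration fit is a through-origin least-squares slope
`k = sum(xy)/sum(x^2)`, and the minimum input for a 9:1 ratio (90% of reads
from input) is `9/k`. Mass-to-molecule conversion uses
`mass / (mean_length x 321.5 Da / N_A)`.

## Numerical and design choices

* Ties in adapter search resolve to the leftmost best-scoring occurrence.
* The reliable-subset check uses the mapping aligner at its default
  tolerance, so "misaligns" means "has another equal-or-better placement".
* Entries too short for the 3+3 end trim are excluded from the reliable set
  with a warning, not an error (16-nt pool entries survive the trim).
* Derived per-library seeds come from `SeedSequence([master, index])`,
  keeping all seeds below 2^31.
* Degenerate inputs error loudly: empty references, zero-mean CV, constant
  vectors for rank correlation, all-zero titration ratios, fewer than three
  qualifying t-test pairs.

## Problem sizes

Simulated experiments in the test suite and the reproduction script use
40,000-100,000 reads per library, a 962-entry pool, and kilobase-scale
contaminant surrogates; estimator checks run at five seeds, statistical
calibration at 10,000 null replicates. These sizes put Monte-Carlo error
well inside the asserted tolerances while keeping a full run to minutes on
one CPU.

## Known limitations

* Headline values reported for real sequencing data (library CVs around
  0.57-0.86, the 52 pg / 2.8 pg minimum-input extrapolations) depend on the
  deposited raw libraries and the commercial pool sequences, neither of
  which ships here; the package reproduces the *procedures* and their
  directional behaviour on synthetic data.
* No indel handling in the aligner, no paired-end support, no
  demultiplexing.
* The simulator's contaminant draw uses fixed category/feature weights
  rather than a learned abundance model.
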