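# ottr-endqc

Simulation and QC analytics for **OTTR** (ordered two-template relay)
small-RNA sequencing libraries: end-capture precision, equimolar-pool bias,
enzyme-borne contamination, and adapter-dimer diagnostics.

## Who this is for

OTTR converts an input RNA into a sequencing-ready cDNA in one reaction: the
RNA receives a single 3' dideoxypurine label (ddR), a primer duplex with a
pyrimidine +1 overhang pairs that label to prime reverse transcription, and
the enzyme then jumps to an adapter template, appending both adapters. The
fidelity of this chemistry is judged with an equimolar pool of synthetic
miRNAs: deviations from equimolar representation (library-wide CV), reads
that miss the molecule's true 3' or 5' terminal nucleotide (end
imprecision), contaminating reads from the enzyme preparation, and
adapter-dimer side products are all quantifiable from the sequenced reads.
This package gives method developers and pipeline authors an executable,
testable version of that entire evaluation: a mechanistic read simulator
with per-read ground truth, the trimming/mapping/metrics stages, and the
comparison statistics.

## The core quantities

For miRNA *j* with `T_j` aligned reads of which `b_j` cover the terminal
reference nucleotide, end precision is the per-miRNA fraction averaged over
the *m* evaluated miRNAs:

```
precision = (1/m) * sum_j b_j / T_j
```

(3' precision uses the final nucleotide, 5' precision the first). Library
bias is the coefficient of variation of per-miRNA counts, `CV = sd/mean`.
Contamination is summarised by the miRNA:contaminant read ratio across an
input titration; a through-origin fit `k = sum(xy)/sum(x^2)` extrapolates
the minimum input at which the ratio reaches 9:1 (90% informative reads).
Libraries are compared by paired two-sided t-tests on per-miRNA precision
fractions (>= 30 alignments in both libraries, Bonferroni-adjusted).

The simulator distinguishes five 3'-capture mechanisms (precise capture on
the label; over-capture of unlabeled 3'-purines; +2-overhang capture of
unlabeled 3'-pyrimidines, terminal or internal; internal +1 capture), each
with its characteristic apparent truncation — see `docs/methods.md`.

## Worked example

```python
from ottr_endqc import (
    CaptureModel, Cascade, CascadeConfig, TrimScheme,
    coefficient_of_variation, end_precision, length_filter,
    make_synthetic_references, mirna_counts_cpm, reliable_subset,
    run_trim_pipeline, simulate_library,
)

pool, contaminants = make_synthetic_references(seed=7)
mapping_pool = length_filter(pool, 19, 24)      # 943 of 962 entries
reliable = reliable_subset(mapping_pool)

model = CaptureModel(p_label=0.0)               # 3'-labeling step omitted
lib = simulate_library(pool, contaminants, model,
                       input_amount_pg=100, n_reads=40_000, seed=3)
trimmed, stats = run_trim_pipeline(
    ((r.read_id, r.raw_sequence, r.raw_qualities) for r in lib.reads),
    TrimScheme(),
)
records = Cascade(mapping_pool, contaminants, CascadeConfig()).classify(
    (t.read_id, t.insert_sequence) for t in trimmed
)
counts = mirna_counts_cpm(records, mapping_pool)
print(f"CV {coefficient_of_variation(counts['count']):.3f}")
print(f"3' precision "
      f"{end_precision(records, mapping_pool, reliable, end='3p').mean_precision:.3f}")
```

prints

```
CV 0.677
3' precision 0.354
```

— without the labeling step, only about a third of alignments reach the
true 3' end (unlabeled pyrimidine-terminal molecules are rescued by
+2-overhang capture, purine-terminal ones appear one nucleotide short), and
the count CV worsens because 3'-purine miRNAs are over-represented. With
`p_label=1.0` the same pipeline reports `CV 0.612` and `3' precision 1.000`.

## Analysis scripts

The `analysis/` directory holds numbered drivers that walk the full study
on synthetic data and write tables under `results/`:

1. `01_build_references.py` — pool + contaminant references, reliable subset
2. `02_simulate_libraries.py` — labeled vs unlabeled libraries with truth
3. `03_trim_and_map.py` — 4-pass trimming, truth round-trip, cascade, BED
4. `04_labeling_bias_and_precision.py` — CV, 3'/5' precision, terminal-nt
   bias, paired comparison
5. `05_contamination_titration.py` — composition vs input, 9:1 extrapolation
6. `06_adapter_dimer_junctions.py` — junction classification, input-scale
   arithmetic

There is also a `ottr-endqc` CLI (`simulate`, `trim`, `map`, `metrics`,
`compare`, `extrapolate`, `run`) over the same library, driven by a YAML
config for full pipeline runs.

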