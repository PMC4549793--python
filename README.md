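# msikit

Microsatellite instability (MSI) is a hypermutation phenotype caused by
defective DNA mismatch repair, characterized by frequent somatic mutations
that change the length of simple repeats (mononucleotide runs such as
`AAAAA…` and 2–4 bp microsatellites such as `GATAGATA…`). Clinical MSI
assays genotype a handful of repeat markers; tumor exome sequencing assays
thousands of repeat loci at once — but the marker loci themselves are
non-exonic, so MSI status has to be inferred from the somatic mutation
catalog itself.

`msikit` determines MSI status directly from a somatic mutation list (MAF
format) plus two pieces of annotation: the genomic locations of simple
repeats and the total length of the sequence targeted for capture. It is
aimed at cancer-genomics analysts who have tumor/normal variant calls but
no laboratory MSI test result.

## Method

For each tumor, mutations are split into single-nucleotide substitutions
(SNS) and microindels, counted in total and within simple repeats
(mononucleotide runs of length ≥ 5 scanned from the reference, plus di-,
tri- and tetranucleotide repeats from a UCSC-`simpleRepeats`-style table),
and normalized by the capture length in Mb:

> *T.sns*, *S.sns*, *T.ind*, *S.ind*, *T*, *S*, *S.sns/T.sns*,
> *S.ind/T.ind*, *S/T*, plus cancer type.

The default classifier is a one-variable decision stump — the direct
molecular readout of repeat instability:

* **whole exome:** call MSI-H iff *S.ind* > 0.395 microindels in simple
  repeats per Mb;
* **whole genome:** call MSI-H iff *S.ind* > 0.909/Mb (simple repeats are
  denser genome-wide, ≈7.4/Kb vs ≈5.6/Kb in exome target regions).

Independently, samples with *T.sns* > 60/Mb and *S.ind* < 0.18/Mb are
flagged as possible **POLE-exonuclease-deficient ultramutators** — tumors
with extreme substitution burden but few repeat indels, which are not MSI.

The decision tree can also be retrained (gain-ratio C4.5-style induction
with midpoint thresholds and training-error pruning) and evaluated by
stratified k-fold cross-validation, ROC/AUC on *S.ind*, and a
capture-subset robustness experiment that reclassifies tumors from random
subsets of the target regions. A seeded synthetic-cohort generator
(`msikit simulate`) produces MAF/BED/FASTA/TSV fixtures with known truth,
so the entire pipeline is testable without any data downloads.

## Worked example

Everything below is synthetic and seeded, so it reproduces exactly.

```sh
$ msikit simulate --out-dir cohort --seed 11
wrote cohort of 100 samples (40429 mutations) to cohort
$ msikit compute-features --maf cohort/cohort.maf --regions cohort/capture.bed \
    --repeats cohort/repeats.bed --metadata cohort/samples.tsv --out features.tsv
wrote features for 100 samples to features.tsv
$ msikit classify --features features.tsv --out calls.tsv
100 samples: 20 MSI-H, 4 flagged as possible POLE-deficient
$ head -3 calls.tsv
sample_id	predicted_status	pole_flag	S.ind
SIM-MSIH-001	MSI-H	False	2.1333333333333333
SIM-MSIH-002	MSI-H	False	3.333333333333333
```

The simulated cohort contains 20 mismatch-repair-deficient (MSI-H), 75
MSI-stable and 5 POLE-like tumors over a 30 Mb capture; all 20 MSI-H
tumors are called correctly (their *S.ind*, e.g. 2.13/Mb, sits far above
the 0.395 cutoff) and 4 of the 5 POLE-like ultramutators trip the flag
(the fifth drew a substitution burden below 60/Mb — burdens are
negative-binomially dispersed). Retraining and cross-validating on the
same features:

```sh
$ msikit train --features features.tsv --labels cohort/samples.tsv --seed 5 --out model.json
trained tree of depth 1; saved to model.json   # stump on S.ind, threshold 0.5
$ msikit crossval --features features.tsv --labels cohort/samples.tsv --k 5 --seed 5
pooled concordance: 100.0% (n=100)
```

The library API mirrors the CLI (`read_maf`, `compute_features`,
`classify`, `train`, `cross_validate`, `subset_experiment`, …); see the
module docstrings and `docs/methods.md`.

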