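# barcodegap

Threshold-based DNA-barcoding analysis for single-locus (typically COI)
datasets: does a barcode gap exist, what distance threshold best separates
within- from between-species variation, how reliably does leave-one-out
identification work under that threshold, and do the resulting molecular
clusters (MOTUs) agree with the morphospecies labels?

The package is aimed at taxonomists and molecular ecologists working with a
small to moderate set of aligned barcode sequences from one genus or family
— the typical "is COI a usable barcode for this group?" study — and at
anyone who wants those analyses reproducible and testable rather than
buried in an interactive session.

## What it computes

Given an aligned matrix of sequences and a specimen table with
morphospecies labels:

1. **K2P distances.** Pairwise Kimura 2-parameter distances
   `d = -½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)`, where `P` and `Q` are the
   observed transition (A↔G, C↔T) and transversion proportions over the
   columns where both sequences carry an unambiguous base (pairwise
   deletion).
2. **Barcode gap.** Distances are partitioned into intraspecific and
   interspecific sets; the package reports medians, ranges, a Wilcoxon
   rank-sum test (exact for small tie-free samples), the global
   `min(inter) > max(intra)` criterion, and a per-specimen table comparing
   each specimen's furthest conspecific with its nearest non-conspecific.
3. **Threshold optimisation.** A Gaussian-kernel density of all pairwise
   distances (rule-of-thumb bandwidth `0.9·min(sd, IQR/1.34)·n^(−1/5)`,
   512-point grid) is scanned for local minima; the first dip between the
   intra- and interspecific modes is the proposed identification threshold.
4. **Leave-one-out identification.** Each specimen is queried against all
   others under three criteria: *best close match* (nearest candidate
   within the threshold → correct / incorrect / ambiguous / no-ID), *near
   neighbour* (is the single closest candidate conspecific → true/false),
   and *threshold identification* (all candidates within a fixed 1%
   distance, the rule used by the BOLD "Identify Specimen" service).
5. **MOTU delimitation.** Single-linkage clustering at the threshold:
   specimens joined by any chain of distances ≤ t form one MOTU. The
   congruence report lists each MOTU's species composition and flags every
   specimen whose label disagrees with its MOTU's majority species —
   candidate morphological misidentifications.

A synthetic-data generator (`barcodegap.simulate`) produces COI-like
alignments with known species structure and optional injected label errors,
so the whole pipeline is testable end-to-end with exact ground truth.

## Worked example

Simulate a 56-specimen, 5-species study (654 bp, AT-rich composition,
within-species depth 0.002 and between-species depth 0.075
substitutions/site) with 5 deliberately mislabelled specimens, and run the
full pipeline:

```sh
barcodegap run --simulate-seed 42 --n-mislabels 5 --outdir demo
```

```
barcodegap 0.1.0 run summary
========================================

Barcode gap
  intraspecific median distance: 0.004601
  interspecific median distance: 0.150692
  Wilcoxon rank-sum p (two-sided): 8.61e-126
  gap by extremes (min inter > max intra): False
  note: pairwise distances are non-independent; the p-value is descriptive.

Optimised threshold (density dip): 0.0675

Identification (leave-one-out)
  criterion         outcome         n        %
  near_neighbour    true           50    89.29
  near_neighbour    false           6    10.71
  best_close_match  correct        42    75.00
  best_close_match  incorrect       6    10.71
  best_close_match  ambiguous       8    14.29
  best_close_match  no_id           0     0.00
  thresh_id         correct        32    57.14
  thresh_id         incorrect       3     5.36
  thresh_id         ambiguous      21    37.50
  thresh_id         no_id           0     0.00

MOTUs at threshold 0.0675: 5
  label/MOTU mismatches: 5 (species_A_03, species_C_01, species_D_02, species_D_08, species_D_10)
```

Reading the output: the intra- and interspecific distance distributions are
separated by more than an order of magnitude (medians 0.0046 vs 0.151), the
density dip proposes a threshold of 0.0675, and single-linkage clustering
at that threshold recovers exactly the 5 generating species as MOTUs. The
congruence report flags exactly the 5 specimens whose labels were swapped —
this is how real morphological misidentifications surface in a barcoding
study. The identification percentages show the knock-on cost of label
errors: a mislabelled specimen not only scores "incorrect" itself, it also
contaminates the nearest-neighbour sets of its true conspecifics, which is
why more than 5 specimens score incorrect or ambiguous. The global
`min(inter) > max(intra)` criterion fails here for the same reason: with
swapped labels, some nominally "intraspecific" pairs are actually
between-species comparisons. Re-running with `--n-mislabels 0` gives 100%
correct under all three criteria, an intact gap by extremes, and zero
mismatches.

Each stage is also available separately (`simulate`, `distances`, `gap`,
`threshold`, `identify`, `motu`), reading/writing plain FASTA, TSV, JSON
and newick; `barcodegap run --config run.toml` drives the pipeline from a
single config file. All of this is equally usable as a library — see the
docstrings in `barcodegap.distances`, `barcodegap.gap`,
`barcodegap.thresholding`, `barcodegap.identify`, `barcodegap.motu` and
`barcodegap.simulate`.

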