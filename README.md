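# nmascope

Reusable pipeline for the computational dissection of ACTB/ACTG1
non-muscle actinopathies (NMAs):

- **`transcript_saturation`** — exhaustive enumeration of every possible
  single-nucleotide alternate allele over a coding transcript (3 alternates
  per reference position), internal consequence annotation (start/stop
  loss, stop gain with a 50-nt NMD-escape call, missense, synonymous,
  canonical splice, UTR, intronic) and joins against gnomAD-style
  population variant tables.
- **`cohort_classifier`** — deterministic, totally-defined rule engine
  assigning variant carriers to NMA subtypes (ACTB pLoF disorder, BWCFF1/2,
  DDS1, ACTG1 hearing loss, provisional unNMA, likely-benign ACTG1 pLoF,
  17q25 contiguous-deletion syndrome) with an auditable rule trace.
- **`gestalt_stats`** — embedding-space cohort statistics downstream of a
  facial-encoder: pairwise cosine distances, resampled same/different
  control distributions, ROC (Youden) threshold derivation, the subsampled
  100-iteration decision rule, PPV, and within-group cohesion percentiles.
- **`biophys_kinetics`** — single-exponential fits of pyrene
  polymerization/depolymerization traces (apparent half-time = ln2/k) and
  Thermofluor melt-curve Tm extraction from the first-derivative peak.
- **`synthetic_data`** — seeded generators for all five input families
  (transcripts, population tables, cohorts, embeddings, kinetic/melt
  traces) with ground-truth sidecars for parameter-recovery tests.
- **`pipeline`** / **`cli`** — end-to-end orchestration with a
  checksummed run manifest.

## CLI

```sh
# synthetic inputs (FASTA/TSV/CSV + truth sidecars)
nmascope simulate all --config cfg.json --out sim/

# saturation enumeration + population join
nmascope saturate --transcript sim/transcript.fa \
    --exons sim/transcript_intervals.tsv \
    --population sim/population.tsv --region coding_only --out sat/

# cohort classification
nmascope classify --cohort sim/cohort.tsv --out cls/

# embedding statistics
nmascope gestalt compare --embeddings sim/embeddings.csv --cohorts A,B
nmascope gestalt cohesion --embeddings sim/embeddings.csv --cohort A

# curve analysis
nmascope kinetics fit --traces sim/traces.csv --mode polymerization --out fits.tsv
nmascope kinetics tm --curves sim/melts.csv --out tms.tsv

# everything, with a manifest
nmascope run --config cfg.json --out run/
```

A minimal config:

```json
{"seed": 17,
 "transcript": {"n_codons": 375, "n_exons": 3},
 "cohort": {"flag_noise": 0.0},
 "embedding": {"cluster_sizes": {"grpA": 20, "grpB": 20}, "n_dims": 512}}
```

## Conventions

All genomic coordinates are 1-based inclusive (VCF convention). Alleles
are reported on the genome forward strand; minus-strand transcripts are
handled by complementing onto the coding strand before codon lookup.
Every stochastic routine takes an explicit seed.
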