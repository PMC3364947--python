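# rholandscape

Analysis pipeline for the systems-level consequences of a leaky
transcription-terminator allele in *E. coli* — a single amino-acid change in
Rho that weakens Rho-dependent termination. The package implements, as a
tested library plus numbered analysis drivers, the full chain of analyses
such a study needs:

- **growth**: logistic growth-curve fitting in log2-OD space
  (γ = max slope in doublings/hour, lag, time to saturation), posterior
  sampling of parameters (Laplace approximation), and rate ratios
  Γ = γ₁/γ₂ with paired-draw 95% CIs;
- **epistasis**: multiplicative epistasis ε = w_AB − w_A·w_B between two
  mutations from growth rates, with resampled CIs, sign calls, and a
  competition-experiment cross-check;
- **tiling**: differential-transcription calling on tiling-array log2
  ratios (moderated one-sample test, Bonferroni p < 0.01 and > 2-fold),
  sense/antisense orientation against a gene model, 1.5-fold gene-level
  calls, and track smoothing;
- **enrichment**: permutation overlap enrichment of flagged probes in
  genomic feature sets, and the windowed signal profile downstream of
  antisense transcription start sites with a circular-permutation null
  envelope and loess smooth;
- **pathway_mi**: pathway analysis by mutual information between a
  7-bin discretized expression profile (breaks at 3-, 2-, 1.5-fold) and
  pathway membership, with permutation significance, per-bin signed
  −log10 hypergeometric scores, and greedy redundancy filtering;
- **tnseq**: transposon-selection scoring (log2 reference:selected),
  Z-scores with 500 bp running-median smoothing, strict/relaxed locus
  flagging, and fitness-landscape comparison between genetic backgrounds;
- **synthetic**: seeded generators for all of the above with recorded
  ground truth, so every stage is testable without any external data.

## Worked example

Run the numbered drivers in order (each writes tables under `results/`):

```bash
python analysis/01_simulate_data.py
python analysis/02_growth_rates.py
python analysis/03_transcription_calls.py
python analysis/04_readthrough_profile.py
python analysis/05_pathways.py
python analysis/06_tn_landscape.py
python analysis/07_epistasis.py
```

Representative output (seeded, so reproducible exactly):

```
$ python analysis/03_transcription_calls.py
significant probes: 492 of 6000 (480 up in rho*)
antisense fraction among up gene-overlapping probes: 80.3%
gene calls at 1.5-fold: 5 overexpressed, 1 underexpressed

$ python analysis/04_readthrough_profile.py
up_in_rho*: 3.64-fold enriched overlap with features (p = 9.999e-05, 175 vs 48.1 expected)
TSS profile: 12/21 offsets exceed the 97.5% circular-permutation envelope; peak at 100 bp

$ python analysis/06_tn_landscape.py
70% of flagged loci are unique to one background
(replicate r = 0.99, cross-background r = 0.45)
```

Reading these numbers: of 6,000 probes, 492 change significantly between the
two backgrounds, and 80% of the gene-overlapping up-changes lie antisense to
the gene they overlap — the signature of terminator readthrough rather than
ordinary up-regulation. Up-changed probes are 3.6-fold enriched in the
horizontally-acquired feature intervals (relocation-permutation p ≈ 1e-4).
The readthrough signal downstream of antisense TSS exceeds the
circular-rotation null envelope out to a few hundred bp and decays. In the
transposon landscapes, 70% of fitness-relevant loci are unique to one
genetic background even though replicate experiments correlate at r ≈ 0.99 —
the same insertion can help in one background and do nothing, or harm, in
the other.

The full pipeline can also run from one config:

```bash
rholandscape pipeline --seed 1 --out-dir pipeline_run
```

## Layout

```
src/rholandscape/   library (annotation, synthetic, growth, epistasis,
                    tiling, enrichment, pathway_mi, tnseq, pipeline, cli)
analysis/           numbered narrative drivers writing results/
tests/              pytest suite (unit, property, and calibration tests)
scripts/            acceptance.py
docs/methods.md     modelling choices, assumptions, and limitations
```
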