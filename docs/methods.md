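# Methods

This package re-implements, as a tested pipeline over synthetic data, the
computational analyses used to characterize a hypomorphic allele of the
transcription terminator Rho in *E. coli*: a single amino-acid change that
weakens Rho-dependent termination, producing transcriptional readthrough
(biased toward antisense strands and horizontally acquired elements),
condition-dependent growth effects, epistatic interactions with secondary
mutations, and a largely background-specific transposon-insertion fitness
landscape. Every stage operates on data from the package's own seeded
generators, with planted ground truth retained so that recovery and
calibration are testable end to end.

## Growth model

A well's optical density is modeled as logistic in log2-OD space:

    y(t) = baseline + A / (1 + exp(-k (t - t_m))),   y = log2(OD - blank)

- growth rate gamma = A·k/4 (doublings/hour), the maximum slope of y;
- lag = t_m - 2/k, the intercept of the max-slope tangent with the baseline;
- time to saturation = t_m + ln(19)/k, where y reaches 95% of A.

Although the model is specified on the log2 scale, residuals are minimized on
the OD scale (`od - blank` vs `2**y(t)`): plate-reader noise is approximately
constant in OD units, so the unweighted OD-space fit is the correctly
weighted estimator. Fitting the log-transformed signal instead biases the
baseline downward (floored log values of near-baseline readings carry large
negative errors) and inflated rate estimates by several percent at realistic
noise in our simulations. Parameter bounds anchor the sigmoid to the data
range (baseline within 2 doublings of the observed minimum, inflection inside
the observed window); without them the optimizer occasionally finds a
degenerate stretched-exponential solution whose nominal maximum slope lies
outside the measured time range.

Uncertainty is a Laplace approximation with flat priors: draws from a
multivariate normal centered on the least-squares optimum with the fit
covariance, recomputing gamma per draw (default 10,000 draws; the calibration
grid uses 600 per fit for speed). A non-positive-definite covariance is
jittered and flagged. Rate ratios between strains are medians over paired
draws with 2.5/97.5-percentile CIs; two conditions differ significantly when
their ratio CIs do not overlap. Flat or monotonically decreasing curves
return an explicit no-growth result (gamma = 0) rather than a spurious fit.

Alternative estimators, selected per dataset by `fit_method`:

- *effective rate*: OLS slope of log2(OD - blank) over a stated time window,
  for conditions whose curves never take a clean logistic shape;
- *early-exponential pooled rate*: shared slope with one intercept per well,
  restricted to points before the culture exceeds 2^3 times its initial
  above-blank OD. Implemented as least-squares dummy-variable (fixed
  per-well-intercept) regression rather than a random-intercept mixed model:
  on balanced designs the pooled slope is identical, and the fixed-effect fit
  remains exact on the noiseless constructions the tests verify, where a
  zero-residual mixed model is numerically degenerate;
- *spline-guided*: GCV smoothing spline on log2 OD (scipy
  `make_smoothing_spline`), gamma = maximum derivative.

Outlier wells are pruned automatically when their residual SD exceeds 3x the
median across replicate wells — an automated analog of discarding wells with
optical artifacts.

## Epistasis

For alleles A and B with relative fitnesses w_X = gamma_X / gamma_00,
multiplicative epistasis is epsilon = w_AB - w_A·w_B (linear scale, default;
a log2 variant epsilon = log2(w_AB / (w_A·w_B)) is available behind a flag
since both are consistent with "multiplicative"). CIs recompute epsilon over
paired posterior draws of all four rates; the four strains are treated as
independently measured. Sign calls: positive iff the 95% CI lies above 0,
negative iff below. A zero reference rate makes epsilon undefined (raised
explicitly — the analog of a condition where the wild type does not grow).
The competition cross-check estimates a per-passage selection coefficient as
the OLS slope of the log2 count ratio over passages and reports a
normal-approximation posterior probability that its sign matches the
growth-curve call; zero counts receive a 0.5 pseudo-count, and with fewer
than three passages the slope SE is undefined and the probability defaults to
0.5 (no information).

## Tiling-array probe and gene calls

The probe-level statistic is a moderated one-sample z: replicate mean over a
standard error built from the per-probe SD shrunk half-way toward the global
median SD (equal weights). Its p-value is NOT taken from a standard normal —
that reference is badly anticonservative in the far tails when the per-probe
SD can fluctuate low with few replicates. Instead the p-value integrates the
statistic's exact null distribution under iid Gaussian replicate noise: with
u the per-probe SD in units of the true sigma (u² ~ chi²_(n-1)/(n-1)) and m
the median of that distribution, P(|T| > t) = E_u[2·Phibar(t·(u+m)/2)],
evaluated by Gauss–Legendre quadrature (400 nodes, cached per replicate
count). This keeps Bonferroni family-wise error control calibrated at n = 4
replicates (verified by simulation at 10,000 probes). The real-data caveat:
the derivation assumes homoscedastic Gaussian replicate noise; a plain
t-test is available behind `test="t"` for heteroscedastic data.

A probe is significant when Bonferroni-corrected p < 0.01 AND its
|median log2 ratio| exceeds 2-fold. Orientation against the gene model:
sense / antisense when the probe overlaps genes on exactly one strand, "both"
when covered on both strands (excluded from sense/antisense fraction
denominators), intergenic otherwise. Gene-level calls take the median of
sense-oriented probe ratios against a 1.5-fold threshold; genes without sense
probes are flagged rather than called. The internal ratio convention is
log2(mutant/WT) throughout, with an explicit orientation field on I/O because
published tables mix both conventions.

Track smoothing: Gaussian kernel (SD = width, truncated at 4 SD, default
100 bp) or exact running median over a centered window (default 500 bp),
with truncated edge windows.

## Enrichment and the TSS downstream profile

Feature-overlap enrichment relocates each feature interval independently and
uniformly on the circular genome (lengths preserved, overlaps permitted) and
compares the observed flagged-probe overlap count against the relocated
null; fold = observed / mean(null), p = (1 + #{null at least as extreme}) /
(n_perm + 1) in the observed direction. A gap-preserving shuffle was
considered and rejected as the default: independent relocation is the
simplest null consistent with "random permutation of site locations", and
the choice is isolated in one function.

The antisense-TSS profile takes, at each offset d (0 to 1,000 bp in 50 bp
steps), the median across TSS of the median probe signal in a 250 bp window
centered d bp downstream (strand-respecting, circular); profile values are
reported as log10 ratios (log2 inputs converted explicitly at the module
boundary). The null rotates the entire probe signal by a uniform random
genomic offset — preserving the signal's autocorrelation while breaking its
registration with the TSS — and recomputes the profile per rotation
(default 10,000); observed and envelope are centered by subtracting the
per-offset null median, and the 97.5th percentile forms the envelope. Fewer
than 40 rotations are refused (the 97.5th percentile is unstable). On the
regular 50-bp alternating-strand grid the rotation null is computed exactly
via circular sliding-window medians (a rotation by k grid steps is an index
shift), which makes 10,000 rotations cheap; irregular probe sets fall back
to a generic path. The loess smooth of the profile is statsmodels `lowess`
(local linear, tricube weights, no robustness iterations), which is exact on
straight lines.

## Pathway mutual information

Gene (or probe) log2 ratios are discretized into 7 bins with fixed edges at
±log2(3), ±log2(2), ±log2(1.5); values exactly on an edge go to the more
central bin, and non-finite values are excluded and counted. A pathway's
score is the MI in bits between its binary membership indicator and the bin
variable. Significance permutes gene labels; because MI depends only on the
2x7 contingency table, the permutation null is sampled exactly as
multivariate hypergeometric per-bin membership counts, which is
distribution-identical to explicit shuffles and orders of magnitude faster.
Per-bin over/under-representation is the signed -log10 hypergeometric tail
(+ over, - under). Redundancy filtering is greedy in descending MI: a
pathway is kept only if its conditional MI given each already-accepted
pathway (computed within membership strata, with within-stratum permutation
nulls) stays significant. This simplifies the published iPAGE machinery to
the level exercised here; the original's exact stopping rule is not
reproduced. The strict screening threshold (p < 1e-4) requires permutation
counts of order 10^5 for exact calling; smaller runs report a bound.

## Transposon-selection landscapes

Per probe, score = log2(reference/selected) after per-array median centering
(non-positive intensities floored to the array's smallest positive value), so
negative scores mean the insertion is *enriched* — advantageous — under
selection. Scores are standardized over the table (mean/SD; a median/MAD
variant is available) and smoothed with a 500 bp running median. A locus —
gene, or intergenic region labelled by its flanking genes — is flagged when
any of its probes reaches |smoothed Z| >= 2 (strict) or >= 1 (relaxed);
probe-to-locus assignment ignores probe strand because an insertion disrupts
a locus regardless of the strand the array reports. The strict/relaxed
values are stand-ins for an unpublished thresholding procedure and are
recorded in output metadata and configurable. Background comparison:
unique-to-X = strict in X and not even relaxed in the other background;
shared loci are split by the sign agreement of their gene-median scores;
Pearson correlations are reported between backgrounds and between replicates
on gene-median scores.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses assume:

- *annotation*: circular genome (default 300 kb, 120 genes of 800–1,400 bp
  alternating strands with 600–1,200 bp gaps — gene density and size scaled
  down ~15x from a real enterobacterial chromosome to keep runs fast),
  terminators at gene 3' ends, antisense TSS inside half the genes, feature
  blocks (a horizontally-acquired-DNA stand-in) covering ~10% of the genome;
- *arrays*: probes every 50 bp alternating strands; iid Gaussian log2 noise
  (default SD 0.1, 4 replicates);
- *planted effects*: exponentially decaying readthrough tails (500 bp length
  scale, matching the reported few-hundred-bp spatial extent) downstream of
  a subset of terminators and of every antisense TSS; flat sense effects on
  differentially expressed genes, sized so that ~80% of planted
  gene-overlapping up-effects are antisense (the reported bias); extra
  intergenic effects inside features so ~25% of planted up-effects fall in
  the feature set, creating genuine overlap enrichment;
- *growth*: OD = blank + 2^y(t) with additive OD-scale Gaussian noise
  (default SD 0.005, 10-minute sampling over 16 h — 97 points per well);
- *selections*: selected abundance = reference x 2^(s·generations) x noise
  per probe, with background-specific selection-coefficient maps (default
  |s| = 0.15 over 10 generations, 40 effect loci of which 30% shared between
  backgrounds — mirroring a landscape where >70% of fitness-relevant loci
  are background-unique); log-normal library abundance, log2 depth noise
  SD 0.2.

Not emulated: scanner/image artifacts, intensity-dependent (heteroscedastic)
array noise, cross-hybridization, probe GC effects, correlated replicate
structure, insertion-site sequence bias, and real GO annotation structure
(pathway fixtures are synthetic gene sets). Passing tests therefore
demonstrate correctness of the procedures under their stated assumptions,
not robustness to every artifact of real microarray data.

## Numerical choices and degenerate inputs

- Seeds: every stochastic routine takes an explicit seed; the pipeline
  expands one top-level seed into per-stage seeds via fixed SeedSequence
  spawn keys, so stages are independently reproducible and reports are
  byte-identical across runs.
- Permutation p-values always carry the +1 correction and can never be 0.
- Growth: curves with fewer than 10 usable points are rejected; OD values at
  or below blank are floored to half the smallest positive value before any
  log transform.
- Ratio/fitness denominators at 0 raise explicit errors (growth-rate ratios
  drop non-positive denominator draws and flag it).
- CI-coverage checks run on noise > 0 cells only: at zero noise the Laplace
  covariance collapses and the interval is degenerate at the point estimate.
- Probe test: probes with < 2 finite replicates are excluded and counted in
  the QC attribute rather than silently dropped.
- Zero score dispersion (constant selection scores) is an error, not a
  silent all-zero Z table.

## Problem sizes

Default simulation sizes (120 genes / 300 kb / 6,000 probes; 200 curves per
calibration cell; 100 null tables for family-wise error; 300 nulls per
uniformity check; 10,000 rotations for published-scale profiles, 400–2,000
in the calibration suite) were chosen so the full test suite and the
acceptance script each complete in a few minutes on one CPU while keeping
every binomial sampling error well inside the asserted tolerances.

## Known limitations

- The exact published forms of the growth-model priors, the probe-test
  procedure, the strict/relaxed selection thresholds, and the epistasis
  equation's scale are not reproduced in the available text; each stand-in
  is documented above, isolated behind a flag or parameter, and labelled in
  output metadata.
- The Laplace "posterior" is a local Gaussian approximation; strongly
  non-quadratic likelihoods (very noisy or truncated curves) will
  miscalibrate its CIs.
- The moderated probe test's analytic null assumes homoscedastic Gaussian
  replicate noise.
- Accession-dependent quantities (probe counts, gene counts, enrichment
  folds on the deposited arrays) require the original array data and a real
  annotation; the pipeline accepts such inputs through the same readers but
  none are bundled.
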