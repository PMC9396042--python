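# Methods

## Model and assumptions

The package treats radiosensitivity as a property read off bulk gene
expression. Three layers compose:

**Normalization.** Counts per million remove sequencing-depth differences;
TMM factors remove composition bias (a few very abundant transcripts in one
sample deflating the apparent CPM of everything else). For a sample against
a reference sample, per-gene statistics are

- M = log2((obs/N_obs) / (ref/N_ref)) — the expression log-ratio,
- A = ½·log2((obs/N_obs)·(ref/N_ref)) — average abundance,
- weight = 1 / [ (N_obs−obs)/(N_obs·obs) + (N_ref−ref)/(N_ref·ref) ] — the
  inverse delta-method (binomial) variance of M.

Genes with a zero count in either column, or constituting an entire
library, are excluded (M undefined or degenerate). The extreme
ceil(0.30·m) M-values and ceil(0.05·m) A-values are trimmed from each tail
(ties broken by gene index for determinism) and the factor is
2^(weighted mean of the surviving M). The reference sample is the one whose
75th-percentile CPM is closest to the cross-sample mean (ties: lowest
index); factors are rescaled to geometric mean 1 and enter through the
effective library size. Output is log2(CPM_effective + 1); the prior count
of 1 on the CPM scale keeps zeros finite. TMM requires ≥ 2 samples.

A consequence of the depth-dependent weights: rescaling one sample's counts
by a constant leaves M, A and the trimming untouched but perturbs the
weights slightly, so the factor is scale-invariant only to ~1e-3 relative —
the tests assert exactly that.

**RSI.** The ten-gene signature is applied as a plain signed linear
combination of the normalized log2 expression values, with the published
coefficients to all printed digits. The score is calibrated to SF2 and is
*not* clamped to (0, 1]: values outside that range almost always indicate a
normalization problem, and clamping would hide it. Gene identifiers are
resolved through an alias table (symbol → accepted ids, user-overridable
via YAML) with Ensembl version suffixes stripped; zero or multiple matches
for a signature gene are hard errors.

**Dosimetry.** With β fixed at 0.05 Gy⁻² and the 2 Gy calibration fraction,
α = −0.5·ln(RSI) − 0.1 is derived once per sample and reused for any
regimen (the literature never recalibrates α per regimen). GARD =
n·d·(α + β·d); at d = 2 this reduces to −0.5·D·ln(RSI). The minimum dose
for a GARD target is D = target/(α + β·d), also reported as a whole
fraction count (ceiling); the ECDF uses the continuous dose to avoid step
artifacts. α + β·d ≤ 0 (RSI ≥ e^(−0.2) ≈ 0.819 at d = 2) makes the target
unattainable: dose inversion raises an error and cohort curves exclude and
report such patients. The hypofractionation flag is strict: RSI > 0.4.

## Cohort analysis

Group summaries are mean ± sample sd (n−1). Group GARD is
per-sample-then-averaged; because GARD is convex in RSI this differs from
GARD at the mean RSI by a Jensen gap of roughly 0.5–2% at realistic
spreads — reports carry a note to that effect. Welch's t-test (two-sided,
Satterthwaite df) compares tumour vs normal; two-sided is the conservative
default where sidedness is unstated. The GARD-high threshold is the tumour
median (even counts: midpoint of the central pair) or a user-fixed value
such as 21. Coverage at a dose equals the minimum-dose ECDF at that dose by
construction, and both are tested for pointwise agreement. The LOESS
smoother (tricube weights, degree-1 local fits, span 0.75 by default,
output clipped to [0, 1]) is presentation-only.

## Synthetic data generator

The generator emulates what the analysis assumes about real cohorts:

- background genes (default 5000) drawn negative-binomial, variance
  μ + 0.1·μ² (dispersion 0.1, typical of bulk RNA-seq), over a shared
  log-normal abundance profile;
- library sizes log-normal around 5×10⁶ (log-sd 0.3) — deep enough that
  planted panel counts round accurately, small enough to generate quickly;
- composition bias: 5% of background genes get tumour-specific log-normal
  fold-changes (log-sd 1), which TMM must absorb;
- panel genes planted by inverting log2(CPM+1) at the realized library
  size: the nine non-cABL genes sit at a baseline of log2 CPM = 5 and the
  cABL component is solved so the signature equals the sample's target RSI
  exactly (always solvable; the cABL coefficient is the largest in
  magnitude). Counts are rounded to the nearest integer; rounding plus
  TMM noise is the only gap between intended and realized RSI (≲0.02 at
  the default depth);
- per-sample target RSIs are Normal(group mean, rsi_sd = 0.04), matching
  the within-group spread reported for paired-biopsy cohorts; the two
  shipped designs are 1 patient × (9 tumour / 3 normal) with targets
  0.43/0.52, and 14 patients × (1/1) with targets 0.43/0.46;
- a single seed feeds per-sample counter-split streams
  (`SeedSequence(seed, spawn_key=(1, i))`), so extending a cohort never
  perturbs existing samples.

What the generator does **not** model: read-level noise, gene length and GC
effects, batch structure, correlated co-expression among the panel genes,
and any biological coupling between RSI and the background transcriptome.
Passing recovery tests therefore demonstrates that the pipeline's
arithmetic is self-consistent and robust to NB noise, depth variation and
composition bias — not that the signature is biologically valid on real
tumours.

At the default spread (0.04) the 9-vs-3 design has end-to-end Welch power
of only ~0.65 at α = 0.05 — small paired-biopsy cohorts genuinely sit near
the significance boundary. The generator's power bar (≥ 80% rejection over
200 seeds) is therefore asserted for a well-separated configuration,
rsi_sd = 0.02 (the 0.09 group separation is then 4.5 within-group sd);
measured power there is ~0.95.

The TCP-reference helper draws Gaussian α values (mean 0.35, sd 0.08),
redrawing the ~6×10⁻⁶-probability non-positive tail, for comparing
GARD-derived dose distributions against classical tumour-control-
probability sigmoids.

## Numerical choices

- Counts must be integers; fractional estimated counts are rejected unless
  explicitly allowed, in which case they round half-to-even.
- TMM ties (order statistics, reference selection) are broken by index;
  the whole pipeline is deterministic for fixed inputs, and reruns are
  byte-identical apart from the manifest timestamp.
- Percentiles use linear interpolation (numpy default).
- The acceptance script's problem sizes: the four dosimetry figures are
  closed-form scalar computations; recovery and power suites in the tests
  use 100–200 seeds at 300–5000 background genes, sizes at which the
  estimates are stable to well within the asserted tolerances.

## Known limitations

- The signature's microarray ancestor used rank-based expression; here the
  linear form is applied directly to log2 TMM CPM. A rank-transform variant
  is deliberately out of scope.
- Whether the original analysis matched panel genes by symbol or Ensembl id
  is not recoverable; the alias table covers both, but defaults may need
  overriding for a given annotation.
- No normal-tissue complication modelling, EQD2/BED conversion beyond the
  GARD formula, or survival association — the outputs are exploratory
  dosimetry, not treatment advice.
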