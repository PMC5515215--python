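# Methods

This note documents the models, defaults and numerical choices behind
each `quorumflow` module, what the synthetic-data generators do and do
not emulate, and the design decisions made where the underlying
protocols leave room.

## V6 tag profiling

Community composition is profiled by a fast tag method: each read is
scanned for the universal 16S primer `CGACRRCCATGCANCACCT` (19 nt,
IUPAC degenerate at two R positions and one N), and the 33 nt
immediately downstream of every match become a V6 tag, a proxy for a
taxon. Matching is exact (0 mismatches) over the IUPAC expansions; an
`N` in a *read* matches only the primer code `N`, because an ambiguous
base call is not evidence of a match. Reads are scanned on the given
strand only by default; `--scan-reverse-complement` adds the reverse
complement.

Two artefact filters are applied literally to the aggregated tags:

1. tags covered by fewer than `min_reads` (default 2) reads are removed
   (sequencing-error artefacts);
2. tags where a single *read type* (distinct full-read sequence)
   accounts for ≥ `max_type_fraction` (default 0.5) of coverage are
   removed (duplication artefacts).

A consequence of the literal rules is that a tag covered by exactly two
reads can never survive: two identical reads are one type at 100%, two
distinct reads are each at 50%. The effective minimum viable coverage
is therefore 3 distinct reads. Both thresholds are exposed as
parameters for users who prefer a different reading; "two different
reads" is interpreted as total covering reads, not distinct read types,
with the type-fraction rule handling duplication independently.

Tags are ranked for top-N selection (default 50) by mean relative
abundance across samples, with lexicographic tie-breaking so the
selection is deterministic.

## Decay kinetics

Spiked microcosm experiments follow residual AHL concentration over
time in three conditions: live sludge, heat-inactivated sludge, and a
sterile synthetic-wastewater (SWW) control. The SWW control isolates
abiotic loss (negligible below pH ~8.3); the heat-inactivated control
adds adsorption to biomass; the live condition adds enzymatic
quenching.

**Adsorption** is estimated as
`1 − mean(heat at {0, 1 h}) / mean(sww at {0, 1 h})`, clamped to
[0, 1]; a timepoint must exist within ±0.25 h of each target. To
isolate enzymatic decay, live concentrations are rescaled by
`1/(1 − fraction)` at *all* measured timepoints (the t = 0 sample is
drawn immediately after addition and already carries the instantaneous
adsorption drop, so rescaling only t > 0 would leave a spurious step at
the origin). The correction is a toggle, default on.

**Model fitting.** Zero-order: OLS of C on t, t½ = C₀/(2k). First-
order: log-linear OLS of ln C on t followed by a nonlinear
least-squares refinement on the concentration scale
(`scipy.optimize.curve_fit`), t½ = ln 2/k. Zero concentrations are
floored before the log transform at a configurable value (default half
the smallest positive observation, i.e. an LOQ/2-style left-censoring
floor); a series whose all-zero tail exceeds half its length is
reported as a fit failure rather than fitted. Half-life standard errors
come from the delta method on the slope (and, for zero order, the full
OLS covariance of intercept and slope). The order with the higher r² is
selected per series; ties within 1e−6 go to first order. Non-degrading
series (k ≤ 0) are flagged rather than given negative half-lives.

Replicates are fitted individually by default and half-lives aggregated
afterwards (pooled-mean fitting is available), because per-replicate
fits preserve the between-replicate variance the group comparisons
need. Group comparisons use Welch's t-test (unequal variances, the
safer default when none is stated) with Holm–Šidák step-down adjustment
across AHLs (via `statsmodels.multipletests`). The chain-length trend
is the Spearman rank correlation of half-life against acyl-carbon count
within each C3-substitution class; a negative correlation flags the
inverse trend (long chains degraded faster).

## LC-MS/MS quantification

Calibration is an OLS line of peak area on concentration over matrix-
matched standards (0.5–200 µg/l). LOD and LOQ are `3.3·σ/slope` and
`10·σ/slope`; when no blank-noise measurement is supplied, σ defaults
to the residual SD of the calibration fit, since the instrumental
signal-to-noise baseline is not recoverable from a peak-area table.
The ratio LOQ/LOD = 10/3.3 is an invariant of every fit.

Extraction efficiency is the mean of recovered/nominal over spikes at
5 and 50 µg/l; values above 1.5 are rejected as implausible. Quantified
concentrations are `(area − intercept)/slope / efficiency`. Values
below LOD (including negative back-calculations) are reported as 0 with
a `below_lod` flag — numeric rather than NA so that downstream
correlation series stay complete, with the flag preserving the
censoring information; values between LOD and LOQ are corrected but
flagged `below_loq`.

MRM identity confirmation requires the retention-time shift within
`rt_tol` (default 0.2 min), both transition ions present, and the
transition intensity ratio within `ratio_tol` (default ±30%) compared
on the log scale (ratio errors are multiplicative). The criteria are
standard MRM confirmation practice; the tolerances are conventional
windows and are exposed as parameters. Full-scan confirmation and
blank-injection carryover checks are carried as pass/fail fields in
input tables, not computed.

The optional conversion of extract concentrations (µg/l) to in-situ
amounts (pmol/g biomass) requires the AHL molar mass and the biomass
concentration of the extracted sample as explicit inputs.

## Isolate phenotyping

An isolate is a **producer** iff at least one biosensor (A136, CV026 or
JBA357) responds *and* at least one produced AHL is confirmed by
LC-MS/MS — biosensor activation alone is not sufficient. It is a
**quencher** iff, for at least one of the 3OC6/3OC8/3OC12-HSL panel,
the residual after the 2-h incubation is ≤ `quench_threshold` (default
0.5, i.e. ≥ 50% reduction) of the pH-matched sterile control. The
semi-quantitative agar bioassays this models state no numeric cut-off;
the threshold is exposed and the classification is monotone in it
(lowering it never adds quenchers). Records whose control culture
exceeds pH 7.3 are rejected, since alkaline lactonolysis would mimic
enzymatic quenching.

Category summaries report producer_any / quencher_any / both / neither
percentages with the inclusion–exclusion identity
`either = producer_any + quencher_any − both = 100 − neither` enforced
exactly. The quench spectrum splits quenchers into long-chain-only
(3OC12-HSL only) vs long-plus-short/medium.

## Community–signal correlation

Pearson r between every taxon-abundance row and every AHL-concentration
row over the shared timepoints, with two-sided p-values from the exact
t-distribution (n − 2 df). Constant rows give undefined r, are classed
neutral, and are imputed as 0 only for clustering (with a notice).
FDR adjustment is Benjamini–Hochberg, pooled over all taxon × AHL pairs
(the adjustment method and pooling are options). A pair is positive iff
r > r_min and q < α, negative iff r < −r_min and q < α, else neutral;
defaults r_min = 0, α = 0.05, so the neutral class absorbs all
non-significant pairs. Published percentage splits of this kind do not
always state how non-significant pairs are counted; the classification
is therefore treated as structural, and the summary always reports all
three classes (summing to 100).

Taxa are clustered by complete-linkage agglomeration on Euclidean
distances between their correlation profiles (scipy), with flat
clusters cut at k = 3 by default, matching the numbered clusters of the
usual heatmap presentation; heatmap ordering follows dendrogram leaf
order, +1 green / −1 red. Stage comparison reports per-class percentage
deltas and per-AHL granular/floccular mean ratios with a fold-change
flag at 3 by default.

## Synthetic data: what it emulates, and what it does not

* **Reads**: fixed flanking context (default primer offset 10 nt), the
  primer with degenerate positions concretised uniformly (so
  degeneracy-aware matching is actually exercised), the planted tag
  with independent per-base substitution errors, then random bases to
  the read length (default 75 nt). Qualities are constant Q30
  placeholders. The truth table applies the literal tag filters to the
  error-free occurrences of each planted tag, so generator truth and
  profiler behaviour agree by construction. Real sequencing depth, read
  length and error profiles are instrument-dependent and are not
  calibrated here: no quality-dependent errors, indels, chimeras, or
  adapter read-through.
* **Decay**: concentrations follow the closed-form decay law of the
  planted order, an instantaneous adsorption drop shared by live and
  heat-inactivated series (applied at every timepoint, including the
  immediately-after-addition t = 0 sample), and multiplicative
  lognormal noise parameterised by CV with mean 1 — the conventional
  positive-valued noise model for concentration data. Defaults: 5 µM
  spike, timepoints 0–6 h, abiotic SWW loss 0 (negligible at pH ≤ 8.3).
  Enzyme saturation (Michaelis–Menten) and pH drift are not modelled.
* **Calibration**: additive Gaussian area noise on a line, the
  conventional model for integrated peak areas; levels restricted to
  0.5–200 µg/l.
* **Community series**: each AHL follows a bounded unit-variance latent
  driver (uniform on [−√3, √3]); a taxon planted with sign s and effect
  ρ follows `ρ·s·g + √(1−ρ²)·noise_sd·ε` with ε ~ N(0, 1), and
  abundances/concentrations are increasing affine maps of the latents.
  At noise_sd = 1 the population correlation of a planted pair is
  exactly ±ρ; at noise_sd = 0 it is ±1. The bounded driver keeps
  abundances nonnegative without clipping distortion. Real relative
  abundances are compositional and autocorrelated in time; neither
  property is simulated, so passing tests demonstrate correct recovery
  of planted linear associations, not robustness to compositional
  effects.
* **Isolates**: categories are drawn multinomially from the planted
  proportions (defaults 5.2 / 53.3 / 4.8 / 36.7% producer-only /
  quencher-only / both / neither, the composition of the floccular
  community the panel emulates); every planted quencher degrades
  3OC12-HSL, and 77% by default degrade only it. At zero assay noise
  the planted categories are exactly recoverable; the optional Gaussian
  residual jitter models assay noise only crudely.

All generators derive their randomness from `numpy` `SeedSequence`
spawning, so a single seed reproduces every byte of output, and
pipeline stages re-run in isolation see identical randomness.

## Problem sizes in tests and the acceptance script

The test suite exercises parameter recovery at modest, quickly-computed
sizes chosen to keep Monte-Carlo error well inside the asserted
tolerances: 100–200 seeded replicates for recovery checks, 500 seeds
for the false-discovery null, oracle comparisons on instances small
enough for exhaustive computation (≤ 60-nt sequences for primer
expansion, ≤ 6 leaves for brute-force agglomeration). The acceptance
script recovers each published half-life from 200 simulated replicate
series (8 timepoints over 0–6 h, CV 10%), the protocol under which the
mean estimate is comfortably within a few percent of truth.

## Known limitations

* Tag profiling does no taxonomic assignment, chimera detection or
  quality trimming; tags are taxon proxies only.
* The kinetics module fits empirical rate laws; it does not model
  enzyme kinetics mechanistically, and model selection by r² can be
  unstable when both orders fit comparably well over short windows.
* LOD/LOQ from residual SD understate instrument-level detection limits
  when calibration scatter exceeds baseline noise.
* The isolate classifier encodes the logical structure of the
  production/quenching calls; real bioassay colour intensities are not
  modelled.
* Pearson correlation is contemporaneous and linear; time-lagged or
  nonlinear taxon–signal relationships are out of scope.
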