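# Methods

This note documents the statistical models, the processing order, the
synthetic-data generator, and the numerical and design choices behind
`myoaging`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Study design assumed by the pipeline

Donors are spread over five age strata (20–34, 35–49, 50–64, 65–79,
80+ years) and multiplexed with TMT 6-plex: each batch carries one
donor from each stratum in channels 1–5 and a pooled reference sample
in channel 6. The reference is the bridge that makes relative
abundances comparable across batches. RNA-seq (transcript TPM) is
available for a subset of the same donors, processed in separate RNA
batches.

## Reporter-ion processing

Order of operations and the reasoning where the choice was open:

1. **QC filtering.** Decoy, contaminant and shared (multi-protein)
   spectra are removed; remaining spectra may miss at most two of six
   channels, otherwise they are dropped. Spike-in (labeling-control)
   peptides are expected to arrive flagged as contaminants.
2. **Imputation (MICE/PMM).** Missing reporter intensities are imputed
   per batch by chained equations: each incomplete channel is
   regressed (in log2 space) on the other five, and a missing cell
   receives the *observed* intensity of one of the k = 5 spectra with
   the nearest predicted mean, drawn at random. Ten round-robin
   iterations or convergence at 1e-8; a single imputation is retained,
   since downstream consumes one adjudicated value per cell. PMM
   guarantees imputed values are members of the observed value set, so
   no impossible intensities are invented.
3. **Per-protein centering.** log2 intensities are centered by the
   median over all of a protein's spectra × channels. Centering is per
   batch (the global alternative would leave cross-batch offsets to be
   removed twice); this also removes protein-level batch effects.
4. **Roll-up.** Protein × channel abundance is the median over the
   protein's spectra, channel by channel. Medians over even counts are
   the mean of the two central values.
5. **Loading correction.** Each channel's median (over proteins) is
   subtracted, so channel medians are exactly zero — the median-polish
   correction for unequal sample loading.
6. **Reference bridging.** Per protein and batch, the reference-channel
   value is subtracted from the five donor channels and donor columns
   are concatenated across batches. Log-space subtraction is the
   natural arithmetic because every downstream quantity is log2
   relative abundance; it makes the pipeline exactly invariant to
   additive per-batch offsets. A protein missing in a batch's
   reference cannot be bridged there and becomes missing for that
   batch's donors (counted in the QC report).
7. **Coverage filter.** Retain proteins observed in ≥ 3 donors of
   *every* stratum (AND over strata). A more permissive variant —
   observed in ≥ 50% of donors *or* ≥ 3 per stratum — is available as
   `coverage_rule="half_or_per_stratum"`.

## The age-association model

Per feature (protein log2 abundance, or event PSI):

    y_i = x_i'β + u_{batch(i)} + ε_i,   u ~ N(0, σ²_b),  ε ~ N(0, σ²_e)

Fixed effects: age (years), sex and race as reference-coded factors,
physical-activity category as a numeric ordinal 0–3 (<30, 30–75,
75–150, ≥150 min/week of moderate-to-vigorous activity), BMI, and — for
proteins only — the fiber-ratio proxy. The multiplexing batch (TMT set,
or RNA experiment batch for PSI) is a random intercept; it also absorbs
the within-batch correlation that reference subtraction induces (all
five donors of a batch share the same reference measurement error).
Donors missing the response are dropped listwise; covariates are
required complete.

**Fiber ratio.** MYH7 (slow-twitch myosin) over the sum of MYH1 + MYH2
+ MYH4 (fast isoforms), computed on the linear intensity scale
(exponentiating the log2 relative abundances); a missing fast isoform
counts as absent when at least one fast isoform is observed. Note the
ratio is built from the same matrix it adjusts, so the myosin genes
themselves are partially absorbed by their own covariate — a property
of the original design, retained deliberately.

**Estimation.** REML via a profiled scalar optimization: with
λ = σ²_b/σ²_e and the spectral decomposition ZZ' = U diag(d) U', each
profile evaluation is O(n·p²), and thousands of per-feature fits reuse
the decomposition through a design cache keyed by the donor-missingness
pattern. The restricted likelihood is minimized over λ ∈ [0, 1e4] by
bounded Brent search (xatol 1e-8) with an explicit λ = 0 boundary
check.

**Inference.** For a fixed-effect coefficient, f(θ) = Var(β̂_j) with
θ = (σ²_b, σ²_e); the Satterthwaite degrees of freedom are
df = 2 f² / (gᵀ A g), with g = ∂f/∂θ (analytic) and A the inverse
expected REML information ([tr(P V_i P V_j)/2]⁻¹). Two-sided t tails
give p. Degenerate cases: non-positive or non-finite df falls back to
the residual df n − p; an exactly interpolating fit (zero residual,
as in noiseless simulations) falls back to plain least squares with
the coefficient reported and p undefined. The engine is validated in
the test suite against statsmodels MixedLM (estimates, variance
components) and R lmerTest (β, SE, df, p on the same data).

**Calls.** Benjamini–Hochberg q-values are computed across all tested
features (the full-family choice; the BH family is configurable only by
subsetting upstream). The primary age-associated call is unadjusted
p < 0.05 together with the presence rule, with q reported alongside;
direction is the sign of β_age.

## Splicing events and PSI

Transcript models hold exons as 0-based half-open intervals (GTF I/O
converts to/from 1-based inclusive; parsing is delegated to pyranges).
Events come from pairwise transcript comparison within a gene:

- **SE** — an internal exon of one transcript strictly inside an intron
  of the other, with both flanking splice sites shared; inclusion = the
  exon-containing form.
- **RI** — one transcript's single exon spanning exactly two adjacent
  exons plus the intervening intron of the other; inclusion = the
  retaining form.
- **A5/A3** — two introns sharing one boundary and differing at the
  other, with the variable-side exons overlapping; the 5'/3' label is
  strand-aware; inclusion = the shorter-intron form.
- **MX** — non-overlapping internal exons of two transcripts between
  shared flanking splice sites; inclusion = the genomically first exon
  (this convention flips under coordinate reflection, which the strand
  symmetry test accounts for).
- **AF/AL** — non-overlapping terminal exons spliced to a shared site
  of the adjacent common exon (emitted only when the alternative
  terminal exons do not overlap); inclusion = the distal form.

Duplicate events found in several transcript pairs are merged by
coordinates with transcript sets unioned. Event ids follow the SUPPA
`.ioe` layout so outputs interoperate with existing PSI tooling.

PSI(event, donor) = inclusion TPM / total TPM, with denominators below
1e-3 TPM set missing (prevents 0/0 on unexpressed genes). Transcripts
must be expressed (TPM > 0) in ≥ 3 donors of every age group to enter
the analysis. Event models require ≥ 10 finite PSI values and skip
constant rows.

## The synthetic-data generator

The generator *defines* the conditions every test and the acceptance
script run under:

- **Cohort**: ages uniform within strata (only strata counts are
  reported for the real cohort); channels 1–5 randomized within batch;
  sex ~ {F, M} equally, race ~ {C, AA, A} at 65/25/10%, BMI ~ N(25,
  2.5²) truncated below 30 (the study's inclusion cap), weekly
  activity minutes ~ Gamma(1.2, 90) so all four activity categories
  occur; RNA batches of ten consecutive donors.
- **Proteins**: baseline log2 abundance ~ N(16, 1.5²); an exact
  round(n·frac) subset (default 29%) carries age slopes with magnitude
  uniform on [0.001, 0.02] log2/year and random sign — the span of
  printed age coefficients in this literature; the rest are exactly
  null. The four myosins are always present, taking the leading
  nonzero slopes with fixed signs (MYH7 up, MYH1/2/4 down) so the
  slow/fast fiber ratio rises with age as observed in muscle.
  Peptides per protein ~ 1 + Poisson(2); peptide bias offsets
  ~ N(0, 0.5²); per-protein batch effects ~ N(0, 0.2²); residual noise
  0.2 log2 units.
- **Spectra**: intensity = 2^(baseline + β·age + batch + loading +
  bias + ε) with loading ~ N(0, 0.1²) per channel; the reference
  channel carries a pooled pseudo-donor at the cohort mean age (the
  real reference's composition is unstated; the mean-age pool is the
  neutral choice). Missingness is MCAR per cell (default 1%); an
  intensity-dependent mechanism is deliberately *not* the default
  because the original missingness mechanism is uncharacterized.
  Decoy/contaminant/shared spectra are added at ~1% each to exercise
  the filters.
- **Splicing**: planted two-transcript genes, one per event class per
  strand, tiled as needed; expected inclusion share follows
  logistic(a + b·age) with |b| ∈ [0.004, 0.012] per year on the logit
  scale (≈ 0.001–0.003 PSI/year near PSI 0.5, the scale of observed
  age-related splicing drift), centered so the expected PSI stays in
  (0, 1) at every age in 20–87 by construction. Gene expression is
  log-normal; multiplicative log-normal noise (dispersion 0.1) on
  transcript TPM; donor columns normalized to a constant sum (1e6).

What the generator does **not** emulate — and hence what passing tests
do not show about real data: peptide-level interference and ratio
compression of isobaric labeling, intensity-dependent (MNAR)
missingness, correlated proteins/pathways, isoform-specific peptide
evidence, RNA library-size or GC artifacts, and covariate–age
confounding beyond what the cohort randomization produces.

## Problem sizes and tolerances

The test suite and acceptance script use deliberately compact problem
sizes chosen to make their statistical checks decisive: 60-donor /
12-batch cohorts; 200 proteins for the exact noiseless-identity check
(β̂ = β_true to ≥ 6 decimals; observed error is at machine precision);
2500 proteins (2000 null) for calibration — type-I error within
[0.03, 0.07] and 95% CI coverage within [0.92, 0.97]; 210 events at 53
donors for PSI slope recovery (mean bias under 10% of the planted
slope). Oracle-equivalence checks (normalization, roll-up, median
polish, BH, PSI, event generation) run 50 random instances each
against independent brute-force implementations and require exact
agreement (1e-12).

## Known limitations

- Satterthwaite inference is implemented for a single random intercept
  only; richer random structures (donor-level repeats, crossed
  effects) are out of scope.
- The event generator emits local binary events; complex events
  spanning more than two alternatives appear as several pairwise
  events, as in standard `.ioe` tooling.
- The BH family is the full tested set; per-chromosome or per-class
  families must be formed by subsetting before adjustment.
- The fiber-ratio covariate is endogenous for the myosin genes
  themselves (see above).
- `category_distribution` consumes curated category labels as input;
  no enrichment statistics are computed.
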