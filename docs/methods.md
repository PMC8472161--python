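# Methods

## Assay model

Each well contains one quenched FRET peptide (PepA–PepE, S0 = 200 nM from a
10 pmol load in 50 µL) and a diluted specimen. Cleavage de-quenches the
fluorophore, so fluorescence tracks cumulative cleaved product. With all
active proteases far below substrate saturation ([S] ≪ Km; MMP Km values are
typically micromolar against these peptides, three orders above S0), cleavage
is pseudo-first-order with

    k_obs[s] = Σ_e (kcat/Km)[s, e] · [E]_e · survival(e, group),

and the recorded signal is modelled as

    F(t) = baseline + gain · S0 · (1 − exp(−k_obs t)) · exp(−λ t) + ε,

where λ (per min) is a photobleaching decay applied to accumulated signal and
ε is Gaussian reader noise. The bleaching factor multiplying the accumulated
signal is a modelling choice — the decay mechanism is not otherwise
constrained by the assay — as is the single-exponential form. Time is in
minutes at every I/O boundary; rate constants are converted to s⁻¹ inside the
kinetics layer because catalytic efficiencies are catalogued in M⁻¹ s⁻¹.

## Per-well kinetics

* **Vmax (a.u./min)** — the assay's standard activity readout: the maximum
  ordinary-least-squares slope over all windows of four *consecutive*
  timepoints of the background-subtracted series. The four-point window is a
  sliding one with ties broken to the earliest window; window placement is
  otherwise unconstrained by the assay description, so this is a package
  decision. Negative maxima clamp to 0 and flag `below_noise`; slopes are
  computed with the closed-form centered OLS formula so exact ties and
  constant series behave exactly.
* **Background** — the substrate-only negative control is subtracted
  pointwise; grids must match exactly (missing readings are rejected, not
  imputed, because the window fit assumes a complete grid).
* **Bleach rate** — log-linear regression on a positive plateau or
  negative-control baseline; non-decaying series return λ = 0.
* **Progress curve** — nonlinear least squares of A(1 − e^(−kt))e^(−λt) with
  λ fixed, initialised from the series maximum and the Vmax/A ratio, bounded
  nonnegative. The depletion-corrected initial turnover is A·k (a.u./min).
  Non-convergence yields a flagged zero fit, never a crash.
* **QC flags** — `saturated` when the last window's slope falls below 10% of
  Vmax (depletion regime; threshold is a package default), `nonmonotone` for
  any decreasing step, `below_noise` as above.
* **Catalytic efficiency** — k_obs/[E], exact division; used by the
  acceptance recovery tests across the catalogued range
  (2.4 × 10³ … 8.5 × 10⁵ M⁻¹ s⁻¹ at [E] = 1 nM).

## Fingerprints

Per sample and substrate: absolute Vmax (uninhibited), relative contribution
(percent of the five-substrate sum; all-zero panels return zeros with a QC
note), residual percentage 100·Vmax(group)/Vmax(NONE) and its complement
inhibition percentage (their sum is exactly 100 by construction), signed
inhibitor-attributable contributions Vmax(NONE) − Vmax(group), the MP/CSC
ratio (contributions clamped at 0 only inside the ratio; zero CSC
contribution → NaN sentinel), the additivity defect
inhibition(BOTHi) − max(inhibition(MMPi), inhibition(COMi)) whose negative
values mark sub-additive combined inhibition, and disinhibition flags
(residual > 100%). Contributions stay signed outside the ratio so
disinhibition remains analyzable. Cross-sample aggregation is
per-sample-first (means of per-sample ratios), which matters because the two
orders disagree on skewed data. Feature columns follow the
`PepE_COMi_ABS_CONT` naming scheme. Biopsy enrichment multiplies raw Vmax by
the dilution factor (saliva 20, biopsy 750) before forming the biopsy/saliva
ratio.

## Deconvolution

Effective enzyme concentrations solve min‖E·c − k_obs‖₂ subject to c ≥ 0
(scipy NNLS) against the bundled substrates × enzymes efficiency matrix
(MMP-2/-8/-9; "no activity" entries are exactly zero; predicted cleavers
without rate constants are metadata only and cannot enter the fit). An
optional ridge term (default 0) stabilises the near-collinear PepA–PepC
columns. `identifiable` reports the column rank on substrates with nonzero
rows. The class-constraint layer fits metallo enzymes to the
(NONE − MMPi) rate differentials and CSC enzymes to (NONE − COMi), floors
negative differentials at 0 while recording them as disinhibition evidence,
and reports the BOTHi-surviving rate per substrate as the unattributed
residual. The underlying matrix-analysis technique is cited by the assay
literature without a published modification; this NNLS-plus-differentials
formulation is the package's own, documented stand-in.

## Synthetic data

The generator emulates: de-quenching progress curves with substrate
depletion, optional photobleaching and additive Gaussian reader noise;
class-selective inhibition (MMPi removes metallo, COMi removes
cysteine/serine/calpain, BOTHi the union, efficacies overridable);
phenomenological protease–protease interaction (a multiplicative factor on
surviving classes when a class is inhibited — factor > 1 reproduces
disinhibition and sub-additive BOTHi by construction); positive controls as
near-instant complete cleavage and negative controls as baseline + bleach.

Cohorts draw per-subject, per-substrate uninhibited activities from
lognormals parameterised by the documented group means and SDs (lognormal
because the reported SDs approach or exceed the means), and split each
substrate's rate across protease classes by group-specific composition
profiles. Defaults: caries vs healthy PepE mean Vmax 1500.2 vs 601.8
a.u./min; the other substrates use the pooled saliva means/SDs for both
groups (group-specific values are only documented for PepE); healthy class
profiles follow the pooled saliva inhibition percentages, caries profiles
follow the MMP-enriched biopsy percentages (lesion-derived activity carries
over into saliva). Biopsy specimens (fraction 0.69 of caries subjects) use
the biopsy means at 1:750.

Scale note: with the published activity scale (hundreds–thousands of
a.u./min) a gain of 1 a.u./nM would saturate wells before the first read, so
cohort simulation uses gain = 100 a.u./nM (full-cleavage signal 20 000 a.u.)
and, in the analysis drivers, reader noise of 50 a.u. (≈0.25% of full
scale). The measured four-point Vmax on the 5-min grid under-estimates fast
generative rates (finite-difference curvature), uniformly across groups;
generator calibration checks therefore compare generative targets, not
re-measured slopes.

What a green test does *not* establish: the simulator draws substrate
activities independently (no within-subject correlation structure beyond the
class profiles), uses fixed class profiles per group (no biological
variance in composition), and models interaction phenomenologically. Real
saliva has correlated, confounded, drifting activities; classifier metrics
on simulated cohorts validate the protocol's mechanics, not clinical
performance.

## Statistics and classification

Student's t-test by default, Welch's when Levene's test rejects equal
variances at α = 0.05 (the variance-inequality trigger is a package
decision); two-sided p-values; Cohen's d with pooled SD; labels ns/*/**/***
at 0.05/0.01/0.001 with p = 0.05 counting as significant; effect labels at
|d| = 0.2/0.4/0.6. No multiple-testing correction by default (an optional
Benjamini–Hochberg column is available). Biclustering z-normalises columns,
uses 1 − Pearson r distance and average linkage on both axes;
zero-variance rows are treated as uncorrelated (distance 1). Partial
correlations come from the inverse covariance, with Ledoit–Wolf shrinkage
auto-enabled when features ≥ samples.

Classification: deterministic feature selection (absolute standardized mean
difference ranking, then greedy removal of features with |r| > 0.9 to a kept
feature), stratified 5-fold CV repeated 5 times with class-stratified
bootstrap resampling of each training fold, out-of-fold probabilities
averaged per sample, confusion at a 0.5 cut, AUC on the pooled
probabilities. Models are scikit-learn estimators behind the module surface;
the "forward-pruned tree" is a pre-pruned decision tree (depth ≤ 3, leaf
≥ 3). A neural network is deliberately omitted by default — too fragile at
n ≈ 45. All metrics derive exactly from confusion counts and are
prevalence-unweighted.

## Numerical and degenerate-input choices

Exact-tie windows resolve to the earliest; all-zero series flag rather than
error inside fits but error at preconditions (empty tables, <4 points,
non-positive controls); NaN is the sentinel for undefined ratios and is
excluded from aggregates; CSV floats are written as shortest round-trip repr
(fingerprints) or 12 significant digits (bulk artifacts), and read back with
round-trip parsing so write→read is exact. Every stochastic component takes
a single integer seed; reruns are byte-identical.

## Known limitations

No inner-filter or temperature corrections; no separate Km/kcat estimation;
enzymes absent from the specificity matrix land in the unattributed residual
by construction; the cohort simulator's acceptance band (median AUC > 0.8)
is run at reduced size (15/10 subjects, 5 seeds) to keep the default test
suite fast.
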