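# pepfinger

Multiplexed FRET-peptide protease **fingerprinting** for oral-disease
diagnostics: a tested, reproducible pipeline from raw plate-reader time
courses to kinetic rates, inhibitor-resolved proteolytic fingerprints,
enzyme-activity deconvolution, cohort statistics and caries-status
classification.

## The problem and the approach

Saliva carries a dense mixture of host and microbial proteases; in active
dental caries the balance of matrix-metalloprotease (MMP) and
cysteine/serine/calpain (CSC) activity shifts. Rather than quantifying
individual enzymes, the assay measures *function*: five quenched FRET
peptides (PepA–PepE) are incubated with diluted whole-mouth saliva (1:20) or
caries-biopsy homogenate (1:750); cleavage de-quenches 5-FAM and the plate
reader records fluorescence every 5 min for 1 h. Parallel wells add
class-selective inhibitors — Batimastat (**MMPi**, metalloproteases), a
complete cocktail (**COMi**, CSC proteases), or both (**BOTHi**) — so each
sample yields a substrate × inhibitor activity fingerprint.

Under pseudo-first-order conditions ([S] ≪ Km, S0 = 200 nM) the signal of a
well follows

    F(t) = A · (1 − exp(−k_obs · t)) · exp(−λ t),
    k_obs = Σ_e (kcat/Km)[s,e] · [E]_e,

with A = gain · S0 the full-cleavage amplitude and λ a photobleaching decay.
The pipeline computes per well the assay-standard **Vmax** (maximum slope
over four consecutive timepoints, a.u./min) and the depletion-corrected
initial turnover A·k_obs; per sample it derives absolute and relative
activities, residual/inhibition percentages (residual > 100% =
*disinhibition*), MP/CSC ratios and combined-inhibitor additivity defects;
and it deconvolves effective MMP-2/-8/-9 concentrations from the
per-substrate rate vector by nonnegative least squares against the bundled
substrate × enzyme catalytic-efficiency matrix. Cohort layers add
Student/Welch comparisons with Cohen's d, Pearson biclustering,
shrinkage partial-correlation networks, and cross-validated classification
(logistic, kNN, pruned tree, random forest, stacking), including a condensed
single-peptide (PepE + inhibitors) mode.

No clinical data are distributed: a seeded simulator generates plates and
two-group cohorts with the documented effect structure, so every stage is
testable end to end.

## Worked example

```python
import numpy as np
from pepfinger import (SimulationConfig, table2_enzyme, simulate_timecourse,
                       fit_progress_curve, estimate_catalytic_efficiency,
                       build_specificity_matrix, infer_activities)

# 1 nM MMP-9 against PepB, noise-free plate physics
cfg = SimulationConfig(enzymes=[table2_enzyme("MMP9", 1.0)])
well = simulate_timecourse(cfg, "PepB", "NONE")
fit = fit_progress_curve(well.fluorescence_au, well.time_min)
print(f"k_obs   = {fit.kobs_per_s:.3e} s^-1")
print(f"kcat/Km = {estimate_catalytic_efficiency(fit.kobs_per_s, 1e-9):.3e} M^-1 s^-1")

# deconvolve a 3-enzyme mixture from its rate vector
m = build_specificity_matrix()
mix_nM = np.array([0.5, 0.25, 0.25])
est = infer_activities(m.eff @ (mix_nM * 1e-9), m)
print(est.as_dict())
```

prints

```
k_obs   = 8.500e-04 s^-1
kcat/Km = 8.500e+05 M^-1 s^-1
{'MMP2': 0.5, 'MMP8': 0.25, 'MMP9': 0.25}
```

— the progress-curve fit recovers the generative pseudo-first-order rate, the
division by [E] = 1 nM returns the catalogued catalytic efficiency of MMP-9
against PepB (8.5 × 10⁵ M⁻¹ s⁻¹), and the nonnegative deconvolution returns
the planted mixture exactly on noise-free input.

## Analysis drivers and CLI

The numbered scripts under `analysis/` run the full study narrative on the
default simulated cohort (32 caries / 13 healthy, seeded), writing tables to
`results/analysis/`:

```bash
python analysis/01_simulate_cohort.py     # plates, layout, generative truth
python analysis/02_fit_kinetics.py        # per-well Vmax, k_obs, QC flags
python analysis/03_fingerprints.py        # fingerprints + biopsy enrichment
python analysis/04_deconvolve_activities.py
python analysis/05_group_statistics.py    # comparisons, biclusters, network
python analysis/06_classify.py            # full panel vs condensed PepE
```

The same stages are available as a CLI (`pepfinger simulate|fit|fingerprint|
deconvolve|stats|classify|run-all`, with `--config run.yaml --seed N
--outdir DIR`) and as the library function `pepfinger.run(config, stages)`.
Reruns with the same config and seed are byte-identical.

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch —
simulating the default cohort from the given seed, fitting every well,
fingerprinting, deconvolving, computing cohort statistics and evaluating the
classifier — and writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Intermediate artifacts are staged under `scratch/acceptance_run/`.
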