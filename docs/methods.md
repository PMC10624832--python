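# Methods

## The two-state fast-exchange model

The J-domain (JD) of DNAJB6 equilibrates between an inhibited conformation
*I*, in which helix V of the GF region docks onto the JD and occludes the
HPD motif, and a free conformation *F* with helix V undocked. When the
interconversion rate k_ex greatly exceeds the chemical-shift difference
Δω between the states, each cross-peak appears at the population-weighted
average position

    δ_obs = p_I δ_I + p_F δ_F,     p_I + p_F = 1.

Destabilizing mutations therefore move peaks *linearly* between the two
endpoint spectra: the fully inhibited JD-GF construct (δ_I) and the isolated
JD (δ_F). The model assumes (i) exactly two exchanging states, (ii) fast
exchange for every reporter, and (iii) that the mutation does not itself
reshape the endpoint structures except locally around the mutated residue.
Assumption (iii) is why residues near the mutation are excluded; assumption
(i) is monitored, not enforced — see the dispersion warning below.

## Per-residue estimator: 2-D projection

The population equation holds per nucleus, but each amide gives two coupled
observations (¹H and ¹⁵N). Rather than solving each nucleus separately and
reconciling, both are combined into one estimate per residue by working in
the composite-scaled plane

    u = (δ_H, δ_N / w),   w = 5 (the standard amide ¹⁵N down-weighting),

so distances in u-space match the combined-CSP metric. The variant peak
u_M is orthogonally projected onto the segment u_I → u_F:

    p_F = (u_M − u_I)·(u_F − u_I) / |u_F − u_I|²,

with the perpendicular residual |u_M − u_I − p_F (u_F − u_I)| kept as an
off-line diagnostic and |u_F − u_I| as the endpoint separation. This is the
least-squares solution under isotropic noise in u-space and reduces exactly
to the scalar equation when the noise is zero. A unit test verifies the
projection against an independent brute-force 1-D grid minimization
(step 10⁻⁴ over p ∈ [−0.5, 1.5]) on random geometries.

## Reporter selection and aggregation

A residue reports on the equilibrium only if its two endpoints are
distinguishable and its peak actually lies on the I→F line. Defaults
(all configurable via `ReporterCriteria` or the study config):

| parameter | default | meaning |
|---|---|---|
| `min_separation` | 0.05 ppm (composite) | endpoints closer than this cannot resolve p_F |
| `max_off_line_abs` / `max_off_line_frac` | 0.02 ppm / 0.15 | off-line when perpendicular residual > max(abs, frac·separation) |
| `exclusion_window` | ±2 residues | local perturbation by the mutation itself |
| `segments` | none | optional whitelist (e.g. helices II and III) when tables carry annotation |

Each rejected residue carries a single reason with fixed priority
missing_data > near_mutation > separation_too_small > off_line (residues
excluded by the optional segment whitelist get the distinct reason
`off_segment`), and every decision is logged so the reporter set is
auditable. Accepted raw p_F values are averaged; the result is reported as
mean ± SEM (sample SD / √n). Raw values outside [0, 1] are retained and
averaged unclipped — they arise from noise, and clipping would bias the mean
toward the interior; opt-in clipping is deliberately not the default. An
empty reporter set is an error, never a silent NaN. If the per-residue SD
exceeds 0.25 a warning flags likely non-two-state behavior; the module
asserts, but cannot test, the fast-exchange assumption.

## Exchange-rate bound

Fast exchange requires k_ex ≫ Δω of the largest shift difference between
the endpoint spectra. `exchange_lower_bound` finds the residue maximizing
|Δδ| for a chosen nucleus, converts it to Δν (Hz) at that nucleus's Larmor
frequency (γ_N/γ_H = 0.101368, γ_C/γ_H = 0.251450), and reports
k_ex,min = 2πΔν under the default angular convention; the linear convention
(Δν itself) is also available because the field's usage varies. Both are
bounds, not estimates: observing averaged peaks only says k_ex is well above
this number.

## CSP and intensity mapping

Amide CSPs use Δδ = √(Δδ_H² + (Δδ_N/5)²); methyl CSPs use
√((Δδ_H/α)² + (Δδ_C/β)²) with per-methyl-type α (¹H SD) and β (¹³C SD)
shipped as an editable TSV resource of representative values derived from
BMRB chemical-shift statistics — they are configuration, not ground truth,
and users with their own statistics should point `load_methyl_sd` at them.
LEU δ and VAL γ stereo pairs are collapsed by averaging because peak lists
name them inconsistently. Significance is mean + k·SD over all entries
(k = 1 default); sample SD (n−1) is the default flavor since the choice is
otherwise unconstrained, with population SD available. Mean and SD are
computed over all residues, untrimmed — including any already-perturbed
ones — which makes the threshold slightly conservative when perturbations
are widespread.

Intensity mapping flags residues with I/I₀ below mean − k·SD (same SD
conventions, same untrimmed-mean caveat). Inputs are assumed pre-normalized;
no reference-peak or concentration correction is applied. Residues with an
assigned H but missing N (or vice versa) are excluded from CSPs, never
imputed.

## Assay fits

* **Calibration**: OLS line through the five Pi standards; residual SD
  reported. Rates are invariant to common rescaling of all fluorescence.
* **Initial rate**: fluorescence → nM Pi via the calibration, then the OLS
  slope over the default 0–20 min window (the densely sampled part of the
  plate schedule: reads every 40 s for 20 min, then every 2 min to 60 min).
* **One-site isotherm**: r(L) = r_free + (r_bound − r_free)·L/(K_D + L),
  fit by nonlinear least squares (lmfit). Ligand depletion is ignored
  (tracer ~100 nM vs µM–mM titrant). Two ill-posed regimes are flagged
  rather than hidden: a flat isotherm is reported as K_D > max(L) (a bound,
  not a point estimate), and a fit with all L ≫ K_D is noted as having a
  degenerate r_free. The transition-detection gate compares the isotherm
  amplitude to a robust noise scale (median absolute successive difference
  / 0.6745) and requires amplitude > 3× noise.
* **Aggregation**: baseline and plateau are means over the first/last 10%
  of the time span unless windows are given; t₁/₂ is the first linear-interp
  crossing of (baseline + plateau)/2; the lag time is the intersection of
  the maximal-slope tangent with the baseline level (an alternative
  10%-of-amplitude definition exists in the literature; the tangent
  construction was chosen because it is parameter-free and standard for
  sigmoidal amyloid kinetics). Both are invariant under affine transforms
  of the signal. Light-scattering traces reuse the same definitions.
* **Melt**: T_m is the temperature of the interior maximum of the
  Savitzky–Golay-smoothed first derivative (window 5, order 2,
  configurable); a flat derivative (linear baseline drift only) is an
  error, and a secondary interior peak above half the main peak triggers a
  two-transition warning.

## Synthetic data: what it emulates and what it does not

The generator (`SyntheticSpec`, one `numpy.random.default_rng(seed)` PCG64
stream, fixed draw order, fully deterministic across platforms) emulates:
inhibited amide peaks uniform in ¹H 6.5–10 / ¹⁵N 105–135 ppm; free-state
displacements with composite magnitude uniform in 0.05–0.5 ppm and random
direction; variants placed exactly on the I→F line at p_F with Gaussian
peak-position noise (defaults σ_H = 0.01, σ_N = 0.05 ppm — typical HSQC
reproducibility) and optional perpendicular displacement for a configurable
fraction of residues; log-normal peak heights (σ = 0.02 log units) with a
fixed fractional intensity loss on binding-site residues; and the four
assay read-outs with additive Gaussian noise on the instrument schedules.
Default study conditions mirror the real experiment: 21 reporter-quality
residues for population fits, a basal ATPase rate of 0.2 nM Pi·min⁻¹,
calibration slope 2 FU/nM, K_D values on the 1.5–290 µM ladder, a logistic
aggregation midpoint at 150 min, and T_m = 55 °C.

It does **not** emulate: lineshapes or any exchange-regime broadening
(slow/intermediate exchange shifts and broadens peaks in ways no projection
can rescue), peak overlap and misassignment, temperature/pH-dependent shift
drifts, correlated noise between residues, baseline drift in kinetic traces,
or secondary aggregation pathways. Passing tests therefore demonstrate
estimator correctness under the stated noise model, not robustness to
pathologies of real spectra; on real data the off-line filter is the main
guard against exactly those pathologies.

## Numerical and design choices

* Residue numbering is author numbering as deposited (isoform b); readers
  never renumber but accept a per-table `residue_offset` for deposits with
  shifted numbering frames.
* The TSV dialect serializes shifts with `repr`, so write→read round trips
  are bit-exact (tested by property).
* `field_mhz` defaults to 600.13 when a file carries no field metadata.
* Zero endpoint separation yields an undefined p_F reported as
  `separation_too_small`, never a division error.
* SEM with a single reporter is reported as 0 (undefined variance); the
  pipeline requires ≥ 2 reporters before quoting uncertainty-bearing
  results.
* Aggregated study output is JSON with sorted keys, so identical inputs and
  seed reproduce byte-identical summaries.
* The orchestrator adds no numeric transformation: summary values equal
  stage outputs exactly.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the study's natural scale: 21-residue reporter sets, 200-replicate
recovery/coverage ensembles, 100-instance oracle comparisons, 100-seed
calibration ensembles, 60–75-residue intensity maps, 12-point titrations
and ~180-point kinetic traces. The whole suite completes in a few seconds.

## Known limitations

Three-state or intermediate-exchange systems violate the core assumption and
are out of scope (the dispersion warning is the only tell). The exchange
bound depends on which residue happens to show the largest endpoint
difference, so it is only as good as the reference tables' coverage.
Methyl α/β defaults are representative, not authoritative. The one-site fit
reports asymptotic standard errors only. Per-dataset p_Free estimates from
different experiment types (amide vs methyl) are reported separately and
never reconciled into a single number.
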