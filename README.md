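# jdpop

NMR population analysis of J-domain autoinhibition in the DNAJB6 chaperone.

DNAJB6 is an Hsp70 co-chaperone whose J-domain is autoinhibited: the fifth
helix of its glycine/phenylalanine-rich (GF) region docks onto the J-domain
and blocks the HPD motif that triggers Hsp70 ATP hydrolysis.
Disease mutations (limb-girdle muscular dystrophy D1) loosen this dock, and
because docked and undocked conformations interconvert rapidly, each NMR
cross-peak of a mutant sits at the population-weighted average position of
the two states:

```
δ_obs = p_I·δ_I + p_F·δ_F ,   p_I + p_F = 1
```

`jdpop` turns that observation into numbers. Given assigned chemical-shift
tables for a variant and for the two reference states — the fully inhibited
JD-GF construct (state *I*) and the isolated, free J-domain (state *F*) — it
estimates the open-state population p_Free per residue by orthogonal
projection in the composite-scaled plane (δ_H, δ_N/5), filters reporter
residues (endpoint separation, deviation from the I→F line, distance from
the mutation site), and reports mean ± SEM over the reporters. Around this
core it provides:

- **CSP mapping** — combined amide `√(Δδ_H² + (Δδ_N/5)²)` and per-methyl-type
  SD-scaled perturbations, with mean + k·SD significance flags;
- **intensity binding-site mapping** — bound/free peak ratios I/I₀, residues
  more than 1 SD below the mean flagged as broadened, summarized by
  structural segment;
- **fast-exchange rate bounds** — k_ex ≫ 2πΔν from the largest reference
  shift difference;
- **functional-assay fits** — PBP phosphate-release calibration and
  steady-state ATPase initial rates with fold-activation, one-site binding
  isotherms (K_D), aggregation half-times and lag times, melt T_m;
- **a seeded synthetic-data generator** that emulates all of the above, so
  every stage is testable without any downloads;
- **an orchestrated study runner** (config file or `jdpop` CLI) plus
  structure–function correlation (p_Free vs activation or K_D).

Shift tables are read from a fixed TSV dialect or from NMR-STAR v3
assigned-chemical-shift saveframes as deposited in the BMRB.

## Worked example

```python
from jdpop import SyntheticSpec, fit_pfree_pipeline, gen_mutant_shifts, gen_reference

spec = SyntheticSpec(seed=42, n_residues=21, p_f_true=0.67,
                     noise_h=0.01, noise_n=0.05, mutation_site=200)
rng = spec.rng()
reference = gen_reference(spec, rng)
variant = gen_mutant_shifts(reference, spec, rng, label="P96R-like")
est = fit_pfree_pipeline(variant, reference, mutation_site=200)
print(est.p_f_mean, est.p_f_sem, est.n_reporters)
```

prints

```
p_Free = 0.650 +/- 0.014 (mean +/- SEM over 21 reporter residues)
```

i.e. a variant generated with two thirds of its molecules in the open state
is recovered within noise, with the SEM quantifying per-residue scatter of
the projections. The scripts in `examples/` walk through each capability
(population fitting, CSP mapping, binding-site mapping, assay fits, a full
orchestrated study) and print annotated output; for instance
`examples/functional_assays.py` ends with

```
basal rate       0.200 nM Pi/min
stimulated rate  1.740 nM Pi/min -> 8.7-fold activation
K_D = 9.00 uM (r_free 0.050, r_bound 0.250)
aggregation t_1/2 = 150.0 min, lag = 129.6 min
T_m = 55.0 degC
```

## Command line

A thin CLI wraps the same functions:

```
jdpop synth --out study/ --seed 1      # write a synthetic study directory
jdpop run --config study.cfg           # full orchestrated run
jdpop popfit --mutant m.tsv --inhibited i.tsv --free f.tsv --mutation-site 96
jdpop csp / intensity / assays / correlate ...
```

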