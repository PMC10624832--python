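"""Estimate the open-state population p_Free of a destabilized variant.

Builds a synthetic two-state reference pair (inhibited JD-GF-like and free
JD-like shift tables), places a variant at p_Free = 0.67 with realistic HSQC
peak-position noise, and recovers the population by projecting each
reporter's peak onto its inhibited->free line.
"""

from dataclasses import replace

from jdpop import SyntheticSpec, fit_pfree_pipeline, gen_mutant_shifts, gen_reference

spec = SyntheticSpec(seed=42, n_residues=21, p_f_true=0.67,
                     noise_h=0.01, noise_n=0.05, mutation_site=200)
rng = spec.rng()
reference = gen_reference(spec, rng)
variant = gen_mutant_shifts(reference, spec, rng, label="P96R-like")

estimate = fit_pfree_pipeline(variant, reference, mutation_site=200, label="P96R-like")
print(f"p_Free = {estimate.p_f_mean:.3f} +/- {estimate.p_f_sem:.3f} "
      f"(mean +/- SEM over {estimate.n_reporters} reporter residues)")
print(f"p_Inhibited = {estimate.p_i_mean:.3f}")
print(estimate.report_frame().head(8).to_string(index=False))

# p_Free ~ 0.67 means two thirds of the molecules have the inhibitory GF
# helix undocked from the J-domain; the SEM reflects per-residue scatter of
# the projections, and the report lists every residue with its filter verdict.
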