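"""Run a complete study end-to-end and correlate structure with function.

Writes a synthetic study directory (references, a ladder of variants,
intensity pair), runs the orchestrated pipeline from a config file, and
correlates the recovered p_Free values with a functional read-out.
"""

import tempfile
from pathlib import Path

from jdpop import PopulationEstimate, StudyConfig, SyntheticSpec, correlate_populations, run_study
from jdpop.synthetic import write_study

workdir = Path(tempfile.mkdtemp(prefix="jdpop_study_"))
spec = SyntheticSpec(seed=19, n_residues=40, mutation_site=200)
ladder = (0.06, 0.37, 0.67, 0.91, 0.95)
manifest = write_study(spec, workdir / "data", p_f_ladder=ladder)

cfg_lines = ["[references]",
             f"inhibited = {manifest['reference_inhibited']}",
             f"free = {manifest['reference_free']}",
             "[variants]"]
sites = ["[mutation_sites]"]
for p, path in manifest["variants"].items():
    cfg_lines.append(f"p{p} = {path}")
    sites.append(f"p{p} = 200")
cfg_lines += sites + ["[options]", f"outdir = {workdir / 'out'}"]
(workdir / "study.cfg").write_text("\n".join(cfg_lines) + "\n")

summary = run_study(StudyConfig.from_file(workdir / "study.cfg"))
print("variant   p_Free (est)   SEM     n")
for label, v in sorted(summary["variants"].items()):
    print(f"{label:8s}  {v['p_f_mean']:.3f}        {v['p_f_sem']:.3f}  {v['n_reporters']}")

ests = [PopulationEstimate(l, v["p_f_mean"], v["p_f_sem"], v["n_reporters"])
        for l, v in summary["variants"].items()]
functional = {f"p{p}": 0.2 + 1.6 * p for p in ladder}  # activation-like read-out
rep = correlate_populations(ests, functional)
print(f"\np_Free vs activation: Pearson {rep.pearson:.3f}, Spearman {rep.spearman:.3f}")
print(f"outputs in {workdir / 'out'}")

# Each recovered p_Free sits within noise of its generating value, and the
# functional read-out correlates with the degree of J-domain opening — the
# structural signature of unregulated chaperone activation.
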