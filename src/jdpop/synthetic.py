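"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Every generator draws from one ``numpy.random.default_rng(seed)`` stream
(PCG64) in a fixed order, so a seed pins the entire synthetic study.  What is
emulated, per stage:

* two-state fast-exchange amide shifts: an inhibited reference with peaks in
  realistic amide ranges (1H 6.5-10 ppm, 15N 105-135 ppm), a free reference
  displaced by a composite-plane vector whose magnitude is drawn from a
  configurable separation range, and variants placed at
  delta_I + p_F * (delta_F - delta_I) per nucleus plus Gaussian peak-position
  noise (optionally with a fraction of residues pushed off the I->F line);
* residue-selective intensity loss on partner binding: log-normal peak
  heights, attenuated by a fixed depth on the binding-site residues;
* assay read-outs: linear Pi accumulation pushed back through a fluorescence
  calibration on the plate-reader schedule (every 40 s for 20 min, then every
  2 min for 40 min), one-site anisotropy isotherms, logistic aggregation
  traces and sigmoidal thermal melts, each with additive Gaussian noise.

Generators write the same TSV dialect the readers consume, so fixtures are
self-hosting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .assays import BindingIsotherm, CalibrationCurve, KineticTrace
from .csp import DEFAULT_NITROGEN_WEIGHT
from .io import IntensityTable, ShiftRecord, ShiftTable, write_shift_table
from .popfit import TwoStateReference

# default segment annotation loosely following a four-helix J-domain + GF
DEFAULT_SEGMENTS = {
    "helix I": (6, 17),
    "helix II": (19, 32),
    "HPD loop": (33, 36),
    "helix III": (38, 55),
    "helix IV": (57, 66),
    "GF 70-74": (70, 74),
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study; defaults mirror the real one.

    Shift noise defaults (sigma_H 0.01 ppm, sigma_N 0.05 ppm) are typical
    HSQC peak-position reproducibility; 21 reporter-quality residues and
    composite endpoint separations of 0.05-0.5 ppm match the reporter set
    the population fit expects to see.
    """

    seed: int = 0
    n_residues: int = 60
    p_f_true: float = 0.5
    separation_range: tuple[float, float] = (0.05, 0.5)
    noise_h: float = 0.01  # ppm
    noise_n: float = 0.05  # ppm
    mutation_site: int = 50
    off_line_fraction: float = 0.0
    off_line_displacement: float = 0.2  # composite ppm, perpendicular
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT
    field_mhz: float = 600.13
    # intensity mapping; None = binding-competent segments (helix II end,
    # HPD loop, helix III start, GF 70-74) clipped to the residue range
    binding_site: tuple[int, ...] | None = None
    broadening_depth: float = 0.8
    intensity_noise: float = 0.02  # log-scale SD
    # assays
    atpase_rate: float = 0.2  # nM Pi / min (basal Hsp70 scale)
    cal_slope: float = 2.0  # FU per nM Pi
    cal_intercept: float = 100.0
    cal_noise: float = 0.0  # FU
    atpase_noise: float = 0.0  # FU
    kd: float = 9.0  # uM
    r_free: float = 0.05
    r_bound: float = 0.25
    anisotropy_noise_frac: float = 0.0  # fraction of amplitude
    agg_baseline: float = 100.0
    agg_plateau: float = 1100.0
    agg_midpoint: float = 150.0  # min
    agg_steepness: float = 10.0  # min
    agg_noise: float = 0.0
    melt_tm: float = 55.0  # degC
    melt_width: float = 2.0
    melt_noise: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_f_true <= 1.0:
            raise ValueError(f"p_f_true must be in [0, 1], got {self.p_f_true}")
        if self.noise_h < 0 or self.noise_n < 0:
            raise ValueError("noise must be >= 0")
        if not 0.0 <= self.broadening_depth < 1.0:
            raise ValueError("broadening_depth must be in [0, 1)")
        lo, hi = self.separation_range
        if hi < lo or lo < 0:
            raise ValueError("invalid separation_range")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _amide_records(h: np.ndarray, n: np.ndarray, residues) -> list[ShiftRecord]:
    recs = []
    for res, hh, nn in zip(residues, h, n):
        recs.append(ShiftRecord(int(res), "XXX", "H", float(hh)))
        recs.append(ShiftRecord(int(res), "XXX", "N", float(nn)))
    return recs


def gen_reference(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> TwoStateReference:
    """Inhibited + free reference tables for the two-state model.

    Free-state peaks are displaced from the inhibited ones by a random
    direction in the composite-scaled plane with magnitude drawn uniformly
    from ``separation_range``.
    """
    if spec.n_residues < 2:
        raise ValueError("need >= 2 residues")
    lo, hi = spec.separation_range
    if hi == 0.0 and lo == 0.0:
        raise ValueError("separation_range collapses to zero: no exchange axis")
    rng = rng or spec.rng()
    residues = np.arange(1, spec.n_residues + 1)
    h_i = rng.uniform(6.5, 10.0, spec.n_residues)
    n_i = rng.uniform(105.0, 135.0, spec.n_residues)
    sep = rng.uniform(lo, hi, spec.n_residues)
    theta = rng.uniform(0.0, 2.0 * np.pi, spec.n_residues)
    # displacement defined in the scaled plane, mapped back to raw ppm
    h_f = h_i + sep * np.cos(theta)
    n_f = n_i + sep * np.sin(theta) * spec.nitrogen_weight
    inhibited = ShiftTable(
        "synthetic-inhibited", "WT-JDGF-like", _amide_records(h_i, n_i, residues),
        field_mhz=spec.field_mhz, segments=dict(DEFAULT_SEGMENTS),
    )
    free = ShiftTable(
        "synthetic-free", "JD-like", _amide_records(h_f, n_f, residues),
        field_mhz=spec.field_mhz, segments=dict(DEFAULT_SEGMENTS),
    )
    return TwoStateReference(inhibited=inhibited, free=free)


def gen_mutant_shifts(
    ref: TwoStateReference, spec: SyntheticSpec, rng: np.random.Generator | None = None,
    label: str | None = None,
) -> ShiftTable:
    """Variant table at p_f_true along each residue's I->F line, plus noise.

    ``off_line_fraction`` of the residues are additionally displaced
    perpendicular to their I->F line (exercising the off-line filter).
    With zero noise and zero off-line fraction the estimator round-trips
    p_f_true exactly.
    """
    rng = rng or spec.rng()
    p = spec.p_f_true
    w = spec.nitrogen_weight
    residues = sorted(set(ref.inhibited.residues()) & set(ref.free.residues()))
    n_off = int(round(spec.off_line_fraction * len(residues)))
    off = set(rng.choice(residues, size=n_off, replace=False).tolist()) if n_off else set()
    recs = []
    for res in residues:
        hi_, ni_ = ref.inhibited.shift(res, "H"), ref.inhibited.shift(res, "N")
        hf_, nf_ = ref.free.shift(res, "H"), ref.free.shift(res, "N")
        h = hi_ + p * (hf_ - hi_) + rng.normal(0.0, spec.noise_h)
        n = ni_ + p * (nf_ - ni_) + rng.normal(0.0, spec.noise_n)
        if res in off:
            # unit perpendicular to the I->F direction in the scaled plane
            d = np.array([hf_ - hi_, (nf_ - ni_) / w])
            norm = np.linalg.norm(d)
            if norm > 0:
                perp = np.array([-d[1], d[0]]) / norm * spec.off_line_displacement
                h += perp[0]
                n += perp[1] * w
        recs.append(ShiftRecord(res, "XXX", "H", float(h)))
        recs.append(ShiftRecord(res, "XXX", "N", float(n)))
    return ShiftTable(
        label or f"synthetic-mutant-p{p:g}", label or f"mutant-p{p:g}", recs,
        field_mhz=spec.field_mhz, segments=dict(DEFAULT_SEGMENTS),
    )


def gen_intensity_pair(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[IntensityTable, IntensityTable]:
    """(free, bound) intensity tables with binding-site-selective loss.

    Free peak heights are log-normal around 1000 AU; bound heights keep the
    same multiplicative noise model and are attenuated by
    ``broadening_depth`` on the binding-site residues only.
    """
    rng = rng or spec.rng()
    residues = np.arange(1, spec.n_residues + 1)
    if spec.binding_site is None:
        default = (28, 29, 30, 31, 32, 33, 34, 35, 36, 38, 39, 40, 70, 71, 72)
        site = {r for r in default if r <= spec.n_residues}
    else:
        site = set(spec.binding_site)
        bad = site - set(residues.tolist())
        if bad:
            raise ValueError(f"binding_site residues outside range: {sorted(bad)}")
    free_vals = 1000.0 * np.exp(rng.normal(0.0, spec.intensity_noise, spec.n_residues))
    ratio_noise = np.exp(rng.normal(0.0, spec.intensity_noise, spec.n_residues))
    depth = np.where(np.isin(residues, list(site)), 1.0 - spec.broadening_depth, 1.0)
    bound_vals = free_vals * depth * ratio_noise
    free = IntensityTable(
        "synthetic-free-int", "free", {int(r): float(v) for r, v in zip(residues, free_vals)}
    )
    bound = IntensityTable(
        "synthetic-bound-int",
        "bound Hsp70-like 1:1",
        {int(r): float(v) for r, v in zip(residues, bound_vals)},
    )
    return free, bound


def atpase_schedule() -> np.ndarray:
    """Plate-reader time axis: every 40 s for 20 min, then every 2 min to 60 min."""
    first = np.arange(0.0, 20.0 + 1e-9, 40.0 / 60.0)
    second = np.arange(22.0, 60.0 + 1e-9, 2.0)
    return np.concatenate([first, second])


def gen_calibration_standards(
    spec: SyntheticSpec, rng: np.random.Generator | None = None,
    concentrations=(0.0, 100.0, 200.0, 300.0, 400.0),
) -> np.ndarray:
    """Five Pi standards (nM, FU) on the plate's linear PBP response."""
    rng = rng or spec.rng()
    conc = np.asarray(concentrations, dtype=float)
    fluor = spec.cal_intercept + spec.cal_slope * conc
    if spec.cal_noise > 0:
        fluor = fluor + rng.normal(0.0, spec.cal_noise, conc.size)
    return np.column_stack([conc, fluor])


def gen_atpase_trace(
    spec: SyntheticSpec, rng: np.random.Generator | None = None, rate: float | None = None
) -> KineticTrace:
    """Linear Pi accumulation mapped through the calibration to fluorescence."""
    rng = rng or spec.rng()
    t = atpase_schedule()
    pi = (rate if rate is not None else spec.atpase_rate) * t
    fluor = spec.cal_intercept + spec.cal_slope * pi
    if spec.atpase_noise > 0:
        fluor = fluor + rng.normal(0.0, spec.atpase_noise, t.size)
    return KineticTrace(time=t, signal=fluor, signal_unit="FU")


def gen_isotherm(
    spec: SyntheticSpec, rng: np.random.Generator | None = None, n_points: int = 12,
    max_conc: float = 1000.0,
) -> BindingIsotherm:
    """One-site anisotropy titration, log-spaced up to ``max_conc`` uM plus a
    zero point."""
    rng = rng or spec.rng()
    conc = np.concatenate([[0.0], np.geomspace(max_conc / 10 ** (n_points / 4), max_conc, n_points)])
    r = spec.r_free + (spec.r_bound - spec.r_free) * conc / (spec.kd + conc)
    if spec.anisotropy_noise_frac > 0:
        amp = abs(spec.r_bound - spec.r_free)
        r = r + rng.normal(0.0, spec.anisotropy_noise_frac * amp, conc.size)
    return BindingIsotherm(ligand_conc=conc, anisotropy=r)


def gen_aggregation_trace(
    spec: SyntheticSpec, rng: np.random.Generator | None = None,
    t_max: float = 900.0, dt: float = 5.0,
) -> KineticTrace:
    """Logistic ThT-style trace with set baseline, plateau and midpoint."""
    rng = rng or spec.rng()
    t = np.arange(0.0, t_max + 1e-9, dt)
    y = spec.agg_baseline + (spec.agg_plateau - spec.agg_baseline) / (
        1.0 + np.exp(-(t - spec.agg_midpoint) / spec.agg_steepness)
    )
    if spec.agg_noise > 0:
        y = y + rng.normal(0.0, spec.agg_noise, t.size)
    return KineticTrace(time=t, signal=y, signal_unit="ThT FU")


def gen_melt_trace(
    spec: SyntheticSpec, rng: np.random.Generator | None = None,
    t_min: float = 20.0, t_max: float = 90.0, dt: float = 0.5,
) -> KineticTrace:
    """Sigmoidal fluorescence-ratio melt centered at ``melt_tm``."""
    rng = rng or spec.rng()
    t = np.arange(t_min, t_max + 1e-9, dt)
    y = 0.8 + 0.4 / (1.0 + np.exp(-(t - spec.melt_tm) / spec.melt_width))
    if spec.melt_noise > 0:
        y = y + rng.normal(0.0, spec.melt_noise, t.size)
    return KineticTrace(time=t, signal=y, time_unit="degC", signal_unit="F350/F330")


def gen_assay_traces(spec: SyntheticSpec) -> dict:
    """All four assay read-outs from one seed, in a fixed draw order."""
    rng = spec.rng()
    return {
        "calibration": gen_calibration_standards(spec, rng),
        "atpase": gen_atpase_trace(spec, rng),
        "isotherm": gen_isotherm(spec, rng),
        "aggregation": gen_aggregation_trace(spec, rng),
        "melt": gen_melt_trace(spec, rng),
    }


def write_study(spec: SyntheticSpec, outdir: str | Path,
                p_f_ladder=(0.06, 0.18, 0.37, 0.67, 0.91, 0.95)) -> dict:
    """Write a complete synthetic study directory: the two references,
    variants at each ladder p_F, an intensity pair, and assay traces, all in
    the TSV dialects the readers consume.  Returns a manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = spec.rng()
    ref = gen_reference(spec, rng)
    write_shift_table(ref.inhibited, outdir / "reference_inhibited.tsv")
    write_shift_table(ref.free, outdir / "reference_free.tsv")
    manifest = {
        "reference_inhibited": str(outdir / "reference_inhibited.tsv"),
        "reference_free": str(outdir / "reference_free.tsv"),
        "variants": {},
    }
    for p in p_f_ladder:
        vspec = replace(spec, p_f_true=p)
        table = gen_mutant_shifts(ref, vspec, rng, label=f"variant-p{p:g}")
        path = outdir / f"variant_p{int(round(p * 100)):03d}.tsv"
        write_shift_table(table, path)
        manifest["variants"][f"{p:g}"] = str(path)
    free, bound = gen_intensity_pair(spec, rng)
    for tbl, name in ((free, "intensity_free.tsv"), (bound, "intensity_bound.tsv")):
        lines = ["residue_number\tintensity"] + [
            f"{r}\t{tbl.entries[r]!r}" for r in tbl.residues()
        ]
        (outdir / name).write_text("\n".join(lines) + "\n")
    manifest["intensity_free"] = str(outdir / "intensity_free.tsv")
    manifest["intensity_bound"] = str(outdir / "intensity_bound.tsv")
    assays = gen_assay_traces(spec)
    np.savetxt(
        outdir / "calibration.tsv", assays["calibration"], delimiter="\t",
        header="conc_nM\tfluorescence", comments="",
    )
    for key in ("atpase", "aggregation", "melt"):
        tr = assays[key]
        np.savetxt(
            outdir / f"{key}.tsv", np.column_stack([tr.time, tr.signal]), delimiter="\t",
            header=f"time_{tr.time_unit}\tsignal", comments="",
        )
        manifest[key] = str(outdir / f"{key}.tsv")
    iso = assays["isotherm"]
    np.savetxt(
        outdir / "isotherm.tsv", np.column_stack([iso.ligand_conc, iso.anisotropy]),
        delimiter="\t", header="conc_uM\tanisotropy", comments="",
    )
    manifest["calibration"] = str(outdir / "calibration.tsv")
    manifest["isotherm"] = str(outdir / "isotherm.tsv")
    return manifest
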