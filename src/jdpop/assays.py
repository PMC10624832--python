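"""Functional-assay fits: ATPase rates, binding isotherms, aggregation, melts.

Four independent read-outs accompany the NMR populations:

* steady-state Hsp70 ATPase activity, measured as phosphate release via the
  fluorescent PBP sensor — a linear calibration converts fluorescence to nM
  Pi, and the initial rate is the least-squares slope over an early window;
* fluorescence-anisotropy titrations fit to a one-site binding model
  r(L) = r_free + (r_bound - r_free) * L / (K_D + L), valid when the tracer
  is dilute relative to the titrant (no ligand depletion);
* aggregation kinetics (ThT fluorescence or light scattering): t_1/2 is the
  first time the signal crosses halfway between the baseline and plateau
  levels; the lag time comes from the maximal-slope tangent construction;
* thermal melts: T_m is the inflection point, located as the maximum of the
  smoothed first derivative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model
from scipy import stats
from scipy.signal import argrelmax, savgol_filter


class AssayError(ValueError):
    pass


@dataclass
class CalibrationCurve:
    """Linear fluorescence-vs-[Pi] calibration (slope: FU per nM Pi)."""

    slope: float
    intercept: float
    n_points: int
    residual_sd: float

    def to_concentration(self, fluorescence: np.ndarray) -> np.ndarray:
        return (np.asarray(fluorescence, dtype=float) - self.intercept) / self.slope


@dataclass
class KineticTrace:
    """A strictly increasing time (or temperature) axis with one signal."""

    time: np.ndarray
    signal: np.ndarray
    time_unit: str = "min"
    signal_unit: str = "AU"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 3:
            raise AssayError("trace needs at least 3 points")
        if self.time.size != self.signal.size:
            raise AssayError("time and signal lengths differ")
        if not np.all(np.diff(self.time) > 0):
            raise AssayError("time axis must be strictly increasing")


@dataclass
class RateResult:
    """Initial rate in nM Pi per minute over the analysis window."""

    rate: float
    window: tuple[float, float]
    rate_stderr: float = 0.0
    fold_activation: float | None = None


@dataclass
class BindingIsotherm:
    """One-site anisotropy titration, before and after fitting.

    When the signal never approaches saturation within the titration range
    the K_D is reported as a lower bound (``kd_is_lower_bound``), mirroring
    how very weak interactions are reported from anisotropy data.
    """

    ligand_conc: np.ndarray  # uM
    anisotropy: np.ndarray
    kd: float | None = None
    r_free: float | None = None
    r_bound: float | None = None
    kd_stderr: float | None = None
    kd_is_lower_bound: bool = False
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if np.any(self.ligand_conc < 0):
            raise AssayError("ligand concentrations must be non-negative")
        if self.ligand_conc.size != self.anisotropy.size:
            raise AssayError("concentration and anisotropy lengths differ")


@dataclass
class AggregationSummary:
    baseline: float
    plateau: float
    t_half: float
    lag_time: float


def fit_calibration(standards) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration nM, fluorescence)
    standards; typically the five Pi standards measured per plate."""
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise AssayError("need >= 2 (concentration, fluorescence) standards")
    conc, fluor = arr[:, 0], arr[:, 1]
    if np.ptp(conc) == 0:
        raise AssayError("all standard concentrations are equal; cannot fit a line")
    res = stats.linregress(conc, fluor)
    resid = fluor - (res.slope * conc + res.intercept)
    dof = max(len(conc) - 2, 1)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(conc),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def initial_rate(
    trace: KineticTrace, cal: CalibrationCurve, window: tuple[float, float] = (0.0, 20.0)
) -> RateResult:
    """Initial phosphate-release rate: convert fluorescence to nM Pi through
    the calibration, then take the least-squares slope over ``window``
    (default the densely sampled first 20 minutes)."""
    t0, t1 = window
    if t1 <= t0:
        raise AssayError("window must have positive width")
    mask = (trace.time >= t0) & (trace.time <= t1)
    if mask.sum() < 3:
        raise AssayError(
            f"window [{t0}, {t1}] {trace.time_unit} contains {int(mask.sum())} points (< 3)"
        )
    conc = cal.to_concentration(trace.signal[mask])
    res = stats.linregress(trace.time[mask], conc)
    return RateResult(rate=float(res.slope), window=(t0, t1), rate_stderr=float(res.stderr))


def fold_activation(stimulated: RateResult, basal: RateResult) -> float:
    """Ratio of stimulated to basal initial rates."""
    if basal.rate <= 0:
        raise AssayError(f"basal rate must be > 0, got {basal.rate}")
    return stimulated.rate / basal.rate


def _one_site(L, r_free, r_bound, kd):
    return r_free + (r_bound - r_free) * L / (kd + L)


def fit_one_site(isotherm: BindingIsotherm) -> BindingIsotherm:
    """Nonlinear least-squares fit of the one-site model.

    Flags rather than hides the two ill-posed regimes: a flat isotherm (no
    binding up to the highest concentration) is reported as K_D > max(L),
    and a fitted K_D beyond max(L) is marked lower-bound-only.  Points with
    all L >> K_D leave r_free poorly determined; a note is attached.
    """
    L = isotherm.ligand_conc
    r = isotherm.anisotropy
    if len(np.unique(L)) < 4:
        raise AssayError("need >= 4 distinct concentrations for a one-site fit")
    lmax = float(np.max(L))
    amplitude = float(np.ptp(r))
    noise_scale = _local_noise(L, r)
    out = isotherm
    if amplitude <= 3.0 * noise_scale:
        out.kd = lmax
        out.kd_is_lower_bound = True
        out.r_free = float(np.mean(r))
        out.r_bound = None
        out.notes.append(
            f"no binding transition detected up to {lmax:g} uM; K_D > {lmax:g} uM"
        )
        return out
    model = Model(_one_site)
    params = model.make_params(
        r_free=float(r[np.argmin(L)]),
        r_bound=float(r[np.argmax(L)]),
        kd=max(float(np.median(L[L > 0])) if np.any(L > 0) else 1.0, 1e-12),
    )
    params["kd"].set(min=1e-12)
    fit = model.fit(r, params, L=L)
    if not fit.success:
        raise AssayError(f"one-site fit failed: {fit.message}")
    out.kd = float(fit.params["kd"].value)
    out.r_free = float(fit.params["r_free"].value)
    out.r_bound = float(fit.params["r_bound"].value)
    out.kd_stderr = (
        float(fit.params["kd"].stderr) if fit.params["kd"].stderr is not None else None
    )
    if out.kd > lmax:
        out.kd_is_lower_bound = True
        out.notes.append(f"fitted K_D {out.kd:g} uM exceeds max titrant {lmax:g} uM; bound only")
    lmin_pos = float(np.min(L[L > 0])) if np.any(L > 0) else 0.0
    if lmin_pos and out.kd < lmin_pos / 10.0:
        out.notes.append(
            "all concentrations far above K_D; r_free poorly determined (degenerate fit)"
        )
    return out


def _local_noise(L, r) -> float:
    """Crude noise scale from successive differences along the sorted curve."""
    order = np.argsort(L)
    d = np.diff(r[order])
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d)) / 0.6745) or float(np.std(d))


def aggregation_times(
    trace: KineticTrace,
    baseline_window: tuple[float, float] | None = None,
    plateau_window: tuple[float, float] | None = None,
) -> AggregationSummary:
    """Half-time and lag time of a sigmoidal aggregation trace.

    baseline/plateau default to the first/last 10% of the time span; t_1/2
    is the first crossing of the midpoint level, linearly interpolated
    between samples; the lag time is where the maximal-slope tangent meets
    the baseline level.  Both are invariant under affine transforms of the
    signal.
    """
    t, y = trace.time, trace.signal
    span = t[-1] - t[0]
    if baseline_window is None:
        baseline_window = (t[0], t[0] + 0.1 * span)
    if plateau_window is None:
        plateau_window = (t[-1] - 0.1 * span, t[-1])
    baseline = float(np.mean(y[(t >= baseline_window[0]) & (t <= baseline_window[1])]))
    plateau = float(np.mean(y[(t >= plateau_window[0]) & (t <= plateau_window[1])]))
    if not plateau > baseline:
        raise AssayError(
            f"no transition detected: plateau ({plateau:g}) <= baseline ({baseline:g})"
        )
    level = 0.5 * (baseline + plateau)
    above = y >= level
    idx = np.nonzero(above[1:] & ~above[:-1])[0]
    if above[0]:
        t_half = float(t[0])
    elif idx.size == 0:
        raise AssayError("no transition detected: signal never crosses the midpoint level")
    else:
        i = idx[0]
        frac = (level - y[i]) / (y[i + 1] - y[i])
        t_half = float(t[i] + frac * (t[i + 1] - t[i]))
    # lag: tangent at maximal slope intersects the baseline level
    slopes = np.diff(y) / np.diff(t)
    j = int(np.argmax(slopes))
    tj = 0.5 * (t[j] + t[j + 1])
    yj = 0.5 * (y[j] + y[j + 1])
    lag = tj - (yj - baseline) / slopes[j] if slopes[j] > 0 else t[0]
    lag = float(min(max(lag, t[0]), t_half))
    return AggregationSummary(baseline=baseline, plateau=plateau, t_half=t_half, lag_time=lag)


def tm_from_inflection(melt: KineticTrace, smooth_window: int = 5) -> float:
    """Melting temperature from the inflection of a thermal-melt curve.

    The first derivative of signal vs temperature is smoothed (Savitzky-Golay,
    window ``smooth_window``) and T_m is the temperature of its interior
    maximum; a clear secondary interior peak triggers a warning.
    """
    t, y = melt.time, melt.signal
    if t.size < 7:
        raise AssayError("melt needs >= 7 points")
    dy = np.gradient(y, t)
    win = min(smooth_window if smooth_window % 2 == 1 else smooth_window + 1, t.size - 1)
    if win >= 3:
        dy = savgol_filter(dy, window_length=win, polyorder=2)
    j = int(np.argmax(dy))
    # a flat derivative (linear melt curve) has no inflection to report
    if np.ptp(dy) <= 1e-9 * max(float(np.max(np.abs(dy))), 1e-12):
        raise AssayError("derivative has no interior maximum; no melting transition")
    if j == 0 or j == t.size - 1 or dy[j] <= 0:
        raise AssayError("derivative has no interior maximum; no melting transition")
    peaks = argrelmax(dy)[0]
    secondary = [p for p in peaks if p != j and dy[p] > 0.5 * dy[j]]
    if secondary:
        warnings.warn(
            f"secondary derivative peak near T = {t[secondary[0]]:g}; "
            "possible second transition",
            stacklevel=2,
        )
    return float(t[j])
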