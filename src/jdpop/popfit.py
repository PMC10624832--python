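"""Two-state fast-exchange population estimation from chemical shifts.

The J-domain of DNAJB6 interconverts between an inhibited conformation
(GF helix V docked, state I) and a free conformation (helix V undocked,
state F).  When the interconversion is fast on the chemical-shift timescale
each cross-peak sits at the population-weighted average of the two state
positions,

    delta_obs = p_I * delta_I + p_F * delta_F,        p_I + p_F = 1,

so a variant's peaks lie on the straight line between the inhibited
reference (WT JD-GF) and the free reference (isolated JD).  Both amide
nuclei constrain a single p_F per residue: working in the composite-scaled
plane u = (delta_H, delta_N / w) (w = 5, matching the amide CSP weighting),
the per-residue estimate is the orthogonal projection of the variant's peak
onto the I->F segment,

    p_F = (u_M - u_I) . (u_F - u_I) / |u_F - u_I|^2 .

Reporter residues are then filtered (sufficient endpoint separation, small
perpendicular deviation from the I->F line, not adjacent to the mutation)
and the accepted raw p_F values are averaged; the result is reported as
mean +/- SEM over the reporters.  The same chemical-shift differences give
a lower bound on the exchange rate: fast exchange requires
k_ex >> delta_omega of the largest-shifted reporter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .csp import DEFAULT_NITROGEN_WEIGHT
from .io import ShiftTable, align_tables

# gyromagnetic ratios relative to 1H
_GAMMA_REL = {"H": 1.0, "N": 0.10136767, "C": 0.25144953}


class PopulationFitError(ValueError):
    pass


@dataclass
class TwoStateReference:
    """The two exchange endpoints: inhibited (state I) and free (state F)."""

    inhibited: ShiftTable
    free: ShiftTable

    def __post_init__(self) -> None:
        shared = set(self.inhibited.residues()) & set(self.free.residues())
        if not shared:
            raise PopulationFitError("reference tables share no residues")


@dataclass
class ResiduePopulation:
    """Raw per-residue population estimate with filter bookkeeping.

    ``p_f_raw`` may legitimately fall outside [0, 1] through noise and is
    never clipped here.  ``endpoint_separation`` and
    ``perpendicular_distance`` are in composite-scaled ppm.
    """

    residue_number: int
    p_f_raw: float | None
    endpoint_separation: float
    perpendicular_distance: float
    accepted: bool = False
    rejection_reason: str = "none"
    # one of: missing_data | near_mutation | separation_too_small | off_line
    #         | off_segment | none


@dataclass
class PopulationEstimate:
    """Aggregated open-state population for one variant."""

    variant_label: str
    p_f_mean: float
    p_f_sem: float
    n_reporters: int
    residues: list[ResiduePopulation] = field(default_factory=list)

    @property
    def p_i_mean(self) -> float:
        return 1.0 - self.p_f_mean

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_number": [r.residue_number for r in self.residues],
                "p_f_raw": [r.p_f_raw for r in self.residues],
                "separation": [r.endpoint_separation for r in self.residues],
                "distance": [r.perpendicular_distance for r in self.residues],
                "accepted": [r.accepted for r in self.residues],
                "reason": [r.rejection_reason for r in self.residues],
            }
        )

    def summary(self) -> dict:
        return {
            "variant": self.variant_label,
            "p_f_mean": self.p_f_mean,
            "p_f_sem": self.p_f_sem,
            "p_i_mean": self.p_i_mean,
            "n_reporters": self.n_reporters,
        }

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.report_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2, sort_keys=True) + "\n")


@dataclass
class ReporterCriteria:
    """Filters deciding which residues may report on the I<->F equilibrium.

    min_separation : composite ppm below which I and F are indistinguishable.
    max_off_line_abs / max_off_line_frac : a residue is off-line when its
        perpendicular distance exceeds max(abs, frac * separation).
    exclusion_window : residues within +/- this window of the mutation site
        are excluded (local structural perturbation, not equilibrium shift).
    segments : optional whitelist of segment labels (e.g. helices II and III)
        applied when the tables carry segment annotation.
    """

    min_separation: float = 0.05
    max_off_line_abs: float = 0.02
    max_off_line_frac: float = 0.15
    exclusion_window: int = 2
    segments: tuple[str, ...] | None = None

    def off_line_limit(self, separation: float) -> float:
        return max(self.max_off_line_abs, self.max_off_line_frac * separation)


@dataclass
class ExchangeBound:
    """Lower bound on the I<->F exchange rate implied by fast exchange."""

    k_ex_min: float  # s^-1
    reporter_residue: int
    delta_nu: float  # Hz
    convention: str  # "angular" (2*pi*delta_nu) or "linear" (delta_nu)
    nucleus: str
    field_mhz: float


def _scaled_point(table: ShiftTable, residue: int, w: float) -> np.ndarray | None:
    h = table.get(residue, "H")
    n = table.get(residue, "N")
    if h is None or n is None:
        return None
    return np.array([h.shift, n.shift / w])


def residue_population(
    mutant: ShiftTable,
    ref: TwoStateReference,
    residue: int,
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
) -> ResiduePopulation:
    """Project one residue's mutant peak onto its I->F segment.

    Requires H and N in all three tables; a zero-length I->F segment is
    reported as ``separation_too_small`` with undefined p_f_raw.
    """
    u_m = _scaled_point(mutant, residue, nitrogen_weight)
    u_i = _scaled_point(ref.inhibited, residue, nitrogen_weight)
    u_f = _scaled_point(ref.free, residue, nitrogen_weight)
    if u_m is None or u_i is None or u_f is None:
        return ResiduePopulation(residue, None, np.nan, np.nan, False, "missing_data")
    d = u_f - u_i
    sep = float(np.linalg.norm(d))
    if sep == 0.0:
        return ResiduePopulation(residue, None, 0.0, float(np.linalg.norm(u_m - u_i)),
                                 False, "separation_too_small")
    p = float(np.dot(u_m - u_i, d) / (sep * sep))
    perp = float(np.linalg.norm(u_m - u_i - p * d))
    return ResiduePopulation(residue, p, sep, perp)


def select_reporters(
    populations: list[ResiduePopulation],
    mutation_site: int,
    criteria: ReporterCriteria | None = None,
    segment_of=None,
) -> list[ResiduePopulation]:
    """Accept/reject each residue, assigning a single rejection reason.

    Reason priority: missing_data > near_mutation > separation_too_small >
    off_line.  ``segment_of`` (residue -> label or None) applies the optional
    segment whitelist.  Raises if nothing survives — aggregation must never
    proceed silently on an empty reporter set.
    """
    criteria = criteria or ReporterCriteria()
    out = []
    for r in populations:
        reason = "none"
        if r.p_f_raw is None or r.rejection_reason == "missing_data":
            reason = "missing_data"
        elif abs(r.residue_number - mutation_site) <= criteria.exclusion_window:
            reason = "near_mutation"
        elif r.endpoint_separation < criteria.min_separation:
            reason = "separation_too_small"
        elif r.perpendicular_distance > criteria.off_line_limit(r.endpoint_separation):
            reason = "off_line"
        elif criteria.segments is not None:
            seg = segment_of(r.residue_number) if segment_of else None
            if seg not in criteria.segments:
                reason = "off_segment"
        out.append(
            ResiduePopulation(
                r.residue_number,
                r.p_f_raw,
                r.endpoint_separation,
                r.perpendicular_distance,
                accepted=(reason == "none"),
                rejection_reason=reason,
            )
        )
    if not any(r.accepted for r in out):
        raise PopulationFitError(
            "no reporters: every residue was rejected "
            f"({pd.Series([r.rejection_reason for r in out]).value_counts().to_dict()})"
        )
    return out


def aggregate_population(
    accepted: list[ResiduePopulation], label: str = ""
) -> PopulationEstimate:
    """Mean +/- SEM of raw per-residue p_F over the accepted reporters.

    Values outside [0, 1] are averaged as-is (clipping would bias the mean
    toward the interior); a dispersion warning fires when the per-residue
    spread exceeds 0.25, which suggests the two-state picture is breaking.
    """
    vals = np.array([r.p_f_raw for r in accepted if r.accepted], dtype=float)
    if len(vals) == 0:
        raise PopulationFitError("aggregate_population needs >= 1 accepted residue")
    mean = float(np.mean(vals))
    if len(vals) >= 2:
        sd = float(np.std(vals, ddof=1))
        sem = sd / np.sqrt(len(vals))
        if sd > 0.25:
            warnings.warn(
                f"{label or 'variant'}: per-residue p_F SD {sd:.2f} > 0.25; "
                "two-state fast exchange may not hold",
                stacklevel=2,
            )
    else:
        sem = 0.0
    return PopulationEstimate(
        variant_label=label,
        p_f_mean=mean,
        p_f_sem=float(sem),
        n_reporters=int(len(vals)),
        residues=[r for r in accepted],
    )


def fit_pfree_pipeline(
    mutant: ShiftTable,
    ref: TwoStateReference,
    mutation_site: int,
    criteria: ReporterCriteria | None = None,
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
    label: str | None = None,
) -> PopulationEstimate:
    """End-to-end p_Free estimate for one variant: align -> project ->
    filter reporters -> aggregate; the per-residue report (including every
    rejected residue and its reason) rides along on the result."""
    aligned = align_tables([mutant, ref.inhibited, ref.free], atoms=("H", "N"))
    pops = [
        residue_population(mutant, ref, res, nitrogen_weight) for res in aligned.residues
    ]
    # residues visible in the mutant but dropped in alignment: report as missing
    for res, why in sorted(aligned.dropped.items()):
        if res in set(mutant.residues()):
            pops.append(ResiduePopulation(res, None, np.nan, np.nan, False, "missing_data"))
    pops.sort(key=lambda r: r.residue_number)
    seg = mutant.segment_of if mutant.segments else (ref.inhibited.segment_of)
    selected = select_reporters(pops, mutation_site, criteria, segment_of=seg)
    return aggregate_population(selected, label=label or mutant.construct_label)


def exchange_lower_bound(
    ref: TwoStateReference,
    field_mhz: float | None = None,
    nucleus: str = "N",
    convention: str = "angular",
) -> ExchangeBound:
    """Fast-exchange lower bound on k_ex from the largest I->F shift change.

    The reporter is the residue maximizing |delta_delta| for the chosen
    nucleus; its shift difference is converted to Hz at that nucleus's Larmor
    frequency and, under the default angular convention, to
    k_ex_min = 2*pi*delta_nu (fast exchange means k_ex >> delta_omega).
    The linear convention reports delta_nu itself.
    """
    if nucleus not in _GAMMA_REL:
        raise ValueError(f"nucleus must be one of {sorted(_GAMMA_REL)}")
    if convention not in ("angular", "linear"):
        raise ValueError("convention must be 'angular' or 'linear'")
    if field_mhz is None:
        field_mhz = ref.inhibited.field_mhz
    shared = sorted(set(ref.inhibited.residues()) & set(ref.free.residues()))
    best_res, best_dd = None, 0.0
    for res in shared:
        a = ref.inhibited.get(res, nucleus)
        b = ref.free.get(res, nucleus)
        if a is None or b is None:
            continue
        dd = abs(b.shift - a.shift)
        if best_res is None or dd > best_dd:
            best_res, best_dd = res, dd
    if best_res is None:
        raise PopulationFitError(
            f"no shared residues with nucleus {nucleus} between the references"
        )
    if best_dd == 0.0:
        raise PopulationFitError("all shift differences are zero; no exchange-sensitive reporter")
    larmor_mhz = field_mhz * _GAMMA_REL[nucleus]
    delta_nu = best_dd * larmor_mhz  # ppm * MHz = Hz
    k = 2.0 * np.pi * delta_nu if convention == "angular" else delta_nu
    return ExchangeBound(
        k_ex_min=float(k),
        reporter_residue=best_res,
        delta_nu=float(delta_nu),
        convention=convention,
        nucleus=nucleus,
        field_mhz=field_mhz,
    )
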