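"""Study orchestration: references + variants -> p_Free report -> correlations.

A study is described by a flat key-value config file with ``[section]``
headers (INI syntax).  The orchestrator composes the library stages without
adding any numeric transformation of its own: values in the summary are
exactly the stage outputs.  Every residue-level filter decision is logged so
the reporter selection is auditable.
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .intensity import intensity_ratios, segment_summary
from .io import read_intensity_pair, read_shift_table
from .popfit import (
    PopulationEstimate,
    ReporterCriteria,
    TwoStateReference,
    exchange_lower_bound,
    fit_pfree_pipeline,
)

log = logging.getLogger("jdpop")


class ConfigError(ValueError):
    pass


@dataclass
class StudyConfig:
    """Validated study description (paths checked before any computation)."""

    reference_inhibited: Path
    reference_free: Path
    variants: dict[str, Path]  # label -> table path
    mutation_sites: dict[str, int]  # label -> residue
    outdir: Path
    criteria: ReporterCriteria = field(default_factory=ReporterCriteria)
    nitrogen_weight: float = 5.0
    field_mhz: float = 600.13
    convention: str = "angular"
    intensity_free: Path | None = None
    intensity_bound: Path | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise ConfigError(f"cannot read config {path}")
        try:
            refs = cp["references"]
            ref_i = Path(refs["inhibited"])
            ref_f = Path(refs["free"])
            variants = {k: Path(v) for k, v in cp["variants"].items()}
            sites = {k: int(v) for k, v in cp["mutation_sites"].items()}
        except KeyError as exc:
            raise ConfigError(f"{path}: missing section/key {exc}") from exc
        missing_sites = set(variants) - set(sites)
        if missing_sites:
            raise ConfigError(f"{path}: variants without mutation_site: {sorted(missing_sites)}")
        opts = cp["options"] if cp.has_section("options") else {}
        crit = ReporterCriteria(
            min_separation=float(opts.get("min_separation", 0.05)),
            max_off_line_abs=float(opts.get("max_off_line_abs", 0.02)),
            max_off_line_frac=float(opts.get("max_off_line_frac", 0.15)),
            exclusion_window=int(opts.get("exclusion_window", 2)),
        )
        cfg = cls(
            reference_inhibited=ref_i,
            reference_free=ref_f,
            variants=variants,
            mutation_sites=sites,
            outdir=Path(opts.get("outdir", "study_out")),
            criteria=crit,
            nitrogen_weight=float(opts.get("nitrogen_weight", 5.0)),
            field_mhz=float(opts.get("field_mhz", 600.13)),
            convention=str(opts.get("convention", "angular")),
            intensity_free=Path(opts["intensity_free"]) if "intensity_free" in opts else None,
            intensity_bound=Path(opts["intensity_bound"]) if "intensity_bound" in opts else None,
            seed=int(opts.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.reference_inhibited, self.reference_free, *self.variants.values()]
        if self.intensity_free:
            paths += [self.intensity_free, self.intensity_bound]
        missing = [str(p) for p in paths if p is None or not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")


def run_study(config: StudyConfig) -> dict:
    """Execute the full study: per-variant population fits (CSV + JSON),
    the exchange-rate lower bound, and the intensity map when provided.

    Any stage failure aborts with the stage name and input path in the
    exception message.  Re-running with identical inputs produces
    byte-identical JSON (keys sorted, floats repr-stable).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        ref = TwoStateReference(
            inhibited=read_shift_table(config.reference_inhibited, field_mhz=config.field_mhz),
            free=read_shift_table(config.reference_free, field_mhz=config.field_mhz),
        )
    except Exception as exc:
        raise RuntimeError(
            f"stage 'references' failed on {config.reference_inhibited} / "
            f"{config.reference_free}: {exc}"
        ) from exc
    summary: dict = {"variants": {}, "n_reference_residues": len(ref.inhibited.residues())}
    estimates: dict[str, PopulationEstimate] = {}
    for label, path in sorted(config.variants.items()):
        try:
            table = read_shift_table(path, field_mhz=config.field_mhz, construct_label=label)
            est = fit_pfree_pipeline(
                table, ref, config.mutation_sites[label], config.criteria,
                nitrogen_weight=config.nitrogen_weight, label=label,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'popfit:{label}' failed on {path}: {exc}") from exc
        for r in est.residues:
            if not r.accepted:
                log.info("variant %s: residue %d rejected (%s)", label, r.residue_number,
                         r.rejection_reason)
        est.write(out / f"population_{label}.csv", out / f"population_{label}.json")
        estimates[label] = est
        summary["variants"][label] = est.summary()
    try:
        bound = exchange_lower_bound(ref, config.field_mhz, convention=config.convention)
        summary["exchange_bound"] = {
            "k_ex_min_s-1": bound.k_ex_min,
            "reporter_residue": bound.reporter_residue,
            "delta_nu_hz": bound.delta_nu,
            "convention": bound.convention,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'exchange_bound' failed: {exc}") from exc
    if config.intensity_free and config.intensity_bound:
        try:
            free_t, bound_t = read_intensity_pair(config.intensity_free, config.intensity_bound)
            profile = intensity_ratios(bound_t, free_t)
            profile.to_csv(out / "intensity_profile.csv")
            seg = ref.inhibited.segments
            if seg:
                segment_summary(profile, seg).to_csv(out / "intensity_segments.csv", index=False)
            summary["intensity"] = {
                "n_broadened": len(profile.broadened_residues()),
                "threshold": profile.threshold,
            }
        except Exception as exc:
            raise RuntimeError(
                f"stage 'intensity' failed on {config.intensity_free}: {exc}"
            ) from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    summary["_estimates"] = estimates
    return summary


@dataclass
class CorrelationReport:
    """p_Free vs functional-readout correlation across variants."""

    pairs: pd.DataFrame  # variant, p_f_mean, functional (transformed)
    pearson: float
    spearman: float
    n: int
    transform: str


def correlate_populations(
    estimates: list[PopulationEstimate],
    functional: dict[str, float],
    transform: str = "identity",
) -> CorrelationReport:
    """Correlate per-variant p_F with a functional value (fold-activation,
    rate, or K_D with a log10 transform); Pearson on transformed values plus
    Spearman rank correlation."""
    if transform not in ("identity", "log10"):
        raise ValueError("transform must be 'identity' or 'log10'")
    rows = []
    for est in estimates:
        if est.variant_label in functional:
            val = functional[est.variant_label]
            if transform == "log10":
                if val <= 0:
                    raise ValueError(f"log10 transform needs positive values, got {val}")
                val = float(np.log10(val))
            rows.append((est.variant_label, est.p_f_mean, val))
    if len(rows) < 3:
        raise ValueError(f"need >= 3 shared variants for correlation, got {len(rows)}")
    df = pd.DataFrame(rows, columns=["variant", "p_f_mean", "functional"])
    pearson = float(stats.pearsonr(df["p_f_mean"], df["functional"]).statistic)
    spearman = float(stats.spearmanr(df["p_f_mean"], df["functional"]).statistic)
    return CorrelationReport(
        pairs=df, pearson=pearson, spearman=spearman, n=len(df), transform=transform
    )
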