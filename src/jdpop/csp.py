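"""Combined chemical-shift perturbations (CSPs) between two states.

Amide CSPs use the standard nitrogen-down-weighted combination

    ddelta = sqrt(ddelta_H**2 + (ddelta_N / w)**2),      w = 5 by default,

so that the composite is expressed in 1H-equivalent ppm.  Methyl CSPs are
scaled per methyl type by one standard deviation of the methyl 1H (alpha)
and 13C (beta) chemical-shift distributions, giving a dimensionless
composite in SD units:

    ddelta = sqrt((ddelta_H / alpha)**2 + (ddelta_C / beta)**2).

Significance uses the field's usual rule: a residue is significant when its
combined CSP exceeds mean + k*SD over the profile (k = 1 by default; sample
SD, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ShiftTable, align_tables

DEFAULT_NITROGEN_WEIGHT = 5.0


def load_methyl_sd(path: str | Path | None = None) -> dict[str, tuple[float, float]]:
    """Load the per-methyl-type (alpha_h, beta_c) SD table.

    Without a path, the packaged default resource is used; users may point at
    their own TSV (columns: methyl_type, alpha_h, beta_c).
    """
    if path is None:
        text = resources.files("jdpop").joinpath("data/methyl_shift_sd.tsv").read_text()
    else:
        text = Path(path).read_text()
    out: dict[str, tuple[float, float]] = {}
    header: list[str] | None = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split("\t")]
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        out[row["methyl_type"]] = (float(row["alpha_h"]), float(row["beta_c"]))
    return out


@dataclass
class ScalingConstants:
    """CSP combination weights.

    ``nitrogen_weight`` is the amide 15N denominator; ``methyl_sd`` maps a
    methyl type label (e.g. ``ILE-CD1``) to (alpha 1H SD, beta 13C SD) in ppm.
    """

    mode: str = "amide"  # "amide" | "methyl"
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT
    methyl_sd: dict[str, tuple[float, float]] = field(default_factory=load_methyl_sd)

    def __post_init__(self) -> None:
        if self.mode not in ("amide", "methyl"):
            raise ValueError(f"mode must be 'amide' or 'methyl', got {self.mode!r}")
        if self.nitrogen_weight <= 0:
            raise ValueError("nitrogen_weight must be > 0")
        for mtype, (a, b) in self.methyl_sd.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"non-positive SD for methyl type {mtype}")


@dataclass
class CSPProfile:
    """Per-residue (or per-methyl-group) combined shift differences.

    ``data`` columns: key (residue number or methyl label), delta_h, delta_x
    (15N or 13C difference, signed), combined (non-negative), and after
    :func:`flag_significant` also ``significant`` and ``threshold``.
    """

    mode: str
    data: pd.DataFrame
    threshold: float | None = None
    k: float | None = None

    def significant_keys(self) -> list:
        if "significant" not in self.data:
            return []
        return list(self.data.loc[self.data["significant"], "key"])

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def amide_csp(
    a: ShiftTable, b: ShiftTable, nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT
) -> CSPProfile:
    """Combined amide (1H, 15N) CSP per residue shared by the two tables.

    Raw signed per-nucleus differences (b - a) are retained; the combination
    discards the sign.
    """
    aligned = align_tables([a, b], atoms=("H", "N"))
    ih, inn = aligned.atoms.index("H"), aligned.atoms.index("N")
    dh = aligned.values[:, 1, ih] - aligned.values[:, 0, ih]
    dn = aligned.values[:, 1, inn] - aligned.values[:, 0, inn]
    combined = np.sqrt(dh**2 + (dn / nitrogen_weight) ** 2)
    df = pd.DataFrame(
        {"key": aligned.residues, "delta_h": dh, "delta_x": dn, "combined": combined}
    )
    return CSPProfile(mode="amide", data=df)


# stereo-pair methyl positions collapsed to one group label
_STEREO_COLLAPSE = {"CD1": "CD", "CD2": "CD", "CG1": "CG", "CG2": "CG"}
_STEREO_RESIDUES = {"LEU": ("CD1", "CD2"), "VAL": ("CG1", "CG2")}


def normalize_methyls(table: ShiftTable) -> list[tuple[str, str, float, float]]:
    """Collapse a table's methyl assignments to (group_key, methyl_type, h, c).

    Methyl records are stored with carbon atom names (CB, CG1, CG2, CD1, CD2,
    CE) and the matching proton names (HB, HG1, ...).  LEU delta and VAL gamma
    stereo pairs are averaged into a single group, keyed e.g. ``45-LEU-CD``.
    """
    groups: dict[tuple[int, str, str], list[tuple[float, float]]] = {}
    for rec in table.records:
        if not rec.atom_name.startswith("C"):
            continue
        pos = rec.atom_name
        h = table.get(rec.residue_number, "H" + pos[1:])
        if h is None:
            continue
        rt = rec.residue_type.upper()
        collapse = rt in _STEREO_RESIDUES and pos in _STEREO_RESIDUES[rt]
        label = _STEREO_COLLAPSE[pos] if collapse else pos
        groups.setdefault((rec.residue_number, rt, label), []).append((h.shift, rec.shift))
    out = []
    for (res, rt, label), pairs in sorted(groups.items()):
        h = float(np.mean([p[0] for p in pairs]))
        c = float(np.mean([p[1] for p in pairs]))
        out.append((f"{res}-{rt}-{label}", f"{rt}-{label}", h, c))
    return out


def methyl_csp(a: ShiftTable, b: ShiftTable, scales: ScalingConstants) -> CSPProfile:
    """Combined methyl (1H, 13C) CSP in SD units per shared methyl group."""
    ga = {k: (t, h, c) for k, t, h, c in normalize_methyls(a)}
    gb = {k: (t, h, c) for k, t, h, c in normalize_methyls(b)}
    shared = sorted(set(ga) & set(gb))
    if not shared:
        raise ValueError(
            f"no shared methyl groups between '{a.dataset_id}' and '{b.dataset_id}'"
        )
    rows = []
    for key in shared:
        mtype, ha, ca = ga[key]
        _, hb, cb = gb[key]
        if mtype not in scales.methyl_sd:
            raise KeyError(f"no alpha/beta scaling constants for methyl type {mtype!r}")
        alpha, beta = scales.methyl_sd[mtype]
        dh, dc = hb - ha, cb - ca
        rows.append((key, dh, dc, np.hypot(dh / alpha, dc / beta)))
    df = pd.DataFrame(rows, columns=["key", "delta_h", "delta_x", "combined"])
    return CSPProfile(mode="methyl", data=df)


def flag_significant(profile: CSPProfile, k: float = 1.0, sd: str = "sample") -> CSPProfile:
    """Flag entries with combined CSP > mean + k*SD over the whole profile.

    ``sd`` selects sample (ddof=1, default) or population (ddof=0) SD; mean
    and SD are computed over all entries, untrimmed.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if sd not in ("sample", "population"):
        raise ValueError("sd must be 'sample' or 'population'")
    vals = profile.data["combined"].to_numpy()
    if len(vals) == 0:
        raise ValueError("empty CSP profile")
    if len(vals) < 2:
        raise ValueError(
            "cannot form a mean + k*SD threshold from a single entry; "
            "pass an explicit threshold instead"
        )
    ddof = 1 if sd == "sample" else 0
    threshold = float(np.mean(vals) + k * np.std(vals, ddof=ddof))
    data = profile.data.copy()
    data["significant"] = data["combined"] > threshold
    data["threshold"] = threshold
    return replace(profile, data=data, threshold=threshold, k=k)
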