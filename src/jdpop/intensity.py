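"""Binding-site mapping from bound/free peak-intensity ratios.

Residues at or near an Hsp70-binding interface broaden on complex formation,
so their I/I0 ratio (bound over free) drops well below the bulk of the
profile.  A residue is flagged as broadened when its ratio falls more than
k standard deviations below the profile mean (k = 1 by default; sample SD
over all shared residues, untrimmed).  Inputs are assumed pre-normalized —
no reference-peak or concentration correction is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import IntensityTable


@dataclass
class IntensityProfile:
    """Per-residue I/I0 with broadening flags.

    ``data`` columns: residue_number, i (bound), i0 (free), ratio, broadened.
    """

    data: pd.DataFrame
    mean_ratio: float
    sd_ratio: float
    threshold: float
    k: float
    excluded_zero_free: list[int]

    def broadened_residues(self) -> list[int]:
        return list(self.data.loc[self.data["broadened"], "residue_number"])

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def intensity_ratios(
    bound: IntensityTable, free: IntensityTable, k: float = 1.0
) -> IntensityProfile:
    """I/I0 per residue shared by the two conditions, flagging ratios below
    mean - k*SD.  Residues with zero free intensity cannot form a ratio and
    are excluded (and reported on the profile)."""
    shared = sorted(set(bound.entries) & set(free.entries))
    if not shared:
        raise ValueError("bound and free tables share no residues")
    excluded = [r for r in shared if free.entries[r] == 0.0]
    usable = [r for r in shared if free.entries[r] > 0.0]
    if not usable:
        raise ValueError("all shared residues have zero free intensity")
    i = np.array([bound.entries[r] for r in usable])
    i0 = np.array([free.entries[r] for r in usable])
    ratio = i / i0
    mean = float(np.mean(ratio))
    sd = float(np.std(ratio, ddof=1)) if len(ratio) >= 2 else 0.0
    threshold = mean - k * sd
    df = pd.DataFrame(
        {
            "residue_number": usable,
            "i": i,
            "i0": i0,
            "ratio": ratio,
            "broadened": ratio < threshold,
        }
    )
    return IntensityProfile(
        data=df, mean_ratio=mean, sd_ratio=sd, threshold=float(threshold), k=k,
        excluded_zero_free=excluded,
    )


def segment_summary(
    profile: IntensityProfile, segments: dict[str, tuple[int, int]]
) -> pd.DataFrame:
    """Summarize broadening per annotated segment, ranked by flagged fraction.

    Columns: segment, n_residues, n_flagged, flagged_fraction, mean_ratio.
    An empty annotation yields an empty table.
    """
    rows = []
    for label, (lo, hi) in segments.items():
        sub = profile.data[
            (profile.data["residue_number"] >= lo) & (profile.data["residue_number"] <= hi)
        ]
        n = len(sub)
        flagged = int(sub["broadened"].sum())
        rows.append(
            (
                label,
                n,
                flagged,
                flagged / n if n else 0.0,
                float(sub["ratio"].mean()) if n else np.nan,
            )
        )
    df = pd.DataFrame(
        rows, columns=["segment", "n_residues", "n_flagged", "flagged_fraction", "mean_ratio"]
    )
    return df.sort_values(
        ["flagged_fraction", "n_flagged"], ascending=False, kind="stable"
    ).reset_index(drop=True)


def max_flagged_run(profile: IntensityProfile) -> int:
    """Length of the longest run of consecutive flagged residue numbers —
    a quick check that a null experiment calls no contiguous patch."""
    flagged = sorted(profile.broadened_residues())
    best = run = 0
    prev = None
    for r in flagged:
        run = run + 1 if prev is not None and r == prev + 1 else 1
        best = max(best, run)
        prev = r
    return best
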