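"""Reading, validation and alignment of assigned chemical-shift and peak-intensity tables.

Shift tables hold one assigned construct/state at one spectrometer field and
are the common currency of the whole pipeline: the inhibited (GF-docked) and
free (GF-undocked) reference states, and each variant, are all ``ShiftTable``
instances.  Residue numbering is author numbering exactly as deposited
(1-based, DNAJB6 isoform b); the readers never renumber, but accept an
explicit per-table ``residue_offset`` for deposits numbered on a different
frame.

Two on-disk formats are supported:

* a fixed TSV dialect (tab-delimited, mandatory header, ``#`` comments,
  ``.`` for missing values) that round-trips shifts bit-exactly, and
* NMR-STAR v3 assigned-chemical-shift saveframes as downloaded from the BMRB
  (only the ``Atom_chem_shift`` loop is consumed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._nmrstar import read_atom_chem_shift_loop

DEFAULT_FIELD_MHZ = 600.13

_TSV_COLUMNS = ("residue_number", "residue_type", "atom_name", "shift", "shift_uncertainty")


class ShiftTableError(ValueError):
    """Malformed or inconsistent shift/intensity table."""


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned chemical shift: a (residue, atom) position in ppm."""

    residue_number: int
    residue_type: str
    atom_name: str
    shift: float
    shift_uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ShiftTableError(f"residue_number must be >= 1, got {self.residue_number}")
        if not self.atom_name:
            raise ShiftTableError("atom_name must be non-empty")
        if not math.isfinite(self.shift):
            raise ShiftTableError(
                f"shift for residue {self.residue_number} atom {self.atom_name} is not finite"
            )


@dataclass
class ShiftTable:
    """Assigned chemical shifts for one construct/state at one field.

    Parameters
    ----------
    dataset_id
        Free-text identifier (BMRB accession, file stem, ...).
    construct_label
        e.g. ``WT-JDGF``, ``JD``, ``A50V-JDGF``.
    records
        The assigned shifts; duplicate (residue, atom) pairs are rejected.
    field_mhz
        Proton Larmor frequency in MHz (default 600.13).
    segments
        Optional map of segment label -> inclusive residue range, e.g.
        ``{"helix II": (19, 32), "HPD loop": (33, 36)}``.
    """

    dataset_id: str
    construct_label: str
    records: list[ShiftRecord]
    field_mhz: float = DEFAULT_FIELD_MHZ
    segments: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.field_mhz <= 0:
            raise ShiftTableError(f"field_mhz must be > 0, got {self.field_mhz}")
        seen: dict[tuple[int, str], int] = {}
        dups = []
        for rec in self.records:
            key = (rec.residue_number, rec.atom_name)
            if key in seen:
                dups.append(key)
            seen[key] = seen.get(key, 0) + 1
        if dups:
            listing = ", ".join(f"(residue {r}, atom {a})" for r, a in sorted(set(dups)))
            raise ShiftTableError(f"duplicate assignments in '{self.dataset_id}': {listing}")
        self._index = {(r.residue_number, r.atom_name): r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def residues(self) -> list[int]:
        return sorted({r.residue_number for r in self.records})

    def atoms(self, residue: int) -> set[str]:
        return {r.atom_name for r in self.records if r.residue_number == residue}

    def get(self, residue: int, atom: str) -> ShiftRecord | None:
        return self._index.get((residue, atom))

    def shift(self, residue: int, atom: str) -> float:
        rec = self._index.get((residue, atom))
        if rec is None:
            raise KeyError(f"no shift for residue {residue} atom {atom} in '{self.dataset_id}'")
        return rec.shift

    def segment_of(self, residue: int) -> str | None:
        if not self.segments:
            return None
        for label, (lo, hi) in self.segments.items():
            if lo <= residue <= hi:
                return label
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_number": [r.residue_number for r in self.records],
                "residue_type": [r.residue_type for r in self.records],
                "atom_name": [r.atom_name for r in self.records],
                "shift": [r.shift for r in self.records],
                "shift_uncertainty": [r.shift_uncertainty for r in self.records],
            }
        )


@dataclass
class IntensityTable:
    """Per-residue peak intensities for one condition (free or Hsp70-bound)."""

    dataset_id: str
    condition_label: str
    entries: dict[int, float]

    def __post_init__(self) -> None:
        base = self.condition_label.split()[0].lower() if self.condition_label else ""
        if base not in {"free", "bound"}:
            raise ShiftTableError(
                f"condition_label must start with 'free' or 'bound', got {self.condition_label!r}"
            )
        bad = {r: v for r, v in self.entries.items() if v < 0 or not math.isfinite(v)}
        if bad:
            raise ShiftTableError(
                f"negative or non-finite intensities in '{self.dataset_id}': {sorted(bad)}"
            )

    def residues(self) -> list[int]:
        return sorted(self.entries)


def _parse_tsv_rows(path: Path) -> list[dict[str, str]]:
    lines = path.read_text().splitlines()
    header: list[str] | None = None
    rows: list[dict[str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            continue
        if len(fields) < len(header):
            fields = fields + ["."] * (len(header) - len(fields))
        rows.append({"__line__": str(lineno), **dict(zip(header, (f.strip() for f in fields)))})
    if header is None:
        raise ShiftTableError(f"{path}: empty file, expected a header row")
    missing = [c for c in ("residue_number", "residue_type", "atom_name", "shift") if c not in header]
    if missing:
        raise ShiftTableError(f"{path}: header is missing columns {missing}")
    return rows


def read_shift_table(
    path: str | Path,
    format: str = "tsv",
    *,
    dataset_id: str | None = None,
    construct_label: str = "",
    field_mhz: float | None = None,
    residue_offset: int = 0,
    segments: dict[str, tuple[int, int]] | None = None,
) -> ShiftTable:
    """Read an assigned chemical-shift table from TSV or NMR-STAR.

    ``residue_offset`` is added to every residue number, for deposits whose
    sequence numbering is offset from the author (isoform b) frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        records = _read_tsv_records(path, residue_offset)
    elif format == "nmrstar":
        records = _read_nmrstar_records(path, residue_offset)
    else:
        raise ValueError(f"unknown format {format!r}, expected 'tsv' or 'nmrstar'")
    return ShiftTable(
        dataset_id=dataset_id or path.stem,
        construct_label=construct_label or path.stem,
        records=records,
        field_mhz=field_mhz if field_mhz is not None else DEFAULT_FIELD_MHZ,
        segments=segments,
    )


def _read_tsv_records(path: Path, residue_offset: int) -> list[ShiftRecord]:
    records = []
    for row in _parse_tsv_rows(path):
        lineno = row["__line__"]
        try:
            unc = row.get("shift_uncertainty", ".")
            records.append(
                ShiftRecord(
                    residue_number=int(row["residue_number"]) + residue_offset,
                    residue_type=row["residue_type"],
                    atom_name=row["atom_name"],
                    shift=float(row["shift"]),
                    shift_uncertainty=None if unc in (".", "", None) else float(unc),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ShiftTableError(f"{path}: line {lineno}: {exc}") from exc
    return records


def _read_nmrstar_records(path: Path, residue_offset: int) -> list[ShiftRecord]:
    rows = read_atom_chem_shift_loop(path)
    records = []
    for row in rows:
        records.append(
            ShiftRecord(
                residue_number=int(row["seq_id"]) + residue_offset,
                residue_type=row["comp_id"],
                atom_name=row["atom_id"],
                shift=float(row["val"]),
                shift_uncertainty=row.get("val_err"),
            )
        )
    return records


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    """Write the TSV dialect; shifts are serialized with ``repr`` so the
    TSV round trip is bit-exact."""
    path = Path(path)
    lines = ["\t".join(_TSV_COLUMNS)]
    for rec in table.records:
        unc = "." if rec.shift_uncertainty is None else repr(rec.shift_uncertainty)
        lines.append(
            f"{rec.residue_number}\t{rec.residue_type}\t{rec.atom_name}\t{rec.shift!r}\t{unc}"
        )
    path.write_text("\n".join(lines) + "\n")


@dataclass
class AlignedShifts:
    """Residue x table x atom shift matrix over the common complete residues."""

    residues: list[int]
    atoms: list[str]
    table_ids: list[str]
    values: np.ndarray  # shape (n_residues, n_tables, n_atoms)
    dropped: dict[int, str]  # residue -> why it was dropped

    def shift(self, residue: int, table_id: str, atom: str) -> float:
        return float(
            self.values[
                self.residues.index(residue), self.table_ids.index(table_id), self.atoms.index(atom)
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, res in enumerate(self.residues):
            for j, tid in enumerate(self.table_ids):
                for k, atom in enumerate(self.atoms):
                    recs.append((res, tid, atom, self.values[i, j, k]))
        return pd.DataFrame(recs, columns=["residue_number", "dataset_id", "atom_name", "shift"])


def align_tables(tables: Sequence[ShiftTable], atoms: Iterable[str]) -> AlignedShifts:
    """Align >= 2 shift tables on residues that carry *all* requested atoms in
    *all* tables; every dropped residue is reported with the table/atom that
    caused the drop."""
    tables = list(tables)
    atoms = sorted(set(atoms))
    if len(tables) < 2:
        raise ValueError("align_tables needs at least 2 tables")
    all_residues: set[int] = set()
    for t in tables:
        all_residues.update(t.residues())
    kept: list[int] = []
    dropped: dict[int, str] = {}
    for res in sorted(all_residues):
        reason = None
        for t in tables:
            missing = [a for a in atoms if t.get(res, a) is None]
            if missing:
                reason = f"missing {','.join(missing)} in '{t.dataset_id}'"
                break
        if reason is None:
            kept.append(res)
        else:
            dropped[res] = reason
    if not kept:
        raise ShiftTableError(
            "no common residues with atoms {" + ",".join(atoms) + "} across "
            + ", ".join(t.dataset_id for t in tables)
        )
    values = np.empty((len(kept), len(tables), len(atoms)))
    for i, res in enumerate(kept):
        for j, t in enumerate(tables):
            for k, atom in enumerate(atoms):
                values[i, j, k] = t.shift(res, atom)
    return AlignedShifts(
        residues=kept,
        atoms=atoms,
        table_ids=[t.dataset_id for t in tables],
        values=values,
        dropped=dropped,
    )


def read_intensity_table(
    path: str | Path, condition_label: str, dataset_id: str | None = None
) -> IntensityTable:
    """Read a two-column (residue_number, intensity) TSV."""
    path = Path(path)
    entries: dict[int, float] = {}
    for row in _parse_tsv_rows_generic(path, ("residue_number", "intensity")):
        res = int(row["residue_number"])
        if res in entries:
            raise ShiftTableError(f"{path}: duplicate residue {res}")
        entries[res] = float(row["intensity"])
    return IntensityTable(
        dataset_id=dataset_id or path.stem, condition_label=condition_label, entries=entries
    )


def _parse_tsv_rows_generic(path: Path, required: tuple[str, ...]) -> list[dict[str, str]]:
    lines = path.read_text().splitlines()
    header: list[str] | None = None
    rows = []
    for raw in lines:
        line = raw.split("#", 1)[0]
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if header is None:
            header = fields
            missing = [c for c in required if c not in header]
            if missing:
                raise ShiftTableError(f"{path}: header is missing columns {missing}")
            continue
        rows.append(dict(zip(header, fields)))
    if header is None:
        raise ShiftTableError(f"{path}: empty file")
    return rows


def read_intensity_pair(
    path_free: str | Path, path_bound: str | Path
) -> tuple[IntensityTable, IntensityTable]:
    """Read the free/bound intensity pair and report one-sided residues."""
    free = read_intensity_table(path_free, "free")
    bound = read_intensity_table(path_bound, "bound")
    only_free = set(free.entries) - set(bound.entries)
    only_bound = set(bound.entries) - set(free.entries)
    if not (set(free.entries) & set(bound.entries)):
        raise ShiftTableError("free and bound intensity tables share no residues")
    if only_free or only_bound:
        import warnings

        warnings.warn(
            f"residues present only in free: {sorted(only_free)}; "
            f"only in bound: {sorted(only_bound)}",
            stacklevel=2,
        )
    return free, bound
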