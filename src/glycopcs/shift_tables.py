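"""Chemical-shift tables and pseudocontact-shift (PCS) arithmetic.

A pseudocontact shift is the change in a nucleus's chemical shift caused by
the anisotropic magnetic susceptibility of a nearby paramagnetic center.  For
a lanthanide-tagged oligosaccharide it is measured as

    Δδ_obs = δ(paramagnetic metal) − δ(diamagnetic reference)

per assigned resonance, where the diamagnetic reference is the same tagged
molecule chelating La³⁺ and the paramagnetic spectra use Tm³⁺ or Tb³⁺.
This module reads per-metal shift tables (delimited text, one row per
assigned resonance and metal), forms observed PCSs by differencing matched
assignments, and differences PCS tables between molecules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Nucleus",
    "ResonanceAssignment",
    "ShiftMeasurement",
    "PCSMeasurement",
    "TableParseError",
    "read_shift_table",
    "write_shift_table",
    "compute_pcs",
    "diff_pcs_tables",
    "read_pcs_table",
    "write_pcs_table",
    "gm2_table1_path",
]

#: Sanity bounds (ppm) for detected shifts, by nucleus.
_SHIFT_BOUNDS = {"H1": (-5.0, 15.0), "C13": (0.0, 250.0)}

#: Cell contents treated as "not detected".
_ND_TOKENS = {"n.d.", "nd", "n.d", "na", "n/a", ""}


class TableParseError(ValueError):
    """A shift table row could not be parsed; the message names the line."""


class Nucleus(str, Enum):
    H1 = "H1"
    C13 = "C13"

    @classmethod
    def parse(cls, text: str) -> "Nucleus":
        t = str(text).strip().upper().replace("¹", "1").replace("³", "3")
        if t in {"H1", "1H", "H"}:
            return cls.H1
        if t in {"C13", "13C", "C"}:
            return cls.C13
        raise ValueError(f"unknown nucleus {text!r} (expected H1 or C13)")


@dataclass(frozen=True, order=True)
class ResonanceAssignment:
    """One assigned resonance: residue label, atom label and nucleus type."""

    residue_label: str
    atom_label: str
    nucleus: Nucleus

    def __post_init__(self) -> None:
        if not self.atom_label:
            raise ValueError("atom_label must be non-empty")
        if not self.residue_label:
            raise ValueError("residue_label must be non-empty")


@dataclass(frozen=True)
class ShiftMeasurement:
    """A chemical shift for one assignment under one chelated metal."""

    assignment: ResonanceAssignment
    metal: str
    shift_ppm: float | None
    detected: bool = True

    def __post_init__(self) -> None:
        if self.detected:
            if self.shift_ppm is None or not math.isfinite(self.shift_ppm):
                raise ValueError(
                    f"{self.assignment}: detected shift must be finite"
                )
            lo, hi = _SHIFT_BOUNDS[self.assignment.nucleus.value]
            if not lo <= self.shift_ppm <= hi:
                raise ValueError(
                    f"{self.assignment} ({self.metal}): shift "
                    f"{self.shift_ppm} ppm outside sanity bounds [{lo}, {hi}]"
                )
        elif self.shift_ppm is not None:
            raise ValueError("undetected measurement must not carry a shift")


@dataclass(frozen=True)
class PCSMeasurement:
    """Observed PCS (ppm): paramagnetic minus diamagnetic shift."""

    assignment: ResonanceAssignment
    paramagnetic_metal: str
    diamagnetic_metal: str
    delta_delta_ppm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_delta_ppm):
            raise ValueError(f"{self.assignment}: PCS must be finite")


def gm2_table1_path() -> Path:
    """Path to the packaged GM2 tetrasaccharide shift-table fixture."""
    return Path(
        resources.files("glycopcs.data").joinpath("gm2_table1_shifts.tsv")
    )


def _read_delimited(path: str | Path) -> pd.DataFrame:
    import csv

    try:
        return pd.read_csv(
            path, sep=None, engine="python", dtype=str, comment="#",
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    except csv.Error:
        # delimiter sniffing fails on blank/one-column files; retry as TSV
        try:
            return pd.read_csv(path, sep="\t", dtype=str, comment="#")
        except pd.errors.EmptyDataError:
            return pd.DataFrame()


def read_shift_table(
    path: str | Path, dialect: str | None = None
) -> list[ShiftMeasurement]:
    """Read a long-format shift table (TSV or CSV, delimiter sniffed).

    Required columns: residue, atom, nucleus, metal, shift_ppm (or shift).
    Cells equal to ``n.d.`` (or empty) yield ``detected=False`` records.
    Duplicate (assignment, metal) rows raise a validation error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_delimited(path)
    if df.empty:
        logger.warning("shift table %s is empty", path)
        return []
    cols = {c.strip().lower(): c for c in df.columns}
    if "shift_ppm" not in cols and "shift" in cols:
        cols["shift_ppm"] = cols["shift"]
    missing = [c for c in ("residue", "atom", "nucleus", "metal", "shift_ppm")
               if c not in cols]
    if missing:
        raise TableParseError(f"{path}: missing column(s) {missing}")

    out: list[ShiftMeasurement] = []
    seen: set[tuple[ResonanceAssignment, str]] = set()
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header on line 1 (comments aside)
        try:
            assignment = ResonanceAssignment(
                residue_label=str(row[cols["residue"]]).strip(),
                atom_label=str(row[cols["atom"]]).strip(),
                nucleus=Nucleus.parse(row[cols["nucleus"]]),
            )
            metal = str(row[cols["metal"]]).strip()
            if not metal or metal.lower() == "nan":
                raise ValueError("missing metal label")
            cell = row[cols["shift_ppm"]]
            cell = "" if pd.isna(cell) else str(cell).strip()
            if cell.lower() in _ND_TOKENS:
                m = ShiftMeasurement(assignment, metal, None, detected=False)
            else:
                m = ShiftMeasurement(assignment, metal, float(cell))
        except (ValueError, KeyError) as exc:
            raise TableParseError(f"{path}, line {line}: {exc}") from exc
        key = (assignment, metal)
        if key in seen:
            raise ValueError(
                f"{path}, line {line}: duplicate entry for "
                f"{assignment} / {metal}"
            )
        seen.add(key)
        out.append(m)
    return out


def write_shift_table(
    measurements: Iterable[ShiftMeasurement], path: str | Path
) -> None:
    rows = [
        {
            "residue": m.assignment.residue_label,
            "atom": m.assignment.atom_label,
            "nucleus": m.assignment.nucleus.value,
            "metal": m.metal,
            "shift_ppm": (repr(m.shift_ppm) if m.detected else "n.d."),
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _single_metal(measurements: Sequence[ShiftMeasurement], role: str) -> str:
    metals = {m.metal for m in measurements}
    if len(metals) != 1:
        raise ValueError(f"{role} table must hold one metal, found {metals}")
    return metals.pop()


def compute_pcs(
    dia: Sequence[ShiftMeasurement], para: Sequence[ShiftMeasurement]
) -> list[PCSMeasurement]:
    """Observed PCSs: Δδ = δ(para) − δ(dia) per matched detected assignment.

    Assignments undetected in either spectrum, or present in only one, are
    skipped (counted in the log).  Raises if no pair matches.
    """
    dia_metal = _single_metal(dia, "diamagnetic")
    para_metal = _single_metal(para, "paramagnetic")
    dia_shift = {m.assignment: m.shift_ppm for m in dia if m.detected}
    out: list[PCSMeasurement] = []
    skipped = 0
    for m in para:
        ref = dia_shift.get(m.assignment)
        if not m.detected or ref is None:
            skipped += 1
            continue
        out.append(
            PCSMeasurement(
                assignment=m.assignment,
                paramagnetic_metal=para_metal,
                diamagnetic_metal=dia_metal,
                delta_delta_ppm=m.shift_ppm - ref,
            )
        )
    if skipped:
        logger.info(
            "compute_pcs: skipped %d unmatched/undetected assignments", skipped
        )
    if not out:
        raise ValueError("no matched detected assignment pairs; nothing to compute")
    return out


def diff_pcs_tables(
    a: Sequence[PCSMeasurement], b: Sequence[PCSMeasurement]
) -> tuple[list[tuple[ResonanceAssignment, float]], list[ResonanceAssignment]]:
    """Per-assignment PCS differences Δδ_a − Δδ_b between two molecules.

    Both tables must use the same paramagnetic/diamagnetic metal pair.
    Returns (differences for assignments present in both, assignments present
    in only one table).
    """
    pairs = {(m.paramagnetic_metal, m.diamagnetic_metal) for m in a} | {
        (m.paramagnetic_metal, m.diamagnetic_metal) for m in b
    }
    if len(pairs) > 1:
        raise ValueError(f"metal-pair mismatch between tables: {pairs}")
    amap = {m.assignment: m.delta_delta_ppm for m in a}
    bmap = {m.assignment: m.delta_delta_ppm for m in b}
    common = [k for k in amap if k in bmap]
    diffs = [(k, amap[k] - bmap[k]) for k in common]
    missing = sorted(set(amap) ^ set(bmap))
    if missing:
        logger.info("diff_pcs_tables: %d assignments present in only one table",
                    len(missing))
    return diffs, missing


def write_pcs_table(pcs: Iterable[PCSMeasurement], path: str | Path) -> None:
    rows = [
        {
            "residue": m.assignment.residue_label,
            "atom": m.assignment.atom_label,
            "nucleus": m.assignment.nucleus.value,
            "para_metal": m.paramagnetic_metal,
            "dia_metal": m.diamagnetic_metal,
            "pcs_ppm": repr(m.delta_delta_ppm),
        }
        for m in pcs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pcs_table(path: str | Path) -> list[PCSMeasurement]:
    df = _read_delimited(path)
    if df.empty:
        return []
    return [
        PCSMeasurement(
            assignment=ResonanceAssignment(
                str(r["residue"]).strip(),
                str(r["atom"]).strip(),
                Nucleus.parse(r["nucleus"]),
            ),
            paramagnetic_metal=str(r["para_metal"]).strip(),
            diamagnetic_metal=str(r["dia_metal"]).strip(),
            delta_delta_ppm=float(r["pcs_ppm"]),
        )
        for _, r in df.iterrows()
    ]
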