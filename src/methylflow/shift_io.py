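"""Read methyl chemical-shift tables and assemble CSP matrices.

A mutant-versus-wildtype comparison of methyl ¹H-¹³C HMQC peak positions
yields, per methyl group, a combined chemical-shift perturbation (CSP) in
Hz.  Collecting these over a panel of point mutants gives the residue ×
mutant CSP matrix that every downstream network stage consumes.

Stereo-specific methyl pairs (Leu δ1/δ2, Val γ1/γ2) are independent
observables and are kept as distinct rows keyed by ``(residue_id,
methyl_label)``.  Peaks missing in either spectrum (overlap, unassigned)
are masked with NaN rather than zero-filled: an absent peak is not an
observation of "no perturbation".
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CARBON_PROTON_RATIO",
    "ShiftRecord",
    "CSPMatrix",
    "FormatError",
    "DataError",
    "compute_csp",
    "read_shift_table",
    "write_shift_table",
    "build_csp_matrix",
]

#: γ(¹³C)/γ(¹H) scaling used to express a ¹³C shift on the ¹H Hz scale.
#: Fixed so that at a 750 MHz spectrometer the carbon factor is exactly
#: the conventional 188.8 Hz/ppm.
CARBON_PROTON_RATIO = 188.8 / 750.0

ResidueKey = tuple[int, str]


class FormatError(ValueError):
    """A shift table (or matrix file) could not be parsed."""


class DataError(ValueError):
    """Inputs are well-formed but mutually inconsistent."""


@dataclass(frozen=True)
class ShiftRecord:
    """One methyl resonance: sequence position, methyl label, peak position."""

    residue_id: int
    methyl_label: str
    h_ppm: float
    c_ppm: float

    def __post_init__(self) -> None:
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")
        if not (math.isfinite(self.h_ppm) and math.isfinite(self.c_ppm)):
            raise ValueError(
                f"non-finite ppm for residue {self.residue_id}-{self.methyl_label}"
            )

    @property
    def key(self) -> ResidueKey:
        return (self.residue_id, self.methyl_label)


def compute_csp(delta_h, delta_c, field_mhz: float = 750.0):
    """Combined ¹H-¹³C chemical-shift perturbation in Hz.

    Δν = sqrt((Δ¹H · f)² + (Δ¹³C · f · 188.8/750)²) with f the ¹H
    spectrometer frequency in MHz; at 750 MHz the carbon factor is the
    conventional 188.8 Hz/ppm.  Accepts scalars or arrays.
    """
    if field_mhz <= 0:
        raise ValueError(f"field_mhz must be positive, got {field_mhz}")
    dh = np.asarray(delta_h, dtype=float)
    dc = np.asarray(delta_c, dtype=float)
    if not (np.all(np.isfinite(dh)) and np.all(np.isfinite(dc))):
        raise ValueError("compute_csp requires finite ppm differences")
    out = np.hypot(dh * field_mhz, dc * field_mhz * CARBON_PROTON_RATIO)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# shift-table readers / writers

_SPARKY_ASSIGN = re.compile(
    r"^([A-Za-z]{1,3})(\d+)C([A-Z])(\d?)-H[A-Z]\d?$"
)


def _parse_sparky_assignment(text: str) -> ResidueKey:
    """``L77CD1-HD1`` -> (77, "d1"); ``M109CE-HE`` -> (109, "e")."""
    m = _SPARKY_ASSIGN.match(text.strip())
    if m is None:
        raise FormatError(f"unparseable sparky assignment {text!r}")
    _, resid, carbon, index = m.groups()
    return int(resid), (carbon + index).lower()


def read_shift_table(path, dialect: str = "csv") -> list[ShiftRecord]:
    """Read one sample's methyl shift list.

    dialect "csv"/"tsv": columns residue_id, methyl, h_ppm, c_ppm.
    dialect "sparky_list": whitespace table with a header line and columns
    Assignment, w1 (¹³C ppm), w2 (¹H ppm), e.g. ``L77CD1-HD1  24.913  0.764``.

    Duplicate (residue, methyl) keys are rejected.
    """
    path = Path(path)
    if dialect not in ("csv", "tsv", "sparky_list"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[ShiftRecord] = []
    seen: set[ResidueKey] = set()

    if dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh, delimiter=sep)
            required = {"residue_id", "methyl", "h_ppm", "c_ppm"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise FormatError(
                    f"{path}: expected columns {sorted(required)}, "
                    f"got {reader.fieldnames}"
                )
            for i, row in enumerate(reader, start=2):
                try:
                    rec = ShiftRecord(
                        residue_id=int(row["residue_id"]),
                        methyl_label=row["methyl"].strip(),
                        h_ppm=float(row["h_ppm"]),
                        c_ppm=float(row["c_ppm"]),
                    )
                except (TypeError, ValueError) as exc:
                    raise FormatError(f"{path}: row {i}: {exc}") from exc
                if rec.key in seen:
                    raise FormatError(
                        f"{path}: row {i}: duplicate methyl "
                        f"{rec.residue_id}-{rec.methyl_label}"
                    )
                seen.add(rec.key)
                records.append(rec)
    else:  # sparky_list
        with path.open() as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.lower().startswith("assignment"):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise FormatError(f"{path}: line {i}: expected 3 columns")
                try:
                    resid, label = _parse_sparky_assignment(parts[0])
                    c_ppm, h_ppm = float(parts[1]), float(parts[2])
                    rec = ShiftRecord(resid, label, h_ppm=h_ppm, c_ppm=c_ppm)
                except (FormatError, ValueError) as exc:
                    raise FormatError(f"{path}: line {i}: {exc}") from exc
                if rec.key in seen:
                    raise FormatError(f"{path}: line {i}: duplicate {parts[0]}")
                seen.add(rec.key)
                records.append(rec)
    return records


_LABEL_TO_SPARKY = {
    "d1": "CD1-HD1", "d2": "CD2-HD2",
    "g1": "CG1-HG1", "g2": "CG2-HG2",
    "e": "CE-HE", "e1": "CE1-HE1",
}


def write_shift_table(records: Iterable[ShiftRecord], path, dialect: str = "csv",
                      residue_type: str = "L") -> None:
    """Write records in a format :func:`read_shift_table` reads back."""
    path = Path(path)
    records = list(records)
    if dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter=sep)
            writer.writerow(["residue_id", "methyl", "h_ppm", "c_ppm"])
            for r in records:
                writer.writerow([r.residue_id, r.methyl_label,
                                 repr(r.h_ppm), repr(r.c_ppm)])
    elif dialect == "sparky_list":
        with path.open("w") as fh:
            fh.write("Assignment   w1   w2\n")
            for r in records:
                atoms = _LABEL_TO_SPARKY.get(r.methyl_label)
                if atoms is None:
                    atoms = f"C{r.methyl_label.upper()}-H{r.methyl_label.upper()}"
                fh.write(f"{residue_type}{r.residue_id}{atoms}  "
                         f"{r.c_ppm!r}  {r.h_ppm!r}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# CSP matrix

_FIRST_INT = re.compile(r"(\d+)")


def mutation_site(mutant_label: str) -> int | None:
    """Sequence position encoded in a mutant label such as ``L268V``."""
    m = _FIRST_INT.search(mutant_label)
    return int(m.group(1)) if m else None


@dataclass
class CSPMatrix:
    """Residue × mutant matrix of combined shift perturbations (Hz).

    ``values`` holds NaN where a cell is masked (peak missing in either
    spectrum, or the mutant's own mutated residue).
    """

    residues: list[ResidueKey]
    mutants: list[str]
    values: np.ndarray  # (n_residues, n_mutants), NaN = masked
    field_mhz: float = 750.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.residues), len(self.mutants)):
            raise ValueError("values shape does not match residues × mutants")
        present = self.values[np.isfinite(self.values)]
        if present.size and present.min() < 0:
            raise ValueError("CSP values must be non-negative")
        empty = ~np.any(np.isfinite(self.values), axis=0)
        if np.any(empty):
            bad = [m for m, e in zip(self.mutants, empty) if e]
            raise DataError(f"mutant column(s) with no observations: {bad}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean present/absent per cell."""
        return np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def residue_index(self) -> dict[ResidueKey, int]:
        return {k: i for i, k in enumerate(self.residues)}

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{rid}:{lab}" for rid, lab in self.residues]
        return pd.DataFrame(self.values, index=idx, columns=self.mutants)

    def to_csv(self, path) -> None:
        """Rows = residue:methyl, columns = mutants, empty cell = masked."""
        df = self.to_frame()
        df.index.name = f"residue@{self.field_mhz!r}MHz"
        df.to_csv(path, float_format="%.17g", na_rep="")

    @classmethod
    def from_csv(cls, path) -> "CSPMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        name = df.index.name or ""
        field = 750.0
        m = re.match(r"residue@(.+)MHz$", name)
        if m:
            field = float(m.group(1))
        residues: list[ResidueKey] = []
        for key in df.index:
            rid, lab = str(key).split(":", 1)
            residues.append((int(rid), lab))
        return cls(residues=residues, mutants=[str(c) for c in df.columns],
                   values=df.to_numpy(dtype=float), field_mhz=field)

    def subset_mutants(self, labels: Sequence[str]) -> "CSPMatrix":
        cols = [self.mutants.index(l) for l in labels]
        return CSPMatrix(residues=list(self.residues), mutants=list(labels),
                         values=self.values[:, cols].copy(),
                         field_mhz=self.field_mhz)


def build_csp_matrix(
    wildtype: Iterable[ShiftRecord],
    mutants: Mapping[str, Iterable[ShiftRecord]],
    field_mhz: float = 750.0,
    restrict_to_common: bool = True,
) -> CSPMatrix:
    """Assemble the residue × mutant CSP matrix.

    Each cell is ``compute_csp(mutant − wildtype)`` where the methyl is
    observed in both spectra, NaN otherwise.  The mutated residue's own
    methyls are masked in its column.  With ``restrict_to_common`` (the
    default) the residue set is the intersection of methyls observed in
    the wildtype and in *every* mutant, mirroring the common-set
    convention; otherwise the union is used with masking.
    """
    wt = {r.key: r for r in wildtype}
    if not wt:
        raise DataError("empty wildtype shift table")
    mut_tables: dict[str, dict[ResidueKey, ShiftRecord]] = {
        label: {r.key: r for r in recs} for label, recs in mutants.items()
    }
    if not mut_tables:
        raise DataError("no mutant shift tables supplied")
    for label, table in mut_tables.items():
        if not set(table) & set(wt):
            raise DataError(f"mutant {label} shares no methyl with wildtype")

    keys = set(wt)
    if restrict_to_common:
        for table in mut_tables.values():
            keys &= set(table)
        if not keys:
            raise DataError(
                "no methyl observed in wildtype and all mutants "
                "(restrict_to_common)"
            )
    else:
        for table in mut_tables.values():
            keys |= set(table)
        keys &= set(wt) | set().union(*map(set, mut_tables.values()))

    residues = sorted(keys)
    labels = list(mut_tables)
    values = np.full((len(residues), len(labels)), np.nan)
    for j, label in enumerate(labels):
        table = mut_tables[label]
        site = mutation_site(label)
        for i, key in enumerate(residues):
            if key[0] == site:
                continue  # own-site methyls carry no usable perturbation
            w, m = wt.get(key), table.get(key)
            if w is None or m is None:
                continue
            values[i, j] = compute_csp(m.h_ppm - w.h_ppm, m.c_ppm - w.c_ppm,
                                       field_mhz)
    return CSPMatrix(residues=residues, mutants=labels, values=values,
                     field_mhz=field_mhz)
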