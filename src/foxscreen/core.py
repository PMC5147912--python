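"""Shared plumbing: image pairs, 96-well plate layouts, concentration units.

Wells are named in the conventional ``A01``..``H12`` style (row letter,
zero-padded column). Concentrations are carried with an explicit unit and
converted to micromolar internally; dose-response fits report midpoints in
micromolar unless stated otherwise.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

#: Recognised well roles on a plate map.
ROLES = frozenset({"negative", "positive", "compound", "blank", "empty"})

#: Multiplicative factors to micromolar.
UNIT_TO_UM = {
    "pM": 1e-6,
    "nM": 1e-3,
    "uM": 1.0,
    "µM": 1.0,  # µM
    "mM": 1e3,
    "M": 1e6,
}


def conc_to_uM(value: float, unit: str) -> float:
    """Convert a concentration to micromolar."""
    try:
        return float(value) * UNIT_TO_UM[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


def well_name(row: int, col: int) -> str:
    """0-based (row, col) grid position -> well id like 'B07'."""
    if not (0 <= row < 26):
        raise ValueError(f"row index {row} out of range")
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


@dataclass(frozen=True)
class ImagePair:
    """Registered DAPI + GFP intensity images for one field/well."""

    dapi: np.ndarray
    gfp: np.ndarray

    def __post_init__(self) -> None:
        if self.dapi.ndim != 2 or self.gfp.ndim != 2:
            raise ValueError("channel images must be 2-D")
        if self.dapi.shape != self.gfp.shape:
            raise ValueError(
                f"channel shape mismatch: DAPI {self.dapi.shape} vs GFP {self.gfp.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape


class WellEntry(NamedTuple):
    well: str
    role: str
    compound: str | None
    conc: float | None
    conc_unit: str | None


_LAYOUT_COLUMNS = ["well", "role", "compound", "conc", "conc_unit"]


@dataclass
class PlateLayout:
    """Plate map: one row per well with a role and, for compound wells, a dose.

    The canonical interchange format is a CSV with header
    ``well,role,compound,conc,conc_unit``.
    """

    table: pd.DataFrame
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"layout missing columns {missing}")
        df = df[_LAYOUT_COLUMNS]
        df["conc"] = pd.to_numeric(df["conc"], errors="coerce")
        for col in ("compound", "conc_unit"):
            df[col] = df[col].where(pd.notna(df[col]), np.nan)
        bad = set(df["role"]) - ROLES
        if bad:
            raise ValueError(f"unknown well role(s) {sorted(bad)} in plate {self.plate_id}")
        if df["well"].duplicated().any():
            dups = df.loc[df["well"].duplicated(), "well"].tolist()
            raise ValueError(f"duplicate wells {dups} in plate {self.plate_id}")
        is_cpd = df["role"] == "compound"
        if df.loc[is_cpd, "conc"].isna().any():
            raise ValueError("compound wells must carry a concentration")
        if df.loc[~is_cpd, "conc"].notna().any():
            raise ValueError("only compound wells may carry a concentration")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def entries(self, roles: Iterable[str] | None = None) -> Iterator[WellEntry]:
        """Iterate wells (optionally restricted to given roles) in table order."""
        sel = self.table if roles is None else self.table[self.table["role"].isin(set(roles))]
        for row in sel.itertuples(index=False):
            conc = None if pd.isna(row.conc) else float(row.conc)
            compound = None if pd.isna(row.compound) else str(row.compound)
            unit = None if pd.isna(row.conc_unit) else str(row.conc_unit)
            yield WellEntry(str(row.well), str(row.role), compound, conc, unit)

    def wells(self, role: str | None = None) -> list[str]:
        if role is None:
            return self.table["well"].tolist()
        return self.table.loc[self.table["role"] == role, "well"].tolist()

    def conc_uM(self, well: str) -> float:
        row = self.table.set_index("well").loc[well]
        return conc_to_uM(row["conc"], row["conc_unit"])

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_csv(cls, path: str | Path, plate_id: str | None = None) -> "PlateLayout":
        df = pd.read_csv(path)
        return cls(df, plate_id=plate_id or Path(path).stem)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    # ----------------------------------------------------------- builders
    @classmethod
    def from_entries(cls, entries: Iterable[tuple], plate_id: str = "plate1") -> "PlateLayout":
        df = pd.DataFrame(list(entries), columns=_LAYOUT_COLUMNS)
        return cls(df, plate_id=plate_id)

    @classmethod
    def dose_response(
        cls,
        compound: str,
        concentrations: Iterable[float],
        conc_unit: str = "uM",
        n_negative: int = 8,
        n_positive: int = 8,
        replicates: int = 1,
        plate_id: str = "plate1",
        n_rows: int = 8,
    ) -> "PlateLayout":
        """Dose plate in the screening convention: vehicle (negative) controls
        in the first column, reference (positive) controls in the last column,
        the dilution series (optionally in replicate wells) filling interior
        wells row-major."""
        rows: list[tuple] = []
        for i in range(n_negative):
            rows.append((well_name(i % n_rows, 0), "negative", None, None, None))
        for i in range(n_positive):
            rows.append((well_name(i % n_rows, 11), "positive", None, None, None))
        concs = [float(c) for c in concentrations for _ in range(replicates)]
        r, c = 0, 1
        for conc in concs:
            rows.append((well_name(r, c), "compound", compound, conc, conc_unit))
            c += 1
            if c > 10:
                c, r = 1, r + 1
                if r >= n_rows:
                    raise ValueError("too many doses for one plate")
        return cls.from_entries(rows, plate_id=plate_id)

    @classmethod
    def single_dose_screen(
        cls,
        compounds: Iterable[str],
        conc: float = 10.0,
        conc_unit: str = "uM",
        n_rows: int = 8,
        n_cols: int = 12,
        plate_prefix: str = "plate",
    ) -> list["PlateLayout"]:
        """Split a compound collection over as many plates as needed.

        Column 1 holds negative (vehicle) controls, the last column positive
        (reference) controls; interior wells take one compound each at a single
        dose. Unused interior wells are marked ``empty``.
        """
        compounds = list(compounds)
        per_plate = n_rows * (n_cols - 2)
        layouts: list[PlateLayout] = []
        for p in range(0, max(1, -(-len(compounds) // per_plate))):
            chunk = compounds[p * per_plate : (p + 1) * per_plate]
            rows: list[tuple] = []
            for r in range(n_rows):
                rows.append((well_name(r, 0), "negative", None, None, None))
                rows.append((well_name(r, n_cols - 1), "positive", None, None, None))
            idx = 0
            for r in range(n_rows):
                for c in range(1, n_cols - 1):
                    if idx < len(chunk):
                        rows.append((well_name(r, c), "compound", chunk[idx], float(conc), conc_unit))
                        idx += 1
                    else:
                        rows.append((well_name(r, c), "empty", None, None, None))
            layouts.append(cls.from_entries(rows, plate_id=f"{plate_prefix}{p + 1}"))
        return layouts
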