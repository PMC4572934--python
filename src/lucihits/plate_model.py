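"""Domain types and tabular I/O for dual-luciferase reporter screens.

A screen is a set of physical library plates, each assayed in one or more
replicates. Every well carries two luminescence readouts: firefly (the
pathway reporter, here NF-kB driven) and renilla (a constitutive internal
control for transfection efficiency and cell number). Wells are either
library wells (one compound at one dose, in the presence of the inducer)
or controls: DMSO vehicle, the reference agonist GW4064, the inducer TNFa
alone, or GW4064 plus TNFa.

Tables are plain UTF-8 CSV/TSV in long format, one row per well.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "WellRecord",
    "PlateLayout",
    "ScreenDataset",
    "ScreenValidationError",
    "read_screen",
    "write_screen",
    "read_layouts",
    "write_layouts",
]

#: Canonical well roles. LIBRARY wells carry a compound; the rest are controls.
ROLES = ("LIBRARY", "DMSO", "GW4064", "TNFA", "GW4064_TNFA")

#: Canonical column order for screen tables.
SCREEN_COLUMNS = [
    "plate_id",
    "replicate",
    "row",
    "col",
    "role",
    "compound_id",
    "concentration_M",
    "firefly",
    "renilla",
]

LAYOUT_COLUMNS = ["plate_id", "row", "col", "role", "compound_id"]

#: Supported plate formats: wells -> (n_rows, n_cols).
PLATE_FORMATS = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}


class ScreenValidationError(ValueError):
    """Raised when a screen table or layout violates an invariant."""


@dataclass(frozen=True)
class WellRecord:
    """One well's raw dual-reporter measurement.

    Rows are letters (A = top), columns are 1-based integers, following
    plate-reader export convention.
    """

    plate_id: str
    replicate: int
    row: str
    col: int
    role: str
    compound_id: str = ""
    concentration_M: float = float("nan")
    firefly: float = 0.0
    renilla: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ScreenValidationError(f"unknown role {self.role!r}")
        if self.role == "LIBRARY" and not self.compound_id:
            raise ScreenValidationError(
                f"LIBRARY well {self.plate_id}/{self.replicate} "
                f"{self.row}{self.col} has no compound_id"
            )
        if self.role != "LIBRARY" and self.compound_id:
            raise ScreenValidationError(
                f"control well {self.row}{self.col} carries a compound_id"
            )
        if self.firefly < 0 or self.renilla < 0:
            raise ScreenValidationError(
                f"negative luminescence at {self.plate_id}/{self.replicate} "
                f"{self.row}{self.col}"
            )

    @property
    def well(self) -> str:
        return f"{self.row}{self.col}"


@dataclass
class PlateLayout:
    """Role and compound assignment for one physical plate.

    Parameters
    ----------
    plate_id : str
        Identifier of the physical library plate.
    n_wells : int
        Plate format; one of 96, 384, 1536.
    roles : dict
        Mapping ``(row, col) -> role``. Positions absent from the mapping
        are unused wells.
    compounds : dict
        Mapping ``(row, col) -> compound_id`` for LIBRARY positions.
    """

    plate_id: str
    n_wells: int = 384
    roles: dict = field(default_factory=dict)
    compounds: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return PLATE_FORMATS[self.n_wells]

    def validate(self) -> None:
        if self.n_wells not in PLATE_FORMATS:
            raise ScreenValidationError(
                f"plate {self.plate_id}: unsupported format {self.n_wells}"
            )
        n_rows, n_cols = self.shape
        valid_rows = set(string.ascii_uppercase[:n_rows])
        for (row, col), role in self.roles.items():
            if row not in valid_rows or not (1 <= col <= n_cols):
                raise ScreenValidationError(
                    f"plate {self.plate_id}: position {row}{col} outside "
                    f"{n_rows}x{n_cols} format"
                )
            if role not in ROLES:
                raise ScreenValidationError(
                    f"plate {self.plate_id}: unknown role {role!r} at {row}{col}"
                )
            if role == "LIBRARY" and (row, col) not in self.compounds:
                raise ScreenValidationError(
                    f"plate {self.plate_id}: LIBRARY position {row}{col} "
                    "has no compound"
                )
        # the TNFa wells anchor both normalization and the null model
        counts = pd.Series(list(self.roles.values())).value_counts()
        if counts.get("TNFA", 0) < 3:
            raise ScreenValidationError(
                f"plate {self.plate_id}: fewer than 3 TNFA control wells"
            )
        for role in ("DMSO", "GW4064", "GW4064_TNFA"):
            if counts.get(role, 0) < 1:
                raise ScreenValidationError(
                    f"plate {self.plate_id}: no {role} control well"
                )

    def library_positions(self) -> list[tuple[str, int]]:
        return sorted(
            (pos for pos, role in self.roles.items() if role == "LIBRARY"),
            key=lambda rc: (rc[0], rc[1]),
        )


@dataclass
class ScreenDataset:
    """All wells of a screen, grouped by library plate and replicate.

    Attributes
    ----------
    wells : pandas.DataFrame
        Long-format well table with columns ``SCREEN_COLUMNS``.
    layouts : dict
        ``plate_id -> PlateLayout``.
    truth : pandas.DataFrame or None
        Optional ground-truth labels from synthetic generation, columns
        ``compound_id, true_inhibition_fraction, is_cytotoxic``.
    """

    wells: pd.DataFrame
    layouts: dict[str, PlateLayout]
    truth: pd.DataFrame | None = None

    @property
    def plate_ids(self) -> list[str]:
        return sorted(self.layouts)

    def replicates(self, plate_id: str) -> list[int]:
        mask = self.wells["plate_id"] == plate_id
        return sorted(self.wells.loc[mask, "replicate"].unique())

    def validate(self) -> None:
        df = self.wells
        missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
        if missing:
            raise ScreenValidationError(f"missing columns: {missing}")
        unknown_plates = set(df["plate_id"]) - set(self.layouts)
        if unknown_plates:
            raise ScreenValidationError(
                f"wells reference plates without layout: {sorted(unknown_plates)}"
            )
        bad_role = ~df["role"].isin(ROLES)
        if bad_role.any():
            i = df.index[bad_role][0]
            raise ScreenValidationError(
                f"row {i}: unknown role {df.at[i, 'role']!r}"
            )
        lib = df["role"] == "LIBRARY"
        no_cmpd = lib & (df["compound_id"].fillna("") == "")
        if no_cmpd.any():
            i = df.index[no_cmpd][0]
            raise ScreenValidationError(
                f"row {i}: LIBRARY well {df.at[i, 'plate_id']} "
                f"{df.at[i, 'row']}{df.at[i, 'col']} without compound_id"
            )
        if (df[["firefly", "renilla"]] < 0).any().any():
            bad = (df[["firefly", "renilla"]] < 0).any(axis=1)
            i = df.index[bad][0]
            raise ScreenValidationError(f"row {i}: negative luminescence")
        dup = df.duplicated(["plate_id", "replicate", "row", "col"])
        if dup.any():
            i = df.index[dup][0]
            raise ScreenValidationError(
                f"row {i}: duplicate well {df.at[i, 'plate_id']}/"
                f"{df.at[i, 'replicate']} {df.at[i, 'row']}{df.at[i, 'col']}"
            )
        for plate_id, layout in self.layouts.items():
            layout.validate()
            expected = set(layout.roles)
            for rep, grp in df[df["plate_id"] == plate_id].groupby("replicate"):
                got = set(zip(grp["row"], grp["col"]))
                if got != expected:
                    raise ScreenValidationError(
                        f"plate {plate_id} replicate {rep}: wells do not "
                        "match layout"
                    )
                roles = dict(zip(zip(grp["row"], grp["col"]), grp["role"]))
                for pos, role in roles.items():
                    if layout.roles[pos] != role:
                        raise ScreenValidationError(
                            f"plate {plate_id} replicate {rep}: role mismatch "
                            f"at {pos[0]}{pos[1]}"
                        )


def _canonical_wells(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["role"] = out["role"].str.upper()
    out["compound_id"] = out["compound_id"].fillna("").astype(str)
    out["replicate"] = out["replicate"].astype(int)
    out["col"] = out["col"].astype(int)
    for c in ("concentration_M", "firefly", "renilla"):
        out[c] = out[c].astype(float)
    out = out[SCREEN_COLUMNS].sort_values(
        ["plate_id", "replicate", "row", "col"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_layouts(path) -> dict[str, PlateLayout]:
    """Read a layout table (``plate_id, row, col, role, compound_id``)."""
    df = pd.read_csv(path, sep=_sep(path), dtype={"compound_id": str},
                     comment="#", keep_default_na=False)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenValidationError(f"layout missing columns: {missing}")
    layouts: dict[str, PlateLayout] = {}
    for plate_id, grp in df.groupby("plate_id"):
        roles, compounds = {}, {}
        for _, r in grp.iterrows():
            pos = (str(r["row"]), int(r["col"]))
            if pos in roles:
                raise ScreenValidationError(
                    f"plate {plate_id}: position {pos[0]}{pos[1]} mapped twice"
                )
            roles[pos] = str(r["role"]).upper()
            if roles[pos] == "LIBRARY":
                compounds[pos] = str(r["compound_id"])
        layout = PlateLayout(str(plate_id), 384, roles, compounds)
        layout.validate()
        layouts[str(plate_id)] = layout
    return layouts


def write_layouts(layouts: dict[str, PlateLayout], path) -> None:
    rows = []
    for plate_id in sorted(layouts):
        lay = layouts[plate_id]
        for (row, col) in sorted(lay.roles, key=lambda rc: (rc[0], rc[1])):
            rows.append(
                {
                    "plate_id": plate_id,
                    "row": row,
                    "col": col,
                    "role": lay.roles[(row, col)],
                    "compound_id": lay.compounds.get((row, col), ""),
                }
            )
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(
        path, sep=_sep(path), index=False
    )


def read_screen(path, layout_path) -> ScreenDataset:
    """Read and validate a screen table against its layout.

    Raises
    ------
    ScreenValidationError
        On missing columns, unknown roles, duplicate wells, LIBRARY wells
        without a compound, or layout mismatches; the message names the
        offending row or plate.
    """
    layouts = read_layouts(layout_path)
    df = pd.read_csv(path, sep=_sep(path), dtype={"compound_id": str},
                     comment="#", keep_default_na=False,
                     float_precision="round_trip")
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenValidationError(f"screen table missing columns: {missing}")
    df["concentration_M"] = pd.to_numeric(
        df["concentration_M"].replace("", np.nan)
    )
    for c in ("firefly", "renilla"):
        df[c] = pd.to_numeric(df[c])
    bad_role = ~df["role"].str.upper().isin(ROLES)
    if bad_role.any():
        i = df.index[bad_role][0]
        raise ScreenValidationError(f"row {i}: unknown role {df.at[i, 'role']!r}")
    ds = ScreenDataset(_canonical_wells(df), layouts)
    ds.validate()
    return ds


def write_screen(dataset: ScreenDataset, path, provenance: str | None = None) -> None:
    """Write a screen table with deterministic column order and row sort.

    Rows sort by (plate_id, replicate, row, col); output is re-readable by
    :func:`read_screen`. An optional provenance string is written as a
    leading ``#`` comment line.
    """
    df = _canonical_wells(dataset.wells)
    sep = _sep(path)
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep=sep, index=False)
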