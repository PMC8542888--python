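"""Typed readers/writers and validation for batch tables, breakthrough tables,
packaged reference fixtures and run configuration.

All tables are plain CSV (comma-separated, UTF-8, header row mandatory,
"." decimal separator).  Internal units: concentrations mg/L, volumes L,
sorbent masses kg, so partition coefficients come out in L/kg without
conversion factors.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, ParseError, SchemaError, UnitError, ValidationError
from .transport import BreakthroughCurve, ColumnLayer, FilterColumn, SolverSettings

logger = logging.getLogger(__name__)

__all__ = [
    "Micropollutant",
    "BatchRecord",
    "BatchDataset",
    "RunConfig",
    "read_batch_table",
    "write_batch_table",
    "read_breakthrough_table",
    "write_breakthrough_table",
    "read_filter_config",
    "write_kbc_matrix",
    "read_kbc_matrix",
    "load_compound_properties",
    "load_field_batch_table",
]

#: relative tolerance for Ce <= C0 (absorbs triplicate analytical scatter)
CE_TOLERANCE = 0.05
#: default contact time in hours when the column is absent
DEFAULT_CONTACT_H = 24.0


@dataclass(frozen=True)
class Micropollutant:
    """Physico-chemical properties of one compound.

    ``pka_values`` is a list of floats where numeric values are known, or
    the sentinel strings ``"multiple"`` / ``"n/a"`` where only qualitative
    information exists.
    """

    name: str
    molecular_mass: float  # g/mol
    pka_values: tuple | str
    logp: float

    def __post_init__(self) -> None:
        if self.molecular_mass <= 0:
            raise ValidationError(f"{self.name}: molecular mass must be positive")


@dataclass(frozen=True)
class BatchRecord:
    """One equilibrium batch sorption observation."""

    compound: str
    sorbent: str
    c0: float  # initial aqueous concentration, mg/L
    ce: float  # equilibrium aqueous concentration, mg/L
    volume: float  # solution volume, L
    mass: float  # sorbent mass, kg
    nacl_molarity: float = 0.0
    ph_initial: float | None = None
    contact_time: float = DEFAULT_CONTACT_H  # h

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.ce < 0:
            raise ValidationError("concentrations must be non-negative")
        if self.volume <= 0 or self.mass <= 0:
            raise ValidationError("volume and mass must be positive")
        if self.ce > self.c0 * (1.0 + CE_TOLERANCE):
            raise ValidationError(
                f"ce={self.ce} exceeds c0={self.c0} beyond the {CE_TOLERANCE:.0%} tolerance"
            )
        if self.ph_initial is not None and not 0.0 <= self.ph_initial <= 14.0:
            raise ValidationError("pH must lie in [0, 14]")
        if self.contact_time <= 0:
            raise ValidationError("contact time must be positive")

    @property
    def loading(self) -> float:
        """Sorbent loading in mg/L (mass over solution volume)."""
        return self.mass / self.volume * 1e6


class BatchDataset:
    """An ordered collection of validated :class:`BatchRecord` objects."""

    def __init__(self, records):
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, idx):
        return self.records[idx]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "compound": r.compound,
                "sorbent": r.sorbent,
                "c0_mg_L": r.c0,
                "ce_mg_L": r.ce,
                "volume_L": r.volume,
                "mass_kg": r.mass,
                "nacl_M": r.nacl_molarity,
                "ph": r.ph_initial,
                "contact_h": r.contact_time,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=MANDATORY_BATCH_COLUMNS + OPTIONAL_BATCH_COLUMNS)

    def subset(self, compound=None, sorbent=None):
        records = [
            r
            for r in self.records
            if (compound is None or r.compound == compound)
            and (sorbent is None or r.sorbent == sorbent)
        ]
        return BatchDataset(records)


MANDATORY_BATCH_COLUMNS = ["compound", "sorbent", "c0_mg_L", "ce_mg_L", "volume_L", "mass_kg"]
OPTIONAL_BATCH_COLUMNS = ["nacl_M", "ph", "contact_h"]


def _numeric(frame: pd.DataFrame, column: str, path) -> pd.Series:
    raw = frame[column]
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: non-numeric value {raw.iloc[row]!r} in column {column!r}, row {row}")
    return converted


def read_batch_table(path) -> BatchDataset:
    """Read and validate a batch sorption CSV.

    Mandatory headers: compound, sorbent, c0_mg_L, ce_mg_L, volume_L,
    mass_kg.  Optional: nacl_M (default 0), ph, contact_h (default 24).
    Rows with ce > c0*(1+5%) raise :class:`ValidationError` naming the row.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANDATORY_BATCH_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    if frame.empty:
        logger.warning("%s: valid header but no data rows; returning empty dataset", path)
        return BatchDataset([])
    for column in MANDATORY_BATCH_COLUMNS[2:] + [c for c in OPTIONAL_BATCH_COLUMNS if c in frame.columns]:
        frame[column] = _numeric(frame, column, path)
    records = []
    for idx, row in frame.iterrows():
        try:
            records.append(
                BatchRecord(
                    compound=str(row["compound"]),
                    sorbent=str(row["sorbent"]),
                    c0=row["c0_mg_L"],
                    ce=row["ce_mg_L"],
                    volume=row["volume_L"],
                    mass=row["mass_kg"],
                    nacl_molarity=0.0 if pd.isna(row.get("nacl_M")) else float(row.get("nacl_M", 0.0)),
                    ph_initial=None if pd.isna(row.get("ph")) else float(row.get("ph")),
                    contact_time=DEFAULT_CONTACT_H
                    if pd.isna(row.get("contact_h"))
                    else float(row.get("contact_h")),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}: row {idx}: {err}") from err
    return BatchDataset(records)


def write_batch_table(dataset: BatchDataset, path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


BREAKTHROUGH_COLUMNS = ["filter_id", "cum_volume_L", "c_out", "c_in", "unit"]


def read_breakthrough_table(path) -> list[BreakthroughCurve]:
    """Read observed breakthrough curves, one per filter_id.

    Points are sorted by cumulative volume within each filter; duplicate or
    non-monotone volumes and mixed units within a filter are rejected.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in BREAKTHROUGH_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    for column in ("cum_volume_L", "c_out", "c_in"):
        frame[column] = _numeric(frame, column, path)
    curves = []
    for filter_id, group in frame.groupby("filter_id", sort=False):
        units = group["unit"].astype(str).unique()
        if len(units) > 1:
            raise UnitError(f"{path}: filter {filter_id!r} mixes units {sorted(units)}")
        group = group.sort_values("cum_volume_L")
        volumes = group["cum_volume_L"].to_numpy()
        if np.any(np.diff(volumes) <= 0):
            raise ValidationError(
                f"{path}: filter {filter_id!r}: cumulative volume not strictly increasing"
            )
        if (group["c_in"] <= 0).any():
            raise ValidationError(f"{path}: filter {filter_id!r}: c_in must be positive")
        curves.append(
            BreakthroughCurve(
                volumes=volumes,
                c_over_cin=(group["c_out"] / group["c_in"]).to_numpy(),
                provenance="observed",
                label=str(filter_id),
                unit=str(units[0]),
            )
        )
    return curves


def write_breakthrough_table(curves, path, c_in: float = 1.0, unit: str = "mg/L") -> None:
    frames = []
    for curve in curves:
        frames.append(
            pd.DataFrame(
                {
                    "filter_id": curve.label or curve.provenance,
                    "cum_volume_L": curve.volumes,
                    "c_out": curve.c_over_cin * (curve.c_in or c_in),
                    "c_in": curve.c_in or c_in,
                    "unit": curve.unit or unit,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# --------------------------------------------------------------------------
# K_bc matrix CSV (first line is a metadata comment)
# --------------------------------------------------------------------------

def write_kbc_matrix(matrix, path) -> None:
    """Write a KbcMatrix with a metadata comment line (loading, censoring)."""
    path = Path(path)
    censored = sorted(
        f"{c}/{s}"
        for c in matrix.values.index
        for s in matrix.values.columns
        if matrix.censored.loc[c, s]
    )
    meta = f"# loading_mg_L={matrix.loading}; censored_cells={';'.join(censored) or 'none'}\n"
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(meta)
        matrix.values.to_csv(handle, index_label="compound")


def read_kbc_matrix(path):
    from .batch import KbcMatrix  # local import avoids a cycle

    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        meta = handle.readline()
        if not meta.startswith("#"):
            raise SchemaError(f"{path}: expected a leading metadata comment line")
        frame = pd.read_csv(handle, index_col="compound", float_precision="round_trip")
    frame.index.name = None
    frame.columns.name = None
    loading = float(meta.split("loading_mg_L=")[1].split(";")[0])
    censored = pd.DataFrame(False, index=frame.index, columns=frame.columns)
    token = meta.split("censored_cells=")[1].strip()
    if token != "none":
        for cell in token.split(";"):
            compound, sorbent = cell.split("/")
            censored.loc[compound, sorbent] = True
    counts = pd.DataFrame(np.nan, index=frame.index, columns=frame.columns)
    return KbcMatrix(values=frame, counts=counts, sds=counts.copy(), censored=censored, loading=loading)


# --------------------------------------------------------------------------
# packaged fixtures
# --------------------------------------------------------------------------

def _fixture(name: str):
    return resources.files("sorbfate.data").joinpath(name)


def _parse_pka(token: str):
    token = token.strip()
    if token in ("multiple", "n/a"):
        return token
    values = []
    for part in token.split(";"):
        part = part.strip()
        if "-" in part[1:]:  # a range like 5.88-6.06 -> midpoint
            lo, hi = part.rsplit("-", 1)
            values.append((float(lo) + float(hi)) / 2.0)
        else:
            values.append(float(part))
    return tuple(values)


def load_compound_properties() -> list[Micropollutant]:
    """Packaged compound-property fixture (molecular mass, pKa, logP)."""
    with resources.as_file(_fixture("compound_properties.csv")) as path:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        Micropollutant(
            name=row["name"],
            molecular_mass=float(row["molecular_mass_g_mol"]),
            pka_values=_parse_pka(row["pka"]),
            logp=float(row["logp"]),
        )
        for _, row in frame.iterrows()
    ]


def load_field_batch_table() -> pd.DataFrame:
    """Packaged field-vs-batch partition-coefficient fixture.

    Columns: compound, coefficient (K_s or K_bc), sorbent, field_L_kg
    (string; may be left-censored like ``"<0.1"``), batch_L_kg (float or
    missing for K_s rows).
    """
    with resources.as_file(_fixture("field_batch_kbc.csv")) as path:
        return pd.read_csv(path, dtype={"field_L_kg": str})


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Filter geometry, solver and fitting settings plus the run seed.

    Serialised as YAML; :meth:`provenance` returns the config hash and seed
    that every output artifact should carry.
    """

    column: FilterColumn
    solver: SolverSettings = field(default_factory=SolverSettings)
    fitting: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        column = _column_from_dict(raw.get("column", raw))
        solver = SolverSettings(**raw.get("solver", {}))
        return cls(column=column, solver=solver, fitting=raw.get("fitting", {}), seed=int(raw.get("seed", 0)))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    def to_dict(self) -> dict:
        return {
            "column": _column_to_dict(self.column),
            "solver": {
                "n_cells": self.solver.n_cells,
                "courant": self.solver.courant,
                "peclet_max": self.solver.peclet_max,
                "max_cells": self.solver.max_cells,
                "inlet": self.solver.inlet,
                "compensate_numerical_dispersion": self.solver.compensate_numerical_dispersion,
                "dt_max": self.solver.dt_max,
            },
            "fitting": self.fitting,
            "seed": self.seed,
        }

    def provenance(self) -> dict:
        digest = hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()
        return {"config_sha256": digest, "seed": self.seed}


def _column_from_dict(raw: dict) -> FilterColumn:
    try:
        layers = tuple(
            ColumnLayer(
                name=layer["name"],
                mass=float(layer["mass_kg"]),
                bulk_density=float(layer["bulk_density_kg_L"]),
                porosity=float(layer["porosity"]),
                sand_fraction=float(layer.get("sand_fraction", 0.0)),
                biochar_fraction=float(layer.get("biochar_fraction", 0.0)),
            )
            for layer in raw["layers"]
        )
        return FilterColumn(
            layers=layers,
            cross_section=float(raw["cross_section_m2"]),
            flow_rate=float(raw["flow_rate_L_min"]),
            dispersivity=raw.get("dispersivity_m"),
            molecular_diffusion=float(raw.get("molecular_diffusion_m2_s", 1.0e-9)),
            conditioning_time=float(raw.get("conditioning_min", 15.0)),
        )
    except KeyError as err:
        raise ConfigError(f"filter config missing key: {err}") from err


def _column_to_dict(column: FilterColumn) -> dict:
    return {
        "cross_section_m2": column.cross_section,
        "flow_rate_L_min": column.flow_rate,
        "dispersivity_m": column.dispersivity,
        "molecular_diffusion_m2_s": column.molecular_diffusion,
        "conditioning_min": column.conditioning_time,
        "layers": [
            {
                "name": layer.name,
                "mass_kg": layer.mass,
                "bulk_density_kg_L": layer.bulk_density,
                "porosity": layer.porosity,
                "sand_fraction": layer.sand_fraction,
                "biochar_fraction": layer.biochar_fraction,
            }
            for layer in column.layers
        ],
    }


def read_filter_config(path) -> FilterColumn:
    """Read a YAML filter configuration into a :class:`FilterColumn`."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    return _column_from_dict(raw.get("column", raw))
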