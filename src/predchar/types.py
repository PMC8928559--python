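"""Shared domain types.

The package is DataFrame-centric: tables of populations and evaluation
records travel as :class:`pandas.DataFrame` objects with documented column
schemas, while gridded data and results use the dataclasses below.  The
record dataclasses (:class:`OccurrencePopulation`, :class:`EvaluationRecord`)
exist for typing single entities and for tests; bulk operations never build
one object per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Sentinel used in delimited files for missing numeric values.  Internally
#: missing values are NaN; "0" is a legal value and never means missing.
NODATA = -9999.0

#: The three ecogeographic components every variable belongs to.
COMPONENTS = ("bioclimatic", "edaphic", "geophysic")

#: Controlled taxon vocabulary for wild lentil occurrence tables.
TAXA = (
    "L. nigricans",
    "L. ervoides",
    "L. lamottei",
    "L. culinaris ssp. orientalis",
    "L. culinaris ssp. odemensis",
)

OCCURRENCE_COLUMNS = ("pop_id", "taxon", "lon", "lat", "country", "source")
EVALUATION_COLUMNS = ("accession_id", "lon", "lat", "trait", "dsr")


class SchemaError(ValueError):
    """A required column is missing or a table violates its schema."""


class ValidationError(ValueError):
    """Row-level contract violation (duplicates, out-of-range values)."""


class DimensionError(ValueError):
    """Grids with incompatible specs were combined."""


class DomainError(ValueError):
    """An index or classification was requested outside its domain."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid (WGS84 decimal degrees).

    ``xll``/``yll`` are the coordinates of the lower-left *corner* of the
    grid, matching the ESRI ASCII convention; cell centers sit half a cell
    inward.  Cell size defaults to 2.5 arc-minutes.
    """

    n_rows: int
    n_cols: int
    xll: float = 0.0
    yll: float = 0.0
    cell_size: float = 2.5 / 60.0
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise DimensionError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise DimensionError("grid must have at least one cell")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center; row 0 is the *top* row."""
        lon = self.xll + (col + 0.5) * self.cell_size
        lat = self.yll + (self.n_rows - row - 0.5) * self.cell_size
        return lon, lat

    def index_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Nearest-center cell index for a point, or None if outside."""
        col = int(np.floor((lon - self.xll) / self.cell_size))
        row_from_bottom = int(np.floor((lat - self.yll) / self.cell_size))
        row = self.n_rows - 1 - row_from_bottom
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) for all cell centers."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.xll + (cols + 0.5) * self.cell_size
        lat = self.yll + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(lon, lat)


@dataclass
class EnvironmentalStack:
    """Named gridded layers sharing one grid spec, tagged by component."""

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    component: dict[str, str] = field(default_factory=dict)

    def add_layer(self, name: str, values: np.ndarray, component: str) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise DimensionError(
                f"layer {name!r} has shape {values.shape}, grid expects "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )
        if component not in COMPONENTS:
            raise ValidationError(f"unknown component {component!r} for {name!r}")
        self.layers[name] = values
        self.component[name] = component

    def names(self, component: str | None = None) -> list[str]:
        if component is None:
            return list(self.layers)
        return [n for n in self.layers if self.component[n] == component]

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells finite in every layer."""
        mask = np.ones((self.grid.n_rows, self.grid.n_cols), dtype=bool)
        for arr in self.layers.values():
            mask &= np.isfinite(arr)
        return mask


@dataclass(frozen=True)
class Variable:
    name: str
    component: str
    units: str = ""
    description: str = ""


@dataclass
class VariableRegistry:
    """Declares every ecogeographic variable and its component."""

    variables: dict[str, Variable] = field(default_factory=dict)

    def add(self, name: str, component: str, units: str = "", description: str = "") -> None:
        if name in self.variables:
            raise ValidationError(f"duplicate variable name {name!r}")
        if component not in COMPONENTS:
            raise ValidationError(f"unknown component {component!r}")
        self.variables[name] = Variable(name, component, units, description)

    def component_of(self, name: str) -> str:
        return self.variables[name].component

    def names(self, component: str | None = None) -> list[str]:
        if component is None:
            return list(self.variables)
        return [n for n, v in self.variables.items() if v.component == component]

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    def __len__(self) -> int:
        return len(self.variables)


@dataclass(frozen=True)
class OccurrencePopulation:
    """One georeferenced wild population."""

    pop_id: str
    taxon: str
    lon: float
    lat: float
    country: str = ""
    genebank_held: bool = False
    env: Mapping[str, float] = field(default_factory=dict)
    elc_category: int | None = None


@dataclass
class EvaluationRecord:
    """One trait-evaluated accession with a 0-100 disease severity rating."""

    accession_id: str
    lon: float
    lat: float
    trait: str
    dsr: float
    resistant: bool | None = None


def genebank_held(pop_id: str) -> bool:
    """Whether an identifier denotes a genebank-preserved population.

    Genebank entries carry identifier codes starting with "GE"; in-situ-only
    records use other prefixes (e.g. "ID_...").
    """
    return str(pop_id).startswith("GE")
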