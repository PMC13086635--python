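"""From range maps to a cell x species presence matrix and richness.

Ranges arrive either as per-species cell lists or as polygons in the
grid's lon/lat frame; polygons are rasterised with an "intersects"
rule by default (a cell is occupied if the polygon overlaps it at
all), with "centroid" available as the stricter alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DiversityLayer, GridSpec
from .synthetic import RangeSet
from .traits import TraitTable

__all__ = [
    "PresenceMatrix",
    "TaxonomyFilter",
    "rasterize_ranges",
    "filter_taxa",
    "taxonomic_diversity",
    "missingness_summary",
]


@dataclass
class PresenceMatrix:
    """Binary cell x species occurrence table on a rectangular grid."""

    grid: GridSpec
    species_ids: list[str]
    values: np.ndarray  # (n_cells, n_species) of 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (self.grid.n_cells, len(self.species_ids)):
            raise ValueError("values shape must be (n_cells, n_species)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence values must be 0 or 1")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species ids")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def column(self, species: str) -> np.ndarray:
        return self.values[:, self.species_ids.index(species)]

    def species_in_cell(self, cell: int) -> list[str]:
        present = np.flatnonzero(self.values[cell])
        return [self.species_ids[j] for j in present]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(np.arange(self.grid.n_cells), name="cell"),
            columns=self.species_ids,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path, grid: GridSpec) -> "PresenceMatrix":
        df = pd.read_csv(path, index_col="cell")
        return cls(grid, list(df.columns), df.to_numpy())


@dataclass
class TaxonomyFilter:
    """Synonym merges and exclusions applied before analysis.

    ``synonym_map`` maps an old name to its accepted name; chains must
    resolve in one step. ``exclusions`` are dropped outright.
    """

    synonym_map: dict[str, str] = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        excluded = set(self.exclusions)
        for old, new in self.synonym_map.items():
            if new in excluded:
                raise ValueError(f"synonym target {new!r} is excluded")
            if new in self.synonym_map:
                raise ValueError(f"synonym chain {old!r} -> {new!r} -> ... must resolve in one step")


def rasterize_ranges(ranges, grid: GridSpec, rule: str = "intersects") -> PresenceMatrix:
    """Superimpose ranges onto the grid, one binary column per species.

    Accepts a :class:`RangeSet` (cell lists, used as-is) or a mapping
    of species id to a shapely geometry. For polygons, ``rule``
    chooses between "intersects" (any overlap occupies the cell) and
    "centroid" (the cell centroid must fall inside). Species whose
    range touches no cell keep an all-zero column and trigger a
    warning rather than being dropped.
    """
    values_cols: list[np.ndarray] = []
    species: list[str] = []

    if isinstance(ranges, RangeSet):
        if ranges.grid != grid:
            raise ValueError("RangeSet grid differs from target grid")
        items = [(sp, ("cells", cells)) for sp, cells in ranges.ranges.items()]
    else:
        items = [(sp, ("geom", geom)) for sp, geom in ranges.items()]

    for sp, (kind, payload) in items:
        col = np.zeros(grid.n_cells, dtype=np.uint8)
        if kind == "cells":
            col[payload] = 1
        else:
            col = _rasterize_geometry(payload, grid, rule)
        if col.sum() == 0:
            warnings.warn(f"range of {sp!r} intersects no grid cell", stacklevel=2)
        species.append(sp)
        values_cols.append(col)

    values = (
        np.column_stack(values_cols) if values_cols else np.zeros((grid.n_cells, 0), np.uint8)
    )
    return PresenceMatrix(grid, species, values)


def _rasterize_geometry(geom, grid: GridSpec, rule: str) -> np.ndarray:
    from shapely.geometry import Point, box

    if rule not in ("intersects", "centroid"):
        raise ValueError("rule must be 'intersects' or 'centroid'")
    col = np.zeros(grid.n_cells, dtype=np.uint8)
    for cell in range(grid.n_cells):
        if rule == "intersects":
            hit = geom.intersects(box(*grid.cell_bounds(cell)))
        else:
            hit = geom.contains(Point(*grid.centroid(cell)))
        col[cell] = 1 if hit else 0
    return col


def filter_taxa(matrix: PresenceMatrix, taxo: TaxonomyFilter) -> PresenceMatrix:
    """Merge synonyms (logical OR of columns) and drop excluded taxa.

    A synonym whose accepted name is absent from the matrix is simply
    renamed. Retained columns keep their original order; a merged
    column sits at the position of the accepted name (or of the old
    name when renaming).
    """
    cols: dict[str, np.ndarray] = {}
    for j, sp in enumerate(matrix.species_ids):
        name = taxo.synonym_map.get(sp, sp)
        if name in cols:
            cols[name] = np.maximum(cols[name], matrix.values[:, j])
        else:
            cols[name] = matrix.values[:, j].copy()
    for sp in taxo.exclusions:
        cols.pop(sp, None)
    species = list(cols)
    values = (
        np.column_stack([cols[s] for s in species])
        if species
        else np.zeros((matrix.grid.n_cells, 0), np.uint8)
    )
    return PresenceMatrix(matrix.grid, species, values)


def taxonomic_diversity(matrix: PresenceMatrix, mask: np.ndarray | None = None) -> DiversityLayer:
    """Per-cell species richness (row sums); NaN outside the mask."""
    td = matrix.values.sum(axis=1).astype(float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).ravel()
        td = np.where(mask, td, np.nan)
    return DiversityLayer(matrix.grid, td, name="TD")


def missingness_summary(traits: TraitTable) -> dict:
    """Count species missing any quantitative value.

    Returns ``n_species``, ``n_missing`` and ``percent_missing``
    (rounded to one decimal, e.g. 180 of 1091 species -> 16.5).
    """
    if traits.n_species == 0:
        raise ValueError("empty trait table")
    n_missing = len(traits.species_with_missing())
    return {
        "n_species": traits.n_species,
        "n_missing": n_missing,
        "percent_missing": round(100.0 * n_missing / traits.n_species, 1),
    }
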