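"""Readers and writers for the package's plain-text interchange formats.

Trees travel as Newick, tables and per-cell layers as CSV, ranges
optionally as GeoJSON polygons (cell boxes dissolved per species).
"""

from __future__ import annotations

import json

import dendropy
import numpy as np
import pandas as pd

from .grid import DiversityLayer, GridSpec
from .synthetic import BiomeMap, ClimateStack, RangeSet

__all__ = [
    "write_tree", "read_tree",
    "layer_to_csv", "layer_from_csv",
    "climate_to_csv", "climate_from_csv",
    "biomes_to_csv", "biomes_from_csv",
    "ranges_to_csv", "ranges_from_csv", "ranges_to_geojson",
]


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def layer_to_csv(layer: DiversityLayer, path) -> None:
    rows, cols = np.divmod(np.arange(layer.grid.n_cells), layer.grid.n_cols)
    pd.DataFrame(
        {"cell": np.arange(layer.grid.n_cells), "row": rows, "col": cols,
         layer.name: layer.values}
    ).to_csv(path, index=False)


def layer_from_csv(path, grid: GridSpec, name: str) -> DiversityLayer:
    df = pd.read_csv(path).sort_values("cell")
    return DiversityLayer(grid, df[name].to_numpy(dtype=float), name=name)


def climate_to_csv(stack: ClimateStack, path) -> None:
    stack.to_dataframe().to_csv(path, index=False)


def climate_from_csv(path, grid: GridSpec) -> ClimateStack:
    df = pd.read_csv(path)
    layers = list(dict.fromkeys(df["layer"]))
    ages = sorted(df["age_kyr"].unique(), reverse=True)
    values = np.empty((len(layers), len(ages), grid.n_cells))
    for li, layer in enumerate(layers):
        for si, age in enumerate(ages):
            sub = df[(df["layer"] == layer) & (df["age_kyr"] == age)].sort_values("cell")
            values[li, si] = sub["value"].to_numpy()
    return ClimateStack(grid, layers, [float(a) for a in ages], values)


def biomes_to_csv(biomes: BiomeMap, path) -> None:
    biomes.to_dataframe().to_csv(path, index=False)


def biomes_from_csv(path, grid: GridSpec) -> BiomeMap:
    df = pd.read_csv(path).sort_values("cell")
    return BiomeMap(grid, df["biome"].to_numpy(dtype=object))


def ranges_to_csv(ranges: RangeSet, path) -> None:
    ranges.to_dataframe().to_csv(path, index=False)


def ranges_from_csv(path, grid: GridSpec) -> RangeSet:
    df = pd.read_csv(path)
    return RangeSet(
        grid, {sp: g["cell"].to_numpy() for sp, g in df.groupby("species", sort=True)}
    )


def ranges_to_geojson(ranges: RangeSet, path) -> None:
    """Each species' range as a dissolved polygon of its cell boxes."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    features = []
    for sp, cells in ranges.ranges.items():
        geom = unary_union([box(*ranges.grid.cell_bounds(int(c))) for c in cells])
        features.append(
            {"type": "Feature", "properties": {"species": sp}, "geometry": mapping(geom)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
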