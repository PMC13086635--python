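"""Synthetic worlds with the statistical structure the pipeline assumes.

Everything downstream of raw data ingestion — community assembly,
diversity metrics, distribution modelling, spatial regression, the
ecotone test — can be exercised on worlds built here: an ultrametric
phylogeny, Brownian-motion quantitative traits and Markov-chain
categorical traits, climate histories as smoothed random fields with a
controlled temporal drift, climate-defined contiguous species ranges,
and a multi-biome band mosaic with shared boundaries.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec
from .traits import TraitTable

__all__ = [
    "ClimateStack",
    "BiomeMap",
    "RangeSet",
    "generate_phylogeny",
    "simulate_traits",
    "mask_trait_values",
    "generate_climate_stack",
    "derive_terrain",
    "generate_biome_map",
    "generate_ranges",
    "paleo_slice_ages",
]

OUTSIDE = "outside"

#: 8-connectivity structuring element for connected-component labelling.
_CONN8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ClimateStack:
    """Named environmental layers across ordered paleo time slices.

    ``values`` has shape (n_layers, n_slices, n_cells). ``slice_ages``
    are in kyr before present and strictly decrease toward the present;
    the last slice (age 0) is the present day.
    """

    grid: GridSpec
    layer_names: list[str]
    slice_ages: list[float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.layer_names), len(self.slice_ages), self.grid.n_cells)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        ages = np.asarray(self.slice_ages, dtype=float)
        if len(ages) > 1 and not np.all(np.diff(ages) < 0):
            raise ValueError("slice ages must strictly decrease toward the present")

    @property
    def n_slices(self) -> int:
        return len(self.slice_ages)

    @property
    def present_index(self) -> int:
        return self.n_slices - 1

    def layer_index(self, name: str) -> int:
        try:
            return self.layer_names.index(name)
        except ValueError:
            raise KeyError(f"no layer named {name!r}") from None

    def layer(self, name: str, slice_index: int | None = None) -> np.ndarray:
        """Flat per-cell values of one layer at one slice (default: present)."""
        if slice_index is None:
            slice_index = self.present_index
        return self.values[self.layer_index(name), slice_index]

    def with_layer(self, name: str, per_slice: np.ndarray) -> "ClimateStack":
        """Return a copy with an extra layer (shape (n_slices, n_cells) or (n_cells,))."""
        per_slice = np.asarray(per_slice, dtype=float)
        if per_slice.ndim == 1:
            per_slice = np.broadcast_to(per_slice, (self.n_slices, self.grid.n_cells))
        return ClimateStack(
            self.grid,
            self.layer_names + [name],
            list(self.slice_ages),
            np.concatenate([self.values, per_slice[None]], axis=0),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Flat CSV layout: one row per (cell, layer, slice)."""
        layer_idx, slice_idx, cell_idx = np.meshgrid(
            np.arange(len(self.layer_names)),
            np.arange(self.n_slices),
            np.arange(self.grid.n_cells),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "cell": cell_idx.ravel(),
                "layer": np.asarray(self.layer_names)[layer_idx.ravel()],
                "age_kyr": np.asarray(self.slice_ages)[slice_idx.ravel()],
                "value": self.values.ravel(),
            }
        )


@dataclass
class BiomeMap:
    """Per-cell biome labels; ``"outside"`` marks cells in no modelled biome."""

    grid: GridSpec
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.grid.n_cells,):
            raise ValueError("one label per cell required")

    @property
    def biomes(self) -> list[str]:
        """Modelled biome names in sorted order (excludes 'outside')."""
        return sorted(set(self.labels) - {OUTSIDE})

    def cells_of(self, biome: str) -> np.ndarray:
        if biome != OUTSIDE and biome not in self.biomes:
            raise KeyError(f"unknown biome label {biome!r}")
        return np.flatnonzero(self.labels == biome)

    def mask_of(self, biome: str) -> np.ndarray:
        """2-D boolean membership mask."""
        if biome != OUTSIDE and biome not in self.biomes:
            raise KeyError(f"unknown biome label {biome!r}")
        return self.grid.to_array(self.labels == biome)

    def to_dataframe(self) -> pd.DataFrame:
        rows, cols = np.divmod(np.arange(self.grid.n_cells), self.grid.n_cols)
        return pd.DataFrame(
            {"cell": np.arange(self.grid.n_cells), "row": rows, "col": cols,
             "biome": self.labels}
        )


@dataclass
class RangeSet:
    """Per-species occupied cell sets on a shared grid."""

    grid: GridSpec
    ranges: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for sp, cells in self.ranges.items():
            arr = np.unique(np.asarray(cells, dtype=int))
            if arr.size and (arr.min() < 0 or arr.max() >= self.grid.n_cells):
                raise ValueError(f"range of {sp!r} has cells outside the grid")
            clean[sp] = arr
        self.ranges = clean

    @property
    def species(self) -> list[str]:
        return list(self.ranges)

    def to_dataframe(self) -> pd.DataFrame:
        recs = [
            (sp, int(c)) for sp, cells in self.ranges.items() for c in cells
        ]
        return pd.DataFrame(recs, columns=["species", "cell"])


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def generate_phylogeny(n_species: int, seed: int) -> dendropy.Tree:
    """Simulate a rooted, ultrametric, binary tree with ``n_species`` tips.

    A coalescent-style construction: all tips start at the present and
    random pairs of lineages merge at exponentially spaced times; node
    ages are finally rescaled so the root sits at height 1. Tip labels
    are ``sp0001`` ... and the tree is bit-identical for a given seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    width = max(4, len(str(n_species)))
    lineages: list[tuple[dendropy.Node, float]] = []
    for i in range(n_species):
        label = f"sp{i + 1:0{width}d}"
        node = dendropy.Node(taxon=dendropy.Taxon(label=label))
        taxa.add_taxon(node.taxon)
        lineages.append((node, 0.0))

    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(scale=1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, _), (b, _) = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        for child, h in (lineages[i], lineages[j]):
            child.edge.length = t - h
        # replace the two merged lineages, keep list order deterministic
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append((parent, t))

    root, height = lineages[0]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    # rescale to unit height
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in leaf-iteration order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _bm_on_tree(tree: dendropy.Tree, sigma2: float, rng: np.random.Generator,
                root_value: float = 0.0) -> dict[str, float]:
    """One Brownian-motion realisation; returns tip-label -> value."""
    values: dict[int, float] = {id(tree.seed_node): root_value}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            val = root_value
        else:
            bl = node.edge.length or 0.0
            val = values[id(node.parent_node)] + rng.normal(0.0, np.sqrt(sigma2 * bl))
        values[id(node)] = val
        if node.is_leaf():
            out[node.taxon.label] = val
    return out


def _mk_transition_matrix(n_states: int, rate: float, t: float) -> np.ndarray:
    """Transition probabilities of the symmetric k-state Markov chain.

    All states exchange at equal rates; ``rate`` is the total leaving
    rate of a state. Closed form of expm(Q t) for this Q.
    """
    k = n_states
    stay = 1.0 / k + (1.0 - 1.0 / k) * np.exp(-rate * k / (k - 1) * t)
    move = (1.0 - stay) / (k - 1)
    P = np.full((k, k), move)
    np.fill_diagonal(P, stay)
    return P


def _markov_on_tree(tree: dendropy.Tree, states: list[str], rate: float,
                    rng: np.random.Generator) -> dict[str, str]:
    k = len(states)
    idx: dict[int, int] = {}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            s = int(rng.integers(k))
        else:
            bl = node.edge.length or 0.0
            P = _mk_transition_matrix(k, rate, bl)
            s = int(rng.choice(k, p=P[idx[id(node.parent_node)]]))
        idx[id(node)] = s
        if node.is_leaf():
            out[node.taxon.label] = states[s]
    return out


def simulate_traits(
    tree: dendropy.Tree,
    n_quant: int,
    sigma2: float | list[float] = 1.0,
    categorical_spec: dict[str, tuple[list[str], float]] | None = None,
    seed: int = 0,
    quant_names: list[str] | None = None,
) -> TraitTable:
    """Evolve traits on a tree: BM for quantitative, Markov for categorical.

    Parameters
    ----------
    n_quant:
        Number of quantitative traits (each an independent BM).
    sigma2:
        BM rate(s); scalar or one per trait. Rates must be >= 0; a rate
        of 0 yields a constant trait (the zero-variance limit).
    categorical_spec:
        Mapping trait name -> (state labels, total transition rate) for
        symmetric continuous-time Markov evolution.
    """
    rates = np.broadcast_to(np.asarray(sigma2, dtype=float), (n_quant,))
    if np.any(rates < 0):
        raise ValueError("sigma2 rates must be non-negative")
    categorical_spec = categorical_spec or {}
    for name, (states, rate) in categorical_spec.items():
        if len(set(states)) != len(states) or len(states) < 2:
            raise ValueError(f"trait {name!r}: need >= 2 distinct state labels")
        if rate < 0:
            raise ValueError(f"trait {name!r}: negative transition rate")

    rng = np.random.default_rng(seed)
    labels = tip_labels(tree)
    if quant_names is None:
        quant_names = [f"q{i + 1}" for i in range(n_quant)]
    data: dict[str, list] = {}
    for name, s2 in zip(quant_names, rates):
        vals = _bm_on_tree(tree, s2, rng)
        data[name] = [vals[sp] for sp in labels]
    for name, (states, rate) in categorical_spec.items():
        vals = _markov_on_tree(tree, list(states), rate, rng)
        data[name] = [vals[sp] for sp in labels]
    df = pd.DataFrame(data, index=pd.Index(labels, name="species"))
    return TraitTable(df, list(quant_names), list(categorical_spec))


def mask_trait_values(traits: TraitTable, fraction: float, seed: int) -> TraitTable:
    """Blank quantitative values for ``round(fraction * n_species)`` species.

    Each selected species loses at least one quantitative value (a
    random non-empty subset of its quantitative traits). Categorical
    traits are never masked. ``fraction = 0`` returns a copy unchanged.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    out = traits.copy()
    n_mask = int(round(fraction * traits.n_species))
    if n_mask == 0 or not traits.quantitative:
        return out
    rng = np.random.default_rng(seed)
    chosen = rng.choice(traits.n_species, size=n_mask, replace=False)
    q = len(traits.quantitative)
    for i in chosen:
        which = rng.random(q) < 0.5
        if not which.any():
            which[rng.integers(q)] = True
        for j in np.flatnonzero(which):
            out.data.iloc[i, out.data.columns.get_loc(traits.quantitative[j])] = np.nan
    return out


# ---------------------------------------------------------------------------
# climate, terrain, biomes, ranges
# ---------------------------------------------------------------------------

def paleo_slice_ages(horizon_kyr: float = 120.0, interval_kyr: float = 4.0) -> list[float]:
    """Slice ages (kyr BP) for an inclusive horizon: 120, 116, ..., 4, 0.

    A 0-120 kyr horizon at 4-kyr intervals gives 31 slices.
    """
    n = int(round(horizon_kyr / interval_kyr)) + 1
    return [horizon_kyr - i * interval_kyr for i in range(n)]


def _smooth_field(grid: GridSpec, spatial_range: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian-smoothed white noise on the grid (flat)."""
    noise = rng.standard_normal((grid.n_rows, grid.n_cols))
    if spatial_range > 0:
        field2d = ndimage.gaussian_filter(noise, sigma=spatial_range, mode="nearest")
    else:
        field2d = noise
    flat = field2d.ravel()
    sd = flat.std()
    if sd > 0:
        flat = (flat - flat.mean()) / sd
    return flat


def generate_climate_stack(
    grid: GridSpec,
    layer_names: list[str],
    n_slices: int,
    spatial_range: float = 3.0,
    temporal_drift: float = 0.0,
    seed: int = 0,
    interval_kyr: float = 4.0,
    temporal_noise: float = 0.0,
    gradient: dict[str, float] | None = None,
) -> ClimateStack:
    """Spatially autocorrelated climate layers across paleo time slices.

    Each layer is smoothed white noise (Gaussian kernel of sd
    ``spatial_range`` cells, standardised to mean 0 / sd 1 at present).
    Going back in time, slice means shift by ``temporal_drift`` per
    step; ``temporal_noise`` optionally adds independent smoothed noise
    of that sd to each past slice. With drift and noise both 0, all
    slices are identical. ``gradient`` adds a fixed west-to-east linear
    component (per-layer amplitude over the grid width) so that biome
    bands can be made climatically separable.

    Slice ages run oldest to present: ``(n_slices-1)*interval, ..., 0``.
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    if spatial_range < 0:
        raise ValueError("spatial_range must be >= 0")
    rng = np.random.default_rng(seed)
    ages = [interval_kyr * (n_slices - 1 - i) for i in range(n_slices)]
    gradient = gradient or {}

    cols = np.tile(np.linspace(-0.5, 0.5, grid.n_cols), grid.n_rows)
    values = np.empty((len(layer_names), n_slices, grid.n_cells))
    for li, name in enumerate(layer_names):
        base = _smooth_field(grid, spatial_range, rng)
        if name in gradient:
            base = base + gradient[name] * cols * 2.0
        for si in range(n_slices):
            steps_back = n_slices - 1 - si
            slice_vals = base - temporal_drift * steps_back
            if temporal_noise > 0 and steps_back > 0:
                slice_vals = slice_vals + temporal_noise * _smooth_field(
                    grid, spatial_range, rng
                )
            values[li, si] = slice_vals
    return ClimateStack(grid, list(layer_names), ages, values)


def derive_terrain(elevation: np.ndarray, cell_size: float = 1.0) -> dict[str, np.ndarray]:
    """Slope, aspect and roughness from an elevation surface.

    * slope — magnitude of the central-difference gradient (3x3
      neighbourhood; one-sided differences at edges);
    * aspect — compass direction of the downhill gradient, degrees
      clockwise from north (a ramp rising eastward faces due west, 270);
    * roughness — max minus min over the 8-neighbourhood including the
      centre (truncated at edges), a landscape-heterogeneity measure.
    """
    elev = np.asarray(elevation, dtype=float)
    if elev.ndim != 2 or min(elev.shape) < 3:
        raise ValueError("elevation must be 2-D and at least 3 x 3")
    d_south, d_east = np.gradient(elev, cell_size)
    slope = np.hypot(d_east, d_south)
    # downhill direction: east component -dz/dE, north component +dz/d(row)
    aspect = np.degrees(np.arctan2(-d_east, d_south)) % 360.0
    aspect[slope == 0] = 0.0
    rough = (
        ndimage.maximum_filter(elev, size=3, mode="nearest")
        - ndimage.minimum_filter(elev, size=3, mode="nearest")
    )
    return {"slope": slope, "aspect": aspect, "roughness": rough}


def generate_biome_map(
    grid: GridSpec,
    n_biomes: int,
    seed: int = 0,
    outside_cols: int = 0,
    perturb: int = 0,
) -> BiomeMap:
    """Vertical-band biome mosaic with shared boundaries.

    The leftmost ``n_cols - outside_cols`` columns are split into
    ``n_biomes`` contiguous bands labelled ``biome_1`` ...; the
    rightmost ``outside_cols`` columns are ``"outside"`` (background
    for pseudo-absence sampling). ``perturb`` jitters the band
    boundaries by up to that many columns per row while keeping every
    band 8-connected.
    """
    usable = grid.n_cols - outside_cols
    if not 1 <= n_biomes <= usable:
        raise ValueError("need 1 <= n_biomes <= number of non-outside columns")
    rng = np.random.default_rng(seed)
    # band boundaries: biome b covers columns [edges[b], edges[b+1])
    edges = np.round(np.linspace(0, usable, n_biomes + 1)).astype(int)
    labels2d = np.full((grid.n_rows, grid.n_cols), OUTSIDE, dtype=object)
    for r in range(grid.n_rows):
        row_edges = edges.copy()
        if perturb:
            jitter = rng.integers(-perturb, perturb + 1, size=n_biomes - 1)
            row_edges[1:-1] = np.clip(edges[1:-1] + jitter, 1, usable - 1)
            row_edges[1:-1].sort()
        for b in range(n_biomes):
            labels2d[r, row_edges[b]:row_edges[b + 1]] = f"biome_{b + 1}"
    return BiomeMap(grid, labels2d.ravel())


def _largest_component(mask2d: np.ndarray) -> np.ndarray:
    """Flat cell ids of the largest 8-connected True component."""
    lab, n = ndimage.label(mask2d, structure=_CONN8)
    if n == 0:
        return np.array([], dtype=int)
    sizes = ndimage.sum_labels(mask2d, lab, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    return np.flatnonzero((lab == best).ravel())


def generate_ranges(
    grid: GridSpec,
    tree: dendropy.Tree,
    climate: np.ndarray,
    niche_breadth: float = 1.0,
    seed: int = 0,
) -> RangeSet:
    """Climate-limited contiguous ranges with phylogenetic structure.

    Each species receives a niche optimum evolved by Brownian motion on
    the tree (so related species have similar optima and overlapping
    ranges) rescaled to the span of the supplied present-day climate
    layer. Its range is the largest 8-connected patch of cells whose
    climate is within ``niche_breadth`` of the optimum; when no cell
    qualifies the species falls back to the single climatically closest
    cell, so every range is non-empty.
    """
    if niche_breadth <= 0:
        raise ValueError("niche_breadth must be positive")
    climate = np.asarray(climate, dtype=float)
    if climate.shape != (grid.n_cells,):
        raise ValueError("climate layer must match the grid")
    rng = np.random.default_rng(seed)
    labels = tip_labels(tree)
    optima_bm = _bm_on_tree(tree, 1.0, rng)
    z = np.array([optima_bm[sp] for sp in labels])
    zsd = z.std()
    if zsd > 0:
        z = (z - z.mean()) / zsd
    lo, hi = climate.min(), climate.max()
    optima = (lo + hi) / 2 + z * (hi - lo) / 4  # most optima fall inside the span

    ranges: dict[str, np.ndarray] = {}
    for sp, opt in zip(labels, optima):
        suitable = np.abs(climate - opt) <= niche_breadth
        cells = _largest_component(grid.to_array(suitable))
        if cells.size == 0:
            cells = np.array([int(np.argmin(np.abs(climate - opt)))])
        ranges[sp] = cells
    return RangeSet(grid, ranges)
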