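"""Functional trait space: Gower distances, PCoA, decoupling, FDis.

The trait space combines quantitative and nominal traits through the
Gower index, is embedded by principal coordinates analysis (with a
square-root transform of the dissimilarities to tame negative
eigenvalues), and is then *decoupled* from the phylogeny: each
functional axis is regressed on phylogenetic eigenvectors and only the
residuals — trait variation independent of shared ancestry — feed the
per-cell functional dispersion (FDis, mean distance of co-occurring
species to their trait-space centroid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import PresenceMatrix
from .grid import DiversityLayer
from .traits import TraitTable

__all__ = [
    "Ordination",
    "ResidualTraitSpace",
    "gower",
    "pcoa",
    "decouple",
    "functional_dispersion",
]


@dataclass
class Ordination:
    """PCoA embedding: species coordinates on axes of descending eigenvalue."""

    species: list[str]
    coordinates: np.ndarray  # (n_species, n_retained_axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    correction: str = "none"

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis_{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.species, columns=cols)


@dataclass
class ResidualTraitSpace:
    """Functional coordinates with phylogenetic structure regressed out."""

    species: list[str]
    coordinates: np.ndarray
    variance_explained_by_phylogeny: float

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis_{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.species, columns=cols)


def gower(traits: TraitTable, weights: dict[str, float] | None = None
          ) -> tuple[list[str], np.ndarray]:
    """Gower dissimilarity over mixed quantitative and nominal traits.

    Per pair, the (weighted) mean over traits of ``|xi - xj| / range``
    for quantitative traits and a 0/1 mismatch for nominal ones;
    bounded in [0, 1]. Requires a complete (imputed) table. A
    quantitative trait with zero range carries no information and is
    dropped with a warning.
    """
    if traits.species_with_missing():
        raise ValueError("Gower requires a complete table; impute first")
    species = traits.species
    n = len(species)
    weights = weights or {}
    parts: list[np.ndarray] = []
    wts: list[float] = []

    for name in traits.quantitative:
        x = traits.data[name].to_numpy(dtype=float)
        rng = np.ptp(x)
        if rng == 0:
            warnings.warn(f"quantitative trait {name!r} has zero range; dropped",
                          stacklevel=2)
            continue
        parts.append(np.abs(x[:, None] - x[None, :]) / rng)
        wts.append(weights.get(name, 1.0))
    for name in traits.categorical:
        s = traits.data[name].to_numpy()
        parts.append((s[:, None] != s[None, :]).astype(float))
        wts.append(weights.get(name, 1.0))
    if not parts:
        raise ValueError("no informative traits")
    w = np.asarray(wts)
    D = np.tensordot(w, np.stack(parts), axes=1) / w.sum()
    np.fill_diagonal(D, 0.0)
    return species, (D + D.T) / 2.0


def pcoa(dist: np.ndarray, correction: str = "none",
         species: list[str] | None = None, eig_tol: float = 1e-10) -> Ordination:
    """Classical metric scaling of a dissimilarity matrix.

    Double-centres the squared (optionally element-wise square-rooted)
    dissimilarities and eigendecomposes; axes with eigenvalue above
    ``eig_tol`` are retained and scaled so that inter-point Euclidean
    distances reproduce the input when all eigenvalues are
    non-negative. The square-root correction makes Gower matrices of
    mixed data (near-)metric, bounding negative eigenvalues near zero.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if correction == "sqrt":
        D = np.sqrt(D)
    elif correction != "none":
        raise ValueError("correction must be 'none' or 'sqrt'")
    n = D.shape[0]
    if species is None:
        species = [f"s{i}" for i in range(n)]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > eig_tol
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return Ordination(list(species), coords, eigval, correction)


def decouple(
    functional_dist: np.ndarray,
    phylo_eigenvectors: Ordination,
    species: list[str] | None = None,
    max_predictors: int | None = None,
) -> ResidualTraitSpace:
    """Remove phylogenetically structured trait variation.

    The functional dissimilarities are embedded by PCoA (square-root
    corrected) and each functional axis is regressed, with intercept,
    on the phylogenetic eigenvectors; the residual coordinates span
    the trait variation independent of the phylogeny. Species order
    must agree between the two inputs.
    """
    E = phylo_eigenvectors.coordinates
    if max_predictors is not None:
        E = E[:, :max_predictors]
    func = pcoa(functional_dist, correction="sqrt",
                species=species or phylo_eigenvectors.species)
    if func.species != phylo_eigenvectors.species:
        raise ValueError("species sets/order differ between inputs")
    n = len(func.species)
    if E.shape[1] > n - 1:
        raise ValueError(
            f"{E.shape[1]} phylogenetic predictors for {n} species; "
            f"truncate to at most n-1 = {n - 1} (max_predictors)"
        )
    Y = func.coordinates
    Xd = np.column_stack([np.ones(n), E])
    beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    resid = Y - Xd @ beta
    Yc = Y - Y.mean(axis=0)
    total = float(np.sum(Yc ** 2))
    explained = 0.0 if total == 0 else 1.0 - float(np.sum(resid ** 2)) / total
    return ResidualTraitSpace(func.species, resid, explained)


def functional_dispersion(matrix: PresenceMatrix, space: ResidualTraitSpace | Ordination
                          ) -> DiversityLayer:
    """Per-cell FDis: mean distance of present species to their centroid.

    Presence-absence data, so species are unweighted. Single-species
    cells score 0 (no dispersion); empty cells are NaN.
    """
    pos = {sp: i for i, sp in enumerate(space.species)}
    missing = [sp for sp in matrix.species_ids if sp not in pos]
    if missing:
        raise ValueError(f"species without trait coordinates: {missing[:5]}")
    coords = space.coordinates
    col_map = np.array([pos[sp] for sp in matrix.species_ids])
    out = np.full(matrix.grid.n_cells, np.nan)
    for cell in range(matrix.grid.n_cells):
        present = np.flatnonzero(matrix.values[cell])
        if present.size == 0:
            continue
        if present.size == 1:
            out[cell] = 0.0
            continue
        pts = coords[col_map[present]]
        centroid = pts.mean(axis=0)
        out[cell] = float(np.linalg.norm(pts - centroid, axis=1).mean())
    return DiversityLayer(matrix.grid, out, name="FD")
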