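"""Biome distribution modelling and the climatic-stability layer.

A random-forest classifier is trained per biome on present-day climate
at biome cells (presences) versus pseudo-absence cells drawn from the
region outside every modelled biome. The fitted model is projected
onto each paleo time slice, the suitability probability is dichotomised,
and the binary projections are overlaid: a cell's stability is the
number of slices in which it remains classified as suitable — 0 is
maximal instability, n_slices (31 for a 120-kyr horizon at 4-kyr
steps) maximal stability. The metric measures temporal persistence of
biome-scale climatic suitability, not the absence of climate change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .grid import DiversityLayer, GridSpec
from .synthetic import OUTSIDE, BiomeMap, ClimateStack

__all__ = [
    "TrainingPoints",
    "BiomeClassifier",
    "StabilityLayer",
    "sample_pseudo_absences",
    "make_training_points",
    "fit_biome_classifier",
    "project_slices",
    "stability",
    "thin_points",
]


@dataclass
class TrainingPoints:
    """Labelled cells with their present-day predictor values."""

    cell_ids: np.ndarray
    labels: np.ndarray  # 1 = focal-biome presence, 0 = pseudo-absence
    X: np.ndarray  # (n_points, n_predictors)
    predictor_names: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("a cell appears with both labels or twice")
        if self.X.shape != (len(self.cell_ids), len(self.predictor_names)):
            raise ValueError("X shape mismatch")


@dataclass
class StabilityLayer:
    """Per-cell count of paleo slices predicted climatically suitable."""

    grid: GridSpec
    values: np.ndarray
    n_slices: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > self.n_slices:
            raise ValueError("stability values must lie in [0, n_slices]")

    def as_layer(self) -> DiversityLayer:
        return DiversityLayer(self.grid, self.values.astype(float), name="stability")


def sample_pseudo_absences(
    region_mask: np.ndarray,
    biome_map: BiomeMap,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Cells sampled uniformly from the region outside every modelled biome.

    ``region_mask`` is a boolean per-cell vector (or a cell-id array)
    delimiting the study region; eligible cells are those in the region
    labelled ``"outside"`` on the biome map. Sampling is without
    replacement and deterministic given the seed.
    """
    region_mask = np.asarray(region_mask)
    if region_mask.dtype == bool:
        region = np.flatnonzero(region_mask.ravel())
    else:
        region = region_mask.astype(int)
    eligible = region[biome_map.labels[region] == OUTSIDE]
    if n > eligible.size:
        raise ValueError(
            f"requested {n} pseudo-absences but only {eligible.size} cells "
            f"lie outside the modelled biomes"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(eligible, size=n, replace=False))


def thin_points(cells: np.ndarray, grid: GridSpec, min_distance: int) -> np.ndarray:
    """Greedy spatial thinning: keep cells pairwise > min_distance apart.

    Distance is Chebyshev (grid steps). Off by default in the pipeline
    since no thinning distance is reported for the original analysis.
    """
    cells = np.asarray(cells, dtype=int)
    rows, cols = np.divmod(cells, grid.n_cols)
    kept: list[int] = []
    for i in range(len(cells)):
        if all(
            max(abs(rows[i] - rows[j]), abs(cols[i] - cols[j])) > min_distance
            for j in kept
        ):
            kept.append(i)
    return cells[kept]


def make_training_points(
    biome_map: BiomeMap,
    stack: ClimateStack,
    focal: str,
    pseudo_absences: np.ndarray,
    predictors: list[str] | None = None,
) -> TrainingPoints:
    """Presences (focal-biome cell centroids) plus pseudo-absences."""
    predictors = predictors or list(stack.layer_names)
    pres = biome_map.cells_of(focal)
    cells = np.concatenate([pres, pseudo_absences])
    labels = np.concatenate([np.ones(pres.size, int), np.zeros(len(pseudo_absences), int)])
    cols = [stack.layer(p)[cells] for p in predictors]
    return TrainingPoints(cells, labels, np.column_stack(cols), list(predictors))


@dataclass
class BiomeClassifier:
    model: RandomForestClassifier
    predictor_names: list[str]
    importance: pd.DataFrame
    oob_accuracy: float | None


def fit_biome_classifier(
    points: TrainingPoints,
    n_trees: int = 500,
    seed: int = 0,
    importance_repeats: int = 10,
) -> BiomeClassifier:
    """Bootstrap-aggregated classification trees for one biome.

    500 trees with sqrt(p) candidate variables per split (the standard
    classification defaults). The importance table reports the mean
    decrease in accuracy under predictor permutation alongside the mean
    decrease in Gini impurity, ranked by the former.
    """
    if len(points.predictor_names) < 2:
        raise ValueError("need at least 2 predictors")
    if len(np.unique(points.labels)) < 2:
        raise ValueError("training data contains a single class")
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    model.fit(points.X, points.labels)
    perm = permutation_importance(
        model, points.X, points.labels,
        n_repeats=importance_repeats, random_state=int(seed), scoring="accuracy",
    )
    importance = pd.DataFrame(
        {
            "variable": points.predictor_names,
            "mean_decrease_accuracy": perm.importances_mean,
            "mean_decrease_gini": model.feature_importances_,
        }
    ).sort_values("mean_decrease_accuracy", ascending=False, ignore_index=True)
    return BiomeClassifier(model, list(points.predictor_names), importance,
                           float(model.oob_score_))


def project_slices(
    clf: BiomeClassifier,
    stack: ClimateStack,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Project the present-day model across every paleo slice.

    Returns ``(binary, probability)`` arrays of shape
    (n_cells, n_slices): the fraction of trees voting presence,
    dichotomised at ``threshold`` (suitable when probability >=
    threshold, with threshold 0 marking every cell suitable).
    """
    missing = [p for p in clf.predictor_names if p not in stack.layer_names]
    if missing:
        raise KeyError(f"climate stack lacks predictor layer(s): {missing}")
    n_cells = stack.grid.n_cells
    prob = np.empty((n_cells, stack.n_slices))
    pos = list(clf.model.classes_).index(1)
    for si in range(stack.n_slices):
        X = np.column_stack([stack.layer(p, si) for p in clf.predictor_names])
        prob[:, si] = clf.model.predict_proba(X)[:, pos]
    binary = (prob >= threshold).astype(np.uint8) if threshold > 0 else (prob > 0).astype(np.uint8)
    return binary, prob


def stability(binary_stack: np.ndarray, grid: GridSpec,
              mask: np.ndarray | None = None) -> StabilityLayer:
    """Overlay binary projections: per-cell count of suitable slices."""
    binary_stack = np.asarray(binary_stack)
    counts = binary_stack.sum(axis=1).astype(float)
    if mask is not None:
        counts = np.where(np.asarray(mask, bool).ravel(), counts, np.nan)
    return StabilityLayer(grid, counts, int(binary_stack.shape[1]))
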