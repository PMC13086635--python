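"""Species-by-trait tables mixing quantitative and categorical traits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TraitTable"]


@dataclass
class TraitTable:
    """A species x trait table with explicit trait typing.

    ``data`` is indexed by species id. Quantitative traits are floats
    (NaN = missing); categorical traits are strings drawn from a
    declared vocabulary and are never masked by the missing-data
    machinery.
    """

    data: pd.DataFrame
    quantitative: list[str] = field(default_factory=list)
    categorical: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing_cols = [
            c for c in self.quantitative + self.categorical if c not in self.data.columns
        ]
        if missing_cols:
            raise ValueError(f"declared traits absent from table: {missing_cols}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate species ids in trait table")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_species(self) -> int:
        return len(self.data)

    def quantitative_matrix(self) -> np.ndarray:
        """Quantitative block as a float array (NaN = missing)."""
        return self.data[self.quantitative].to_numpy(dtype=float)

    def species_with_missing(self) -> list[str]:
        """Species with at least one missing quantitative value."""
        if not self.quantitative:
            return []
        mask = self.data[self.quantitative].isna().any(axis=1)
        return list(self.data.index[mask])

    def is_complete(self) -> bool:
        return not self.species_with_missing()

    def copy(self) -> "TraitTable":
        return TraitTable(self.data.copy(), list(self.quantitative), list(self.categorical))

    def to_csv(self, path) -> None:
        """Write as CSV with empty fields for missing values."""
        self.data.to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path, quantitative: list[str], categorical: list[str]) -> "TraitTable":
        df = pd.read_csv(path, index_col="species")
        for c in quantitative:
            df[c] = pd.to_numeric(df[c])
        return cls(df, quantitative, categorical)
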