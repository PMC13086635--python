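"""Spatially explicit regression of diversity on environment.

Predictors are screened for collinearity by iteratively dropping the
variable with the highest variance inflation factor (VIF > 3), then
z-scored. Diversity surfaces are regressed on them with a Gaussian
conditional autoregressive (CAR) error structure over the grid
adjacency, fitted by maximum likelihood:

    y = X beta + u,   u ~ N(0, sigma2 * (I - rho * W)^(-1))

with W the symmetric binary adjacency and rho constrained to the
interval where I - rho*W stays positive definite (the reciprocal
extreme eigenvalues of W). Model fit is summarised by the
Kissling-Carl R-squared: the squared Pearson correlation between the
observations and the full prediction, trend plus the spatial signal
rho * W (y - X beta). Ordinary least squares on z-scored data supplies
standardized betas for cross-predictor comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .grid import GridSpec, QUEEN_OFFSETS, ROOK_OFFSETS

__all__ = [
    "NeighborhoodMatrix",
    "CARFit",
    "vif_filter",
    "standardize",
    "build_adjacency",
    "fit_car",
    "fit_ols_standardized",
    "simulate_car_field",
]


# ---------------------------------------------------------------------------
# predictor screening
# ---------------------------------------------------------------------------

def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 - R^2) from regressing j on the rest."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    Z = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_filter(predictors: pd.DataFrame, threshold: float = 3.0
               ) -> tuple[pd.DataFrame, list[dict]]:
    """Iteratively drop the highest-VIF predictor until all VIF <= threshold.

    Perfectly collinear predictors (infinite VIF) are removed one at a
    time like any other; ties break on column order. Returns the
    retained table and a removal log of ``{"variable", "vif"}`` records
    in drop order.
    """
    if predictors.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if len(predictors) <= predictors.shape[1]:
        raise ValueError("need more observations than predictors")
    cols = list(predictors.columns)
    removed: list[dict] = []
    while len(cols) > 1:
        X = predictors[cols].to_numpy(dtype=float)
        vifs = np.array([_vif_one(X, j) for j in range(len(cols))])
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        removed.append({"variable": cols[worst], "vif": float(vifs[worst])})
        cols.pop(worst)
    return predictors[cols].copy(), removed


def standardize(predictors: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, variance 1 over the analysis cells)."""
    out = {}
    for name in predictors.columns:
        x = predictors[name].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"predictor {name!r} has zero variance")
        out[name] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=predictors.index)


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

@dataclass
class NeighborhoodMatrix:
    """Sparse symmetric binary adjacency over the analysis cells."""

    cells: np.ndarray  # cell ids, in the row/col order of W
    W: sparse.csr_matrix
    scheme: str = "queen"
    _eigs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def isolated(self) -> np.ndarray:
        """Cells with no neighbour inside the analysis set."""
        deg = np.asarray(self.W.sum(axis=1)).ravel()
        return self.cells[deg == 0]

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of W (cached); bound the admissible rho interval."""
        if self._eigs is None:
            self._eigs = np.linalg.eigvalsh(self.W.toarray())
        return self._eigs

    def rho_bounds(self) -> tuple[float, float]:
        lam = self.eigenvalues()
        lo = 1.0 / lam.min() if lam.min() < 0 else -np.inf
        hi = 1.0 / lam.max() if lam.max() > 0 else np.inf
        return lo, hi

    def to_edge_list(self) -> pd.DataFrame:
        coo = sparse.triu(self.W, k=1).tocoo()
        return pd.DataFrame(
            {"cell_i": self.cells[coo.row], "cell_j": self.cells[coo.col]}
        )


def build_adjacency(
    grid: GridSpec,
    cells: np.ndarray | None = None,
    scheme: str = "queen",
) -> NeighborhoodMatrix:
    """Binary adjacency among analysis cells (queen = 8, rook = 4 moves)."""
    if scheme not in ("queen", "rook"):
        raise ValueError("scheme must be 'queen' or 'rook'")
    offsets = QUEEN_OFFSETS if scheme == "queen" else ROOK_OFFSETS
    if cells is None:
        cells = np.arange(grid.n_cells)
    cells = np.asarray(sorted(cells), dtype=int)
    pos = {int(c): i for i, c in enumerate(cells)}
    rows_i, cols_j = [], []
    for i, cell in enumerate(cells):
        r, c = divmod(int(cell), grid.n_cols)
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                j = pos.get(rr * grid.n_cols + cc)
                if j is not None:
                    rows_i.append(i)
                    cols_j.append(j)
    W = sparse.csr_matrix(
        (np.ones(len(rows_i)), (rows_i, cols_j)), shape=(len(cells), len(cells))
    )
    nb = NeighborhoodMatrix(cells, W, scheme)
    if nb.isolated.size:
        warnings.warn(f"{nb.isolated.size} isolated cell(s) in adjacency", stacklevel=2)
    return nb


# ---------------------------------------------------------------------------
# CAR / OLS fitting
# ---------------------------------------------------------------------------

@dataclass
class CARFit:
    params: pd.DataFrame  # beta, se, z, p per predictor (incl. intercept)
    rho: float
    sigma2: float
    r2_kc: float
    loglik: float
    converged_at_boundary: bool
    n: int

    def to_json_dict(self) -> dict:
        return {
            "rho": self.rho,
            "sigma2": self.sigma2,
            "r2_kc": self.r2_kc,
            "loglik": self.loglik,
            "n": self.n,
            "converged_at_boundary": self.converged_at_boundary,
        }


def _car_profile(rho: float, mats: dict) -> tuple[float, np.ndarray, float]:
    """Profile negative log-likelihood at rho, with GLS beta and sigma2.

    All rho-dependent forms are linear combinations of precomputed
    cross-products, so each evaluation costs O(p^2).
    """
    XtQX = mats["XtX"] - rho * mats["XtWX"]
    XtQy = mats["Xty"] - rho * mats["XtWy"]
    beta = np.linalg.solve(XtQX, XtQy)
    ytQy = mats["yty"] - rho * mats["ytWy"]
    rss = ytQy - 2 * beta @ XtQy + beta @ XtQX @ beta
    n = mats["n"]
    sigma2 = max(rss / n, 1e-300)
    logdet = np.sum(np.log1p(-rho * mats["eigs"]))
    nll = 0.5 * (n * np.log(2 * np.pi * sigma2) - logdet + n)
    return nll, beta, sigma2


def fit_car(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    W: NeighborhoodMatrix,
    add_intercept: bool = True,
) -> CARFit:
    """Maximum-likelihood Gaussian CAR regression on a lattice.

    ``y`` and the rows of ``X`` must align with ``W.cells``. The
    spatial parameter rho is profiled out by bounded scalar
    optimisation over its admissible interval; with an empty adjacency
    the model collapses to OLS (rho = 0). Standard errors come from the
    GLS information, p-values from asymptotic z-statistics.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j + 1}" for j in range(Xa.shape[1])]
    if len(y) != W.n or len(Xa) != W.n:
        raise ValueError("y, X and W must cover the same cells")
    if np.isnan(y).any() or np.isnan(Xa).any():
        raise ValueError("NaN in response or predictors")
    if add_intercept:
        Xa = np.column_stack([np.ones(len(y)), Xa])
        names = ["intercept"] + names
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise ValueError("singular design matrix")

    Wd = W.W
    mats = {
        "XtX": Xa.T @ Xa,
        "XtWX": Xa.T @ (Wd @ Xa),
        "Xty": Xa.T @ y,
        "XtWy": Xa.T @ (Wd @ y),
        "yty": y @ y,
        "ytWy": y @ (Wd @ y),
        "eigs": W.eigenvalues(),
        "n": len(y),
    }

    boundary = False
    if Wd.nnz == 0:
        rho = 0.0
    else:
        lo, hi = W.rho_bounds()
        pad = 1e-6 * (hi - lo)
        res = minimize_scalar(
            lambda r: _car_profile(r, mats)[0],
            bounds=(lo + pad, hi - pad),
            method="bounded",
            options={"xatol": 1e-10},
        )
        rho = float(res.x)
        if min(rho - lo, hi - rho) < 10 * pad:
            boundary = True
            warnings.warn("CAR spatial parameter converged at its boundary",
                          stacklevel=2)
    nll, beta, sigma2 = _car_profile(rho, mats)

    XtQX = mats["XtX"] - rho * mats["XtWX"]
    cov_beta = sigma2 * np.linalg.inv(XtQX)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2 * norm.sf(np.abs(z))
    params = pd.DataFrame({"beta": beta, "se": se, "z": z, "p": pvals}, index=names)

    trend = Xa @ beta
    fitted = trend + rho * (Wd @ (y - trend))
    if np.std(fitted) == 0 or np.std(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    return CARFit(params, rho, float(sigma2), r2, float(-nll), boundary, len(y))


def fit_ols_standardized(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Standardized OLS betas: coefficients on z-scored response and predictors.

    With a single predictor the beta equals the Pearson correlation.
    Returns the coefficient table (beta, se, t, p) and the R-squared.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    ysd = y.std(ddof=0)
    if ysd == 0:
        raise ValueError("response has zero variance")
    yz = (y - y.mean()) / ysd
    Xz = standardize(X)
    if np.linalg.matrix_rank(Xz.to_numpy()) < Xz.shape[1]:
        raise ValueError("singular design matrix")
    model = sm.OLS(yz, sm.add_constant(Xz.to_numpy()))
    fit = model.fit()
    table = pd.DataFrame(
        {
            "beta": fit.params[1:],
            "se": fit.bse[1:],
            "t": fit.tvalues[1:],
            "p": fit.pvalues[1:],
        },
        index=list(X.columns),
    )
    return table, float(fit.rsquared)


def simulate_car_field(
    W: NeighborhoodMatrix,
    beta: np.ndarray,
    X: np.ndarray,
    rho: float,
    sigma2: float = 1.0,
    seed: int = 0,
    add_intercept: bool = True,
) -> np.ndarray:
    """Draw y = X beta + u with CAR-structured noise (testing/calibration).

    u has covariance sigma2 * (I - rho W)^(-1); sampled by solving the
    Cholesky factor of the precision against white noise.
    """
    lo, hi = W.rho_bounds()
    if not lo < rho < hi:
        raise ValueError(f"rho {rho} outside admissible interval ({lo:.4f}, {hi:.4f})")
    n = W.n
    Q = np.eye(n) - rho * W.W.toarray()
    L = np.linalg.cholesky(Q)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    u = np.sqrt(sigma2) * np.linalg.solve(L.T, z)
    Xa = np.column_stack([np.ones(n), X]) if add_intercept else X
    return Xa @ np.asarray(beta, dtype=float) + u
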