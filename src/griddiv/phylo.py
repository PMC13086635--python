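"""Phylogenetic distances, community metrics, signal tests and imputation.

The community metric here is the standardised effect size of mean
pairwise distance (SES-MPD) against an equal-richness null drawn from a
regional species pool, and its sign-flipped twin the net relatedness
index (NRI = -SES): positive NRI means co-occurring species are more
closely related than random draws from the pool. Trait machinery
covers Blomberg's K with a contrasts-based randomisation test, the
Maddison-Slatkin parsimony test for categorical traits, and imputation
of missing quantitative values under a multivariate Brownian-motion
model fitted by expectation-maximisation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .assembly import PresenceMatrix
from .grid import DiversityLayer
from .traits import TraitTable

__all__ = [
    "SESResult",
    "SignalResult",
    "graft_taxa",
    "cophenetic_matrix",
    "phylo_covariance",
    "ses_mpd",
    "blomberg_k",
    "categorical_signal",
    "impute_traits",
    "mpd",
]


# ---------------------------------------------------------------------------
# tree utilities
# ---------------------------------------------------------------------------

def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _root_distances(tree: dendropy.Tree) -> dict[int, float]:
    d: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            d[id(node)] = 0.0
        else:
            d[id(node)] = d[id(node.parent_node)] + (node.edge.length or 0.0)
    return d


def _mrca_depths(tree: dendropy.Tree, labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Tip depths and pairwise MRCA depths for tips in ``labels`` order.

    One postorder sweep: at each internal node, tip pairs first united
    there get that node's depth as their MRCA depth.
    """
    idx = {sp: i for i, sp in enumerate(labels)}
    n = len(labels)
    rootdist = _root_distances(tree)
    depths = np.zeros(n)
    M = np.zeros((n, n))
    tipsets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx.get(node.taxon.label)
            if i is None:  # tip outside the requested label set
                tipsets[id(node)] = np.array([], dtype=int)
                continue
            depths[i] = rootdist[id(node)]
            M[i, i] = depths[i]
            tipsets[id(node)] = np.array([i])
        else:
            children = [tipsets.pop(id(c)) for c in node.child_nodes()]
            d = rootdist[id(node)]
            for a, b in itertools.combinations(children, 2):
                M[np.ix_(a, b)] = d
                M[np.ix_(b, a)] = d
            tipsets[id(node)] = np.concatenate(children)
    return depths, M


def cophenetic_matrix(tree: dendropy.Tree, labels: list[str] | None = None
                      ) -> tuple[list[str], np.ndarray]:
    """Patristic (cophenetic) distances between all tip pairs.

    ``distance(i, j)`` is the total branch length on the i-j path;
    returns tip labels and the symmetric matrix in that order.
    """
    if labels is None:
        labels = _leaf_labels(tree)
    depths, M = _mrca_depths(tree, labels)
    D = depths[:, None] + depths[None, :] - 2.0 * M
    np.fill_diagonal(D, 0.0)
    return labels, D


def phylo_covariance(tree: dendropy.Tree, labels: list[str] | None = None
                     ) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance: shared root-to-MRCA path lengths."""
    if labels is None:
        labels = _leaf_labels(tree)
    tree_tips = set(_leaf_labels(tree))
    missing = [sp for sp in labels if sp not in tree_tips]
    if missing:
        raise ValueError(f"species not in tree: {missing[:5]}")
    _, M = _mrca_depths(tree, labels)
    return labels, M


def _mrca_node(leaves: list[dendropy.Node]) -> dendropy.Node:
    """Most recent common ancestor by ancestor-path intersection."""
    paths = []
    for lf in leaves:
        path, node = [], lf
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths.append(path)
    shared = set(id(n) for n in paths[0])
    for path in paths[1:]:
        shared &= {id(n) for n in path}
    for node in paths[0]:  # deepest shared ancestor comes first
        if id(node) in shared:
            return node
    raise ValueError("anchor tips share no common ancestor")


def graft_taxa(tree: dendropy.Tree, placements: dict[str, list[str]]) -> dendropy.Tree:
    """Attach species without phylogenetic data inside anchor clades.

    Each new species is placed at the most recent common ancestor of
    its anchor tip set (a genus- or family-level clade) with a pendant
    branch equal to that node's height, so the tree stays ultrametric
    and the node becomes a polytomy. A single-tip anchor gets a new
    attachment node at the midpoint of the anchor's terminal branch.
    Returns a modified clone; the input tree is untouched.
    """
    out = tree.clone(depth=1)
    out.is_rooted = True
    for sp, anchors in placements.items():
        anchor_set = set(anchors)
        leaves = {lf.taxon.label: lf for lf in out.leaf_node_iter()
                  if lf.taxon.label in anchor_set}
        if len(leaves) != len(anchor_set):
            raise ValueError(
                f"cannot place {sp!r}: anchor tips not in tree: "
                f"{sorted(anchor_set - set(leaves))}"
            )
        rootdist = _root_distances(out)
        height = max(rootdist[id(lf)] for lf in out.leaf_node_iter())
        if len(leaves) == 1:
            leaf = next(iter(leaves.values()))
            half = (leaf.edge.length or 0.0) / 2.0
            parent = leaf.parent_node
            mid = dendropy.Node()
            parent.remove_child(leaf)
            parent.add_child(mid)
            mid.edge.length = (leaf.edge.length or 0.0) - half
            mid.add_child(leaf)
            leaf.edge.length = half
            node, pendant = mid, half
        else:
            node = _mrca_node(list(leaves.values()))
            pendant = height - rootdist[id(node)]
        new_taxon = dendropy.Taxon(label=sp)
        out.taxon_namespace.add_taxon(new_taxon)
        tip = dendropy.Node(taxon=new_taxon)
        node.add_child(tip)
        tip.edge.length = pendant
    return out


def _binary_resolved(tree: dendropy.Tree) -> dendropy.Tree:
    """Clone with polytomies arbitrarily resolved via zero-length edges."""
    bt = tree.clone(depth=1)
    bt.resolve_polytomies()
    for edge in bt.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return bt


# ---------------------------------------------------------------------------
# SES-MPD / NRI
# ---------------------------------------------------------------------------

@dataclass
class SESResult:
    """Per-cell SES-MPD with its null summary. ``nri`` is exactly ``-ses``."""

    grid: object
    obs_mpd: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    ses: np.ndarray
    nri: np.ndarray
    p_rank: np.ndarray
    n_null: int

    def layer(self, which: str = "nri") -> DiversityLayer:
        return DiversityLayer(self.grid, getattr(self, which), name=f"PD-{which}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": np.arange(len(self.obs_mpd)),
                "obs_mpd": self.obs_mpd,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "ses": self.ses,
                "nri": self.nri,
                "p_rank": self.p_rank,
            }
        )


def mpd(D: np.ndarray, idx: np.ndarray) -> float:
    """Mean pairwise distance among the community indexed by ``idx``."""
    k = len(idx)
    if k < 2:
        return np.nan
    sub = D[np.ix_(idx, idx)]
    return sub.sum() / (k * (k - 1))


def _null_mpds(D: np.ndarray, pool_size: int, k: int, n_null: int,
               rng: np.random.Generator) -> np.ndarray:
    """MPDs of ``n_null`` equal-richness draws (without replacement)."""
    if k > 40:
        out = np.empty(n_null)
        for r in range(n_null):
            out[r] = mpd(D, rng.choice(pool_size, size=k, replace=False))
        return out
    draws = np.argsort(rng.random((n_null, pool_size)), axis=1)[:, :k]
    sub = D[draws[:, :, None], draws[:, None, :]]
    return sub.sum(axis=(1, 2)) / (k * (k - 1))


def ses_mpd(
    matrix: PresenceMatrix,
    dist: tuple[list[str], np.ndarray],
    pool: list[str] | None = None,
    n_null: int = 999,
    seed: int = 0,
) -> SESResult:
    """Standardised effect size of MPD against an equal-richness null.

    For every cell with at least two species, observed MPD is compared
    with ``n_null`` random draws of the same richness from the regional
    ``pool`` (default: all species in the matrix) without replacement.
    ``ses = (obs - null_mean) / null_sd`` and ``nri = -ses``; ``p_rank``
    is the +1-corrected fraction of null values <= observed. Cells with
    fewer than two species are NaN (undefined, not zero); a degenerate
    null whose draws are all identical yields ses 0 when the observed
    value equals the null (community = pool) and NaN with a warning
    otherwise. Null draws are independent across cells.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    dist_labels, D = dist
    pos = {sp: i for i, sp in enumerate(dist_labels)}
    if pool is None:
        pool = list(matrix.species_ids)
    unknown = [sp for sp in matrix.species_ids if sp not in pos]
    if unknown:
        raise ValueError(f"species without distances: {unknown[:5]}")
    if not set(matrix.species_ids) <= set(pool):
        raise ValueError("matrix contains species outside the pool")
    pool_idx = np.array([pos[sp] for sp in pool])
    Dp = D[np.ix_(pool_idx, pool_idx)]
    col_in_pool = {sp: i for i, sp in enumerate(pool)}
    col_map = np.array([col_in_pool[sp] for sp in matrix.species_ids])

    rng = np.random.default_rng(seed)
    n_cells = matrix.grid.n_cells
    obs = np.full(n_cells, np.nan)
    nmean = np.full(n_cells, np.nan)
    nsd = np.full(n_cells, np.nan)
    ses = np.full(n_cells, np.nan)
    p_rank = np.full(n_cells, np.nan)

    richness = matrix.values.sum(axis=1)
    for cell in range(n_cells):
        k = int(richness[cell])
        if k < 2:
            continue
        idx = col_map[np.flatnonzero(matrix.values[cell])]
        obs[cell] = mpd(Dp, idx)
        null = _null_mpds(Dp, len(pool), k, n_null, rng)
        nmean[cell] = null.mean()
        nsd[cell] = null.std(ddof=1)
        # float summation order makes identical draws differ by ~1e-16
        degenerate = nsd[cell] <= 1e-10 * max(1.0, abs(nmean[cell]))
        if not degenerate:
            ses[cell] = (obs[cell] - nmean[cell]) / nsd[cell]
        elif np.isclose(obs[cell], nmean[cell]):
            ses[cell] = 0.0
        else:
            warnings.warn(f"cell {cell}: zero null sd, SES undefined", stacklevel=2)
        p_rank[cell] = (1 + np.sum(null <= obs[cell])) / (n_null + 1)

    return SESResult(matrix.grid, obs, nmean, nsd, ses, -ses, p_rank, n_null)


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    statistic: float
    null_mean: float | None
    null_sd: float | None
    p_value: float | None
    n_reps: int
    method: str = ""


def _pic_contrasts(tree: dendropy.Tree, x: dict[str, float]) -> np.ndarray:
    """Felsenstein's standardised independent contrasts (binary tree)."""
    vals: dict[int, float] = {}
    bl: dict[int, float] = {}
    contrasts: list[float] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vals[id(node)] = x[node.taxon.label]
            bl[id(node)] = node.edge.length or 0.0
        else:
            c1, c2 = node.child_nodes()
            v1, v2 = bl.pop(id(c1)), bl.pop(id(c2))
            x1, x2 = vals.pop(id(c1)), vals.pop(id(c2))
            vsum = v1 + v2
            if vsum <= 0:
                # zero-length cherry: contrast undefined; the tips are
                # perfectly correlated, contribute a zero contrast
                contrasts.append(0.0)
                merged = (x1 + x2) / 2.0
                extra = 0.0
            else:
                contrasts.append((x1 - x2) / np.sqrt(vsum))
                merged = (v2 * x1 + v1 * x2) / vsum
                extra = v1 * v2 / vsum
            vals[id(node)] = merged
            bl[id(node)] = (node.edge.length or 0.0) + extra
    return np.array(contrasts)


def blomberg_k(
    tree: dendropy.Tree,
    trait: dict[str, float] | pd.Series,
    n_reps: int = 999,
    seed: int = 0,
    _cov: np.ndarray | None = None,
) -> SignalResult:
    """Blomberg's K with a contrasts-based randomisation p-value.

    K is the ratio of observed to Brownian-expected MSE0/MSE, where
    MSE0 is the tip variance around the phylogenetic GLS mean and MSE
    the phylogenetically corrected error; K ~ 1 under Brownian motion,
    < 1 for weaker and > 1 for stronger signal. Significance comes from
    shuffling trait values across tips and comparing the variance of
    phylogenetically independent contrasts (observed low variance =
    signal); ``n_reps = 0`` skips the test. ``_cov`` lets callers reuse
    a precomputed BM covariance for repeated tests on one tree.
    """
    trait = dict(trait)
    labels = _leaf_labels(tree)
    missing = [sp for sp in labels if sp not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing[:5]}")
    x = np.array([float(trait[sp]) for sp in labels])
    n = len(x)
    if np.allclose(x, x[0]):
        raise ValueError("constant trait: K undefined")
    C = phylo_covariance(tree, labels)[1] if _cov is None else _cov
    Cj = _nearest_pd(C)
    cf = cho_factor(Cj)
    one = np.ones(n)
    Cinv1 = cho_solve(cf, one)
    denom1 = one @ Cinv1
    ahat = (Cinv1 @ x) / denom1
    r = x - ahat
    mse0 = (r @ r) / (n - 1)
    mse = (r @ cho_solve(cf, r)) / (n - 1)
    observed_ratio = mse0 / mse
    expected_ratio = (np.trace(Cj) - n / denom1) / (n - 1)
    k_stat = observed_ratio / expected_ratio

    p = null_mean = null_sd = None
    if n_reps:
        bt = _binary_resolved(tree)
        rng = np.random.default_rng(seed)
        obs_var = np.var(_pic_contrasts(bt, dict(zip(labels, x))))
        null = np.empty(n_reps)
        for rep in range(n_reps):
            shuffled = dict(zip(labels, rng.permutation(x)))
            null[rep] = np.var(_pic_contrasts(bt, shuffled))
        p = (1 + np.sum(null <= obs_var)) / (n_reps + 1)
        null_mean, null_sd = float(null.mean()), float(null.std(ddof=1))
    return SignalResult(float(k_stat), null_mean, null_sd, p, n_reps, method="blomberg_k")


def _fitch_steps(tree: dendropy.Tree, states: dict[str, str]) -> int:
    """Minimum parsimony steps of a categorical trait (Fitch, binary tree)."""
    sets: dict[int, frozenset] = {}
    steps = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset([states[node.taxon.label]])
        else:
            c1, c2 = node.child_nodes()
            s1, s2 = sets.pop(id(c1)), sets.pop(id(c2))
            inter = s1 & s2
            if inter:
                sets[id(node)] = inter
            else:
                sets[id(node)] = s1 | s2
                steps += 1
    return steps


def categorical_signal(
    tree: dendropy.Tree,
    trait: dict[str, str] | pd.Series,
    n_reps: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Maddison-Slatkin test: parsimony steps versus tip-shuffled nulls.

    The tree is fixed and tip states are shuffled; signal shows as an
    observed step count in the lower tail of the null. Resolving
    polytomies with zero-length edges does not change the Fitch
    minimum. A single-state trait returns 0 steps and p = 1.
    """
    trait = {k: str(v) for k, v in dict(trait).items()}
    labels = _leaf_labels(tree)
    missing = [sp for sp in labels if sp not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing[:5]}")
    values = [trait[sp] for sp in labels]
    bt = _binary_resolved(tree)
    if len(set(values)) < 2:
        return SignalResult(0.0, 0.0, 0.0, 1.0, n_reps, method="maddison_slatkin")
    obs = _fitch_steps(bt, dict(zip(labels, values)))
    rng = np.random.default_rng(seed)
    arr = np.array(values, dtype=object)
    null = np.empty(n_reps)
    for rep in range(n_reps):
        null[rep] = _fitch_steps(bt, dict(zip(labels, rng.permutation(arr))))
    p = (1 + np.sum(null <= obs)) / (n_reps + 1)
    return SignalResult(
        float(obs), float(null.mean()), float(null.std(ddof=1)), float(p),
        n_reps, method="maddison_slatkin",
    )


# ---------------------------------------------------------------------------
# Brownian-motion imputation
# ---------------------------------------------------------------------------

def _nearest_pd(C: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Return C, ridged just enough to be Cholesky-decomposable.

    Raises on genuinely indefinite input; positive semi-definite
    matrices (e.g. from zero-length cherries) get a tiny diagonal
    ridge.
    """
    try:
        np.linalg.cholesky(C)
        return C
    except np.linalg.LinAlgError:
        pass
    scale = float(np.mean(np.diag(C))) or 1.0
    eps = jitter * scale
    eye = np.eye(len(C))
    for _ in range(7):  # ridge up to ~1e-4 of scale, no further
        try:
            np.linalg.cholesky(C + eps * eye)
            return C + eps * eye
        except np.linalg.LinAlgError:
            eps *= 10
    raise np.linalg.LinAlgError("covariance matrix is not positive definite")


def impute_traits(
    tree: dendropy.Tree,
    traits: TraitTable,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> TraitTable:
    """Fill missing quantitative values under multivariate Brownian motion.

    Tips are jointly Gaussian with covariance ``kron(R, C)`` where C is
    the BM phylogenetic covariance (shared path lengths) and R the
    among-trait evolutionary covariance. The ancestral mean vector and
    R are estimated by maximum likelihood via EM over the missing
    entries; missing values are then replaced by their conditional
    expectation given everything observed — close relatives and
    correlated traits pull hardest. Observed entries and categorical
    traits pass through untouched.
    """
    out = traits.copy()
    quant = traits.quantitative
    if not quant:
        return out
    X = traits.quantitative_matrix()
    obs_mask = ~np.isnan(X)
    if obs_mask.all():
        return out
    empty = [quant[j] for j in range(len(quant)) if not obs_mask[:, j].any()]
    if empty:
        raise ValueError(f"traits with no observed values: {empty}")

    species = traits.species
    _, C = phylo_covariance(tree, species)
    C = _nearest_pd(C)
    n, p = X.shape
    cfC = cho_factor(C)
    one = np.ones(n)
    Cinv1 = cho_solve(cfC, one)
    a = one @ Cinv1

    # flat vec, trait-major: entry j*n + s is trait j of species s
    flat_missing = np.flatnonzero(~obs_mask.ravel(order="F"))
    flat_obs = np.flatnonzero(obs_mask.ravel(order="F"))
    msp = flat_missing % n
    mtr = flat_missing // n
    x_obs = X.ravel(order="F")[flat_obs]

    mu = np.nanmean(X, axis=0)
    var0 = np.nanvar(X, axis=0, ddof=0)
    R = np.diag(np.maximum(var0, 1e-12 * max(var0.max(), 1.0)))
    Cinv_mm = cho_solve(cfC, np.eye(n))[np.ix_(msp, msp)]

    Xhat = X.copy()
    for _ in range(max_iter):
        Sigma = np.kron(R, C)
        mean_vec = np.repeat(mu, n)
        Soo = Sigma[np.ix_(flat_obs, flat_obs)]
        Som = Sigma[np.ix_(flat_obs, flat_missing)]
        cf = cho_factor(_nearest_pd(Soo))
        w = cho_solve(cf, x_obs - mean_vec[flat_obs])
        xm = mean_vec[flat_missing] + Som.T @ w
        Vm = Sigma[np.ix_(flat_missing, flat_missing)] - Som.T @ cho_solve(cf, Som)

        Xhat = X.copy()
        Xhat[msp, mtr] = xm
        CinvX = cho_solve(cfC, Xhat)
        mu_new = (one @ CinvX) / a
        Xc = Xhat - mu_new
        R_new = Xc.T @ cho_solve(cfC, Xc)
        corr = np.zeros((p, p))
        np.add.at(corr, (mtr[:, None], mtr[None, :]), Cinv_mm * Vm)
        R_new = (R_new + corr) / n
        R_new = (R_new + R_new.T) / 2.0

        shift = max(
            np.max(np.abs(mu_new - mu)) / (1.0 + np.max(np.abs(mu_new))),
            np.max(np.abs(R_new - R)) / (1.0 + np.max(np.abs(R_new))),
        )
        mu, R = mu_new, R_new
        if shift < tol:
            break

    filled = X.copy()
    filled[msp, mtr] = xm
    out.data[quant] = filled
    return out
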