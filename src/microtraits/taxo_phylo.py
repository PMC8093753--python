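"""Taxonomy-derived star trees, Brownian simulation, and PGLS.

A rank-normalized seven-level taxonomy (superkingdom, phylum, class, order,
family, genus, species) is read as a rooted tree: internal nodes are shared
taxonomy prefixes, every node is a star polytomy over its children, every
branch has unit length, and a root sits above the superkingdoms so species
in different domains share no path. Every species therefore sits at depth 7
and, under Brownian trait evolution, the covariance between two species is
the number of leading ranks they share (0..6; 7 on the diagonal).

Generalized least squares under that covariance ("PGLS") measures the
correlation of trait divergences across the ensemble of nodes, rather than
the correlation across present-day tips; it down-weights differences
between major clades that are counted once, not once per descendant.

The GLS solve whitens through a Cholesky factor of V (never an explicit
inverse on the main path), profiles out the residual variance in the
Gaussian likelihood, and reports AIC with the variance counted as one
parameter. R-squared is the squared correlation between fitted and observed
values in the whitened space, which for OLS with an intercept coincides
with the usual 1 - RSS/TSS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from scipy.linalg import qr as _qr
from scipy.linalg import solve_triangular

N_RANKS = 7
_CHOL_JITTER = 1e-10


class _Node:
    __slots__ = ("name", "depth", "children", "tip_index")

    def __init__(self, name: str, depth: int):
        self.name = name
        self.depth = depth
        self.children: dict[str, _Node] = {}
        self.tip_index: int | None = None


class TaxonomyTree:
    """Rooted 7-rank star-polytomy tree with unit branch lengths."""

    def __init__(self, root: _Node, species: list[str], taxonomies: list[tuple]):
        self._root = root
        self.species = species
        self.taxonomies = taxonomies

    @property
    def n_tips(self) -> int:
        return len(self.species)

    def mrca_depth(self, a: str, b: str) -> int:
        """Depth of the most recent common ancestor of two species."""
        ta = self.taxonomies[self.species.index(a)]
        tb = self.taxonomies[self.species.index(b)]
        d = 0
        for x, y in zip(ta, tb):
            if x != y:
                break
            d += 1
        return d

    def to_newick(self) -> str:
        """Newick string with unit branch lengths written explicitly."""

        def render(node: _Node) -> str:
            if not node.children:
                return f"{_quote(node.name)}:1"
            inner = ",".join(render(c) for c in node.children.values())
            return f"({inner}){_quote(node.name)}:1"

        inner = ",".join(render(c) for c in self._root.children.values())
        return f"({inner})root;"

    @classmethod
    def from_newick(cls, newick: str) -> "TaxonomyTree":
        import dendropy

        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
        taxonomies = []
        for leaf in tree.leaf_node_iter():
            path = []
            node = leaf
            while node.parent_node is not None:
                label = node.taxon.label if node.taxon is not None else node.label
                path.append(label)
                node = node.parent_node
            path.reverse()
            if len(path) != N_RANKS:
                raise ValueError(
                    f"leaf {path[-1] if path else '?'} at depth {len(path)}, expected {N_RANKS}"
                )
            taxonomies.append(tuple(path))
        return build_tree(taxonomies)


def _quote(name: str) -> str:
    if any(c in name for c in " ,():;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def build_tree(taxonomies) -> TaxonomyTree:
    """Build the taxonomy trie: one node per shared rank prefix, unit branches."""
    taxs = [tuple(str(r) for r in t) for t in taxonomies]
    for t in taxs:
        if len(t) != N_RANKS or any(not r or r == "nan" for r in t):
            raise ValueError(f"taxonomy must have {N_RANKS} non-empty ranks: {t!r}")
    species = [t[-1] for t in taxs]
    seen = set()
    for s in species:
        if s in seen:
            raise ValueError(f"duplicate species name: {s!r}")
        seen.add(s)
    root = _Node("root", 0)
    for i, t in enumerate(taxs):
        node = root
        for depth, name in enumerate(t, start=1):
            node = node.children.setdefault(name, _Node(name, depth))
        node.tip_index = i
    return TaxonomyTree(root, species, taxs)


@dataclass
class PhyloCovariance:
    """Brownian covariance induced by a taxonomy tree (shared path lengths)."""

    species: list[str]
    matrix: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.species)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def covariance(tree: TaxonomyTree) -> PhyloCovariance:
    """V[i, j] = depth of MRCA(i, j); V[i, i] = 7."""
    n = tree.n_tips
    V = np.zeros((n, n))

    def visit(node: _Node) -> list[int]:
        if node.tip_index is not None:
            return [node.tip_index]
        sets = [visit(c) for c in node.children.values()]
        if node.depth > 0 and len(sets) > 1:
            for i, a in enumerate(sets):
                ia = np.asarray(a)
                for b in sets[i + 1 :]:
                    ib = np.asarray(b)
                    V[np.ix_(ia, ib)] = node.depth
                    V[np.ix_(ib, ia)] = node.depth
        return [t for s in sets for t in s]

    visit(tree._root)
    np.fill_diagonal(V, float(N_RANKS))
    return PhyloCovariance(list(tree.species), V)


def simulate_brownian(
    tree: TaxonomyTree,
    sigma2: float,
    root_value: float = 0.0,
    *,
    seed=None,
    rng: np.random.Generator | None = None,
    n_reps: int | None = None,
):
    """Simulate Brownian motion on the tree: each branch adds N(0, sigma2).

    Returns tip values in ``tree.species`` order; shape (n_tips,) or, with
    ``n_reps``, (n_reps, n_tips). Reproducible under a fixed seed.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    reps = 1 if n_reps is None else int(n_reps)
    out = np.empty((reps, tree.n_tips))
    sd = math.sqrt(sigma2)
    stack = [(tree._root, np.full(reps, float(root_value)))]
    while stack:
        node, val = stack.pop()
        for child in node.children.values():
            cv = val + rng.normal(0.0, sd, size=reps)
            if child.tip_index is not None:
                out[:, child.tip_index] = cv
            else:
                stack.append((child, cv))
    return out[0] if n_reps is None else out


def simulate_correlated_brownian(
    tree: TaxonomyTree,
    sigma2,
    rho,
    root_values=None,
    *,
    seed=None,
    rng: np.random.Generator | None = None,
    depth_weights=None,
) -> np.ndarray:
    """Simulate k correlated Brownian traits on the tree.

    Independent standard-normal branch increments are mixed through the
    Cholesky factor of ``rho`` and scaled by sqrt(sigma2) per trait, so each
    trait is Brownian with its own rate and the increment (and hence tip)
    cross-trait correlation matrix is ``rho``. ``depth_weights`` optionally
    rescales the variance contributed by branches ending at depths 1..7
    (normalized to sum to 7, so the tip variance stays 7*sigma2); the
    default is uniform. Returns (n_tips, k).
    """
    s2 = np.asarray(sigma2, dtype=float)
    rho = np.asarray(rho, dtype=float)
    k = s2.size
    if rho.shape != (k, k) or not np.allclose(rho, rho.T):
        raise ValueError("rho must be a symmetric k x k matrix")
    if np.any(s2 < 0):
        raise ValueError("sigma2 entries must be non-negative")
    try:
        L = np.linalg.cholesky(rho)
    except np.linalg.LinAlgError as e:
        raise ValueError("rho must be positive semi-definite") from e
    M = np.sqrt(s2)[:, None] * L
    if depth_weights is None:
        w = np.ones(N_RANKS)
    else:
        w = np.asarray(depth_weights, dtype=float)
        if w.shape != (N_RANKS,) or np.any(w < 0):
            raise ValueError(f"depth_weights must be {N_RANKS} non-negative values")
        w = w * (N_RANKS / w.sum())
    sqrt_w = np.sqrt(w)
    if rng is None:
        rng = np.random.default_rng(seed)
    if root_values is None:
        root_values = np.zeros(k)
    out = np.empty((tree.n_tips, k))
    stack = [(tree._root, np.asarray(root_values, dtype=float))]
    while stack:
        node, val = stack.pop()
        for child in node.children.values():
            cv = val + sqrt_w[child.depth - 1] * (M @ rng.normal(size=k))
            if child.tip_index is not None:
                out[child.tip_index] = cv
            else:
                stack.append((child, cv))
    return out


@dataclass
class RegressionModel:
    """A fitted linear model (OLS or PGLS)."""

    estimator: str  # "OLS" or "PGLS"
    terms: tuple
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    n: int
    p: int
    rss: float  # whitened residual sum of squares
    loglik: float
    aic: float
    r2: float
    df_resid: int

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Two-sided t confidence intervals for the coefficients."""
        tcrit = _sstats.t.ppf(0.5 + level / 2.0, self.df_resid)
        return np.column_stack([self.beta - tcrit * self.se, self.beta + tcrit * self.se])


def gaussian_loglik(rss: float, n: int) -> float:
    """Profiled Gaussian log-likelihood at the ML variance RSS/n."""
    if rss <= 0:
        raise ValueError("RSS must be positive (degenerate perfect fit)")
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def _cholesky_psd(V: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        try:
            return np.linalg.cholesky(V + _CHOL_JITTER * np.eye(V.shape[0]))
        except np.linalg.LinAlgError as e:
            raise ValueError("covariance matrix is not positive semi-definite") from e


def _gls_core(yw, Xw, logdet_V, estimator, terms) -> RegressionModel:
    n, p = Xw.shape
    if n < p + 1:
        raise ValueError(f"need n >= p + 1 (n={n}, p={p})")
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        _, _, piv = _qr(Xw, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        names = [terms[i] if terms is not None else str(i) for i in bad]
        raise ValueError(f"design matrix is rank-deficient; offending columns: {names}")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        raise ValueError("degenerate perfect fit (RSS = 0)")
    ll = gaussian_loglik(rss, n) - 0.5 * logdet_V
    aic = -2.0 * ll + 2.0 * (p + 1)
    fitted = Xw @ beta
    if np.ptp(fitted) == 0 or np.ptp(yw) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, yw)[0, 1] ** 2)
    sigma2_hat = rss / (n - p)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(sigma2_hat * np.diag(XtX_inv))
    tvals = beta / se
    if terms is None:
        terms = tuple(f"x{i}" for i in range(p))
    return RegressionModel(
        estimator=estimator,
        terms=tuple(terms),
        beta=beta,
        se=se,
        tvalues=tvals,
        n=n,
        p=p,
        rss=rss,
        loglik=ll,
        aic=aic,
        r2=r2,
        df_resid=n - p,
    )


def ols_fit(y, X, terms=None) -> RegressionModel:
    """Ordinary least squares (GLS with identity covariance)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return _gls_core(y, X, 0.0, "OLS", terms)


def pgls_fit(y, X, V, terms=None) -> RegressionModel:
    """Phylogenetic GLS: minimize (y - Xb)' V^-1 (y - Xb).

    ``V`` is a PhyloCovariance or a symmetric PSD matrix aligned with the
    rows of y and X. The solve whitens y and X by the Cholesky factor of V;
    coefficient covariance is sigma2_hat * (X' V^-1 X)^-1 with
    sigma2_hat = RSS/(n - p).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(V, PhyloCovariance):
        V = V.matrix
    V = np.asarray(V, dtype=float)
    n = y.shape[0]
    if V.shape != (n, n):
        raise ValueError(f"V must be {n} x {n}, got {V.shape}")
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("V must be symmetric")
    L = _cholesky_psd(V)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    return _gls_core(yw, Xw, logdet_V, "PGLS", terms)
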