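"""Trait and climatic-niche divergence between sister species.

Similarity in mimicry rings or host plants between two sisters is
x / y: the number of shared labels over the label count of the sister
with the smaller repertoire, so a species using a subset of its
sister's traits scores 1.  Trait similarity versus branch length is
fitted as a binomial GLM (logit link) on (shared, unshared) counts;
when the Pearson dispersion exceeds 1, standard errors are inflated by
sqrt(dispersion) in the quasi-binomial fashion (variance phi * mu),
leaving the coefficients themselves untouched.

Climatic niches are summarised by reducing a stack of bioclim-style
layers to three principal components of the correlation matrix and
taking each species' minimum convex polyhedron (3-D convex hull) of
its occurrence scores; niche overlap is intersection volume over the
smaller volume, mirroring the range-overlap index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError
from scipy.special import expit

from .inference import ArcFit, arc_regression

__all__ = [
    "TraitProfile",
    "NichePolyhedron",
    "QuasiBinomialFit",
    "PCAResult",
    "DegenerateNicheError",
    "trait_similarity",
    "quasibinomial_regression",
    "inverse_logit",
    "climate_regression",
    "overlap_multiple_regression",
    "pca_correlation",
    "niche_polyhedron",
    "polyhedron_overlap",
]


class DegenerateNicheError(ValueError):
    """Point set too degenerate (coplanar/collinear) for a 3-D hull."""


@dataclass(frozen=True)
class TraitProfile:
    """Per-species categorical trait sets, labels case-normalised."""

    species_id: str
    mimicry_rings: frozenset[str] = frozenset()
    host_plants: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mimicry_rings", frozenset(s.strip().lower() for s in self.mimicry_rings)
        )
        object.__setattr__(
            self, "host_plants", frozenset(s.strip().lower() for s in self.host_plants)
        )


def trait_similarity(set_a, set_b) -> float:
    """Shared labels over the size of the smaller repertoire.

    Symmetric; equals 1 exactly when one set is a subset of the other.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("trait similarity undefined for an empty trait set")
    return len(a & b) / min(len(a), len(b))


def inverse_logit(b: float) -> float:
    """Logistic function 1 / (1 + exp(-b)): logit scale to proportion."""
    return float(expit(b))


@dataclass(frozen=True)
class QuasiBinomialFit:
    """Binomial GLM fit with optional quasi-likelihood SE correction.

    ``dispersion`` is Pearson chi-square over residual degrees of
    freedom; corrected SEs equal naive SEs scaled by sqrt(dispersion)
    when dispersion > 1, otherwise the naive SEs.  ``flag`` is None for
    a clean fit, or a diagnostic string (e.g. separation).
    """

    intercept: float
    slope: float
    intercept_se_naive: float
    slope_se_naive: float
    dispersion: float
    intercept_se: float
    slope_se: float
    intercept_backtransformed: float
    n: int
    flag: str | None = None


def quasibinomial_regression(x_shared, y_denominator, predictor) -> QuasiBinomialFit:
    """Trait similarity (shared / total counts) regressed on branch length.

    Fits a logit-link binomial GLM of (x, y - x) on the predictor by
    IRLS.  Degenerate likelihoods (all proportions 0 or all 1, or
    quasi-complete separation) are returned flagged with NaN estimates
    rather than silently.
    """
    x = np.asarray(x_shared, dtype=float)
    y = np.asarray(y_denominator, dtype=float)
    t = np.asarray(predictor, dtype=float)
    if not (x.size == y.size == t.size):
        raise ValueError("inputs differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(x < 0) or np.any(x > y):
        raise ValueError("shared counts must satisfy 0 <= x <= y")
    nan_fit = QuasiBinomialFit(
        intercept=np.nan, slope=np.nan, intercept_se_naive=np.nan,
        slope_se_naive=np.nan, dispersion=np.nan, intercept_se=np.nan,
        slope_se=np.nan, intercept_backtransformed=np.nan, n=int(x.size),
        flag="separation",
    )
    if np.all(x == y) or np.all(x == 0):
        return nan_fit
    endog = np.column_stack([x, y - x])
    model = sm.GLM(endog, sm.add_constant(t), family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            fit = model.fit()
        except Exception:
            return nan_fit
    if not fit.converged or np.any(np.abs(fit.params) > 30):
        return nan_fit
    b0, b1 = fit.params
    phi = float(fit.pearson_chi2 / fit.df_resid)
    scale = np.sqrt(phi) if phi > 1 else 1.0
    return QuasiBinomialFit(
        intercept=float(b0),
        slope=float(b1),
        intercept_se_naive=float(fit.bse[0]),
        slope_se_naive=float(fit.bse[1]),
        dispersion=phi,
        intercept_se=float(fit.bse[0] * scale),
        slope_se=float(fit.bse[1] * scale),
        intercept_backtransformed=inverse_logit(float(b0)),
        n=int(x.size),
    )


def climate_regression(niche_overlaps, branch_lengths) -> ArcFit:
    """OLS of angular-transformed niche overlap on branch length."""
    return arc_regression(branch_lengths, niche_overlaps)


def overlap_multiple_regression(
    range_overlap, branch_length, mimicry_sim, host_sim, climate_sim
) -> pd.DataFrame:
    """Angular-transformed range overlap regressed on time and trait similarity.

    Complete cases only.  Returns one row per term (intercept, branch
    length, mimicry, host plant and climatic niche similarity) with
    coefficient, SE, t and two-sided p columns.  A rank-deficient design
    triggers a warning and a pivoted least-squares fit.
    """
    df = pd.DataFrame(
        {
            "range_overlap": np.asarray(range_overlap, dtype=float),
            "branch_length": np.asarray(branch_length, dtype=float),
            "mimicry_overlap": np.asarray(mimicry_sim, dtype=float),
            "host_plant_overlap": np.asarray(host_sim, dtype=float),
            "climatic_niche_overlap": np.asarray(climate_sim, dtype=float),
        }
    ).dropna()
    predictors = [
        "branch_length", "mimicry_overlap", "host_plant_overlap", "climatic_niche_overlap"
    ]
    if len(df) <= len(predictors) + 1:
        raise ValueError(
            f"{len(df)} complete cases leave no residual degrees of freedom"
        )
    y = np.arcsin(np.sqrt(df["range_overlap"].to_numpy()))
    X = sm.add_constant(df[predictors])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        warnings.warn("design matrix is rank deficient; fit uses a pivoted solve",
                      stacklevel=2)
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {
            "coefficient": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        },
        index=["intercept"] + predictors,
    )


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA of an environmental layer stack."""

    loadings: np.ndarray  # (n_variables, n_components)
    scores: np.ndarray  # (n_cells, n_components)
    variance_explained: np.ndarray  # fraction per retained component
    eigenvalues: np.ndarray  # all eigenvalues, descending


def pca_correlation(layers, n_components: int | None = 3) -> PCAResult:
    """Principal components of the correlation matrix of gridded variables.

    ``layers`` has shape (n_variables, n_cells) or (n_variables, H, W);
    each variable is standardised over cells before eigendecomposition,
    so the analysis is scale-free.  Three components are retained by
    default; pass None to keep all.
    """
    arr = np.asarray(layers, dtype=float)
    if arr.ndim > 2:
        arr = arr.reshape(arr.shape[0], -1)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need a stack of at least 3 variables")
    sd = arr.std(axis=1, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"layer(s) {dead.tolist()} are constant over cells")
    zs = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = (zs @ zs.T) / (arr.shape[1] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    k = arr.shape[0] if n_components is None else n_components
    return PCAResult(
        loadings=eigvec[:, :k],
        scores=zs.T @ eigvec[:, :k],
        variance_explained=eigval[:k] / eigval.sum(),
        eigenvalues=eigval,
    )


@dataclass(frozen=True)
class NichePolyhedron:
    """A species' climatic niche: convex hull of its 3-D PC scores."""

    vertices: np.ndarray
    volume: float
    _hull: ConvexHull | None = None


def niche_polyhedron(points) -> NichePolyhedron:
    """Minimum convex polyhedron enclosing a species' niche-space points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of PC scores")
    if pts.shape[0] < 4:
        raise DegenerateNicheError(
            f"{pts.shape[0]} points cannot span a 3-D polyhedron"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateNicheError(f"degenerate niche point set: {exc}") from exc
    if hull.volume <= 0:
        raise DegenerateNicheError("niche points are coplanar (zero volume)")
    return NichePolyhedron(
        vertices=pts[hull.vertices], volume=float(hull.volume), _hull=hull
    )


def _interior_point(halfspaces: np.ndarray) -> np.ndarray | None:
    """Chebyshev centre of {x : A x + b <= 0}, or None if it has no interior."""
    A, b = halfspaces[:, :-1], halfspaces[:, -1]
    norms = np.linalg.norm(A, axis=1)
    # maximise r subject to A x + r ||A_i|| <= -b
    res = linprog(
        c=np.r_[np.zeros(A.shape[1]), -1.0],
        A_ub=np.c_[A, norms],
        b_ub=-b,
        bounds=[(None, None)] * A.shape[1] + [(0, None)],
        method="highs",
    )
    if not res.success or res.x[-1] <= 1e-9:
        return None
    return res.x[:-1]


def polyhedron_overlap(p: NichePolyhedron, q: NichePolyhedron) -> float:
    """Niche overlap: intersection volume over the smaller polyhedron's volume.

    The intersection is computed exactly by stacking the two hulls'
    facet halfspaces and intersecting them; disjoint or merely touching
    polyhedra score 0.
    """
    hull_p = p._hull or ConvexHull(p.vertices)
    hull_q = q._hull or ConvexHull(q.vertices)
    halfspaces = np.vstack([hull_p.equations, hull_q.equations])
    centre = _interior_point(halfspaces)
    if centre is None:
        return 0.0
    try:
        inter = HalfspaceIntersection(halfspaces, centre)
        vol = float(ConvexHull(inter.intersections).volume)
    except QhullError:
        return 0.0
    return min(vol / min(p.volume, q.volume), 1.0)
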