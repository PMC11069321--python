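"""Edge-wise association between connectivity and PET covariance.

The question: do functionally connected region pairs show similar PET
activity? Operationally, OLS of one edge vector on another (slope beta, with
an unadjusted Pearson r reported alongside), globally, per canonical
network, and optionally controlling for inter-centroid Euclidean distance.

Significance beyond the parametric t-test comes from a permutation null:
the connectivity matrix is shuffled (joint row/column relabelling by
default, or free shuffling of upper-triangle values), beta recomputed
identically each time, and the observed beta ranked within the null by an
exact test with add-one smoothing.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .atlas import AtlasSpec, pairwise_distances
from .connectivity import ConnectivityMatrix, vectorize_upper


class AssociationError(ValueError):
    pass


@dataclass
class EdgeAssociationResult:
    beta: float
    intercept: float
    pearson_r: float
    p_parametric: float
    n_edges: int
    scope: str = "global"
    distance_adjusted: bool = False
    null_betas: np.ndarray | None = None
    p_exact: float | None = None

    @property
    def null_mean(self) -> float | None:
        return None if self.null_betas is None else float(np.mean(self.null_betas))

    @property
    def null_sd(self) -> float | None:
        return None if self.null_betas is None else float(np.std(self.null_betas, ddof=1))


def _as_edge_vector(obj) -> np.ndarray:
    if isinstance(obj, ConnectivityMatrix):
        return vectorize_upper(obj)
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 2:
        return vectorize_upper(arr)
    return arr


def edge_glm(
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    extra_covariates: np.ndarray | None = None,
    scope: str = "global",
    distance_adjusted: bool = False,
) -> EdgeAssociationResult:
    """OLS of y on [1, x, covariates]; beta is the coefficient on x.

    ``pearson_r`` is always the simple (unadjusted) correlation of x and y,
    reported alongside even when covariates are present. The parametric p is
    the two-sided t-test on beta.
    """
    x = np.asarray(x_edges, dtype=float)
    y = np.asarray(y_edges, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AssociationError("x and y edge vectors must be 1-D and equal length")
    if x.size < 3:
        raise AssociationError(f"need >= 3 edges, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise AssociationError("edge vectors must be finite")
    if x.std() == 0:
        raise AssociationError("zero variance in x edges")
    cols = [x]
    if extra_covariates is not None:
        Z = np.atleast_2d(np.asarray(extra_covariates, dtype=float))
        if Z.shape[0] != x.size:
            Z = Z.T
        if Z.shape[0] != x.size:
            raise AssociationError("covariate length does not match edge count")
        keep = Z.std(axis=0) > 0
        if not keep.all():
            warnings.warn(
                "constant extra covariate(s) dropped from edge GLM", stacklevel=2
            )
        Z = Z[:, keep]
        if Z.shape[1]:
            cols.append(Z)
    design = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(y, design).fit()
    r, _ = stats.pearsonr(x, y)
    return EdgeAssociationResult(
        beta=float(fit.params[1]),
        intercept=float(fit.params[0]),
        pearson_r=float(r),
        p_parametric=float(fit.pvalues[1]),
        n_edges=int(x.size),
        scope=scope,
        distance_adjusted=distance_adjusted,
    )


def _fwl_slope_factory(y: np.ndarray, covariates: np.ndarray | None):
    """Return f(x) -> OLS slope of y on [1, x, covariates].

    Frisch–Waugh–Lovell: residualize x and y on [1, covariates] once per
    call for x (y once up front), slope = <x~, y~> / <x~, x~>. Exact match
    to the full OLS coefficient; used in permutation loops.
    """
    n = y.size
    if covariates is None or covariates.size == 0:
        Zd = np.ones((n, 1))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        Z = Z[:, Z.std(axis=0) > 0]
        Zd = np.column_stack([np.ones(n), Z])
    # hat-matrix projector via pseudoinverse (small column count)
    pinv = np.linalg.pinv(Zd)
    y_res = y - Zd @ (pinv @ y)

    def slope(x: np.ndarray) -> float:
        x_res = x - Zd @ (pinv @ x)
        denom = x_res @ x_res
        if denom == 0:
            return 0.0
        return float((x_res @ y_res) / denom)

    return slope


def _p_exact(null_betas: np.ndarray, beta_obs: float, tail: str) -> float:
    stat = np.abs(null_betas) if tail == "two-sided" else null_betas
    obs = abs(beta_obs) if tail == "two-sided" else beta_obs
    return float((1 + np.sum(stat >= obs)) / (null_betas.size + 1))


def permutation_null(
    fc: ConnectivityMatrix | np.ndarray,
    y: ConnectivityMatrix | np.ndarray,
    n_perm: int = 500,
    scheme: str = "node_relabel",
    seed: int | np.random.Generator | None = None,
    extra_covariates: np.ndarray | None = None,
    tail: str = "greater",
    exhaustive: bool = False,
) -> EdgeAssociationResult:
    """Edge association with a shuffled-connectivity null distribution.

    Schemes
    -------
    node_relabel (default)
        One random ROI permutation applied jointly to rows and columns of
        the connectivity matrix; preserves its value distribution and the
        pairing structure of edges.
    edge_shuffle
        Upper-triangle values permuted uniformly.

    ``p_exact = (1 + #{beta_null >= beta_obs}) / (n_perm + 1)`` for the
    default right tail (the hypotheses are directional); ``tail='two-sided'``
    ranks |beta|. With ``exhaustive=True`` (node_relabel, small P) all P!
    relabellings are enumerated and ``p_exact`` is the plain fraction of
    permutations (identity included) with beta at least the observed.
    """
    fc_mat = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, dtype=float)
    P = fc_mat.shape[0]
    if P < 3:
        raise AssociationError(f"need P >= 3 ROIs, got {P}")
    if scheme not in ("node_relabel", "edge_shuffle"):
        raise AssociationError(f"unknown scheme {scheme!r}")
    if tail not in ("greater", "two-sided"):
        raise AssociationError(f"unknown tail {tail!r}")
    x_edges = vectorize_upper(fc_mat)
    y_edges = _as_edge_vector(y)
    observed = edge_glm(x_edges, y_edges, extra_covariates=extra_covariates)
    slope = _fwl_slope_factory(y_edges, extra_covariates)

    if exhaustive:
        if scheme != "node_relabel":
            raise AssociationError("exhaustive enumeration requires node_relabel")
        if P > 8:
            raise AssociationError("exhaustive enumeration is only for small P")
        null = np.array(
            [
                slope(vectorize_upper(fc_mat[np.ix_(perm, perm)]))
                for perm in itertools.permutations(range(P))
            ]
        )
        stat = np.abs(null) if tail == "two-sided" else null
        obs = abs(observed.beta) if tail == "two-sided" else observed.beta
        # plain enumeration fraction; identity permutation makes p >= 1/P!
        p_exact = float(np.mean(stat >= obs - 1e-12))
    else:
        if n_perm < 1:
            raise AssociationError("n_perm must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null = np.empty(n_perm)
        iu = np.triu_indices(P, k=1)
        for i in range(n_perm):
            if scheme == "node_relabel":
                perm = rng.permutation(P)
                x_null = fc_mat[np.ix_(perm, perm)][iu]
            else:
                x_null = rng.permutation(x_edges)
            null[i] = slope(x_null)
        p_exact = _p_exact(null, observed.beta, tail)

    observed.null_betas = null
    observed.p_exact = p_exact
    return observed


@dataclass
class SkippedNetwork:
    network: str
    reason: str


def network_specific(
    fc: ConnectivityMatrix,
    y: ConnectivityMatrix,
    atlas: AtlasSpec,
    extra_covariates_matrix: np.ndarray | None = None,
) -> dict[str, EdgeAssociationResult | SkippedNetwork]:
    """One association per canonical network, within-network edges only.

    Networks with fewer than 3 within-network edges are reported as skipped.
    ``extra_covariates_matrix`` (P x P, e.g. distances) is masked to the same
    edges.
    """
    if fc.P != atlas.P or y.P != atlas.P:
        raise AssociationError("matrix/atlas ROI counts disagree")
    out: dict[str, EdgeAssociationResult | SkippedNetwork] = {}
    for net in atlas.networks_present:
        mask = atlas.network_mask(net)
        m = int(mask.sum())
        if m * (m - 1) // 2 < 3:
            out[net] = SkippedNetwork(
                network=net,
                reason=f"only {m * (m - 1) // 2} within-network edge(s) ({m} ROIs)",
            )
            continue
        x_edges = vectorize_upper(fc, roi_mask=mask)
        y_edges = vectorize_upper(y, roi_mask=mask)
        cov = (
            vectorize_upper(extra_covariates_matrix, roi_mask=mask)
            if extra_covariates_matrix is not None
            else None
        )
        out[net] = edge_glm(
            x_edges,
            y_edges,
            extra_covariates=cov,
            scope=f"network:{net}",
            distance_adjusted=cov is not None,
        )
    return out


def distance_adjusted(
    fc: ConnectivityMatrix,
    y: ConnectivityMatrix,
    atlas: AtlasSpec,
) -> EdgeAssociationResult:
    """Global association controlling the regression for Euclidean distance."""
    if fc.P != atlas.P:
        raise AssociationError("matrix/atlas ROI counts disagree")
    dist_edges = vectorize_upper(pairwise_distances(atlas))
    res = edge_glm(
        vectorize_upper(fc),
        _as_edge_vector(y),
        extra_covariates=dist_edges,
        distance_adjusted=True,
    )
    res.distance_adjusted = True
    return res
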