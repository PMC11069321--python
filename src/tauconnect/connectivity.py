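"""Connectivity and PET-covariance matrix construction.

Three kinds of P x P matrices share one container:

* functional connectivity — Pearson correlation of a subject's ROI time
  series, Fisher-Z transformed, diagonal zeroed, then group-averaged;
* tau covariance and FDG covariance ("metabolic connectivity") — Spearman
  correlation of two ROIs' SUVR values across the subjects of one group,
  Fisher-Z transformed, diagonal zeroed, optionally as partial correlation
  controlling for age/sex/education (ranks residualized on the covariates).

Spearman is used for the inter-subject covariances so a single extreme SUVR
value cannot dominate an edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .atlas import AtlasSpec, SubjectTable, TimeSeriesSet

#: correlations are clipped to +-(1 - R_CLIP) before atanh so perfect
#: correlations stay finite (z ~ 8.4) instead of poisoning regressions.
R_CLIP = 1e-7


class ConnectivityError(ValueError):
    pass


@dataclass
class ConnectivityMatrix:
    """P x P symmetric matrix with provenance metadata."""

    values: np.ndarray
    kind: str  # functional | tau_covariance | fdg_covariance
    scale: str = "fisher_z"  # fisher_z | raw_r
    group: str = "single-subject"  # NC | AD | single-subject
    n_subjects: int = 1
    adjusted_for: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        P = self.values.shape[0]
        if self.values.shape != (P, P):
            raise ConnectivityError("values must be a square matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ConnectivityError("values must be symmetric")
        if self.scale == "fisher_z" and np.abs(np.diag(self.values)).max() > 0:
            raise ConnectivityError("fisher_z matrices must have a zero diagonal")

    @property
    def P(self) -> int:
        return int(self.values.shape[0])


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing z = atanh(r), with |r| clipped to 1 - 1e-7.

    Monotone and odd; rejects |r| > 1 beyond numerical round-off.
    """
    arr = np.asarray(r, dtype=float)
    if np.abs(arr).max(initial=0.0) > 1 + 1e-12:
        raise ConnectivityError("correlation magnitude exceeds 1")
    out = np.arctanh(np.clip(arr, -(1 - R_CLIP), 1 - R_CLIP))
    return out if isinstance(r, np.ndarray) else float(out)


def _check_constant_columns(mat: np.ndarray, what: str) -> None:
    sd = mat.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ConnectivityError(
            f"constant {what} for ROI(s) {(bad + 1).tolist()} (roi_id, 1-based)"
        )


def functional_connectivity(ts: np.ndarray) -> ConnectivityMatrix:
    """Single-subject FC: Pearson r over all ROI pairs -> Fisher-Z, zero diag."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ConnectivityError("need a (T>=3, P) time-series array")
    _check_constant_columns(ts, "time series")
    r = np.corrcoef(ts, rowvar=False)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, kind="functional")


def group_average(matrices: Sequence[ConnectivityMatrix], group: str) -> ConnectivityMatrix:
    """Element-wise mean of Fisher-Z matrices; records the subject count."""
    if not matrices:
        raise ConnectivityError("no matrices to average")
    kinds = {m.kind for m in matrices}
    scales = {m.scale for m in matrices}
    if len(kinds) > 1 or len(scales) > 1:
        raise ConnectivityError(f"cannot average mixed matrices: {kinds}, {scales}")
    stack = np.stack([m.values for m in matrices])
    return ConnectivityMatrix(
        values=stack.mean(axis=0),
        kind=matrices[0].kind,
        scale=matrices[0].scale,
        group=group,
        n_subjects=len(matrices),
    )


def group_functional_connectivity(
    ts_set: TimeSeriesSet, group: str
) -> ConnectivityMatrix:
    """Convenience: per-subject FC then group average in Fisher-Z scale."""
    mats = [functional_connectivity(ts_set[sid]) for sid in ts_set.subject_ids]
    return group_average(mats, group=group)


def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of each column of y on [1, Z] (OLS)."""
    design = np.column_stack([np.ones(len(y)), Z])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def pet_covariance(
    table: SubjectTable,
    group: str,
    modality: str,
    covariates: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Inter-subject Spearman covariance matrix for one group and modality.

    Each edge is the Spearman correlation, across the group's subjects, of
    the two ROIs' SUVR values (average ranks for ties, Pearson on ranks).
    With ``covariates`` the SUVR ranks are residualized on the (raw) subject
    covariates — with intercept — and the residuals correlated, giving the
    partial-correlation variant controlling for age/sex/education.
    """
    suvr = table.group_suvr(group, modality)
    n = suvr.shape[0]
    if n < 4:
        raise ConnectivityError(f"need >= 4 subjects in group {group}, got {n}")
    _check_constant_columns(suvr, f"{modality} SUVR")
    ranks = stats.rankdata(suvr, axis=0)
    adjusted: tuple[str, ...] = ()
    if covariates:
        Z = table.covariate_matrix(group, covariates)
        if n <= Z.shape[1] + 2:
            raise ConnectivityError(
                f"n={n} subjects too few for {Z.shape[1]} covariates"
            )
        ranks = _residualize(ranks, Z)
        adjusted = tuple(covariates)
    # correlate by hand so a ROI whose variance was fully absorbed by the
    # covariates yields partial correlation 0 instead of NaN
    centered = ranks - ranks.mean(axis=0)
    sd = centered.std(axis=0)
    dead = sd < 1e-10 * max(sd.max(), 1.0)
    safe_sd = np.where(dead, 1.0, sd)
    normed = centered / (safe_sd * np.sqrt(n))
    r = normed.T @ normed
    r[dead, :] = 0.0
    r[:, dead] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        values=z,
        kind=f"{modality}_covariance",
        group=group,
        n_subjects=n,
        adjusted_for=adjusted,
    )


def vectorize_upper(
    matrix: np.ndarray | ConnectivityMatrix, roi_mask: np.ndarray | None = None
) -> np.ndarray:
    """Strict upper triangle (i < j) in row-major order.

    With ``roi_mask`` (boolean over ROIs) only edges with both endpoints in
    the mask are kept, in the row-major order of the masked submatrix.
    """
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        values = values[np.ix_(roi_mask, roi_mask)]
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def n_edges(P: int) -> int:
    return P * (P - 1) // 2
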