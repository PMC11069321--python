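"""Three-equation causal mediation with bootstrap inference.

The decomposition asks how much of the total effect of X on Y is routed
through a mediator M, via three OLS fits (covariates Z optional but shared
by all equations)::

    (1)  M = i1 + a*X  + Z
    (2)  Y = i2 + c*X  + Z          (c = total effect)
    (3)  Y = i3 + c'*X + b*M + Z    (c' = direct effect)

indirect = c - c' (equals a*b exactly for shared-covariate OLS), proportion
mediated = indirect / c. Inference is a nonparametric unit-resampling
bootstrap with percentile intervals and a sign-test p for the indirect
effect. The four classical mediation criteria (a significant; c significant;
b significant; |c'| < |c|) are evaluated and reported as booleans.

Applied at two levels by this package:

* edge level — X/M/Y are the upper-triangle edge vectors of the tau
  covariance, functional connectivity and FDG covariance matrices (covariate
  control, when wanted, happens at matrix construction via partial
  correlation, since per-edge subject covariates are undefined);
* hotspot level — units are the P-1 target ROIs; X = group-mean tau SUVR,
  M = FC of each target to the tau hotspot, Y = FDG Z-score vs the NC group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .atlas import SubjectTable
from .connectivity import ConnectivityMatrix, vectorize_upper


class MediationError(ValueError):
    pass


@dataclass
class MediationResult:
    a: float
    b: float
    c_total: float
    c_prime: float
    indirect: float
    proportion: float | None  # None when the total effect is unstably small
    ci_indirect: tuple[float, float]
    ci_proportion: tuple[float, float] | None
    p_indirect: float
    p_a: float
    p_c_total: float
    p_b: float
    criteria: dict[str, bool]
    n_units: int
    n_boot: int
    seed: int | None
    covariates: tuple[str, ...] = ()

    @property
    def proportion_unstable(self) -> bool:
        return self.proportion is None


def _fit_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray, Z: np.ndarray):
    """Fast path coefficients (a, c, c', b) via lstsq. Z includes no constant."""
    n = x.size
    ones = np.ones(n)
    d1 = np.column_stack([ones, x, Z]) if Z.size else np.column_stack([ones, x])
    d3 = (
        np.column_stack([ones, x, m, Z])
        if Z.size
        else np.column_stack([ones, x, m])
    )
    a = np.linalg.lstsq(d1, m, rcond=None)[0][1]
    c = np.linalg.lstsq(d1, y, rcond=None)[0][1]
    coef3 = np.linalg.lstsq(d3, y, rcond=None)[0]
    return float(a), float(c), float(coef3[1]), float(coef3[2])


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: tuple[str, ...] = (),
    n_boot: int = 1000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> MediationResult:
    """Run the three-equation mediation on aligned unit vectors.

    The indirect effect is the difference ``c - c'`` (identical to ``a*b``
    here); percentile bootstrap CIs for indirect and proportion; p_indirect
    is an add-one-smoothed two-sided bootstrap sign test. The proportion is
    withheld (None) when |c| is below a stability threshold relative to the
    scales of x and y, because the ratio explodes near a null total effect.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.shape == m.shape == y.shape) or x.ndim != 1:
        raise MediationError("x, m, y must be 1-D and equal length")
    Z = (
        np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(x.size, -1)
        if covariates is not None
        else np.empty((x.size, 0))
    )
    if x.size < Z.shape[1] + 4:
        raise MediationError(f"need at least covariates+4 units, got {x.size}")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if v.std() == 0:
            raise MediationError(f"zero variance in {name}")
    if abs(np.corrcoef(x, m)[0, 1]) > 1 - 1e-10:
        raise MediationError("x and m are collinear; mediation is unidentified")

    ones = np.ones(x.size)
    d1 = np.column_stack([ones, x, Z])
    d3 = np.column_stack([ones, x, m, Z])
    fit_m = sm.OLS(m, d1).fit()
    fit_y = sm.OLS(y, d1).fit()
    fit_full = sm.OLS(y, d3).fit()
    a = float(fit_m.params[1])
    c = float(fit_y.params[1])
    c_prime = float(fit_full.params[1])
    b = float(fit_full.params[2])
    indirect = c - c_prime

    stable = abs(c) > 1e-8 * (y.std() / x.std())
    proportion = indirect / c if stable else None

    rng = np.random.default_rng(seed)
    boot_ind = np.empty(n_boot)
    boot_prop = np.full(n_boot, np.nan)
    n = x.size
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, mb, yb, Zb = x[idx], m[idx], y[idx], Z[idx]
        if xb.std() == 0 or mb.std() == 0:
            boot_ind[i] = 0.0
            continue
        ab, cb, cpb, bb = _fit_paths(xb, mb, yb, Zb)
        boot_ind[i] = cb - cpb
        if abs(cb) > 1e-12:
            boot_prop[i] = (cb - cpb) / cb
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci_ind = tuple(np.percentile(boot_ind, [lo, hi]))
    prop_ok = np.isfinite(boot_prop)
    ci_prop = (
        tuple(np.percentile(boot_prop[prop_ok], [lo, hi]))
        if stable and prop_ok.sum() >= max(10, n_boot // 2)
        else None
    )
    n_le = int(np.sum(boot_ind <= 0))
    n_ge = int(np.sum(boot_ind >= 0))
    p_ind = min(1.0, 2.0 * (1 + min(n_le, n_ge)) / (n_boot + 1))

    p_a = float(fit_m.pvalues[1])
    p_c = float(fit_y.pvalues[1])
    p_b = float(fit_full.pvalues[2])
    criteria = {
        "x_associated_with_m": p_a < alpha,
        "x_associated_with_y": p_c < alpha,
        "m_associated_with_y": p_b < alpha,
        "direct_effect_reduced": abs(c_prime) < abs(c),
    }
    return MediationResult(
        a=a,
        b=b,
        c_total=c,
        c_prime=c_prime,
        indirect=indirect,
        proportion=proportion,
        ci_indirect=(float(ci_ind[0]), float(ci_ind[1])),
        ci_proportion=None if ci_prop is None else (float(ci_prop[0]), float(ci_prop[1])),
        p_indirect=float(p_ind),
        p_a=p_a,
        p_c_total=p_c,
        p_b=p_b,
        criteria=criteria,
        n_units=int(n),
        n_boot=int(n_boot),
        seed=seed,
        covariates=covariate_names,
    )


def fdg_zscores(table: SubjectTable) -> np.ndarray:
    """Per-ROI Z of the AD group-mean FDG against the NC reference.

    z[j] = (mean_AD - mean_NC) / sd_NC, with the NC sample SD (ddof=1).
    """
    nc = table.group_suvr("NC", "fdg")
    ad = table.group_suvr("AD", "fdg")
    if nc.shape[0] < 2 or ad.shape[0] < 1:
        raise MediationError("need >= 2 NC and >= 1 AD subjects for FDG Z-scores")
    sd = nc.std(axis=0, ddof=1)
    # constant-to-round-off NC values are as degenerate as exactly constant
    bad = np.flatnonzero(sd < 1e-12 * np.maximum(1.0, np.abs(nc.mean(axis=0))))
    if bad.size:
        raise MediationError(
            f"zero NC FDG SD for ROI(s) {(bad + 1).tolist()} (roi_id, 1-based)"
        )
    return (ad.mean(axis=0) - nc.mean(axis=0)) / sd


def edge_mediation(
    tau_cov: ConnectivityMatrix,
    fc: ConnectivityMatrix,
    fdg_cov: ConnectivityMatrix,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> MediationResult:
    """Edge-level mediation: tau covariance -> FC -> FDG covariance.

    Units are the upper-triangle edges. For the covariate-adjusted variant,
    pass partial-correlation matrices (age/sex/education removed at matrix
    construction); the covariate provenance is carried through.
    """
    if not (tau_cov.P == fc.P == fdg_cov.P):
        raise MediationError("matrices disagree on ROI count")
    adj = set(tau_cov.adjusted_for) | set(fdg_cov.adjusted_for)
    return mediate(
        vectorize_upper(tau_cov),
        vectorize_upper(fc),
        vectorize_upper(fdg_cov),
        n_boot=n_boot,
        seed=seed,
        covariate_names=tuple(sorted(adj)),
    )


def hotspot_mediation(
    tau_mean: np.ndarray,
    fc: ConnectivityMatrix | np.ndarray,
    fdg_z: np.ndarray,
    hotspot: int | None = None,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> MediationResult:
    """Hotspot-level mediation: tau SUVR -> FC-to-hotspot -> FDG Z-score.

    Units are the P-1 target ROIs (the hotspot itself is excluded). The
    hotspot defaults to the ROI of maximal group-mean tau.
    """
    tau_mean = np.asarray(tau_mean, dtype=float)
    fdg_z = np.asarray(fdg_z, dtype=float)
    mat = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, dtype=float)
    P = tau_mean.size
    if mat.shape != (P, P) or fdg_z.shape != (P,):
        raise MediationError("tau_mean, fc and fdg_z disagree on ROI count")
    if hotspot is None:
        hotspot = int(np.argmax(tau_mean))
    targets = np.arange(P) != hotspot
    return mediate(
        tau_mean[targets],
        mat[hotspot, targets],
        fdg_z[targets],
        n_boot=n_boot,
        seed=seed,
    )
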