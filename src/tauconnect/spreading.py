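"""Seed-based (epicenter) spreading analysis.

For every seed ROI, target uptake (group-mean SUVR over the P-1 other ROIs)
is regressed on the seed's connectivity to those targets; the slope is that
seed's spreading weight. A positive correlation across seeds between seed
uptake and these slopes is the signature of connectivity-borne spreading:
high-uptake seeds are connected to high-uptake targets, low-uptake seeds to
low-uptake targets. The hotspot (maximal group-mean uptake) and coldspot
(minimal) get individual reports.

Works for any (connectivity, uptake) pairing: FC x tau, FDG-covariance x
tau, FC x FDG.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)


class SpreadError(ValueError):
    pass


@dataclass
class SeedReport:
    """Regression of target uptake on seed-target connectivity for one seed."""

    seed: int  # 0-based ROI index
    beta: float
    beta_standardized: float
    r: float
    p: float


@dataclass
class SeedSpreadResult:
    betas: np.ndarray  # slope per seed; NaN where the seed row is degenerate
    global_r: float
    global_p: float
    hotspot: int  # 0-based ROI index of maximal group-mean uptake
    coldspot: int
    hotspot_report: SeedReport
    coldspot_report: SeedReport
    distance_adjusted: bool = False


def _conn_values(conn) -> np.ndarray:
    return conn.values if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, dtype=float)


def _seed_slope(
    x: np.ndarray, y: np.ndarray, dist: np.ndarray | None
) -> float:
    """OLS slope of y on [1, x(, dist)] via normal equations."""
    cols = [np.ones_like(x), x]
    if dist is not None and dist.std() > 0:
        cols.append(dist)
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[1])


def seed_betas(
    conn: ConnectivityMatrix | np.ndarray,
    uptake: np.ndarray,
    distances: np.ndarray | None = None,
) -> np.ndarray:
    """Per-seed slope of target uptake on seed-target connectivity.

    For each seed s, OLS of ``uptake[targets]`` on ``conn[s, targets]``
    over the P-1 targets (plus the seed-target distance when given).
    Seeds whose connectivity row has zero variance get NaN and are logged.
    """
    mat = _conn_values(conn)
    uptake = np.asarray(uptake, dtype=float)
    P = mat.shape[0]
    if P < 4:
        raise SpreadError(f"need P >= 4 ROIs, got {P}")
    if uptake.shape != (P,) or not np.isfinite(uptake).all():
        raise SpreadError("uptake must be a finite length-P vector")
    betas = np.empty(P)
    for s in range(P):
        targets = np.arange(P) != s
        x = mat[s, targets]
        if x.std() == 0:
            logger.warning("seed %d: degenerate connectivity row, beta undefined", s + 1)
            betas[s] = np.nan
            continue
        d = distances[s, targets] if distances is not None else None
        betas[s] = _seed_slope(x, uptake[targets], d)
    return betas


def spread_correlation(uptake: np.ndarray, betas: np.ndarray) -> tuple[float, float]:
    """Pearson correlation across seeds of uptake vs spreading slope.

    Seeds with undefined (NaN) slopes are excluded pairwise.
    """
    uptake = np.asarray(uptake, dtype=float)
    betas = np.asarray(betas, dtype=float)
    ok = np.isfinite(betas)
    if ok.sum() < 3:
        raise SpreadError("fewer than 3 seeds with defined slopes")
    r, p = stats.pearsonr(uptake[ok], betas[ok])
    return float(r), float(p)


def hotspot_coldspot(uptake: np.ndarray) -> tuple[int, int]:
    """0-based indices of maximal and minimal group-mean uptake.

    Ties are broken toward the lowest ROI index, with a warning.
    """
    uptake = np.asarray(uptake, dtype=float)
    hot = int(np.argmax(uptake))
    cold = int(np.argmin(uptake))
    if (uptake == uptake[hot]).sum() > 1 or (uptake == uptake[cold]).sum() > 1:
        warnings.warn("tied uptake extrema; lowest ROI index chosen", stacklevel=2)
    return hot, cold


def seed_report(
    conn: ConnectivityMatrix | np.ndarray,
    uptake: np.ndarray,
    seed: int,
    distances: np.ndarray | None = None,
) -> SeedReport:
    """Slope, standardized slope, correlation and p for one named seed."""
    mat = _conn_values(conn)
    uptake = np.asarray(uptake, dtype=float)
    P = mat.shape[0]
    if not (0 <= seed < P):
        raise SpreadError(f"seed index {seed} out of range for P={P}")
    targets = np.arange(P) != seed
    x = mat[seed, targets]
    y = uptake[targets]
    if x.std() == 0:
        raise SpreadError(f"seed {seed + 1}: degenerate connectivity row")
    d = distances[seed, targets] if distances is not None else None
    beta = _seed_slope(x, y, d)
    beta_std = beta * x.std(ddof=1) / y.std(ddof=1) if y.std() > 0 else 0.0
    if y.std() == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(x, y)
    return SeedReport(seed=seed, beta=beta, beta_standardized=float(beta_std), r=float(r), p=float(p))


def seed_spread_analysis(
    conn: ConnectivityMatrix | np.ndarray,
    uptake: np.ndarray,
    distances: np.ndarray | None = None,
) -> SeedSpreadResult:
    """Full seed analysis: per-seed slopes, spread correlation, hot/cold rows."""
    uptake = np.asarray(uptake, dtype=float)
    betas = seed_betas(conn, uptake, distances=distances)
    r, p = spread_correlation(uptake, betas)
    hot, cold = hotspot_coldspot(uptake)
    if hot == cold and uptake.std() > 0:  # pragma: no cover - defensive
        raise SpreadError("hotspot equals coldspot for non-constant uptake")
    return SeedSpreadResult(
        betas=betas,
        global_r=r,
        global_p=p,
        hotspot=hot,
        coldspot=cold,
        hotspot_report=seed_report(conn, uptake, hot, distances=distances),
        coldspot_report=seed_report(conn, uptake, cold, distances=distances),
        distance_adjusted=distances is not None,
    )
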