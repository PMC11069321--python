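"""Synthetic cohort generator with analytic ground truth.

Emulates the statistical structure the pipeline is built to detect:

* a block-structured group connectome over the seven canonical networks
  (within-network correlation ``w_within``, between-network ``w_between``);
* per-subject BOLD-like time series drawn from that connectome;
* AD tau SUVR whose inter-subject covariance is coupled to connectivity with
  a single dial ``rho_tau`` (convex blend ``(1-rho)*I + rho*FC`` of the
  residual correlation), and whose mean profile peaks at a configurable
  epicenter (gain ``tau_amplitude`` along the epicenter's connectivity row);
* AD FDG SUVR generated with a known direct (tau -> FDG) and indirect
  (tau -> connectivity-borne mediator -> FDG) effect decomposition, so the
  true proportion mediated is ``a*b / (a*b + c_prime)``.

The mediator's systematic part is the connectivity-to-epicenter profile
(scaled by ``a * tau_amplitude``) and its subject-level noise shares the same
``rho_tau`` spatial blend as tau. That choice is what makes the downstream
mediation analyses — which use *measured* functional connectivity as the
mediator — identifiable: the connectome carries the mediator's systematic
part at the hotspot level, and the spatially structured mediator noise gives
FDG covariance a genuine connectivity channel at the edge level.

NC subjects get tau ~ 1 and fdg ~ 2 with unstructured noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from math import cos, pi, sin
from pathlib import Path

import numpy as np

from .atlas import NETWORKS, AtlasSpec, SubjectTable, TimeSeriesSet
import pandas as pd


class CohortConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass
class CohortConfig:
    """Generator configuration; defaults are the package's study conditions.

    Cohort sizes (22 NC / 57 AD) follow the clinical cohort the analysis
    design targets; P=40 parcels over K=7 networks and T=200 timepoints keep
    a full end-to-end run at desk scale while leaving every network with
    enough within-network edges.
    """

    P: int = 40
    K: int = 7
    n_nc: int = 22
    n_ad: int = 57
    T: int = 200
    w_within: float = 0.5
    w_between: float = 0.1
    rho_tau: float = 0.6
    epicenter: int = 0  # 0-based ROI index
    tau_amplitude: float = 0.75
    a: float = 0.8
    b: float = 0.5
    c_prime: float = 0.4
    sigma_tau: float = 0.2
    sigma_m: float = 0.2
    sigma_y: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.w_between < self.w_within < 1):
            raise CohortConfigError(
                "need 0 <= w_between < w_within < 1, got "
                f"w_between={self.w_between}, w_within={self.w_within}"
            )
        if not (0 <= self.rho_tau < 1):
            raise CohortConfigError(f"rho_tau must be in [0, 1), got {self.rho_tau}")
        if min(self.n_nc, self.n_ad) < 3:
            raise CohortConfigError("need at least 3 subjects per group")
        if not (2 <= self.K <= self.P):
            raise CohortConfigError(f"need 2 <= K <= P, got K={self.K}, P={self.P}")
        if not (0 <= self.epicenter < self.P):
            raise CohortConfigError(
                f"epicenter index {self.epicenter} out of range for P={self.P}"
            )
        if self.T < 3:
            raise CohortConfigError("need T >= 3 timepoints")
        for name in ("sigma_tau", "sigma_m", "sigma_y", "tau_amplitude"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be >= 0")

    @property
    def true_proportion_mediated(self) -> float:
        """Ground-truth proportion of the tau->FDG effect routed via the mediator."""
        denom = self.a * self.b + self.c_prime
        if denom == 0:
            raise CohortConfigError("a*b + c_prime = 0: proportion undefined")
        return self.a * self.b / denom

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


def network_sizes(P: int, K: int) -> list[int]:
    """Near-equal partition of P ROIs over K networks (first blocks larger)."""
    base, extra = divmod(P, K)
    return [base + (1 if k < extra else 0) for k in range(K)]


def network_labels(P: int, K: int) -> list[str]:
    """Per-ROI network labels, canonical order, contiguous blocks."""
    labels: list[str] = []
    for k, size in enumerate(network_sizes(P, K)):
        labels.extend([NETWORKS[k % len(NETWORKS)]] * size)
    return labels


def nearest_correlation(mat: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are floored at ``eig_floor`` and the result rescaled to unit
    diagonal. A no-op (up to symmetrization) for matrices already PD.
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() > eig_floor:
        return sym
    vals = np.clip(vals, eig_floor, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    if not np.isfinite(d).all() or (d <= 0).any():
        raise CohortConfigError("positive-definite projection diverged")
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def make_ground_truth_fc(config: CohortConfig) -> np.ndarray:
    """Block-structured ground-truth correlation matrix over the networks.

    Within-network off-diagonals sit at ``w_within``, between-network at
    ``w_between``, unit diagonal, projected to positive definite if needed.
    """
    P = config.P
    labels = network_labels(P, config.K)
    fc = np.full((P, P), config.w_between, dtype=float)
    for net in set(labels):
        idx = np.flatnonzero(np.asarray(labels) == net)
        fc[np.ix_(idx, idx)] = config.w_within
    np.fill_diagonal(fc, 1.0)
    fc = nearest_correlation(fc)
    if np.linalg.eigvalsh(fc).min() <= 1e-8:
        raise CohortConfigError("block values do not admit a PD correlation matrix")
    return fc


def make_synthetic_atlas(config: CohortConfig, rng: np.random.Generator | None = None) -> AtlasSpec:
    """Atlas with network clusters laid out on a ring, jittered centroids.

    Centroid geometry is independent of the uptake model, so the generator's
    regime is distance-free: distance adjustment should not change signs.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    labels = network_labels(config.P, config.K)
    centers = {
        NETWORKS[k % len(NETWORKS)]: np.array(
            [60.0 * cos(2 * pi * k / config.K), 60.0 * sin(2 * pi * k / config.K), 10.0 * k]
        )
        for k in range(config.K)
    }
    centroids = np.stack([centers[lab] for lab in labels]) + rng.normal(0.0, 8.0, (config.P, 3))
    return AtlasSpec(
        roi_id=np.arange(1, config.P + 1),
        roi_name=tuple(f"{lab}_{i + 1}" for i, lab in enumerate(labels)),
        network=tuple(labels),
        centroid=centroids,
    )


def simulate_timeseries(
    fc: np.ndarray,
    T: int,
    n: int,
    seed: int | np.random.Generator,
    prefix: str = "sub",
) -> TimeSeriesSet:
    """Draw ``n`` subjects' T x P series from N(0, fc).

    For large T the empirical correlation of each series converges to ``fc``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fc = np.asarray(fc, dtype=float)
    P = fc.shape[0]
    L = np.linalg.cholesky(nearest_correlation(fc))
    data = {}
    for i in range(n):
        data[f"{prefix}{i + 1:03d}"] = rng.standard_normal((T, P)) @ L.T
    return TimeSeriesSet(data)


def _structured_noise(
    rng: np.random.Generator, n: int, chol: np.ndarray, sigma: float
) -> np.ndarray:
    """n draws of a P-vector with covariance sigma^2 * chol @ chol.T."""
    return sigma * (rng.standard_normal((n, chol.shape[0])) @ chol.T)


def simulate_pet(
    fc: np.ndarray, config: CohortConfig, rng: np.random.Generator | None = None
) -> SubjectTable:
    """Generate tau and FDG SUVR for both groups with known ground truth.

    AD tau at ROI j for subject i::

        tau_ij = 1 + tau_amplitude * max(fc[epicenter, j], 0) + u_ij

    with across-subject residual correlation ``(1-rho_tau)*I + rho_tau*fc``
    (PD-projected) scaled by ``sigma_tau``. AD FDG::

        fdg_ij = 2 - c_prime * (tau_ij - 1) - b * m_ij + e_ij
        m_ij   = a * tau_amplitude * max(fc[epicenter, j], 0) + em_ij

    where ``em`` shares the tau residuals' spatial blend and ``e`` is iid.
    NC subjects: tau = 1 + noise, fdg = 2 + noise, unstructured.

    Demographics are drawn to resemble a memory-clinic cohort (NC younger
    than AD) but are independent of the PET model, so covariate adjustment
    is a no-op in expectation.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    fc = np.asarray(fc, dtype=float)
    P = fc.shape[0]
    if P != config.P:
        raise CohortConfigError(f"fc has P={P} but config.P={config.P}")
    if not (0 <= config.epicenter < P):
        raise CohortConfigError(f"epicenter {config.epicenter} out of range")

    f_epi = np.clip(fc[config.epicenter], 0.0, None)
    blend = nearest_correlation(
        (1.0 - config.rho_tau) * np.eye(P) + config.rho_tau * nearest_correlation(fc)
    )
    chol = np.linalg.cholesky(blend)

    # AD group
    u = _structured_noise(rng, config.n_ad, chol, config.sigma_tau)
    tau_ad = 1.0 + config.tau_amplitude * f_epi + u
    em = _structured_noise(rng, config.n_ad, chol, config.sigma_m)
    m = config.a * config.tau_amplitude * f_epi + em
    e = rng.normal(0.0, config.sigma_y, (config.n_ad, P))
    fdg_ad = 2.0 - config.c_prime * (tau_ad - 1.0) - config.b * m + e

    # NC group: flat profiles, unstructured noise
    tau_nc = 1.0 + rng.normal(0.0, config.sigma_tau, (config.n_nc, P))
    fdg_nc = 2.0 + rng.normal(0.0, config.sigma_y, (config.n_nc, P))

    # keep SUVR strictly positive (clip far in the noise tail)
    tau = np.clip(np.vstack([tau_nc, tau_ad]), 0.05, None)
    fdg = np.clip(np.vstack([fdg_nc, fdg_ad]), 0.05, None)

    n = config.n_nc + config.n_ad
    groups = ["NC"] * config.n_nc + ["AD"] * config.n_ad
    age = np.where(
        np.asarray(groups) == "NC",
        rng.normal(55.7, 8.8, n),
        rng.normal(64.9, 10.0, n),
    ).round(1)
    sex = np.where(rng.random(n) < 0.33, "M", "F")
    education = np.clip(rng.normal(10.0, 4.0, n), 0, None).round(1)
    subject_ids = [f"nc{i + 1:03d}" for i in range(config.n_nc)] + [
        f"ad{i + 1:03d}" for i in range(config.n_ad)
    ]
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": groups,
            "age": age,
            "sex": sex,
            "education": education,
        }
    )
    return SubjectTable(subjects=subjects, tau=tau, fdg=fdg)


def simulate_mediation_triplet(
    a: float,
    b: float,
    c_prime: float,
    n: int,
    sigma_m: float = 1.0,
    sigma_y: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-test bed for the three-equation mediation model.

    X ~ N(0,1); M = a*X + noise(sigma_m); Y = c_prime*X + b*M + noise(sigma_y).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + sigma_m * rng.standard_normal(n)
    y = c_prime * x + b * m + sigma_y * rng.standard_normal(n)
    return x, m, y


@dataclass
class CohortData:
    """One simulated cohort: atlas, ground truth, time series and PET."""

    config: CohortConfig
    atlas: AtlasSpec
    fc_true: np.ndarray
    timeseries_nc: TimeSeriesSet
    timeseries_ad: TimeSeriesSet
    subjects: SubjectTable

    @property
    def timeseries(self) -> TimeSeriesSet:
        """All subjects' series in subject-table order (NC then AD)."""
        data = dict(self.timeseries_nc.data)
        data.update(self.timeseries_ad.data)
        return TimeSeriesSet(data)


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Generate a full cohort deterministically from ``config.seed``."""
    fc = make_ground_truth_fc(config)
    atlas = make_synthetic_atlas(config)
    ts_nc = simulate_timeseries(
        fc, config.T, config.n_nc,
        np.random.default_rng(np.random.SeedSequence([config.seed, 303])),
        prefix="nc",
    )
    ts_ad = simulate_timeseries(
        fc, config.T, config.n_ad,
        np.random.default_rng(np.random.SeedSequence([config.seed, 404])),
        prefix="ad",
    )
    subjects = simulate_pet(fc, config)
    return CohortData(
        config=config,
        atlas=atlas,
        fc_true=fc,
        timeseries_nc=ts_nc,
        timeseries_ad=ts_ad,
        subjects=subjects,
    )


def write_cohort(cohort: CohortData, outdir: str | Path) -> None:
    """Write atlas/subjects/time-series TSVs plus a ground-truth JSON."""
    import json

    from .atlas import write_atlas, write_matrix, write_subject_table, write_timeseries

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.atlas, outdir / "atlas.tsv")
    write_subject_table(cohort.subjects, outdir / "subjects.tsv")
    write_timeseries(cohort.timeseries, outdir / "timeseries")
    write_matrix(cohort.fc_true, outdir / "fc_true.tsv")
    truth = {
        "true_proportion_mediated": cohort.config.true_proportion_mediated,
        "rho_tau": cohort.config.rho_tau,
        "epicenter_roi_id": cohort.config.epicenter + 1,
        "config": dataclasses.asdict(cohort.config),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
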