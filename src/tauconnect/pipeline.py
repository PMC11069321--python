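"""End-to-end analysis runner.

Ties the stages into one reproducible graph: group statistics; NC and AD
functional connectivity; AD tau and FDG covariance (raw and covariate-
adjusted); the three global edge associations (FC~tau-cov, FC~fdg-cov,
tau-cov~fdg-cov) with permutation nulls, network breakdowns and distance
adjustment; the three seed-spread analyses (FC x tau, FDG-cov x tau,
FC x FDG) with hotspot/coldspot rows; and the edge-level and hotspot-level
mediations. Associations and covariances are computed on the AD group (the
group carrying pathology); NC matrices are still emitted.

Every stochastic stage draws from a seed derived from the config, echoed
into the report, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import association, group_stats, mediation, spreading
from .atlas import AtlasSpec, SubjectTable, pairwise_distances, write_matrix
from .cohort import CohortConfig, CohortData, simulate_cohort
from .connectivity import (
    ConnectivityMatrix,
    group_functional_connectivity,
    pet_covariance,
)

logger = logging.getLogger(__name__)

COVARIATES = ("age", "sex", "education")


@dataclass
class RunConfig:
    """Configuration for a full analysis run on a synthetic cohort."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_perm: int = 500
    n_boot: int = 1000
    scheme: str = "node_relabel"
    tail: str = "greater"
    distance_adjust: bool = True
    covariate_adjust: bool = False

    @property
    def analysis_seed(self) -> int:
        # derived from the cohort seed; kept below 2**31
        return (self.cohort.seed * 1009 + 7) % (2**31)


def _assoc_dict(res: association.EdgeAssociationResult) -> dict:
    out = {
        "beta": res.beta,
        "intercept": res.intercept,
        "pearson_r": res.pearson_r,
        "p_parametric": res.p_parametric,
        "n_edges": res.n_edges,
        "scope": res.scope,
        "distance_adjusted": res.distance_adjusted,
    }
    if res.null_betas is not None:
        out.update(
            p_exact=res.p_exact, null_mean=res.null_mean, null_sd=res.null_sd
        )
    return out


def _network_dict(results: dict) -> dict:
    out = {}
    for net, res in results.items():
        if isinstance(res, association.SkippedNetwork):
            out[net] = {"skipped": True, "reason": res.reason}
        else:
            out[net] = _assoc_dict(res)
    return out


def _mediation_dict(res: mediation.MediationResult) -> dict:
    return {
        "a": res.a,
        "b": res.b,
        "c_total": res.c_total,
        "c_prime": res.c_prime,
        "indirect": res.indirect,
        "proportion": res.proportion,
        "proportion_unstable": res.proportion_unstable,
        "ci_indirect": list(res.ci_indirect),
        "ci_proportion": None if res.ci_proportion is None else list(res.ci_proportion),
        "p_indirect": res.p_indirect,
        "criteria": res.criteria,
        "n_units": res.n_units,
        "n_boot": res.n_boot,
        "covariates": list(res.covariates),
    }


def _spread_dict(res: spreading.SeedSpreadResult) -> dict:
    def rep(r: spreading.SeedReport) -> dict:
        return {
            "seed_roi_id": r.seed + 1,
            "beta": r.beta,
            "beta_standardized": r.beta_standardized,
            "r": r.r,
            "p": r.p,
        }

    return {
        "global_r": res.global_r,
        "global_p": res.global_p,
        "hotspot_roi_id": res.hotspot + 1,
        "coldspot_roi_id": res.coldspot + 1,
        "hotspot": rep(res.hotspot_report),
        "coldspot": rep(res.coldspot_report),
        "distance_adjusted": res.distance_adjusted,
    }


def run_full_analysis(
    config: RunConfig,
    outdir: str | Path | None = None,
    cohort: CohortData | None = None,
) -> dict:
    """Run every stage on a (simulated or supplied) cohort; return the report.

    When ``outdir`` is given, matrices are written as TSV and the summary as
    ``report.json``.
    """
    if cohort is None:
        logger.info("simulating cohort with seed %d", config.cohort.seed)
        cohort = simulate_cohort(config.cohort)
    atlas = cohort.atlas
    table = cohort.subjects
    distances = pairwise_distances(atlas) if config.distance_adjust else None

    report: dict = {
        "config": {
            "cohort": dataclasses.asdict(config.cohort),
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "scheme": config.scheme,
            "tail": config.tail,
            "distance_adjust": config.distance_adjust,
            "covariate_adjust": config.covariate_adjust,
            "analysis_seed": config.analysis_seed,
        }
    }

    # --- group statistics -------------------------------------------------
    nc = table.group_index("NC")
    ad = table.group_index("AD")
    age_cmp = group_stats.two_sample_t(
        table.subjects.loc[nc, "age"].to_numpy(dtype=float),
        table.subjects.loc[ad, "age"].to_numpy(dtype=float),
        variable="age",
    )
    edu_cmp = group_stats.two_sample_t(
        table.subjects.loc[nc, "education"].to_numpy(dtype=float),
        table.subjects.loc[ad, "education"].to_numpy(dtype=float),
        variable="education",
    )
    sex_counts = [
        int(((table.subjects["group"] == g) & (table.subjects["sex"] == s)).sum())
        for g in ("NC", "AD")
        for s in ("M", "F")
    ]
    sex_cmp = group_stats.chi_square_2x2(*sex_counts, variable="sex")
    tau_means, tau_tests = group_stats.network_uptake(table, atlas, "tau")
    fdg_means, fdg_tests = group_stats.network_uptake(table, atlas, "fdg")
    report["group_stats"] = {
        "age": dataclasses.asdict(age_cmp),
        "education": dataclasses.asdict(edu_cmp),
        "sex": dataclasses.asdict(sex_cmp),
        "network_uptake_tau": tau_tests.reset_index().to_dict(orient="records"),
        "network_uptake_fdg": fdg_tests.reset_index().to_dict(orient="records"),
    }

    # --- connectivity & covariance matrices -------------------------------
    logger.info("computing group FC and AD PET covariance matrices")
    fc_nc = group_functional_connectivity(cohort.timeseries_nc, group="NC")
    fc_ad = group_functional_connectivity(cohort.timeseries_ad, group="AD")
    covariates = COVARIATES if config.covariate_adjust else None
    tau_cov = pet_covariance(table, "AD", "tau", covariates=covariates)
    fdg_cov = pet_covariance(table, "AD", "fdg", covariates=covariates)
    matrices = {
        "fc_nc": fc_nc,
        "fc_ad": fc_ad,
        "tau_cov_ad": tau_cov,
        "fdg_cov_ad": fdg_cov,
    }
    report["matrices"] = {
        name: {
            "kind": m.kind,
            "group": m.group,
            "n_subjects": m.n_subjects,
            "adjusted_for": list(m.adjusted_for),
        }
        for name, m in matrices.items()
    }

    # --- edge associations -------------------------------------------------
    logger.info("edge associations (%d permutations, %s)", config.n_perm, config.scheme)
    pairs = {
        "fc_vs_tau_cov": (fc_ad, tau_cov),
        "fc_vs_fdg_cov": (fc_ad, fdg_cov),
        "tau_cov_vs_fdg_cov": (tau_cov, fdg_cov),
    }
    assoc_report = {}
    rng = np.random.default_rng(config.analysis_seed)
    for name, (xm, ym) in pairs.items():
        res = association.permutation_null(
            xm,
            ym,
            n_perm=config.n_perm,
            scheme=config.scheme,
            seed=rng,
            tail=config.tail,
        )
        entry = {"global": _assoc_dict(res)}
        entry["networks"] = _network_dict(association.network_specific(xm, ym, atlas))
        if config.distance_adjust:
            entry["distance_adjusted"] = _assoc_dict(
                association.distance_adjusted(xm, ym, atlas)
            )
        assoc_report[name] = entry
    report["edge_associations"] = assoc_report

    # --- seed spreading ----------------------------------------------------
    logger.info("seed-spread analyses")
    tau_mean_ad = table.group_suvr("AD", "tau").mean(axis=0)
    fdg_mean_ad = table.group_suvr("AD", "fdg").mean(axis=0)
    spreads = {
        "fc_x_tau": spreading.seed_spread_analysis(fc_ad, tau_mean_ad, distances=distances),
        "fdg_cov_x_tau": spreading.seed_spread_analysis(fdg_cov, tau_mean_ad, distances=distances),
        "fc_x_fdg": spreading.seed_spread_analysis(fc_ad, fdg_mean_ad, distances=distances),
    }
    report["seed_spread"] = {k: _spread_dict(v) for k, v in spreads.items()}

    # --- mediation ----------------------------------------------------------
    logger.info("mediation analyses (B=%d)", config.n_boot)
    med_edge = mediation.edge_mediation(
        tau_cov, fc_ad, fdg_cov, n_boot=config.n_boot, seed=config.analysis_seed
    )
    fdg_z = mediation.fdg_zscores(table)
    med_hot = mediation.hotspot_mediation(
        tau_mean_ad,
        fc_ad,
        fdg_z,
        n_boot=config.n_boot,
        seed=config.analysis_seed + 1,
    )
    report["mediation"] = {
        "edge_level": _mediation_dict(med_edge),
        "hotspot_level": _mediation_dict(med_hot),
        "fdg_zscore_min": float(fdg_z.min()),
        "fdg_zscore_argmin_roi_id": int(np.argmin(fdg_z)) + 1,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, m in matrices.items():
            write_matrix(m.values, outdir / f"{name}.tsv")
        (outdir / "report.json").write_text(report_json(report))
        logger.info("report written to %s", outdir / "report.json")
    return report


def report_json(report: dict) -> str:
    """Deterministic JSON serialization of a report (sorted keys)."""

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    return json.dumps(report, indent=2, sort_keys=True, default=default)
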