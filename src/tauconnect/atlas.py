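"""Tabular I/O and atlas-derived structures.

Everything downstream works at the parcel level: an atlas table defines the
ROI order, network membership (the seven canonical cortical systems) and MNI
centroid coordinates; subjects carry per-ROI tau and FDG SUVR vectors plus
covariates; resting-state data arrive as per-subject T x P time-series tables.

All on-disk formats are tab-separated text with header rows so that fixtures
are human-inspectable and diff-able. ROI order everywhere is the atlas file
row order (0-based internally, 1-based ``roi_id`` externally).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

#: The seven canonical cortical networks used to partition parcels.
NETWORKS = ("DAN", "DMN", "FPCN", "Motor", "VAN", "Vis", "Limbic")

#: Sex string -> numeric covariate coding (F=0, M=1).
SEX_CODES = {"F": 0, "M": 1}

GROUPS = ("NC", "AD")


class AtlasError(ValueError):
    """Raised for malformed atlas or subject tables."""


@dataclass(frozen=True)
class AtlasSpec:
    """Parcellation metadata: ROI identities, network labels, centroids.

    Parameters
    ----------
    roi_id
        1-based contiguous integer identifiers, in file row order.
    roi_name
        Human-readable parcel names.
    network
        One of :data:`NETWORKS` per ROI.
    centroid
        ``(P, 3)`` array of MNI x/y/z centroid coordinates in mm.
    """

    roi_id: np.ndarray
    roi_name: tuple[str, ...]
    network: tuple[str, ...]
    centroid: np.ndarray

    def __post_init__(self) -> None:
        roi_id = np.asarray(self.roi_id, dtype=int)
        centroid = np.asarray(self.centroid, dtype=float)
        object.__setattr__(self, "roi_id", roi_id)
        object.__setattr__(self, "centroid", centroid)
        P = roi_id.size
        if P < 2:
            raise AtlasError(f"atlas needs at least 2 ROIs, got {P}")
        uniq, counts = np.unique(roi_id, return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1]
            raise AtlasError(f"duplicate roi_id values: {dup.tolist()}")
        if not np.array_equal(np.sort(roi_id), np.arange(1, P + 1)):
            raise AtlasError("roi_id must be contiguous integers 1..P")
        bad = sorted(set(self.network) - set(NETWORKS))
        if bad:
            raise AtlasError(
                f"unknown network labels {bad}; expected one of {NETWORKS}"
            )
        if centroid.shape != (P, 3) or not np.isfinite(centroid).all():
            raise AtlasError("centroid must be a finite (P, 3) array")

    @property
    def P(self) -> int:
        return int(self.roi_id.size)

    @property
    def networks_present(self) -> tuple[str, ...]:
        """Networks that actually occur, in canonical order."""
        present = set(self.network)
        return tuple(n for n in NETWORKS if n in present)

    def network_mask(self, network: str) -> np.ndarray:
        """Boolean mask over ROIs belonging to ``network``."""
        if network not in NETWORKS:
            raise AtlasError(f"unknown network {network!r}")
        return np.asarray([n == network for n in self.network], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_id,
                "roi_name": list(self.roi_name),
                "network": list(self.network),
                "x": self.centroid[:, 0],
                "y": self.centroid[:, 1],
                "z": self.centroid[:, 2],
            }
        )


@dataclass
class TimeSeriesSet:
    """Per-subject resting-state time series, ``subject_id -> (T, P)``."""

    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        Ps = {arr.shape[1] for arr in self.data.values()}
        if len(Ps) > 1:
            raise AtlasError(f"subjects disagree on ROI count: {sorted(Ps)}")
        for sid, arr in self.data.items():
            if arr.ndim != 2 or arr.shape[0] < 3:
                raise AtlasError(f"subject {sid}: need a (T>=3, P) series")
            if not np.isfinite(arr).all():
                raise AtlasError(f"subject {sid}: non-finite time-series values")

    @property
    def P(self) -> int:
        return next(iter(self.data.values())).shape[1]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, subject_id: str) -> np.ndarray:
        return self.data[subject_id]


@dataclass
class SubjectTable:
    """Cohort table: group labels, covariates and per-ROI SUVR vectors.

    ``tau`` and ``fdg`` are ``(n_subjects, P)`` arrays aligned with
    ``subjects`` row order and the atlas ROI order.
    """

    subjects: pd.DataFrame  # subject_id, group, age, sex, education
    tau: np.ndarray
    fdg: np.ndarray

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "age", "sex", "education"}
        missing = required - set(self.subjects.columns)
        if missing:
            raise AtlasError(f"subject table missing columns: {sorted(missing)}")
        bad_groups = set(self.subjects["group"]) - set(GROUPS)
        if bad_groups:
            raise AtlasError(f"unknown group labels: {sorted(bad_groups)}")
        self.tau = np.asarray(self.tau, dtype=float)
        self.fdg = np.asarray(self.fdg, dtype=float)
        n = len(self.subjects)
        if self.tau.shape[0] != n or self.fdg.shape[0] != n:
            raise AtlasError("SUVR arrays must have one row per subject")
        if self.tau.shape != self.fdg.shape:
            raise AtlasError("tau and fdg SUVR arrays must share shape")
        for name, arr in (("tau", self.tau), ("fdg", self.fdg)):
            if not np.isfinite(arr).all() or (arr <= 0).any():
                raise AtlasError(f"{name} SUVR values must be finite and > 0")

    @property
    def P(self) -> int:
        return int(self.tau.shape[1])

    def group_index(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise AtlasError(f"unknown group {group!r}")
        return np.asarray(self.subjects["group"] == group)

    def group_suvr(self, group: str, modality: str) -> np.ndarray:
        """SUVR matrix (n_group, P) for one group and modality."""
        if modality not in ("tau", "fdg"):
            raise AtlasError(f"modality must be 'tau' or 'fdg', got {modality!r}")
        arr = self.tau if modality == "tau" else self.fdg
        return arr[self.group_index(group)]

    def covariate_matrix(
        self, group: str, covariates: Sequence[str]
    ) -> np.ndarray:
        """Numeric covariate columns for one group (sex coded F=0, M=1).

        Raises if any requested covariate is missing for a subject — adjusted
        analyses require complete covariates.
        """
        sub = self.subjects.loc[self.group_index(group)]
        cols = []
        for cov in covariates:
            if cov not in sub.columns:
                raise AtlasError(f"unknown covariate {cov!r}")
            col = sub[cov]
            if cov == "sex":
                bad = set(col.dropna()) - set(SEX_CODES)
                if bad:
                    raise AtlasError(f"sex must be M/F, got {sorted(bad)}")
                col = col.map(SEX_CODES)
            col = pd.to_numeric(col, errors="coerce")
            if col.isna().any():
                who = sub.loc[col.isna(), "subject_id"].tolist()
                raise AtlasError(
                    f"covariate {cov!r} missing for subjects {who}; "
                    "covariate-adjusted analysis needs complete covariates"
                )
            cols.append(col.to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(sub), 0))


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

_ATLAS_COLUMNS = ("roi_id", "roi_name", "network", "x", "y", "z")


def load_atlas(path: str | Path) -> AtlasSpec:
    """Read an atlas TSV (columns roi_id, roi_name, network, x, y, z)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_ATLAS_COLUMNS) - set(df.columns)
    if missing:
        raise AtlasError(f"atlas file {path}: missing columns {sorted(missing)}")
    for col in ("x", "y", "z"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise AtlasError(
                f"atlas file {path}: non-numeric coordinate in column {col}: {exc}"
            ) from exc
    try:
        roi_id = df["roi_id"].astype(int).to_numpy()
    except (ValueError, TypeError) as exc:
        raise AtlasError(f"atlas file {path}: non-integer roi_id: {exc}") from exc
    return AtlasSpec(
        roi_id=roi_id,
        roi_name=tuple(str(v) for v in df["roi_name"]),
        network=tuple(str(v) for v in df["network"]),
        centroid=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_atlas(atlas: AtlasSpec, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def pairwise_distances(atlas: AtlasSpec) -> np.ndarray:
    """Euclidean distance (mm) between every pair of ROI centroids.

    Symmetric with zero diagonal; used as the spatial covariate in the
    distance-adjusted association analyses.
    """
    return squareform(pdist(atlas.centroid, metric="euclidean"))


def _suvr_columns(df: pd.DataFrame, prefix: str) -> list[str]:
    pat = re.compile(rf"^{prefix}_(\d+)$")
    cols = [(int(m.group(1)), c) for c in df.columns if (m := pat.match(c))]
    cols.sort()
    ids = [i for i, _ in cols]
    if ids != list(range(1, len(ids) + 1)):
        raise AtlasError(f"{prefix}_* columns must be contiguous {prefix}_1..{prefix}_P")
    return [c for _, c in cols]


def load_subject_table(
    path: str | Path,
    atlas: AtlasSpec | None = None,
    require_covariates: Sequence[str] = (),
) -> SubjectTable:
    """Read a subject TSV with columns subject_id, group, age, sex, education,
    tau_1..tau_P, fdg_1..fdg_P.

    ``require_covariates`` triggers an immediate completeness check for the
    named covariates (use when a covariate-adjusted analysis is planned).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    tau_cols = _suvr_columns(df, "tau")
    fdg_cols = _suvr_columns(df, "fdg")
    if len(tau_cols) != len(fdg_cols):
        raise AtlasError(f"{path}: tau and fdg column counts differ")
    if atlas is not None and len(tau_cols) != atlas.P:
        raise AtlasError(
            f"{path}: {len(tau_cols)} SUVR columns but atlas has P={atlas.P} ROIs"
        )
    table = SubjectTable(
        subjects=df[["subject_id", "group", "age", "sex", "education"]].copy(),
        tau=df[tau_cols].to_numpy(dtype=float),
        fdg=df[fdg_cols].to_numpy(dtype=float),
    )
    for group in GROUPS:
        if table.group_index(group).any() and require_covariates:
            table.covariate_matrix(group, require_covariates)
    return table


def write_subject_table(table: SubjectTable, path: str | Path) -> None:
    df = table.subjects.copy()
    P = table.P
    for j in range(P):
        df[f"tau_{j + 1}"] = table.tau[:, j]
    for j in range(P):
        df[f"fdg_{j + 1}"] = table.fdg[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_timeseries(directory: str | Path, atlas: AtlasSpec | None = None) -> TimeSeriesSet:
    """Read all ``*.tsv`` files in ``directory`` as subject time series.

    The file stem is the subject id; each file is T rows x P columns with a
    header row of roi ids.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.tsv"))
    if not files:
        raise AtlasError(f"no .tsv time-series files found in {directory}")
    data: dict[str, np.ndarray] = {}
    for f in files:
        arr = pd.read_csv(f, sep="\t", float_precision="round_trip").to_numpy(dtype=float)
        if atlas is not None and arr.shape[1] != atlas.P:
            raise AtlasError(
                f"{f}: {arr.shape[1]} ROI columns but atlas has P={atlas.P}"
            )
        data[f.stem] = arr
    return TimeSeriesSet(data)


def write_timeseries(ts: TimeSeriesSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    P = ts.P
    header = [str(j + 1) for j in range(P)]
    for sid, arr in ts.data.items():
        pd.DataFrame(arr, columns=header).to_csv(
            directory / f"{sid}.tsv", sep="\t", index=False, float_format="%.17g"
        )


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a dense P x P matrix as TSV with a 1-based roi_id header/index.

    Floats are written with 17 significant digits so read(write(x)) == x.
    """
    matrix = np.asarray(matrix, dtype=float)
    ids = [str(j + 1) for j in range(matrix.shape[1])]
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="roi_id", float_format="%.17g"
    )


def read_matrix(path: str | Path, expected_P: int | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col="roi_id", float_precision="round_trip")
    mat = df.to_numpy(dtype=float)
    if expected_P is not None and mat.shape != (expected_P, expected_P):
        raise AtlasError(
            f"{path}: matrix shape {mat.shape}, expected ({expected_P}, {expected_P})"
        )
    return mat
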