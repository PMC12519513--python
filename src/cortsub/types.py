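"""Core domain containers shared across the pipeline.

The pipeline operates on a handful of plain containers: a parcellation
(ROI names, network labels, centroid geometry), a long-format regional
thickness table with covariates, weighted connectivity templates, the
fitted subtype model, per-ROI longitudinal thinning maps, and results of
spatial permutation tests.  All containers are thin dataclasses around
numpy arrays / pandas frames so they serialize to delimited text and JSON
without ceremony.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

#: canonical resting-state network names used for ROI annotation
CANONICAL_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Frontoparietal",
    "Default",
)

#: metadata columns of a long-format thickness table; ROI columns follow
THICKNESS_META_COLUMNS = (
    "subject_id",
    "visit_index",
    "time_years",
    "age_baseline",
    "sex",
    "centiloid",
    "apoe4",
    "site",
)


class CortsubError(Exception):
    """Base class for user-facing errors."""


class InvalidArgumentError(CortsubError, ValueError):
    """An argument violates a documented precondition."""


class InvalidInputError(CortsubError, ValueError):
    """Input data violates a documented invariant."""


@dataclass
class Parcellation:
    """Cortical parcellation: ROI identities, network labels and centroids.

    roi_ids are the contiguous integers 0..R-1; centroids are 3-vectors in
    millimetres.  ``distances`` is the full symmetric Euclidean distance
    matrix, computed once at construction.
    """

    roi_names: list[str]
    network_labels: list[str]
    centroids: np.ndarray  # R x 3, mm
    distances: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 3:
            raise InvalidArgumentError("centroids must be an R x 3 array")
        if not np.isfinite(self.centroids).all():
            raise InvalidInputError("centroids contain non-finite values")
        if len(self.roi_names) != len(self.network_labels) or len(
            self.roi_names
        ) != self.centroids.shape[0]:
            raise InvalidArgumentError(
                "roi_names, network_labels and centroids disagree on R"
            )
        self.distances = squareform(pdist(self.centroids))

    @property
    def n_rois(self) -> int:
        return self.centroids.shape[0]

    @property
    def roi_ids(self) -> np.ndarray:
        return np.arange(self.n_rois)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "roi_name": self.roi_names,
                "network_label": self.network_labels,
                "x_mm": self.centroids[:, 0],
                "y_mm": self.centroids[:, 1],
                "z_mm": self.centroids[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        df = df.sort_values("roi_id").reset_index(drop=True)
        ids = df["roi_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(df))):
            raise InvalidInputError("roi_id must be 0..R-1 with no gaps")
        return cls(
            roi_names=df["roi_name"].astype(str).tolist(),
            network_labels=df["network_label"].astype(str).tolist(),
            centroids=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        )


@dataclass
class ConnectivityTemplate:
    """Weighted symmetric ROI graph with a modality tag.

    ``weights`` is R x R, symmetric, nonnegative, zero diagonal;
    ``distances`` the inter-centroid Euclidean distances in mm.
    """

    weights: np.ndarray
    modality: str
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        w, d = self.weights, self.distances
        if w.shape != d.shape or w.shape[0] != w.shape[1]:
            raise InvalidArgumentError("weights/distances must be square and aligned")
        if not np.allclose(w, w.T, atol=1e-9):
            raise InvalidInputError("connectivity weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise InvalidInputError("connectivity diagonal must be exactly zero")
        if not np.isfinite(w).all() or (w < 0).any():
            raise InvalidInputError("connectivity weights must be finite and >= 0")

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]

    @property
    def strength(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class RegionalThicknessTable:
    """Long-format subjects x visits table with one column per ROI.

    ``data`` holds the metadata columns of :data:`THICKNESS_META_COLUMNS`
    followed by ROI thickness columns named ``roi_<id>`` (mm).  Extra
    outcome columns (e.g. a cognitive score) are carried through untouched.
    """

    data: pd.DataFrame
    roi_columns: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in THICKNESS_META_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"thickness table missing columns: {missing}")
        missing_roi = [c for c in self.roi_columns if c not in self.data.columns]
        if missing_roi:
            raise InvalidInputError(f"thickness table missing ROI columns: {missing_roi}")
        th = self.data[self.roi_columns].to_numpy(float)
        if (th <= 0).any():
            s, r = np.argwhere(th <= 0)[0]
            raise InvalidInputError(
                f"nonpositive thickness at row {s}, column {self.roi_columns[r]}"
            )
        dup = self.data.duplicated(subset=["subject_id", "visit_index"])
        if dup.any():
            key = self.data.loc[dup.idxmax(), ["subject_id", "visit_index"]]
            raise InvalidInputError(
                f"duplicate (subject, visit) row: {tuple(key)}"
            )
        baseline_ok = (
            self.data.groupby("subject_id")["time_years"].min().eq(0.0)
        )
        if not baseline_ok.all():
            bad = baseline_ok.index[~baseline_ok].tolist()
            raise InvalidInputError(
                f"subjects without a time_years=0 baseline visit: {bad}"
            )

    @property
    def n_rois(self) -> int:
        return len(self.roi_columns)

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    def baseline(self) -> pd.DataFrame:
        """One row per subject at time_years == 0."""
        base = self.data[self.data["time_years"] == 0.0]
        return base.sort_values("subject_id").reset_index(drop=True)

    def baseline_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(S x R baseline thickness, subject ids in matching order)."""
        base = self.baseline()
        return base[self.roi_columns].to_numpy(float), base["subject_id"].to_numpy()

    def latest_followup(self) -> pd.DataFrame:
        """One row per subject: the visit with maximal time_years > 0.

        Subjects with baseline only are dropped.
        """
        longi = self.data[self.data["time_years"] > 0.0]
        idx = longi.groupby("subject_id")["time_years"].idxmax()
        return self.data.loc[idx].sort_values("subject_id").reset_index(drop=True)


@dataclass
class SubtypeModel:
    """Fitted NMF subtype model.

    W (S x k) holds subject scores, H (k x R) regional subtype profiles.
    ``inversion_offsets`` stores the per-ROI max-plus-margin constants used
    to invert thickness, so follow-up scans can be mapped into the same
    space.  Assignments are 1-based subtype labels.
    """

    k: int
    W: np.ndarray
    H: np.ndarray
    rss: float
    subject_ids: np.ndarray
    subject_assignment: np.ndarray
    subject_probability: np.ndarray
    region_assignment: np.ndarray
    consensus: np.ndarray
    inversion_offsets: np.ndarray | None = None
    unassignable: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.W < 0).any() or (self.H < 0).any():
            raise InvalidInputError("factor matrices must be nonnegative")


@dataclass
class RankSelectionReport:
    """Fit statistics per candidate rank and the selected rank."""

    k_values: list[int]
    cophenetic: dict[int, float]
    silhouette: dict[int, float]
    rss: dict[int, float]
    delta_rss: dict[int, float]
    selected_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "cophenetic": [self.cophenetic[k] for k in self.k_values],
                "silhouette": [self.silhouette[k] for k in self.k_values],
                "rss": [self.rss[k] for k in self.k_values],
                "delta_rss": [self.delta_rss[k] for k in self.k_values],
            }
        )


@dataclass
class BetaMap:
    """Per-ROI within-subtype marginal time slopes (mm/year) with SEs."""

    subtype_label: int
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.se = np.asarray(self.se, float)
        self.p = np.asarray(self.p, float)
        defined = np.isfinite(self.beta)
        if (self.se[defined] <= 0).any():
            raise InvalidInputError("standard errors must be positive where beta is defined")


@dataclass
class StabilityResult:
    """Baseline vs follow-up subtype agreement and its predictors."""

    subject_ids: np.ndarray
    baseline_labels: np.ndarray
    followup_labels: np.ndarray
    stable_flag: np.ndarray
    alpha: float
    n_unstable: int
    logistic_table: pd.DataFrame | None = None


@dataclass
class SpatialTestResult:
    """Observed spatial correlation with rewired and autocorrelation nulls."""

    observed_r: float
    null_r_rewired: np.ndarray
    null_r_autocorr: np.ndarray
    p_rewired: float
    p_autocorr: float
    n_perm: int
    modality: str
    subtype_label: int


@dataclass
class ExpressionMatrix:
    """R x G per-gene z-scored regional expression."""

    expr: np.ndarray
    gene_symbols: list[str]
    gene_source: list[str]

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, float)
        if self.expr.ndim != 2 or self.expr.shape[1] != len(self.gene_symbols):
            raise InvalidArgumentError("expr must be R x G matching gene_symbols")
        if len(self.gene_source) != len(self.gene_symbols):
            raise InvalidArgumentError("gene_source must match gene_symbols")
        if not np.isfinite(self.expr).all():
            raise InvalidInputError("expression contains missing values")

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expr, columns=self.gene_symbols)
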