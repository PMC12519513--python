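"""Synthetic cohort generator.

Emulates the data structure of a multi-site amyloid-PET/MRI aging cohort:
a spherical-shell parcellation with canonical-network annotations, three
distance-dependent connectivity templates, a longitudinal regional
cortical-thickness table with two planted regional-vulnerability subtypes,
subtype-specific thinning partially propagated along a connectome, and
regional gene-expression maps with controlled spatial autocorrelation.

Every generator is a pure function of its arguments and seed, so the
entire downstream pipeline is testable without any data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .types import (
    CANONICAL_NETWORKS,
    BetaMap,
    ConnectivityTemplate,
    ExpressionMatrix,
    InvalidArgumentError,
    Parcellation,
    RegionalThicknessTable,
)

#: networks whose ROIs form the limbic-predominant vulnerability set
LIMBIC_LIKE_NETWORKS = ("Limbic", "Default")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a two-subtype cohort with a clearly separated
    baseline vulnerability pattern (0.35 mm mean reduction on the
    vulnerable ROI set against 0.05 mm measurement noise), subtype 1 older
    and more amyloid/APOE-e4 enriched, and subtype-specific thinning rates
    on the order of tens of microns per year.

    thinning_rates holds one (vulnerable-set slope, background slope) pair
    per subtype in mm/year; negative values mean thinning.
    network_coupling is the fraction of the thinning-rate pattern
    propagated along the connectome (0 = purely regional, 1 = fully
    neighbour-driven).
    """

    n_subjects: int = 400
    n_rois: int = 100
    k_true: int = 2
    subtype_profile_effect: float = 0.35  # mm
    visit_schedule: tuple[float, ...] = (0.0, 1.5, 3.0)
    thinning_rates: tuple[tuple[float, float], ...] = (
        (-0.030, -0.008),
        (-0.015, -0.004),
    )
    network_coupling: float = 0.3
    rate_heterogeneity: float = 0.5  # half-width of per-ROI rate multiplier
    noise_sd: float = 0.05  # mm, per visit
    intercept_sd: float = 0.08  # mm, persistent per-subject offset
    age_slope: float = 0.005  # mm thinning per year of baseline age
    sex_offset: float = 0.03  # mm, M minus F global offset
    age_means: tuple[float, ...] = (68.0, 63.0)
    age_sd: float = 6.0
    centiloid_means: tuple[float, ...] = (45.0, 15.0)
    centiloid_sd: float = 25.0
    centiloid_rates: tuple[float, ...] = (3.0, 1.5)  # CL / year
    apoe4_probs: tuple[float, ...] = (0.45, 0.25)
    memory_slopes: tuple[float, ...] = (-0.08, -0.02)  # z-score / year
    subtype_fractions: tuple[float, ...] = (0.5, 0.5)
    n_sites: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_rois <= 0 or self.k_true <= 0:
            raise InvalidArgumentError("counts must be positive")
        if not 0.0 <= self.network_coupling <= 1.0:
            raise InvalidArgumentError("network_coupling must be in [0, 1]")
        vs = tuple(float(v) for v in self.visit_schedule)
        if vs[0] != 0.0 or any(v < 0 for v in vs) or list(vs) != sorted(vs):
            raise InvalidArgumentError(
                "visit_schedule must start at 0 and be nondecreasing"
            )
        for name in (
            "thinning_rates",
            "age_means",
            "centiloid_means",
            "centiloid_rates",
            "apoe4_probs",
            "memory_slopes",
            "subtype_fractions",
        ):
            if len(getattr(self, name)) < self.k_true:
                raise InvalidArgumentError(f"{name} must cover all k_true subtypes")


def generate_parcellation(n_rois: int, seed: int) -> Parcellation:
    """Sample a mirrored two-hemisphere parcellation on a 70 mm shell.

    Half the ROIs are drawn uniformly on the x > 0 hemisphere of a sphere
    of radius 70 mm with 3 mm radial jitter; the other half mirror them
    through the sagittal plane.  Network labels follow the ROI's angular
    sector around the anterior-posterior axis, giving seven contiguous
    canonical-network sectors per hemisphere.
    """
    if n_rois < 4:
        raise InvalidArgumentError("n_rois must be at least 4")
    rng = np.random.default_rng(seed)
    n_half = n_rois // 2
    n_extra = n_rois - 2 * n_half

    # uniform directions on the hemisphere x > 0
    v = rng.standard_normal((n_half + n_extra, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v[:, 0] = np.abs(v[:, 0])
    radius = 70.0 + rng.normal(0.0, 3.0, size=v.shape[0])
    pts = v * radius[:, None]

    mirrored = pts[:n_half].copy()
    mirrored[:, 0] *= -1.0
    centroids = np.vstack([pts, mirrored])

    # sector angle around the y (anterior-posterior) axis
    theta = np.arctan2(centroids[:, 2], centroids[:, 1])  # [-pi, pi)
    sector = np.floor((theta + np.pi) / (2 * np.pi) * len(CANONICAL_NETWORKS))
    sector = np.clip(sector.astype(int), 0, len(CANONICAL_NETWORKS) - 1)
    labels = [CANONICAL_NETWORKS[s] for s in sector]
    hemi = ["L" if x < 0 else "R" for x in centroids[:, 0]]
    names = [f"{h}_{lab}_{i}" for i, (h, lab) in enumerate(zip(hemi, labels))]
    return Parcellation(roi_names=names, network_labels=labels, centroids=centroids)


def _one_connectome(
    parcellation: Parcellation,
    density: float,
    distance_decay: float,
    network_boost: float,
    modality: str,
    rng: np.random.Generator,
) -> ConnectivityTemplate:
    D = parcellation.distances
    R = D.shape[0]
    iu, ju = np.triu_indices(R, k=1)
    d = D[iu, ju]
    labels = np.asarray(parcellation.network_labels)
    same_network = labels[iu] == labels[ju]
    # distance decay plus elevated within-network coupling: long-range
    # intra-network edges give the graph structure beyond pure geometry
    affinity = np.exp(-d / distance_decay) * (1.0 + network_boost * same_network)

    n_pairs = d.size
    m = int(round(density * n_pairs))
    # weighted sampling without replacement via Gumbel-max keys
    keys = np.log(affinity + 1e-300) + rng.gumbel(size=n_pairs)
    keep = np.zeros(n_pairs, dtype=bool)
    keep[np.argsort(keys)[::-1][:m]] = True

    weights = affinity * np.exp(rng.normal(0.0, 0.1, size=n_pairs))
    W = np.zeros((R, R))
    W[iu[keep], ju[keep]] = weights[keep]
    W += W.T

    # guarantee a connected graph: union with the distance MST
    mst = minimum_spanning_tree(D).toarray()
    mi, mj = np.nonzero(mst)
    for a, b in zip(mi, mj):
        if W[a, b] == 0:
            w = np.exp(-D[a, b] / distance_decay)
            W[a, b] = W[b, a] = w
    return ConnectivityTemplate(weights=W, modality=modality, distances=D)


def generate_connectomes(
    parcellation: Parcellation,
    density: float = 0.2,
    distance_decay: float = 30.0,
    network_boost: float = 2.0,
    seed: int = 0,
) -> dict[str, ConnectivityTemplate]:
    """Three connectivity templates with geometry and community structure.

    Edge presence and weight decay as exp(-d/lambda), with within-network
    pairs boosted by (1 + network_boost) to mimic long-range intra-network
    coupling; the functional, structural and morphometric templates are
    independent realizations of the same generative law, so they correlate
    but are not identical.  Connectivity is enforced by adding the
    distance minimum spanning tree.
    """
    if not 0.0 < density <= 1.0:
        raise InvalidArgumentError("density must be in (0, 1]")
    if distance_decay <= 0:
        raise InvalidArgumentError("distance_decay must be positive")
    rng = np.random.default_rng(seed)
    return {
        modality: _one_connectome(
            parcellation, density, distance_decay, network_boost, modality, rng
        )
        for modality in ("functional", "structural", "morphometric")
    }


def vulnerable_roi_sets(parcellation: Parcellation, k_true: int = 2) -> list[np.ndarray]:
    """Disjoint vulnerability ROI sets per planted subtype.

    Subtype 1 is limbic-predominant: its vulnerable set is the ROIs in the
    limbic/default-mode sectors.  Subtype 2 (hippocampal-sparing analogue)
    owns the remaining sectors.  For k_true > 2 the remaining sectors are
    split round-robin.
    """
    labels = np.asarray(parcellation.network_labels)
    limbic = np.flatnonzero(np.isin(labels, LIMBIC_LIKE_NETWORKS))
    rest = np.flatnonzero(~np.isin(labels, LIMBIC_LIKE_NETWORKS))
    if k_true == 1:
        return [np.arange(parcellation.n_rois)]
    sets = [limbic]
    for j in range(k_true - 1):
        sets.append(rest[j::(k_true - 1)])
    return sets


def _coupled_rates(
    template_rates: np.ndarray, connectome: ConnectivityTemplate, coupling: float
) -> np.ndarray:
    """Mix a regional rate template with its neighbour-weighted average."""
    W = connectome.weights
    strength = W.sum(axis=1)
    neighbour_avg = W @ template_rates / np.where(strength > 0, strength, 1.0)
    return (1.0 - coupling) * template_rates + coupling * neighbour_avg


def generate_cohort(
    config: SimulationConfig,
    parcellation: Parcellation,
    connectome: ConnectivityTemplate,
) -> tuple[RegionalThicknessTable, np.ndarray, list[BetaMap]]:
    """Simulate a longitudinal cohort with planted subtypes.

    Returns the thickness table, the planted 1-based subtype label per
    subject (ordered by subject_id) and the true per-subtype thinning-rate
    maps after network coupling (as BetaMaps with zero-uncertainty
    placeholders: se = NaN, p = NaN).
    """
    if connectome.n_rois != parcellation.n_rois or config.n_rois != parcellation.n_rois:
        raise InvalidArgumentError("parcellation, connectome and config disagree on R")
    rng = np.random.default_rng(config.seed)
    S, R, K = config.n_subjects, config.n_rois, config.k_true

    fractions = np.asarray(config.subtype_fractions[:K], float)
    fractions /= fractions.sum()
    labels = rng.choice(np.arange(1, K + 1), size=S, p=fractions)

    sets = vulnerable_roi_sets(parcellation, K)
    # per-ROI vulnerability multiplier adds mild regional heterogeneity
    vuln_scale = rng.uniform(0.7, 1.3, size=R)
    profile = np.zeros((K, R))
    for j, roi_set in enumerate(sets[:K]):
        profile[j, roi_set] = config.subtype_profile_effect * vuln_scale[roi_set]

    rate_maps = np.zeros((K, R))
    h = config.rate_heterogeneity
    for j in range(K):
        vuln_rate, bg_rate = config.thinning_rates[j]
        template = np.full(R, bg_rate)
        template[sets[j]] = vuln_rate
        # per-ROI heterogeneity: regional vulnerability varies around the
        # set-level rate, so network coupling imprints the actual adjacency
        template = template * rng.uniform(1.0 - h, 1.0 + h, size=R)
        rate_maps[j] = _coupled_rates(template, connectome, config.network_coupling)

    mu = rng.uniform(2.0, 4.0, size=R)  # per-ROI population mean thickness
    age = rng.normal(
        np.asarray(config.age_means)[labels - 1], config.age_sd
    ).clip(50.0, 90.0)
    sex = rng.choice(["M", "F"], size=S)
    apoe4 = (rng.random(S) < np.asarray(config.apoe4_probs)[labels - 1]).astype(int)
    cl0 = rng.normal(
        np.asarray(config.centiloid_means)[labels - 1], config.centiloid_sd
    ).clip(-10.0, None)
    site = rng.choice([f"site{i+1}" for i in range(config.n_sites)], size=S)
    intercept = rng.normal(0.0, config.intercept_sd, size=S)
    memory0 = rng.normal(0.0, 1.0, size=S)

    base_true = (
        mu[None, :]
        - config.age_slope * (age - 65.0)[:, None]
        - profile[labels - 1]
        + (np.where(sex == "M", config.sex_offset, 0.0))[:, None]
        + intercept[:, None]
    )

    rows = []
    times = np.asarray(config.visit_schedule, float)
    for vi, t in enumerate(times):
        thick = (
            base_true
            + rate_maps[labels - 1] * t
            + rng.normal(0.0, config.noise_sd, size=(S, R))
        )
        cl = cl0 + np.asarray(config.centiloid_rates)[labels - 1] * t + rng.normal(
            0.0, 2.0, size=S
        ) * (t > 0)
        mem = memory0 + np.asarray(config.memory_slopes)[labels - 1] * t + rng.normal(
            0.0, 0.15, size=S
        ) * (t > 0)
        meta = {
            "subject_id": [f"sub{i:04d}" for i in range(S)],
            "visit_index": vi,
            "time_years": t,
            "age_baseline": age,
            "sex": sex,
            "centiloid": cl,
            "apoe4": apoe4,
            "site": site,
            "memory_score": mem,
        }
        meta.update({f"roi_{r}": thick[:, r] for r in range(R)})
        rows.append(pd.DataFrame(meta))
    data = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["subject_id", "visit_index"])
        .reset_index(drop=True)
    )
    table = RegionalThicknessTable(data=data, roi_columns=[f"roi_{r}" for r in range(R)])

    order = np.argsort([f"sub{i:04d}" for i in range(S)])
    true_labels = labels[order]
    true_maps = [
        BetaMap(
            subtype_label=j + 1,
            beta=rate_maps[j],
            se=np.full(R, np.nan),
            p=np.full(R, np.nan),
        )
        for j in range(K)
    ]
    return table, true_labels, true_maps


def spatial_field(
    distances: np.ndarray, sa_length: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Gaussian random fields with exponential covariance exp(-d/sa_length).

    Returns a (size x R) array; fields have unit marginal variance.
    """
    R = distances.shape[0]
    cov = np.exp(-distances / sa_length) + 1e-8 * np.eye(R)
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((size, R))
    return z @ L.T


def generate_expression(
    parcellation: Parcellation,
    betamap: BetaMap,
    n_coupled: int = 20,
    n_null: int = 80,
    sa_length: float = 30.0,
    coupling_r: float = 0.8,
    seed: int = 0,
) -> ExpressionMatrix:
    """Regional expression maps, a subset spatially coupled to thinning.

    Coupled genes mix the z-scored thinning map with a spatially
    autocorrelated field at the requested correlation; null genes are pure
    exponential-covariance random fields, so they stress the
    autocorrelation-preserving surrogate test rather than a naive
    permutation null.  All genes are z-scored across ROIs.
    """
    if n_coupled + n_null == 0:
        raise InvalidArgumentError("need at least one gene")
    if not 0.0 <= coupling_r < 1.0:
        raise InvalidArgumentError("coupling_r must be in [0, 1)")
    if sa_length <= 0:
        raise InvalidArgumentError("sa_length must be positive")
    rng = np.random.default_rng(seed)
    R = parcellation.n_rois
    beta_z = (betamap.beta - betamap.beta.mean()) / betamap.beta.std()

    fields = spatial_field(parcellation.distances, sa_length, rng, n_coupled + n_null)
    cols = []
    for g in range(n_coupled):
        noise = fields[g]
        noise_z = (noise - noise.mean()) / noise.std()
        # residualize so the planted correlation is exact in expectation
        resid = noise_z - np.dot(noise_z, beta_z) / np.dot(beta_z, beta_z) * beta_z
        resid /= resid.std()
        cols.append(coupling_r * beta_z + np.sqrt(1 - coupling_r**2) * resid)
    for g in range(n_coupled, n_coupled + n_null):
        cols.append(fields[g])
    expr = np.column_stack(cols) if cols else np.empty((R, 0))
    expr = (expr - expr.mean(axis=0)) / expr.std(axis=0)

    symbols = [f"CPL{g:03d}" for g in range(n_coupled)] + [
        f"NUL{g:03d}" for g in range(n_null)
    ]
    other_sources = ["WMH", "CVD", "LATE", "PCA", "other"]
    sources = ["AD"] * n_coupled + [
        other_sources[g % len(other_sources)] for g in range(n_null)
    ]
    return ExpressionMatrix(expr=expr, gene_symbols=symbols, gene_source=sources)
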