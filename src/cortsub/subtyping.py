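"""NMF subtyping of baseline cortical thickness.

Thickness is first inverted per ROI (max-plus-margin subtraction) so that
larger values mean more atrophy, then factorized as X ~ WH with W, H >= 0
by multiplicative-update NMF over multiple random restarts.  Subjects and
regions are assigned to the subtype with the highest score; a consensus
co-assignment matrix over restarts drives rank selection via the
cophenetic coefficient with a silhouette tie-break.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.cluster.hierarchy import average, cophenet
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

from .types import (
    InvalidArgumentError,
    InvalidInputError,
    RankSelectionReport,
    SubtypeModel,
)

logger = logging.getLogger(__name__)

DEFAULT_N_RESTARTS = 50
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-6


def invert_thickness(
    thickness: np.ndarray, margin: float = 0.01, global_max: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Invert an S x R baseline thickness matrix to a nonnegative matrix.

    X[s, r] = max_s'(thickness[s', r]) + margin - thickness[s, r], so a
    thinner cortex maps to a larger value and every entry is >= margin.
    ``global_max=True`` uses a single maximum over the whole matrix
    instead of per-ROI maxima.

    Returns (X, offsets) where offsets are the per-ROI constants
    (max + margin) needed to invert follow-up scans into the same space.
    """
    thickness = np.asarray(thickness, dtype=float)
    bad = np.argwhere(~(thickness > 0))
    if bad.size:
        s, r = bad[0]
        raise InvalidInputError(
            f"nonpositive thickness at subject row {s}, ROI column {r}"
        )
    if global_max:
        offsets = np.full(thickness.shape[1], thickness.max() + margin)
    else:
        offsets = thickness.max(axis=0) + margin
    return offsets[None, :] - thickness, offsets


def _match_components(H_ref: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Permutation aligning H's components to H_ref by row correlation."""
    k = H_ref.shape[0]
    C = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            sa, sb = H_ref[a].std(), H[b].std()
            C[a, b] = (
                np.corrcoef(H_ref[a], H[b])[0, 1] if sa > 0 and sb > 0 else 0.0
            )
    _, perm = linear_sum_assignment(-C)
    return perm


def fit_nmf(
    X: np.ndarray,
    k: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    subject_ids: np.ndarray | None = None,
    inversion_offsets: np.ndarray | None = None,
) -> SubtypeModel:
    """Multi-restart Frobenius NMF with a consensus co-assignment matrix.

    Each restart minimizes ||X - WH||_F^2 by multiplicative updates from a
    nonnegative random initialization; the restart with the lowest
    residual sum of squares is retained.  The consensus matrix counts, for
    every subject pair, the fraction of restarts in which both received
    the same argmax component after greedy component matching to the best
    run's regional profiles.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise InvalidInputError("NMF input must be nonnegative")
    S, R = X.shape
    if not 1 <= k <= min(S, R):
        raise InvalidArgumentError(f"k={k} outside [1, min(S, R)={min(S, R)}]")
    if n_restarts < 1:
        raise InvalidArgumentError("n_restarts must be >= 1")

    rng = np.random.default_rng(seed)
    runs = []
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    for _ in range(n_restarts):
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            # hitting max_iter merely caps refinement of an already-ranked restart
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            W = model.fit_transform(X)
        H = model.components_
        rss = float(np.linalg.norm(X - W @ H) ** 2)
        runs.append((rss, W, H))

    best_rss, W, H = min(runs, key=lambda t: t[0])

    # consensus over restarts, components aligned to the best run
    co = np.zeros((S, S))
    for _, Wr, Hr in runs:
        perm = _match_components(H, Hr)
        labels = np.argmax(Wr[:, perm], axis=1)
        co += labels[:, None] == labels[None, :]
    consensus = co / n_restarts
    np.fill_diagonal(consensus, 1.0)

    assignment, probability, unassignable = assign_from_scores(W)
    region_assignment = np.argmax(H, axis=0) + 1
    if subject_ids is None:
        subject_ids = np.array([f"s{i}" for i in range(S)])
    return SubtypeModel(
        k=k,
        W=W,
        H=H,
        rss=best_rss,
        subject_ids=np.asarray(subject_ids),
        subject_assignment=assignment,
        subject_probability=probability,
        region_assignment=region_assignment,
        consensus=consensus,
        inversion_offsets=inversion_offsets,
        unassignable=unassignable,
    )


def assign_from_scores(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subject assignments and probabilities from a nonnegative score matrix.

    Probabilities are L1 row-normalized scores; assignment is the argmax
    (1-based), ties resolved toward the lower subtype index with a logged
    warning.  All-zero rows get uniform probabilities and are flagged
    unassignable.
    """
    W = np.asarray(W, dtype=float)
    row_sum = W.sum(axis=1)
    unassignable = row_sum == 0
    prob = np.where(
        unassignable[:, None], 1.0 / W.shape[1], W / np.where(row_sum == 0, 1, row_sum)[:, None]
    )
    assignment = np.argmax(prob, axis=1) + 1  # argmax takes the first maximum
    ties = (prob == prob.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if (ties & ~unassignable).any():
        logger.warning(
            "tied NMF scores for %d subject(s); assigned to the lower subtype index",
            int((ties & ~unassignable).sum()),
        )
    if unassignable.any():
        logger.warning("%d subject(s) with all-zero scores flagged unassignable",
                       int(unassignable.sum()))
    return assignment, prob, unassignable


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Stability of a consensus matrix under hierarchical clustering.

    Pearson correlation between the condensed (1 - consensus) distances
    and the cophenetic distances of their average-linkage dendrogram.  A
    perfectly stable (all-ones) consensus has zero distances everywhere
    and is defined as 1.0.
    """
    dist = squareform(1.0 - consensus, checks=False)
    dist = np.clip(dist, 0.0, None)
    if np.allclose(dist, dist.mean()):
        return 1.0  # degenerate: constant distances, perfect stability
    Z = average(dist)
    coph, _ = cophenet(Z, dist)
    return float(coph)


def rank_selection(
    X: np.ndarray,
    k_range: list[int],
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    silhouette_on_consensus: bool = True,
) -> RankSelectionReport:
    """Fit statistics over candidate ranks and the selected rank.

    Selection maximizes the cophenetic coefficient; ties go to the higher
    mean silhouette (computed on 1 - consensus distances by default, raw
    feature distances optionally), then to the lower rank.  The relative
    RSS decrease from k-1 to k is reported but not used for selection.
    """
    if not k_range:
        raise InvalidArgumentError("k_range must be nonempty")
    X = np.asarray(X, dtype=float)
    if min(k_range) < 2 or max(k_range) > min(X.shape):
        raise InvalidArgumentError("k_range must lie within [2, min(S, R)]")

    rng = np.random.default_rng(seed)
    coph: dict[int, float] = {}
    sil: dict[int, float] = {}
    rss: dict[int, float] = {}
    for k in sorted(k_range):
        model = fit_nmf(
            X, k, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            seed=int(rng.integers(2**31 - 1)),
        )
        coph[k] = cophenetic_coefficient(model.consensus)
        labels = model.subject_assignment
        if len(np.unique(labels)) < 2:
            sil[k] = -1.0  # collapsed solution: worst silhouette
        elif silhouette_on_consensus:
            dist = np.clip(1.0 - model.consensus, 0.0, None)
            np.fill_diagonal(dist, 0.0)
            sil[k] = float(silhouette_score(dist, labels, metric="precomputed"))
        else:
            sil[k] = float(silhouette_score(X, labels))
        rss[k] = model.rss

    ks = sorted(k_range)
    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = 0.0
        else:
            prev = rss[ks[i - 1]]
            delta[k] = (prev - rss[k]) / prev if prev > 0 else 0.0
    selected = max(ks, key=lambda k: (coph[k], sil[k], -k))
    return RankSelectionReport(
        k_values=ks, cophenetic=coph, silhouette=sil, rss=rss,
        delta_rss=delta, selected_k=selected,
    )
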