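"""Cross-sectional and longitudinal subtype characterization.

Houses a fast random-intercept linear mixed model (REML via
one-dimensional profiling of the intercept-to-residual variance ratio,
with fixed effects by GLS at the optimum), per-ROI subtype-specific
thinning maps via time-by-subtype interactions, follow-up subtype
re-assignment by Pearson correspondence to the NMF regional profiles,
Krippendorff's alpha for baseline/follow-up agreement, and logistic
models of subtype membership and stability.

The random-intercept model y = X b + Z u + e with u ~ N(0, tau^2) per
subject and e ~ N(0, sigma^2) admits closed-form GLS for any variance
ratio theta = tau^2 / sigma^2 because each subject's marginal covariance
is sigma^2 (I + theta J); only theta needs numerical optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar

from .types import (
    BetaMap,
    InvalidArgumentError,
    InvalidInputError,
    RegionalThicknessTable,
    StabilityResult,
    SubtypeModel,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# random-intercept LMM
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    """REML fit of a random-intercept linear mixed model."""

    params: np.ndarray
    cov_params: np.ndarray
    sigma2: float  # residual variance
    tau2: float    # intercept variance
    theta: float   # tau2 / sigma2
    n_obs: int
    df_resid: int
    param_names: list[str]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def contrast(self, c: np.ndarray) -> tuple[float, float, float]:
        """Estimate, SE and two-sided Wald p of the linear contrast c'b."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov_params @ c))
        p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
        return est, se, p

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.param_names,
        )


class _GroupedDesign:
    """Per-subject sufficient statistics of a fixed design.

    Precomputed once, they make every profile-likelihood evaluation (and
    every additional outcome sharing the design) an O(G p^2) reduction.
    """

    def __init__(self, X: np.ndarray, subject_ids: np.ndarray,
                 param_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        subject_ids = np.asarray(subject_ids)
        order = np.argsort(subject_ids, kind="stable")
        self.order = order
        self.X = X[order]
        ids = subject_ids[order]
        _, starts, counts = np.unique(ids, return_index=True, return_counts=True)
        self.starts = starts
        self.n_g = counts.astype(float)
        self.n, self.p = X.shape
        self.param_names = param_names or [f"x{j}" for j in range(self.p)]

        rank = np.linalg.matrix_rank(X)
        if rank < self.p:
            # name the aliased columns via QR pivoting on the gram matrix
            _, Rq = np.linalg.qr(X)
            aliased = [self.param_names[j] for j in range(self.p)
                       if abs(Rq[j, j]) < 1e-8 * max(1.0, abs(Rq[0, 0]))]
            raise InvalidInputError(
                f"design matrix is rank deficient (rank {rank} < {self.p}); "
                f"aliased columns: {aliased or 'unresolved'}"
            )

        # per-group stats: sum_g X_g' X_g (stacked), X_g' 1
        G = len(starts)
        self.XtX_g = np.empty((G, self.p, self.p))
        self.sx_g = np.add.reduceat(self.X, starts, axis=0)  # G x p
        for g, (s, c) in enumerate(zip(starts, counts)):
            Xg = self.X[s:s + int(c)]
            self.XtX_g[g] = Xg.T @ Xg
        self.XtX = self.XtX_g.sum(axis=0)

    def y_stats(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        y = np.asarray(y, dtype=float)[self.order]
        sy_g = np.add.reduceat(y, self.starts)                  # G
        Xty_g = np.add.reduceat(self.X * y[:, None], self.starts, axis=0)  # G x p
        yty = float(y @ y)
        return sy_g, Xty_g, yty


def _gls_pieces(design: _GroupedDesign, sy_g, Xty_g, yty, theta):
    lam = theta / (1.0 + theta * design.n_g)  # shrinkage per group
    A = design.XtX - np.einsum("g,gi,gj->ij", lam, design.sx_g, design.sx_g)
    b = Xty_g.sum(axis=0) - (lam * sy_g) @ design.sx_g
    c = yty - float(lam @ sy_g**2)
    return A, b, c


def _neg2_reml(design: _GroupedDesign, sy_g, Xty_g, yty, theta) -> float:
    A, b, c = _gls_pieces(design, sy_g, Xty_g, yty, theta)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    rss = c - float(b @ beta)
    if rss <= 0:
        rss = 1e-12
    n, p = design.n, design.p
    sigma2 = rss / (n - p)
    logdet_v = float(np.sum(np.log1p(theta * design.n_g)))
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return (n - p) * np.log(sigma2) + logdet_v + logdet_a


def fit_random_intercept_lmm(
    y: np.ndarray,
    X: np.ndarray,
    subject_ids: np.ndarray,
    param_names: list[str] | None = None,
    _design: _GroupedDesign | None = None,
) -> LMMResult:
    """REML fit of y = X b + (subject intercept) + noise.

    The intercept-to-residual variance ratio theta is profiled on a log
    grid refined by bounded scalar minimization; fixed effects and their
    covariance come from GLS at the optimum.  With no repeated measures
    theta is not identifiable and the fit degrades to OLS (theta = 0)
    with a warning.
    """
    design = _design or _GroupedDesign(X, subject_ids, param_names)
    sy_g, Xty_g, yty = design.y_stats(y)

    if (design.n_g < 2).all():
        logger.warning("no subject has repeated measures; fitting theta = 0 (OLS)")
        theta_hat = 0.0
    else:
        obj = lambda log_theta: _neg2_reml(design, sy_g, Xty_g, yty, np.exp(log_theta))
        grid = np.linspace(-10.0, 6.0, 17)
        vals = [obj(g) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = minimize_scalar(obj, bounds=(g0 - 2.0, g0 + 2.0), method="bounded",
                              options={"xatol": 1e-8})
        theta_hat = float(np.exp(res.x))
        if _neg2_reml(design, sy_g, Xty_g, yty, 0.0) <= res.fun:
            theta_hat = 0.0

    A, b, c = _gls_pieces(design, sy_g, Xty_g, yty, theta_hat)
    beta = np.linalg.solve(A, b)
    rss = max(c - float(b @ beta), 1e-12)
    sigma2 = rss / (design.n - design.p)
    cov = sigma2 * np.linalg.inv(A)
    return LMMResult(
        params=beta,
        cov_params=cov,
        sigma2=sigma2,
        tau2=theta_hat * sigma2,
        theta=theta_hat,
        n_obs=design.n,
        df_resid=design.n - design.p,
        param_names=design.param_names,
    )


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------

def _assigned_probability(model: SubtypeModel) -> pd.Series:
    """Each subject's NMF probability for its assigned subtype."""
    prob = model.subject_probability[
        np.arange(len(model.subject_ids)), model.subject_assignment - 1
    ]
    return pd.Series(prob, index=model.subject_ids)


def _require_repeated_measures(table: RegionalThicknessTable) -> None:
    counts = table.data.groupby("subject_id").size()
    if (counts < 2).all():
        raise InvalidInputError(
            "time-effect model requested but no subject has repeated measures"
        )


def _longitudinal_design(
    df: pd.DataFrame, model: SubtypeModel
) -> tuple[np.ndarray, list[str], np.ndarray, list[np.ndarray]]:
    """Design for thickness/outcome ~ time * subtype + covariates.

    Returns (X, names, subject_ids, per-subtype marginal-slope contrasts).
    Subtype 1 is the reference level; sex is coded M = 1.  Centiloid and
    NMF probability enter as baseline values.
    """
    labels = pd.Series(model.subject_assignment, index=model.subject_ids)
    prob = _assigned_probability(model)
    base = df[df["time_years"] == 0.0].set_index("subject_id")

    sub = labels.reindex(df["subject_id"]).to_numpy()
    t = df["time_years"].to_numpy(float)
    cols = [np.ones(len(df)), t]
    names = ["intercept", "time"]
    k = model.k
    for j in range(2, k + 1):
        cols.append((sub == j).astype(float))
        names.append(f"subtype{j}")
    for j in range(2, k + 1):
        cols.append(t * (sub == j))
        names.append(f"time:subtype{j}")
    cols.append(df["age_baseline"].to_numpy(float))
    names.append("age")
    cols.append((df["sex"] == "M").to_numpy(float))
    names.append("sex_m")
    cols.append(base["centiloid"].reindex(df["subject_id"]).to_numpy(float))
    names.append("centiloid_baseline")
    cols.append(prob.reindex(df["subject_id"]).to_numpy(float))
    names.append("nmf_probability")
    X = np.column_stack(cols)

    contrasts = []
    for j in range(1, k + 1):
        c = np.zeros(X.shape[1])
        c[names.index("time")] = 1.0
        if j >= 2:
            c[names.index(f"time:subtype{j}")] = 1.0
        contrasts.append(c)
    return X, names, df["subject_id"].to_numpy(), contrasts


def thinning_betamaps(
    table: RegionalThicknessTable, model: SubtypeModel
) -> list[BetaMap]:
    """Per-ROI within-subtype marginal thinning slopes (mm/year).

    For every ROI, thickness is modelled as time * subtype + age + sex +
    baseline centiloid + NMF probability with a subject random intercept;
    each subtype's marginal slope is the linear contrast of the time and
    time-by-subtype coefficients (estimated-marginal-means linear trend
    under dummy coding).
    """
    _require_repeated_measures(table)
    df = table.data
    X, names, subj, contrasts = _longitudinal_design(df, model)

    counts = df.groupby("subject_id").size()
    labels = pd.Series(model.subject_assignment, index=model.subject_ids)
    longi_subjects = set(counts.index[counts >= 2])
    has_longi = {
        j: any(labels[s] == j for s in longi_subjects if s in labels.index)
        for j in range(1, model.k + 1)
    }

    design = _GroupedDesign(X, subj, names)
    R = table.n_rois
    maps = []
    betas = np.full((model.k, R), np.nan)
    ses = np.full((model.k, R), np.nan)
    ps = np.full((model.k, R), np.nan)
    for r, col in enumerate(table.roi_columns):
        fit = fit_random_intercept_lmm(df[col].to_numpy(float), X, subj,
                                       names, _design=design)
        for j in range(model.k):
            est, se, p = fit.contrast(contrasts[j])
            betas[j, r], ses[j, r], ps[j, r] = est, se, p
    for j in range(1, model.k + 1):
        if not has_longi[j]:
            logger.warning("subtype %d has no longitudinal subjects; map set to NaN", j)
            betas[j - 1] = np.nan
            ses[j - 1] = np.nan
            ps[j - 1] = np.nan
        maps.append(BetaMap(subtype_label=j, beta=betas[j - 1],
                            se=ses[j - 1], p=ps[j - 1]))
    return maps


def characterize_subtypes(
    table: RegionalThicknessTable, model: SubtypeModel
) -> pd.DataFrame:
    """Cross-sectional logistic model of subtype membership.

    Fits subtype-1 membership on baseline age, sex, centiloid and APOE-e4
    carriership, correcting for the NMF assignment probability.  Returns a
    table with odds ratios, Wald CIs and p-values; perfect separation is
    flagged with a warning rather than raised.
    """
    if model.k != 2:
        raise InvalidArgumentError("subtype characterization expects two subtypes")
    base = table.baseline().set_index("subject_id")
    labels = pd.Series(model.subject_assignment, index=model.subject_ids)
    prob = _assigned_probability(model)
    idx = base.index
    y = (labels.reindex(idx) == 1).astype(float).to_numpy()
    X = pd.DataFrame(
        {
            "age": base["age_baseline"].astype(float),
            "sex_m": (base["sex"] == "M").astype(float),
            "centiloid": base["centiloid"].astype(float),
            "apoe4": base["apoe4"].astype(float),
            "nmf_probability": prob.reindex(idx).astype(float),
        },
        index=idx,
    )
    degenerate = [c for c in X.columns if X[c].nunique() < 2]
    if degenerate:
        raise InvalidInputError(f"degenerate predictors: {degenerate}")
    return _logistic_table(y, sm.add_constant(X))


def _logistic_table(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    separation = False
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        if np.any(np.abs(fit.params) > 15):
            separation = True
    except Exception:  # pragma: no cover - IRLS failure path
        separation = True
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(alpha=1e-4)
    if separation:
        logger.warning("possible perfect separation in logistic model; "
                       "coefficients may be unstable")
    params = np.asarray(fit.params, float)
    se = np.asarray(fit.bse, float) if hasattr(fit, "bse") else np.full_like(params, np.nan)
    z = stats.norm.ppf(0.975)
    out = pd.DataFrame(
        {
            "coef": params,
            "or": np.exp(params),
            "or_low": np.exp(params - z * se),
            "or_high": np.exp(params + z * se),
            "p": 2 * stats.norm.sf(np.abs(params / se)),
        },
        index=list(X.columns),
    )
    out.attrs["separation_flag"] = separation
    return out


def longitudinal_outcome_model(
    table: RegionalThicknessTable,
    model: SubtypeModel,
    outcome: str,
    score_by_time: bool = False,
) -> LMMResult:
    """Random-intercept LMM of a longitudinal outcome on subtype and time.

    Predictors: subtype, time, subtype-by-time interaction, age, sex,
    baseline centiloid and baseline NMF probability.  With
    ``score_by_time`` an NMF-probability-by-time interaction is added,
    testing whether stronger subtype expression steepens the trajectory.
    """
    _require_repeated_measures(table)
    df = table.data
    if outcome not in df.columns:
        raise InvalidArgumentError(f"outcome column {outcome!r} not in table")
    X, names, subj, _ = _longitudinal_design(df, model)
    if score_by_time:
        prob = X[:, names.index("nmf_probability")]
        X = np.column_stack([X, prob * df["time_years"].to_numpy(float)])
        names = names + ["time:nmf_probability"]
    return fit_random_intercept_lmm(df[outcome].to_numpy(float), X, subj, names)


# ---------------------------------------------------------------------------
# follow-up assignment and stability
# ---------------------------------------------------------------------------

def assign_followup(
    thickness_vector: np.ndarray,
    model: SubtypeModel,
    use_inverted: bool = True,
) -> tuple[int, np.ndarray]:
    """Assign a follow-up scan to the best-corresponding subtype profile.

    The vector is inverted with the baseline inversion constants (so it
    lives in the fitted NMF space), then Pearson-correlated against each
    regional profile (H row); the label is the argmax correlation, ties
    resolved toward the lower index with a warning.
    """
    v = np.asarray(thickness_vector, dtype=float)
    if v.shape[0] != model.H.shape[1]:
        raise InvalidArgumentError("thickness vector length does not match model")
    if use_inverted:
        if model.inversion_offsets is None:
            raise InvalidArgumentError("model lacks inversion offsets")
        v = model.inversion_offsets - v
    if np.std(v) == 0:
        raise InvalidInputError("zero-variance thickness vector: correlation undefined")
    rs = np.empty(model.k)
    for j in range(model.k):
        h = model.H[j]
        rs[j] = np.corrcoef(v, h)[0, 1] if h.std() > 0 else 0.0
    best = int(np.argmax(rs)) + 1
    if (rs == rs.max()).sum() > 1:
        logger.warning("tied follow-up correlations; assigned lower subtype index")
    return best, rs


def krippendorff_alpha(codes_t1: np.ndarray, codes_t2: np.ndarray) -> float:
    """Krippendorff's alpha for two nominal codings of the same units.

    alpha = 1 - D_o / D_e with observed and expected disagreement from
    the coincidence matrix over all pairable values.  Degenerate data
    (one unit, or a single distinct code overall) has zero expected
    disagreement and is defined as perfect agreement (alpha = 1).
    """
    a = np.asarray(codes_t1)
    b = np.asarray(codes_t2)
    if a.shape != b.shape:
        raise InvalidArgumentError("codings must have equal length")
    values, inv_a = np.unique(np.concatenate([a, b]), return_inverse=True)
    ia, ib = inv_a[: len(a)], inv_a[len(a):]
    V = len(values)
    # coincidence matrix: each unit contributes its ordered pairs / (m-1)
    o = np.zeros((V, V))
    np.add.at(o, (ia, ib), 1.0)
    np.add.at(o, (ib, ia), 1.0)
    n_c = o.sum(axis=1)
    n = n_c.sum()
    if len(a) < 2 or V < 2:
        logger.warning("degenerate agreement data; alpha defined as 1")
        return 1.0
    d_o = n - np.trace(o)           # off-diagonal coincidence mass
    d_e = (n**2 - n_c @ n_c) / (n - 1)
    if d_e == 0:
        logger.warning("zero expected disagreement; alpha defined as 1")
        return 1.0
    return float(1.0 - d_o / d_e)


def stability_analysis(
    table: RegionalThicknessTable,
    model: SubtypeModel,
    use_inverted: bool = True,
) -> StabilityResult:
    """Baseline vs latest-follow-up subtype agreement and its predictors.

    The latest follow-up scan of every longitudinal subject is assigned
    to a baseline subtype by Pearson correspondence; agreement is
    quantified by Krippendorff's alpha, and instability is modelled by
    logistic regression on age, sex, follow-up time and the baseline NMF
    assignment probability.
    """
    followups = table.latest_followup()
    if followups.empty:
        raise InvalidInputError("no subjects with follow-up scans")
    labels = pd.Series(model.subject_assignment, index=model.subject_ids)
    prob = _assigned_probability(model)

    subj = followups["subject_id"].to_numpy()
    base_labels = labels.reindex(subj).to_numpy()
    fu_labels = np.empty(len(subj), dtype=int)
    for i, (_, row) in enumerate(followups.iterrows()):
        vec = row[table.roi_columns].to_numpy(float)
        fu_labels[i], _ = assign_followup(vec, model, use_inverted=use_inverted)

    stable = base_labels == fu_labels
    alpha = krippendorff_alpha(base_labels, fu_labels)

    X = pd.DataFrame(
        {
            "age": followups["age_baseline"].to_numpy(float),
            "sex_m": (followups["sex"] == "M").to_numpy(float),
            "followup_time": followups["time_years"].to_numpy(float),
            "nmf_probability": prob.reindex(subj).to_numpy(float),
        }
    )
    y = (~stable).astype(float)
    logistic = None
    if 0 < y.sum() < len(y):
        logistic = _logistic_table(y, sm.add_constant(X))
    else:
        logger.warning("all subjects stable (or unstable); skipping logistic model")
    return StabilityResult(
        subject_ids=subj,
        baseline_labels=base_labels,
        followup_labels=fu_labels,
        stable_flag=stable,
        alpha=alpha,
        n_unstable=int((~stable).sum()),
        logistic_table=logistic,
    )
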