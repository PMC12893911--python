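"""Per-cohort adjusted effects and random-effects meta-analysis.

Each cohort contributes an adjusted group effect from an OLS fit of the
outcome on intercept + group(0/1) + covariates; the beta is standardized
to an SMD by dividing by the pooled within-group outcome SD.  Effects are
pooled with a Paule-Mandel random-effects model (moment-based tau^2 by
monotone root search), or — when studies reuse a control arm — by
generalized least squares with an explicit effect-size
variance-covariance matrix.  Exact binomial sign tests summarize
direction counts across pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "EffectEstimate",
    "MetaResult",
    "fit_group_effect",
    "cohens_d",
    "beta_to_smd",
    "paule_mandel",
    "shared_control_covariance",
    "pool_shared_controls",
    "binomial_sign_test",
    "mixed_country_effect",
]


@dataclass
class EffectEstimate:
    dataset_id: str
    beta: float
    se: float
    n_control: int
    n_case: int
    outcome_sd: float | None = None
    smd: float | None = None
    smd_se: float | None = None
    d: float | None = None
    covariates: list[str] = field(default_factory=list)
    note: str | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError("se must be positive")


@dataclass
class MetaResult:
    pooled: float
    se: float
    ci95: tuple[float, float]
    tau2: float
    p: float
    method: str
    weights: np.ndarray
    k: int
    note: str | None = None

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValidationError("tau2 must be non-negative")
        lo, hi = self.ci95
        if not lo <= self.pooled <= hi:
            raise ValidationError("ci95 must contain the pooled estimate")


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float(np.sqrt(var))


def fit_group_effect(
    y,
    group,
    covariates: pd.DataFrame | None = None,
    dataset_id: str = "",
) -> EffectEstimate:
    """OLS of y on intercept + group(0/1) + covariates.

    ``group`` is binary with 0 the reference (control / lower-BMI) arm.
    Rows with a missing value in y, group or any covariate are dropped.
    A singular design raises :class:`CollinearityError` naming an
    offending column.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=float)
    names = ["group"]
    cols = [g]
    if covariates is not None:
        for c in covariates.columns:
            names.append(str(c))
            cols.append(covariates[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[keep], X[keep]
    g = X[:, 0]
    n0, n1 = int((g == 0).sum()), int((g == 1).sum())
    if min(n0, n1) < 4:
        raise InsufficientDataError(f"arms of size {n0}/{n1}; need >= 4 each")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        for j in range(1, len(names)):  # find a column collinear with the rest
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise CollinearityError(
                    f"design is singular; column {names[j]!r} is collinear",
                    column=names[j],
                )
        raise CollinearityError("design is singular", column=None)
    fit = sm.OLS(y, design).fit()
    sd = _pooled_sd(y[g == 1], y[g == 0])
    return EffectEstimate(
        dataset_id=dataset_id,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        n_control=n0,
        n_case=n1,
        outcome_sd=sd,
        d=cohens_d(y[g == 1], y[g == 0]) if sd > 0 else None,
        covariates=names[1:],
    )


def cohens_d(a, b) -> float:
    """(mean(a) - mean(b)) / pooled SD, with (n-1)-weighted variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    sd = _pooled_sd(a, b)
    if sd == 0:
        raise ValidationError("zero pooled SD; d undefined")
    return float((a.mean() - b.mean()) / sd)


def beta_to_smd(estimate: EffectEstimate) -> EffectEstimate:
    """Standardize an adjusted beta by the pooled within-group outcome SD."""
    if estimate.outcome_sd is None or estimate.outcome_sd <= 0:
        raise ValidationError("outcome_sd must be positive")
    estimate.smd = estimate.beta / estimate.outcome_sd
    estimate.smd_se = estimate.se / estimate.outcome_sd
    return estimate


def paule_mandel(
    effects,
    variances,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> MetaResult:
    """Paule-Mandel random-effects pooling.

    tau^2 solves  sum_i w_i(tau^2) (y_i - ybar(tau^2))^2 = k - 1  with
    w_i = 1/(v_i + tau^2), found by bisection on [0, 100 * max(v)] (the
    criterion is monotone decreasing in tau^2); clamped to 0 when already
    below k - 1 at tau^2 = 0.  Pooled effect, its SE and the normal 95%
    CI follow from the final weights.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if len(y) != len(v):
        raise ValidationError("effects and variances differ in length")
    if np.any(v <= 0):
        raise ValidationError("variances must be positive")
    k = len(y)
    if k == 0:
        raise InsufficientDataError("no studies")
    note = None
    if k == 1:
        pooled, se, tau2 = float(y[0]), float(np.sqrt(v[0])), 0.0
        note = "single study: pass-through, degenerate meta-analysis"
        weights = np.array([1.0])
    else:
        def criterion(tau2: float) -> float:
            w = 1.0 / (v + tau2)
            ybar = (w * y).sum() / w.sum()
            return float((w * (y - ybar) ** 2).sum() - (k - 1))

        if criterion(0.0) <= 0:
            tau2 = 0.0
        else:
            lo, hi = 0.0, 100.0 * float(v.max())
            if criterion(hi) > 0:  # pathological spread; extend once
                hi *= 100.0
            for _ in range(max_iter):
                mid = 0.5 * (lo + hi)
                if criterion(mid) > 0:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < tol:
                    break
            tau2 = 0.5 * (lo + hi)
        w = 1.0 / (v + tau2)
        weights = w / w.sum()
        pooled = float((weights * y).sum())
        se = float(w.sum() ** -0.5)
    z = pooled / se
    p = float(2 * stats.norm.sf(abs(z)))
    return MetaResult(
        pooled=pooled,
        se=se,
        ci95=(pooled - 1.96 * se, pooled + 1.96 * se),
        tau2=float(tau2),
        p=p,
        method="paule-mandel",
        weights=weights,
        k=k,
        note=note,
    )


def shared_control_covariance(
    estimates: list[EffectEstimate],
    overlap: dict[tuple[str, str], int] | None = None,
) -> np.ndarray:
    """Effect-size variance-covariance matrix under shared control arms.

    Diagonal: smd_se^2.  Off-diagonal for studies i, j sharing n_c
    controls (the standard multi-arm SMD approximation):

        cov_ij = 1/n_c + smd_i * smd_j / (2 * (n_i + n_j))

    with n_i the total sample size of study i; zero without overlap.
    A tiny jitter (1e-10) is added if needed for positive definiteness.
    """
    ids = [e.dataset_id for e in estimates]
    for e in estimates:
        if e.smd_se is None:
            raise ValidationError(f"estimate {e.dataset_id!r} lacks smd_se")
    k = len(estimates)
    cov = np.diag([e.smd_se**2 for e in estimates])  # type: ignore[misc]
    overlap = overlap or {}
    pos = {d: i for i, d in enumerate(ids)}
    for (a, b), n_c in overlap.items():
        if a not in pos or b not in pos:
            continue
        i, j = pos[a], pos[b]
        for idx, d in ((i, a), (j, b)):
            if n_c > estimates[idx].n_control:
                raise ValidationError(
                    f"overlap {n_c} exceeds control arm of {d!r}"
                )
        ni = estimates[i].n_control + estimates[i].n_case
        nj = estimates[j].n_control + estimates[j].n_case
        si = estimates[i].smd or 0.0
        sj = estimates[j].smd or 0.0
        c = 1.0 / n_c + si * sj / (2.0 * (ni + nj))
        cov[i, j] = cov[j, i] = c
    if np.linalg.eigvalsh(cov).min() <= 0:
        cov = cov + 1e-10 * np.eye(k)
    return cov


def pool_shared_controls(
    estimates: list[EffectEstimate], covariance: np.ndarray
) -> MetaResult:
    """GLS pooling with an explicit effect-size covariance matrix.

    pooled = (1' S^-1 y) / (1' S^-1 1),  se = (1' S^-1 1)^(-1/2).
    Reduces to the inverse-variance fixed-effect mean when S is diagonal.
    """
    y = np.array([e.smd for e in estimates], dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValidationError("every estimate needs an smd")
    k = len(y)
    if covariance.shape != (k, k):
        raise ValidationError("covariance shape mismatch")
    try:
        L = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError:
        try:
            L = np.linalg.cholesky(covariance + 1e-10 * np.eye(k))
        except np.linalg.LinAlgError as exc:
            raise ValidationError("covariance not positive definite") from exc
    ones = np.ones(k)
    siy = np.linalg.solve(L.T, np.linalg.solve(L, y))
    si1 = np.linalg.solve(L.T, np.linalg.solve(L, ones))
    denom = ones @ si1
    pooled = float(ones @ siy / denom)
    se = float(denom**-0.5)
    p = float(2 * stats.norm.sf(abs(pooled / se)))
    return MetaResult(
        pooled=pooled,
        se=se,
        ci95=(pooled - 1.96 * se, pooled + 1.96 * se),
        tau2=0.0,
        p=p,
        method="gls-shared-controls",
        weights=si1 / denom,
        k=k,
    )


def binomial_sign_test(k: int, n: int, alternative: str = "two-sided") -> float:
    """Exact binomial test of k successes in n trials at p0 = 0.5.

    Two-sided p doubles the smaller exact tail, capped at 1.  One-sided
    alternatives are exposed because published direction-count tests do
    not always state their sidedness.
    """
    if not 0 <= k <= n or n < 1:
        raise ValidationError("need 0 <= k <= n, n >= 1")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    if alternative == "two-sided":
        return float(min(1.0, 2 * min(lower, upper)))
    if alternative == "greater":
        return float(upper)
    if alternative == "less":
        return float(lower)
    raise ValidationError(f"unknown alternative: {alternative!r}")


def mixed_country_effect(
    y,
    country,
    dataset_ids,
    depth,
) -> EffectEstimate:
    """Country contrast blocked by dataset, adjusted for sequencing depth.

    With more than one dataset on either side, fits a linear mixed model
    with a random intercept per dataset and fixed effects for country
    (binary 0/1) and depth.  With a single dataset per country on both
    sides the random intercept is unidentifiable and the fit falls back
    to OLS (noted on the estimate).
    """
    y = np.asarray(y, dtype=float)
    c = np.asarray(country, dtype=float)
    ds = pd.Series(dataset_ids).astype(str).to_numpy()
    depth = np.asarray(depth, dtype=float)
    depth_z = (depth - depth.mean()) / (depth.std() or 1.0)
    keep = np.isfinite(y) & np.isfinite(c) & np.isfinite(depth_z)
    y, c, ds, depth_z = y[keep], c[keep], ds[keep], depth_z[keep]
    n_ds = {side: len(set(ds[c == side])) for side in (0.0, 1.0)}
    X = sm.add_constant(np.column_stack([c, depth_z]), has_constant="add")
    if max(n_ds.values()) < 2:
        fit = sm.OLS(y, X).fit()
        return EffectEstimate(
            dataset_id="country-contrast",
            beta=float(fit.params[1]),
            se=float(fit.bse[1]),
            n_control=int((c == 0).sum()),
            n_case=int((c == 1).sum()),
            covariates=["depth"],
            note="single dataset per country: OLS fallback",
        )
    model = sm.MixedLM(y, X, groups=ds)
    fit = model.fit(reml=True, method="lbfgs")
    return EffectEstimate(
        dataset_id="country-contrast",
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        n_control=int((c == 0).sum()),
        n_case=int((c == 1).sum()),
        covariates=["depth"],
        note="mixed model, random intercept per dataset",
    )
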