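"""Species health/diet rankings from covariate-adjusted rank correlations.

The ranking construction:

1. For every (SGB, marker) pair within a cohort, compute the partial
   Spearman correlation rho between SGB relative abundance (zeros
   included) and the marker value, adjusting for sex, age and BMI.
2. Orient each correlation by the marker's health direction
   (oriented score = direction * rho) and convert to percentiles in
   (0, 1]: the SGB most favourably correlated with health gets the
   smallest percentile.
3. Average percentiles within each marker category (personal, fasting,
   postprandial, dietary), then across the three non-dietary categories
   to a per-cohort health value, then across cohorts to the final
   health-rank.  The diet-rank averages the dietary-category percentiles
   across cohorts.  SGBs ranked in fewer than ``min_cohorts`` cohorts
   carry no final rank.

Cross-cohort agreement is summarized by a two-way random-effects,
absolute-agreement, single-measurement ICC (ICC(2,1)) and by plain
Spearman concordance between rank vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)
from .profiles import AbundanceTable

__all__ = [
    "CATEGORIES",
    "HEALTH_CATEGORIES",
    "MarkerPanel",
    "CorrelationFrame",
    "RankingTable",
    "AgreementResult",
    "partial_spearman",
    "correlate_all",
    "marker_percentiles",
    "build_ranking",
    "icc_agreement",
    "rank_concordance",
    "write_ranking",
    "read_ranking",
]

CATEGORIES = ("personal", "fasting", "postprandial", "dietary")
#: Categories entering the health-rank; "dietary" alone drives the diet-rank.
HEALTH_CATEGORIES = ("personal", "fasting", "postprandial")

#: Minimum complete cases for one correlation cell; below it the cell is
#: treated as "not ranked in this cohort".
MIN_CELL_N = 30


@dataclass
class MarkerPanel:
    """Marker definitions: name, category, and health direction.

    direction +1 means a higher marker value indicates better health
    (e.g. HDL); -1 means worse (e.g. triglycerides, GlycA).
    """

    frame: pd.DataFrame  # columns: marker, category, direction

    def __post_init__(self) -> None:
        need = {"marker", "category", "direction"}
        if not need.issubset(self.frame.columns):
            raise ValidationError(f"panel needs columns {sorted(need)}")
        if self.frame["marker"].duplicated().any():
            raise ValidationError("duplicate marker names")
        bad = set(self.frame["category"]) - set(CATEGORIES)
        if bad:
            raise ValidationError(f"unknown categories: {sorted(bad)}")
        if not self.frame["direction"].isin([-1, 1]).all():
            raise ValidationError("directions must be +1 or -1")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "MarkerPanel":
        return cls(pd.DataFrame(records, columns=["marker", "category", "direction"]))

    @property
    def markers(self) -> list[str]:
        return self.frame["marker"].tolist()

    def direction(self, marker: str) -> int:
        row = self.frame.loc[self.frame["marker"] == marker, "direction"]
        if row.empty:
            raise ValidationError(f"marker {marker!r} not in panel")
        return int(row.iloc[0])

    def category(self, marker: str) -> str:
        row = self.frame.loc[self.frame["marker"] == marker, "category"]
        if row.empty:
            raise ValidationError(f"marker {marker!r} not in panel")
        return str(row.iloc[0])

    def markers_in(self, category: str) -> list[str]:
        return self.frame.loc[self.frame["category"] == category, "marker"].tolist()


@dataclass
class CorrelationFrame:
    """Per-cohort (SGB x marker) partial-correlation results."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.rho.shape == self.p.shape == self.n.shape):
            raise ValidationError("rho/p/n shapes differ")


@dataclass
class AgreementResult:
    icc: float
    concordance_rho: float | None = None


@dataclass
class RankingTable:
    """Final per-SGB ranking with per-(cohort, category) percentiles.

    ``table`` is indexed by sgb_id with columns ``health_rank``,
    ``diet_rank``, ``n_cohorts_health``, ``n_cohorts_diet`` plus one
    ``<cohort>|<category>`` percentile column per combination present.
    """

    table: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("health_rank", "diet_rank"):
            if col not in self.table.columns:
                raise ValidationError(f"ranking table missing {col!r}")
            vals = self.table[col].dropna()
            if len(vals) and ((vals <= 0).any() or (vals > 1).any()):
                raise ValidationError(f"{col} values must lie in (0, 1]")

    def ranks(self, which: str = "health") -> pd.Series:
        if which not in {"health", "diet"}:
            raise ValidationError("which must be 'health' or 'diet'")
        return self.table[f"{which}_rank"].dropna()


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_spearman(x, y, covariates=None):
    """Partial Spearman correlation of ``x`` and ``y`` given covariates.

    Computed as the Pearson correlation of the residuals of the
    average-tie rank transforms of ``x`` and ``y``, each regressed on the
    rank transforms of the covariates plus an intercept.  With no
    covariates this is exactly the plain Spearman correlation.  The
    p-value uses the t distribution with n - 2 - k degrees of freedom
    (k = number of covariates).

    Rows with a missing value in x, y or any covariate are dropped
    pairwise.  Zeros in abundance vectors are ordinary (tied) values,
    not missing.

    Returns
    -------
    (rho, p, n_complete)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    if not (len(x) == len(y) == len(cov)):
        raise ValidationError("x, y and covariates must share the sample index")
    keep = np.isfinite(x) & np.isfinite(y)
    if cov.shape[1]:
        keep &= np.isfinite(cov).all(axis=1)
    x, y, cov = x[keep], y[keep], cov[keep]
    n, k = len(x), cov.shape[1]
    if n < max(8, k + 3):
        raise InsufficientDataError(f"only {n} complete cases for {k} covariates")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector after deletion")

    design = np.column_stack([np.ones(n)] + [_rank(cov[:, j]) for j in range(k)])
    rx = _residualize(_rank(x), design)
    ry = _residualize(_rank(y), design)
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise UndefinedCorrelationError("covariates absorb all rank variation")
    rho = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df))
    return rho, p, n


def correlate_all(
    table: AbundanceTable,
    markers: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    min_n: int = MIN_CELL_N,
) -> CorrelationFrame:
    """Partial Spearman of every SGB against every marker.

    ``markers`` is a sample x marker DataFrame (missing values allowed);
    ``covariates`` a sample x covariate DataFrame (typically sex, age,
    BMI).  Complete cases are resolved per marker: a row enters a
    marker's correlations when the marker and all covariates are present.
    Cells with fewer than ``min_n`` complete cases are flagged missing
    (NaN) rather than reported.

    All SGBs are residualized against the covariates jointly per marker,
    which is algebraically identical to calling :func:`partial_spearman`
    cell by cell but runs in one pass.
    """
    shared = table.data.index.intersection(markers.index)
    if shared.empty:
        raise ValidationError("no overlapping samples between table and markers")
    abund = table.data.loc[shared]
    markers = markers.loc[shared]
    if covariates is not None:
        covariates = covariates.loc[shared]
        cov_arr = covariates.to_numpy(dtype=float)
    else:
        cov_arr = np.empty((len(shared), 0))
    k = cov_arr.shape[1]
    sgbs = abund.columns
    rho = pd.DataFrame(np.nan, index=sgbs, columns=markers.columns)
    pmat = pd.DataFrame(np.nan, index=sgbs, columns=markers.columns)
    nmat = pd.DataFrame(0, index=sgbs, columns=markers.columns, dtype=int)

    X = abund.to_numpy(dtype=float)
    for marker in markers.columns:
        yv = markers[marker].to_numpy(dtype=float)
        keep = np.isfinite(yv)
        if k:
            keep &= np.isfinite(cov_arr).all(axis=1)
        n = int(keep.sum())
        nmat[marker] = n
        if n < max(min_n, k + 3) or np.ptp(yv[keep]) == 0:
            continue
        Xs = X[keep]
        design = np.column_stack(
            [np.ones(n)] + [_rank(cov_arr[keep, j]) for j in range(k)]
        )
        rX = np.apply_along_axis(_rank, 0, Xs) if Xs.size else Xs
        rX = rX - design @ np.linalg.lstsq(design, rX, rcond=None)[0]
        ry = _residualize(_rank(yv[keep]), design)
        ss_x = (rX * rX).sum(axis=0)
        ss_y = ry @ ry
        constant = np.ptp(Xs, axis=0) == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (rX.T @ ry) / np.sqrt(ss_x * ss_y)
        r[constant] = np.nan
        r = np.clip(r, -1.0, 1.0)
        df = n - 2 - k
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt(df / (1.0 - r * r))
        pv = 2 * stats.t.sf(np.abs(t), df)
        pv[np.abs(r) >= 1.0] = 0.0
        rho[marker] = r
        pmat[marker] = pv
    return CorrelationFrame(rho=rho, p=pmat, n=nmat)


def marker_percentiles(frame: CorrelationFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Convert oriented correlations to percentiles in (0, 1] per marker.

    Oriented score = direction * rho; SGBs are sorted by descending
    oriented score and assigned percentile = average-tie rank / n, so the
    SGB most favourably correlated with health gets the smallest
    percentile and ties share the average rank.  Missing cells stay
    missing.
    """
    out = pd.DataFrame(np.nan, index=frame.rho.index, columns=frame.rho.columns)
    for marker in frame.rho.columns:
        direction = panel.direction(marker)
        oriented = direction * frame.rho[marker].to_numpy(dtype=float)
        valid = np.isfinite(oriented)
        n = int(valid.sum())
        if n == 0:
            continue
        ranks = stats.rankdata(-oriented[valid], method="average")
        col = np.full(len(oriented), np.nan)
        col[valid] = ranks / n
        out[marker] = col
    return out


def build_ranking(
    cohort_percentiles: dict[str, pd.DataFrame],
    panel: MarkerPanel,
    min_cohorts: int = 2,
    taxonomy: dict[str, str] | None = None,
) -> RankingTable:
    """Aggregate per-cohort marker percentiles into the final rankings.

    Per cohort: each category's mean percentile over its markers (mean
    over available entries); the cohort health value is the unweighted
    mean of the non-dietary category means present.  The final
    health-rank averages cohort health values over the cohorts where the
    SGB was ranked, and is reported only when that count reaches
    ``min_cohorts``; likewise the diet-rank from the dietary category.
    """
    if not cohort_percentiles:
        raise ValidationError("need at least one cohort")
    if min_cohorts < 1:
        raise ValidationError("min_cohorts must be >= 1")
    all_sgbs = sorted(set().union(*[p.index for p in cohort_percentiles.values()]))
    index = pd.Index(all_sgbs, name="sgb_id")

    cat_cols: dict[str, pd.Series] = {}
    health_by_cohort = pd.DataFrame(index=index, dtype=float)
    diet_by_cohort = pd.DataFrame(index=index, dtype=float)
    for cohort, perc in cohort_percentiles.items():
        cat_means: dict[str, pd.Series] = {}
        for category in CATEGORIES:
            cols = [m for m in panel.markers_in(category) if m in perc.columns]
            if not cols:
                continue
            mean = perc[cols].mean(axis=1, skipna=True).reindex(index)
            if mean.notna().any():
                cat_means[category] = mean
                cat_cols[f"{cohort}|{category}"] = mean
        health_cats = [cat_means[c] for c in HEALTH_CATEGORIES if c in cat_means]
        if health_cats:
            health_by_cohort[cohort] = pd.concat(health_cats, axis=1).mean(
                axis=1, skipna=True
            )
        if "dietary" in cat_means:
            diet_by_cohort[cohort] = cat_means["dietary"]

    def _final(per_cohort: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        n = per_cohort.notna().sum(axis=1)
        mean = per_cohort.mean(axis=1, skipna=True)
        mean[n < min_cohorts] = np.nan
        return mean, n

    health_rank, n_health = _final(health_by_cohort)
    diet_rank, n_diet = _final(diet_by_cohort)
    out = pd.DataFrame(
        {
            "health_rank": health_rank,
            "diet_rank": diet_rank,
            "n_cohorts_health": n_health.astype(int),
            "n_cohorts_diet": n_diet.astype(int),
        },
        index=index,
    )
    for name, col in cat_cols.items():
        out[name] = col
    # SGBs ranked in zero cohorts are absent from the output.
    ranked = (out["n_cohorts_health"] > 0) | (out["n_cohorts_diet"] > 0)
    return RankingTable(out.loc[ranked], taxonomy or {})


def icc_agreement(rank_matrix: pd.DataFrame) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Rows are SGBs (targets), columns are cohorts (raters).  Rows with any
    missing value are dropped.  Computed from the two-way ANOVA mean
    squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Also reports the mean pairwise Spearman correlation across columns.
    """
    m = rank_matrix.dropna(axis=0, how="any")
    n, k = m.shape
    if k < 2:
        raise InsufficientDataError("need at least two columns (raters)")
    if n < 3:
        raise InsufficientDataError("need at least three complete rows")
    x = m.to_numpy(dtype=float)
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    pairs = [
        stats.spearmanr(x[:, i], x[:, j]).statistic
        for i in range(k)
        for j in range(i + 1, k)
    ]
    return AgreementResult(icc=float(icc), concordance_rho=float(np.mean(pairs)))


def rank_concordance(rank_a: pd.Series, rank_b: pd.Series) -> float:
    """Plain Spearman (average ties) between two rank vectors on shared ids."""
    shared = rank_a.dropna().index.intersection(rank_b.dropna().index)
    if len(shared) < 8:
        raise InsufficientDataError(f"only {len(shared)} shared SGBs")
    return float(stats.spearmanr(rank_a.loc[shared], rank_b.loc[shared]).statistic)


def write_ranking(ranking: RankingTable, path) -> None:
    out = ranking.table.copy()
    out.insert(0, "taxonomy", [ranking.taxonomy.get(s, "") for s in out.index])
    out.to_csv(path, sep="\t", index_label="sgb_id", float_format="%.10g")


def read_ranking(path) -> RankingTable:
    """Read a ranking TSV; accepts the minimal published columns too."""
    df = pd.read_csv(path, sep="\t")
    if "sgb_id" not in df.columns:
        raise ValidationError("ranking table needs an sgb_id column")
    df = df.set_index("sgb_id")
    taxonomy = {}
    if "taxonomy" in df.columns:
        taxonomy = {
            s: t for s, t in df["taxonomy"].dropna().items() if isinstance(t, str) and t
        }
        df = df.drop(columns="taxonomy")
    for col in ("health_rank", "diet_rank"):
        if col not in df.columns:
            df[col] = np.nan
    return RankingTable(df, taxonomy)
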