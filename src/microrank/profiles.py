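"""Abundance tables, metadata frames, filters and alpha diversity.

The central measurement object is :class:`AbundanceTable`, a thin wrapper
around a samples x species DataFrame of relative abundances stored as
fractions in [0, 1].  MetaPhlAn-style merged profile tables (percentages on
the 0-100 scale, one row per clade) are converted at the I/O boundary; all
downstream statistics (arcsine square-root transform, scoring weights)
operate on fractions.

Species units are SGBs (species-level genome bins, 95% ANI clusters of
isolate genomes and MAGs); identifiers like ``SGB4816`` or ``SGB4816_group``
are carried verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "AbundanceTable",
    "CohortSelectionRules",
    "read_merged_profiles",
    "write_merged_profiles",
    "read_metadata",
    "write_metadata",
    "prevalence_filter",
    "arcsin_sqrt",
    "alpha_diversity",
    "bmi_category",
    "select_public_cohorts",
    "BMI_BREAKS",
    "BMI_LABELS",
]

#: Half-open BMI category edges: [18.5, 25) healthy weight, [25, 30)
#: overweight, [30, inf) obese.  Underweight (<18.5) is excluded upstream.
BMI_BREAKS = (18.5, 25.0, 30.0)
BMI_LABELS = ("healthy weight", "overweight", "obese")

# Rank prefixes of the MetaPhlAn clade-name dialect, most specific last.
_LEVEL_PREFIX = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
    "sgb": "t__",
}

_SUM_TOL = 1e-6


@dataclass
class AbundanceTable:
    """Samples x SGBs relative-abundance matrix (fractions in [0, 1]).

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one column per SGB id.
        Values are fractions; per-sample sums may be below 1 (unclassified
        remainder) but never exceed 1 beyond numerical tolerance.
    taxonomy
        Optional mapping from SGB id to its full clade string, preserved
        from the source file for round-tripping.
    """

    data: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate SGB ids: {dups}")
        values = df.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ValidationError("negative abundance value")
        if values.size:
            sums = np.nansum(values, axis=1)
            bad = np.flatnonzero(sums > 1.0 + _SUM_TOL)
            if bad.size:
                raise ValidationError(
                    f"per-sample abundance sum exceeds 1: {df.index[bad[0]]!r}"
                )
        self.data = df.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sgb_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_sgbs(self) -> int:
        return self.data.shape[1]

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each SGB is present (abundance > 0)."""
        if self.n_samples == 0:
            raise ValidationError("empty table")
        return (self.data > 0).mean(axis=0)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)], self.taxonomy)


@dataclass
class CohortSelectionRules:
    """Eligibility rules for public-cohort meta-analyses.

    Defaults mirror the study-selection filters used for the public
    validation cohorts: adults (>= 16 y), BMI >= 18.5, sex recorded,
    cohorts of at least 30 eligible people, and at least 15 samples per
    arm of any within-cohort comparison.
    """

    min_age: float = 16.0
    min_bmi: float = 18.5
    min_cohort_n: int = 30
    min_stratum_n: int = 15
    bmi_breaks: tuple[float, ...] = BMI_BREAKS

    def __post_init__(self) -> None:
        if list(self.bmi_breaks) != sorted(set(self.bmi_breaks)):
            raise ValidationError("bmi_breaks must be strictly increasing")
        if self.min_cohort_n <= 0 or self.min_stratum_n <= 0:
            raise ValidationError("minimum counts must be positive")


def read_merged_profiles(path, level: str = "sgb") -> AbundanceTable:
    """Read a MetaPhlAn-style merged profile TSV into an AbundanceTable.

    The dialect: first column is the clade name (header ``clade_name``,
    possibly prefixed with ``#``), an optional NCBI taxon-id column is
    tolerated and ignored, and every remaining column is one sample with
    relative abundances as percentages on the 0-100 scale.

    Only rows *terminating* at the requested taxonomic level are retained
    (for the default SGB level: clade names whose last component carries
    the ``t__`` prefix).  Values are divided by 100.  ``_group``-suffixed
    SGB labels are preserved verbatim.
    """
    prefix = _LEVEL_PREFIX.get(level.lower())
    if prefix is None:
        raise ValidationError(f"unknown taxonomic level: {level!r}")
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    if df.shape[1] < 1:
        raise FormatError("empty profile table")
    first = str(df.columns[0]).lstrip("#").strip().lower()
    if first not in {"clade_name", "clade", "taxonomy", "id"}:
        raise FormatError(
            f"first column must be the clade name, got {df.columns[0]!r}"
        )
    clade_col = df.columns[0]
    drop = [c for c in df.columns[1:] if str(c).strip().lower()
            in {"ncbi_tax_id", "clade_taxid", "ncbi_taxid"}]
    sample_cols = [c for c in df.columns[1:] if c not in drop]

    mask = df[clade_col].str.split("|").str[-1].str.startswith(prefix)
    rows = df.loc[mask]
    if rows.empty:
        warnings.warn(
            f"no rows terminate at level {level!r}; returning an empty table",
            stacklevel=2,
        )
        empty = pd.DataFrame(
            index=pd.Index([str(c) for c in sample_cols], name="sample_id"),
            columns=pd.Index([], name="sgb_id"),
            dtype=float,
        )
        return AbundanceTable(empty)

    clades = rows[clade_col].tolist()
    ids = [c.split("|")[-1].removeprefix(prefix) for c in clades]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate SGB id: {dup!r}")
    try:
        values = rows[sample_cols].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance value: {exc}") from exc
    if np.nanmin(values) < 0:
        raise ValidationError("negative abundance value")
    data = pd.DataFrame(
        values.T / 100.0,
        index=pd.Index([str(c) for c in sample_cols], name="sample_id"),
        columns=pd.Index(ids, name="sgb_id"),
    )
    taxonomy = dict(zip(ids, clades))
    return AbundanceTable(data, taxonomy)


def write_merged_profiles(table: AbundanceTable, path) -> None:
    """Write an AbundanceTable back to the merged-profile TSV dialect.

    Inverse of :func:`read_merged_profiles`: fractions are multiplied by
    100 and clade names are restored from the stored taxonomy (or a bare
    ``t__<id>`` when none was recorded).
    """
    clades = [table.taxonomy.get(s, f"t__{s}") for s in table.sgb_ids]
    out = pd.DataFrame(
        table.data.to_numpy().T * 100.0,
        index=pd.Index(clades, name="clade_name"),
        columns=table.sample_ids,
    )
    out.to_csv(path, sep="\t", float_format="%.10g")


_META_REQUIRED = ["sample_id", "cohort_id", "sex", "age", "bmi"]


def read_metadata(path) -> pd.DataFrame:
    """Read a per-sample metadata TSV (one row per sample).

    Required columns: sample_id, cohort_id, sex, age, bmi.  Optional:
    subject_id, twin_group, country, sequencing_depth, status, timepoint.
    """
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_REQUIRED if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    if (meta["age"].dropna() < 0).any():
        raise ValidationError("negative age")
    if (meta["bmi"].dropna() <= 0).any():
        raise ValidationError("non-positive BMI")
    return meta.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format="%.10g")


def prevalence_filter(table: AbundanceTable, threshold: float) -> AbundanceTable:
    """Retain SGBs whose prevalence is strictly greater than ``threshold``.

    Prevalence is the fraction of samples with abundance > 0.  The strict
    inequality means a species present in exactly 20% of samples is
    dropped at threshold 0.2.  The sample set is unchanged.
    """
    if not 0 <= threshold < 1:
        raise ValidationError("threshold must be in [0, 1)")
    if table.n_samples == 0 or table.n_sgbs == 0:
        raise ValidationError("empty table")
    prev = table.prevalence()
    keep = prev.index[prev > threshold]
    return AbundanceTable(table.data[list(keep)], table.taxonomy)


def arcsin_sqrt(x):
    """Arcsine square-root transform of a fraction (vectorized).

    Maps [0, 1] monotonically onto [0, pi/2]; the standard
    variance-stabilizing transform for relative abundances.  Values in
    (1, 1 + 1e-6] are clamped to 1 to absorb closure round-off.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1 + _SUM_TOL):
        raise ValidationError("arcsin_sqrt domain is [0, 1]")
    out = np.arcsin(np.sqrt(np.minimum(arr, 1.0)))
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample richness and Shannon entropy (nats).

    Richness counts SGBs with abundance > 0.  Shannon entropy is
    -sum(p log p) over the nonzero fractions renormalized to sum to 1,
    so it is invariant to the unclassified remainder.  An all-zero
    sample gets richness 0 and entropy 0.
    """
    if table.n_samples == 0:
        raise ValidationError("empty table")
    values = table.data.to_numpy(dtype=float)
    richness = (values > 0).sum(axis=1)
    totals = values.sum(axis=1)
    shannon = np.zeros(len(richness))
    for i, total in enumerate(totals):
        if total > 0:
            p = values[i][values[i] > 0] / total
            shannon[i] = float(-(p * np.log(p)).sum())
    return pd.DataFrame(
        {"richness": richness.astype(int), "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def bmi_category(bmi: float) -> str:
    """BMI category on half-open intervals; callers pre-filter underweight."""
    if not np.isfinite(bmi) or bmi < BMI_BREAKS[0]:
        raise ValidationError(f"BMI {bmi} below {BMI_BREAKS[0]} (underweight excluded)")
    if bmi < BMI_BREAKS[1]:
        return BMI_LABELS[0]
    if bmi < BMI_BREAKS[2]:
        return BMI_LABELS[1]
    return BMI_LABELS[2]


def _eligible(meta: pd.DataFrame, rules: CohortSelectionRules) -> pd.DataFrame:
    ok = (
        meta["age"].ge(rules.min_age)
        & meta["bmi"].ge(rules.min_bmi)
        & meta["sex"].notna()
    )
    return meta.loc[ok.fillna(False)]


def select_public_cohorts(
    meta: pd.DataFrame,
    rules: CohortSelectionRules | None = None,
    mode: str = "bmi-comparison",
) -> pd.DataFrame:
    """Apply the public-cohort eligibility filters and enumerate strata.

    Samples failing the age/BMI/sex rules are dropped first; cohorts with
    fewer than ``min_cohort_n`` eligible samples are excluded entirely.

    ``bmi-comparison`` mode emits one row per (country, cohort,
    BMI-category pair) with both arms >= ``min_stratum_n``.
    ``case-control`` mode emits one row per cohort whose control and case
    arms (from the ``status`` column) both reach ``min_stratum_n``.
    """
    rules = rules or CohortSelectionRules()
    if mode not in {"bmi-comparison", "case-control"}:
        raise ValidationError(f"unknown mode: {mode!r}")
    meta = _eligible(meta, rules)
    counts = meta.groupby("cohort_id")["sample_id"].count()
    kept = counts.index[counts >= rules.min_cohort_n]
    meta = meta[meta["cohort_id"].isin(kept)]

    rows: list[dict] = []
    if mode == "bmi-comparison":
        cats = meta["bmi"].map(bmi_category)
        for cohort, sub in meta.groupby("cohort_id"):
            country = sub["country"].iloc[0] if "country" in sub else ""
            sizes = cats.loc[sub.index].value_counts()
            labels = [l for l in BMI_LABELS if sizes.get(l, 0) >= rules.min_stratum_n]
            for i, lo in enumerate(labels):
                for hi in labels[i + 1:]:
                    rows.append(
                        {
                            "country": country,
                            "cohort_id": cohort,
                            "group_low": lo,
                            "group_high": hi,
                            "n_low": int(sizes[lo]),
                            "n_high": int(sizes[hi]),
                        }
                    )
    else:
        if "status" not in meta.columns:
            raise ValidationError("case-control mode requires a status column")
        for cohort, sub in meta.groupby("cohort_id"):
            n_control = int((sub["status"] == "control").sum())
            n_case = int((sub["status"] != "control").sum())
            if min(n_control, n_case) >= rules.min_stratum_n:
                rows.append(
                    {
                        "country": sub["country"].iloc[0] if "country" in sub else "",
                        "cohort_id": cohort,
                        "n_control": n_control,
                        "n_case": n_case,
                    }
                )
    if not rows:
        warnings.warn("no stratum passes the selection rules", stacklevel=2)
        cols = (
            ["country", "cohort_id", "group_low", "group_high", "n_low", "n_high"]
            if mode == "bmi-comparison"
            else ["country", "cohort_id", "n_control", "n_case"]
        )
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
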