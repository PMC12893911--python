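"""Pre/post intervention differential abundance and rank-shift enrichment.

Within one trial arm, species prevalent at both timepoints (>= 10% by
default) are tested with a two-sided Wilcoxon signed-rank test on paired
abundances; effect size is the log2 ratio of mean endpoint over mean
baseline abundance; p-values are Benjamini-Hochberg adjusted.  The
significant species, split into increasing and decreasing, are then
compared on their health/diet ranks with a two-sided Mann-Whitney U test
to ask whether increasing species are more favourably ranked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .profiles import AbundanceTable
from .ranking import RankingTable

__all__ = [
    "prepost_differential",
    "bh_fdr",
    "rank_shift_enrichment",
    "EnrichmentResult",
]

#: Pseudocount guard for a degenerate zero mean in the log2 ratio; the
#: prevalence gate keeps it inert in practice.
_PSEUDOCOUNT = 1e-8

#: Largest number of informative (nonzero-difference) pairs for which the
#: exact signed-rank null distribution is used; above it, the normal
#: approximation with tie correction.
_EXACT_LIMIT = 25


@dataclass
class EnrichmentResult:
    u_statistic: float | None
    p: float | None
    median_increase: float | None
    median_decrease: float | None
    n_increase: int
    n_decrease: int
    n_unranked: int
    note: str | None = None


def _wilcoxon_paired(diff: np.ndarray) -> float:
    """Two-sided signed-rank p; zero differences dropped, average ties."""
    d = diff[diff != 0]
    if len(d) == 0:
        return 1.0
    ties = len(np.unique(np.abs(d))) < len(d)
    if len(d) <= _EXACT_LIMIT and not ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         correction=False, method=method)
    return float(res.pvalue)


def prepost_differential(
    baseline: AbundanceTable,
    endpoint: AbundanceTable,
    pairing: dict[str, str] | None = None,
    min_prev: float = 0.10,
) -> pd.DataFrame:
    """Paired differential abundance between baseline and endpoint.

    ``pairing`` maps baseline sample ids to endpoint sample ids; omitted,
    samples are paired by position.  Only SGBs with prevalence >=
    ``min_prev`` at BOTH timepoints are tested.  Returns one row per
    tested SGB: prevalences, means, log2 ratio of means, Wilcoxon p,
    BH-adjusted q, and direction.
    """
    if pairing is None:
        if baseline.n_samples != endpoint.n_samples:
            raise ValidationError("unpaired tables; give an explicit pairing")
        pairs = list(zip(baseline.sample_ids, endpoint.sample_ids))
    else:
        missing_b = [b for b in pairing if b not in baseline.data.index]
        missing_e = [e for e in pairing.values() if e not in endpoint.data.index]
        if missing_b or missing_e:
            raise ValidationError(
                f"unpaired subjects: baseline {missing_b}, endpoint {missing_e}"
            )
        if len(set(pairing.values())) != len(pairing):
            raise ValidationError("pairing is not one-to-one")
        pairs = list(pairing.items())
    b_ids, e_ids = zip(*pairs)
    shared = [s for s in baseline.sgb_ids if s in set(endpoint.sgb_ids)]
    b = baseline.data.loc[list(b_ids), shared]
    e = endpoint.data.loc[list(e_ids), shared]

    prev_b = (b > 0).mean(axis=0)
    prev_e = (e > 0).mean(axis=0)
    tested = [s for s in shared if prev_b[s] >= min_prev and prev_e[s] >= min_prev]

    rows = []
    for s in tested:
        xb = b[s].to_numpy()
        xe = e[s].to_numpy()
        mb, me = float(xb.mean()), float(xe.mean())
        ratio = (me or _PSEUDOCOUNT) / (mb or _PSEUDOCOUNT)
        log2_ratio = float(np.log2(ratio))
        p = _wilcoxon_paired(xe - xb)
        rows.append(
            {
                "sgb_id": s,
                "prev_base": float(prev_b[s]),
                "prev_end": float(prev_e[s]),
                "mean_base": mb,
                "mean_end": me,
                "log2_ratio": log2_ratio,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["sgb_id", "prev_base", "prev_end", "mean_base", "mean_end",
                 "log2_ratio", "p"],
    ).set_index("sgb_id")
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else np.nan
    out["direction"] = np.where(out["log2_ratio"] > 0, "increase", "decrease")
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rank_shift_enrichment(
    records: pd.DataFrame,
    ranking: RankingTable,
    q_threshold: float = 0.01,
    which: str = "health",
) -> EnrichmentResult:
    """Are significantly increasing species more favourably ranked?

    Splits records with q < ``q_threshold`` by direction, looks up their
    final ranks, and compares the two rank sets with a two-sided
    Mann-Whitney U test (average ties; exact for small sides).  Species
    lacking a final rank are excluded and counted.  A side with fewer
    than 3 ranked species yields an insufficient-data result, not an
    error.
    """
    ranks = ranking.ranks(which)
    sig = records[records["q"] < q_threshold]
    inc_ids = sig.index[sig["direction"] == "increase"]
    dec_ids = sig.index[sig["direction"] == "decrease"]
    inc = ranks.reindex(inc_ids).dropna()
    dec = ranks.reindex(dec_ids).dropna()
    n_unranked = (len(inc_ids) - len(inc)) + (len(dec_ids) - len(dec))
    if len(inc) < 3 or len(dec) < 3:
        return EnrichmentResult(
            u_statistic=None,
            p=None,
            median_increase=float(inc.median()) if len(inc) else None,
            median_decrease=float(dec.median()) if len(dec) else None,
            n_increase=len(inc),
            n_decrease=len(dec),
            n_unranked=int(n_unranked),
            note="insufficient ranked species on one side",
        )
    res = stats.mannwhitneyu(inc, dec, alternative="two-sided", method="auto")
    return EnrichmentResult(
        u_statistic=float(res.statistic),
        p=float(res.pvalue),
        median_increase=float(inc.median()),
        median_decrease=float(dec.median()),
        n_increase=len(inc),
        n_decrease=len(dec),
        n_unranked=int(n_unranked),
    )
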