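"""Score individual samples against a species ranking.

Each sample is summarized by: the number of the k most favourably and
most unfavourably ranked species it carries; their cumulative relative
abundances (arcsine square-root transformed after summation); and two
rank-sum indices over *all* ranked species present:

    rank_sum          = sum over present SGBs of s,  s = 1 - 2 * rank
    weighted_rank_sum = sum of s * arcsin(sqrt(abundance))

The normalization s maps ranks in (0, 1] onto [-1, 1) with favourable
(low-rank) species contributing positively, so healthier microbiomes get
HIGHER scores.  The sign convention is recorded in the output attrs so
downstream effect-size comparisons can be flipped consistently.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .profiles import AbundanceTable, arcsin_sqrt
from .ranking import RankingTable

__all__ = ["extreme_sets", "score_samples", "SCORE_SIGN_CONVENTION"]

SCORE_SIGN_CONVENTION = "favourable-positive"


def extreme_sets(
    ranking: RankingTable, k: int, which: str = "health"
) -> tuple[list[str], list[str]]:
    """The k most favourably and k most unfavourably ranked SGBs.

    Favourable = smallest final ranks, unfavourable = largest.  Ties at
    the boundary are broken by sgb_id lexicographic order inside a single
    stable sort, so the resolution is deterministic and the two sets are
    disjoint whenever 2k <= number of ranked SGBs.
    """
    ranks = ranking.ranks(which)
    if len(ranks) < 2 * k:
        raise ValidationError(
            f"need at least {2 * k} ranked SGBs, have {len(ranks)}"
        )
    order = ranks.sort_index().sort_values(kind="stable")
    ordered = list(order.index)
    return ordered[:k], ordered[-k:][::-1]


def score_samples(
    table: AbundanceTable,
    ranking: RankingTable,
    k: int = 50,
    which: str = "health",
) -> pd.DataFrame:
    """Per-sample score report against the ``which`` ranking.

    "Present" means abundance strictly > 0.  Cumulative set abundances
    are clamped to 1 before the arcsine square-root transform (closure
    round-off).  Samples sharing no SGB with the ranking get all-zero
    scores and a warning.
    """
    ranks = ranking.ranks(which)
    shared = [s for s in table.sgb_ids if s in ranks.index]
    fav, unfav = extreme_sets(ranking, k, which)
    if not shared:
        warnings.warn("no overlap between table SGBs and ranked SGBs", stacklevel=2)
        zeros = np.zeros(table.n_samples)
        return pd.DataFrame(
            {
                "fav_count": zeros.astype(int),
                "unfav_count": zeros.astype(int),
                "fav_cum": zeros,
                "unfav_cum": zeros,
                "fav_cum_asin": zeros,
                "unfav_cum_asin": zeros,
                "rank_sum": zeros,
                "weighted_rank_sum": zeros,
            },
            index=pd.Index(table.sample_ids, name="sample_id"),
        )

    abund = table.data[shared]
    present = (abund > 0).to_numpy()
    s = (1.0 - 2.0 * ranks.loc[shared]).to_numpy()
    rank_sum = present @ s
    weighted = (arcsin_sqrt(abund.to_numpy()) * present) @ s

    fav_in = [c for c in fav if c in table.data.columns]
    unfav_in = [c for c in unfav if c in table.data.columns]
    fav_abund = table.data[fav_in].to_numpy() if fav_in else np.zeros((table.n_samples, 0))
    unfav_abund = (
        table.data[unfav_in].to_numpy() if unfav_in else np.zeros((table.n_samples, 0))
    )
    fav_cum = np.minimum(fav_abund.sum(axis=1), 1.0)
    unfav_cum = np.minimum(unfav_abund.sum(axis=1), 1.0)
    out = pd.DataFrame(
        {
            "fav_count": (fav_abund > 0).sum(axis=1).astype(int),
            "unfav_count": (unfav_abund > 0).sum(axis=1).astype(int),
            "fav_cum": fav_cum,
            "unfav_cum": unfav_cum,
            "fav_cum_asin": arcsin_sqrt(fav_cum),
            "unfav_cum_asin": arcsin_sqrt(unfav_cum),
            "rank_sum": rank_sum,
            "weighted_rank_sum": weighted,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    out.attrs["sign_convention"] = SCORE_SIGN_CONVENTION
    out.attrs["k"] = k
    out.attrs["which"] = which
    return out
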