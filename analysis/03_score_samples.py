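#!/usr/bin/env python
"""Score every simulated sample against the health ranking.

For each sample: counts and cumulative abundances of the 50 most
favourably and unfavourably ranked species, and the (weighted) rank-sum
health scores over all ranked species present.  Summarizes the score
distribution per cohort.
"""

import sys
from pathlib import Path

import pandas as pd

from microrank.pipeline import run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 17
OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    run_pipeline({"score": {"k": 50}}, OUT, SEED)
    scores = pd.read_csv(OUT / "scores.tsv", sep="\t", index_col="sample_id")
    print(f"scored {len(scores)} samples; wrote {OUT / 'scores.tsv'}")
    summary = scores.groupby("cohort_id")[
        ["fav_count", "unfav_count", "rank_sum", "weighted_rank_sum"]
    ].mean()
    print("\nper-cohort means:")
    print(summary.round(3).to_string())


if __name__ == "__main__":
    main()
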