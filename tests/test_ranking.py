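import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microrank.errors import (
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)
from microrank.profiles import AbundanceTable
from microrank.ranking import (
    MarkerPanel,
    build_ranking,
    correlate_all,
    icc_agreement,
    marker_percentiles,
    partial_spearman,
    rank_concordance,
)


def rank_residual_oracle(x, y, cov):
    """Independent brute-force path: ranks, two explicit OLS
    residualizations, then a Pearson correlation."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack(
        [np.ones(len(x))] + [stats.rankdata(c) for c in np.atleast_2d(cov.T)]
        if cov is not None and cov.size
        else [np.ones(len(x))]
    )
    bx = np.linalg.pinv(design) @ rx
    by = np.linalg.pinv(design) @ ry
    ex, ey = rx - design @ bx, ry - design @ by
    return float(stats.pearsonr(ex, ey).statistic)


class TestPartialSpearman:
    def test_identity_gives_one(self):
        x = np.arange(10.0)
        rho, p, n = partial_spearman(x, x)
        assert rho == pytest.approx(1.0)
        assert p == 0.0 and n == 10

    def test_monotone_transform_of_negation(self):
        x = np.arange(12.0)
        y = np.exp(-x)  # strictly decreasing transform of x
        rho, _, _ = partial_spearman(x, y)
        assert rho == pytest.approx(-1.0)

    def test_matches_brute_force_oracle_with_covariate(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=12)
        z = rng.normal(size=12)
        y = 0.5 * x + z + rng.normal(size=12)
        rho, _, _ = partial_spearman(x, y, z)
        assert rho == pytest.approx(rank_residual_oracle(x, y, z[:, None]), abs=1e-10)

    def test_no_covariates_equals_plain_spearman(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(9, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, p, _ = partial_spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_independent_covariate_barely_changes_rho(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        plain, _, _ = partial_spearman(x, y)
        adj, _, _ = partial_spearman(x, y, z)
        assert abs(plain - adj) < 0.05

    def test_pairwise_deletion_and_zero_retention(self):
        x = np.array([0, 0, 0, 1, 2, 3, 4, 5, 6, np.nan], dtype=float)
        y = np.arange(10, dtype=float)
        rho, _, n = partial_spearman(x, y)
        assert n == 9
        assert rho > 0.9  # zeros entered as ties, not dropped

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            partial_spearman(np.ones(10), np.arange(10.0))

    def test_insufficient_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            partial_spearman(np.arange(5.0), np.arange(5.0))

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        n = 60
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "c1": rng.normal(size=n),
                "c2": rng.normal(size=n),
            }
        )
        df["y"] += 0.4 * df["x"] + 0.5 * df["c1"]
        rho, p, _ = partial_spearman(df["x"], df["y"], df[["c1", "c2"]])
        ref = pingouin.partial_corr(
            df, x="x", y="y", covar=["c1", "c2"], method="spearman"
        )
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-3)


class TestCorrelateAll:
    @staticmethod
    def _setup(n=80, n_sgb=5, n_marker=3, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        abund = pd.DataFrame(
            rng.dirichlet(np.ones(n_sgb) * 0.5, size=n) * 0.9,
            index=idx, columns=[f"SGB{j}" for j in range(n_sgb)],
        )
        markers = pd.DataFrame(
            rng.normal(size=(n, n_marker)), index=idx,
            columns=[f"m{j}" for j in range(n_marker)],
        )
        covs = pd.DataFrame(
            {"sex": rng.integers(0, 2, n), "age": rng.normal(50, 10, n)}, index=idx
        )
        return AbundanceTable(abund), markers, covs

    def test_one_cell_per_pair(self):
        table, markers, covs = self._setup()
        frame = correlate_all(table, markers, covs, min_n=30)
        assert frame.rho.shape == (5, 3)
        assert frame.rho.notna().all().all()

    def test_fast_path_matches_cellwise_partial_spearman(self):
        table, markers, covs = self._setup(seed=4)
        frame = correlate_all(table, markers, covs, min_n=30)
        for sgb in table.sgb_ids:
            for m in markers.columns:
                rho, p, _ = partial_spearman(
                    table.data[sgb], markers[m], covs
                )
                assert frame.rho.loc[sgb, m] == pytest.approx(rho, abs=1e-10)
                assert frame.p.loc[sgb, m] == pytest.approx(p, rel=1e-8)

    def test_all_missing_marker_flagged_others_unaffected(self):
        table, markers, covs = self._setup()
        markers["m1"] = np.nan
        frame = correlate_all(table, markers, covs, min_n=30)
        assert frame.rho["m1"].isna().all()
        assert frame.rho["m0"].notna().all()

    def test_below_min_n_flagged_missing(self):
        table, markers, covs = self._setup(n=40)
        markers.loc[markers.index[:20], "m2"] = np.nan
        frame = correlate_all(table, markers, covs, min_n=30)
        assert frame.rho["m2"].isna().all()
        assert (frame.n["m2"] == 20).all()

    def test_no_overlap_rejected(self):
        table, markers, covs = self._setup()
        markers.index = pd.Index([f"z{i}" for i in range(len(markers))])
        with pytest.raises(ValidationError):
            correlate_all(table, markers, covs)


class TestMarkerPercentiles:
    @staticmethod
    def _frame(rhos, marker="m", direction=+1):
        from microrank.ranking import CorrelationFrame

        idx = [f"SGB{i}" for i in range(len(rhos))]
        rho = pd.DataFrame({marker: rhos}, index=idx)
        panel = MarkerPanel.from_records([(marker, "fasting", direction)])
        return CorrelationFrame(rho, rho * 0, rho * 0 + 100), panel

    def test_hand_ranking(self):
        frame, panel = self._frame([0.9, 0.1, -0.4])
        out = marker_percentiles(frame, panel)
        assert list(out["m"]) == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_ties_share_average_rank(self):
        frame, panel = self._frame([0.5, 0.5, -0.1, -0.2])
        out = marker_percentiles(frame, panel)
        assert out["m"].iloc[0] == out["m"].iloc[1] == pytest.approx(1.5 / 4)

    def test_sign_flip_reverses_order(self):
        rhos = [0.8, 0.3, -0.2, -0.6, 0.05]
        frame, panel = self._frame(rhos)
        fwd = marker_percentiles(frame, panel)["m"].to_numpy()
        frame2, panel2 = self._frame([-r for r in rhos])
        rev = marker_percentiles(frame2, panel2)["m"].to_numpy()
        n = len(rhos)
        assert rev == pytest.approx((n + 1) / n - fwd)

    def test_negative_marker_direction_orients(self):
        frame, panel = self._frame([0.9, -0.9], direction=-1)
        out = marker_percentiles(frame, panel)
        # for a harmful marker, a negative correlation is favourable
        assert out["m"].iloc[1] < out["m"].iloc[0]

    def test_distinct_scores_give_full_percentile_grid(self):
        rng = np.random.default_rng(8)
        rhos = rng.uniform(-1, 1, size=9)
        frame, panel = self._frame(list(rhos))
        out = marker_percentiles(frame, panel)["m"]
        assert sorted(out) == pytest.approx([i / 9 for i in range(1, 10)])


class TestBuildRanking:
    @staticmethod
    def _percentiles(values_by_cohort, marker="m"):
        return {
            cohort: pd.DataFrame({marker: vals},
                                 index=[f"SGB{i}" for i in range(len(vals))])
            for cohort, vals in values_by_cohort.items()
        }

    def test_mean_over_present_cohorts(self):
        panel = MarkerPanel.from_records([("m", "fasting", 1)])
        percs = self._percentiles({"A": [0.2], "B": [0.4]})
        ranking = build_ranking(percs, panel, min_cohorts=2)
        assert ranking.table.loc["SGB0", "health_rank"] == pytest.approx(0.3)
        assert ranking.table.loc["SGB0", "n_cohorts_health"] == 2

    def test_single_cohort_below_retention_gets_no_rank(self):
        panel = MarkerPanel.from_records([("m", "fasting", 1)])
        percs = self._percentiles({"A": [0.2, 0.8]})
        percs["B"] = pd.DataFrame({"m": [0.3]}, index=["SGB0"])
        ranking = build_ranking(percs, panel, min_cohorts=2)
        assert np.isnan(ranking.table.loc["SGB1", "health_rank"])
        assert ranking.table.loc["SGB0", "health_rank"] == pytest.approx(0.25)

    def test_identical_cohorts_idempotent(self):
        panel = MarkerPanel.from_records([("m", "personal", 1)])
        percs = self._percentiles({"A": [0.7, 0.1], "B": [0.7, 0.1], "C": [0.7, 0.1]})
        ranking = build_ranking(percs, panel, min_cohorts=2)
        assert ranking.table["health_rank"].tolist() == pytest.approx([0.7, 0.1])

    def test_dietary_category_feeds_diet_rank_only(self):
        panel = MarkerPanel.from_records(
            [("m", "fasting", 1), ("diet_m", "dietary", 1)]
        )
        idx = ["SGB0"]
        percs = {
            "A": pd.DataFrame({"m": [0.2], "diet_m": [0.9]}, index=idx),
            "B": pd.DataFrame({"m": [0.4], "diet_m": [0.7]}, index=idx),
        }
        ranking = build_ranking(percs, panel, min_cohorts=2)
        assert ranking.table.loc["SGB0", "health_rank"] == pytest.approx(0.3)
        assert ranking.table.loc["SGB0", "diet_rank"] == pytest.approx(0.8)

    def test_category_then_cohort_averaging_order(self):
        # two fasting markers and one personal: category means first,
        # then the unweighted mean of the two category means
        panel = MarkerPanel.from_records(
            [("f1", "fasting", 1), ("f2", "fasting", 1), ("p1", "personal", 1)]
        )
        percs = {
            "A": pd.DataFrame({"f1": [0.2], "f2": [0.4], "p1": [0.9]}, index=["SGB0"])
        }
        ranking = build_ranking(percs, panel, min_cohorts=1)
        assert ranking.table.loc["SGB0", "health_rank"] == pytest.approx(
            ((0.2 + 0.4) / 2 + 0.9) / 2
        )


class TestIccAgreement:
    def test_identical_columns_give_one(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(size=20)
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        assert icc_agreement(m).icc == pytest.approx(1.0)

    def test_matches_hand_anova_oracle(self):
        # 6 targets x 3 raters; oracle computed from the ANOVA table
        m = pd.DataFrame(
            [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]],
            columns=["r1", "r2", "r3"], dtype=float,
        )
        x = m.to_numpy()
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((x - grand) ** 2).sum()
            - k * ((x.mean(1) - grand) ** 2).sum()
            - n * ((x.mean(0) - grand) ** 2).sum()
        ) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_agreement(m).icc == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(14)
        m = pd.DataFrame(rng.uniform(size=(12, 4)), columns=list("abcd"))
        long = m.reset_index().melt(id_vars="index", var_name="rater",
                                    value_name="score")
        ref = pingouin.intraclass_corr(
            long, targets="index", raters="rater", ratings="score"
        )
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_agreement(m).icc == pytest.approx(icc2, abs=1e-9)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.uniform(size=(200, 3)))
        assert abs(icc_agreement(m).icc) < 0.15

    def test_too_few_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            icc_agreement(pd.DataFrame([[1.0, 2.0], [3.0, 4.0]]))


class TestRankConcordance:
    def test_identity_and_reversal(self):
        a = pd.Series(np.linspace(0.1, 0.9, 10), index=[f"S{i}" for i in range(10)])
        assert rank_concordance(a, a) == pytest.approx(1.0)
        assert rank_concordance(a, 1 - a) == pytest.approx(-1.0)

    def test_disjoint_ids_rejected(self):
        a = pd.Series(np.linspace(0, 1, 10), index=[f"A{i}" for i in range(10)])
        b = pd.Series(np.linspace(0, 1, 10), index=[f"B{i}" for i in range(10)])
        with pytest.raises(InsufficientDataError):
            rank_concordance(a, b)


class TestMarkerPanel:
    def test_duplicate_and_bad_category_rejected(self):
        with pytest.raises(ValidationError):
            MarkerPanel.from_records([("m", "fasting", 1), ("m", "dietary", 1)])
        with pytest.raises(ValidationError):
            MarkerPanel.from_records([("m", "weird", 1)])
        with pytest.raises(ValidationError):
            MarkerPanel.from_records([("m", "fasting", 2)])
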