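"""Size classes, correlation screen, rank tests, mixed and odds models."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from tailnet.data import ValidationError
from tailnet.inference import (
    aggregate_size_class,
    assign_size_classes,
    compare_models_aic,
    correlation_screen,
    fit_metric_lmm,
    fit_ordinal_mts,
    fit_victim_logit,
    kruskal_wallis,
)


class TestSizeClasses:
    def test_standard_eight_pig_split(self):
        weights = {f"p{i}": 10.0 * (i + 1) for i in range(8)}
        classes = assign_size_classes(weights)
        assert [classes[f"p{i}"] for i in range(8)] == (
            ["small"] * 3 + ["medium"] * 2 + ["large"] * 3
        )

    def test_ties_break_by_pig_id(self):
        classes = assign_size_classes({f"p{i}": 50.0 for i in range(8)})
        assert [classes[f"p{i}"] for i in range(8)] == (
            ["small"] * 3 + ["medium"] * 2 + ["large"] * 3
        )

    def test_proportional_split_other_pen_sizes(self):
        classes = assign_size_classes({f"p{i}": float(i) for i in range(6)})
        sizes = [list(classes.values()).count(c) for c in ("small", "medium", "large")]
        assert sum(sizes) == 6 and sizes[0] == sizes[2]

    @pytest.mark.parametrize(
        "history,expected",
        [
            (["small", "small", "medium"], "small"),   # modal
            (["small", "medium", "medium"], "medium"),
            (["small", "medium", "large"], "medium"),  # tie -> middle period
        ],
    )
    def test_aggregated_class(self, history, expected):
        assert aggregate_size_class(history) == expected


class TestCorrelationScreen:
    def test_duplicated_column_dropped(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        retained, report = correlation_screen(df, ["a", "b", "c"])
        assert retained == ["a", "c"]
        assert (report.dropped == "b").any()

    def test_independent_columns_retained(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        retained, _ = correlation_screen(df, list("abcd"))
        assert retained == list("abcd")

    def test_unweighted_twin_dropped_not_weighted(self, rng):
        s = rng.poisson(3.0, size=200).astype(float)
        df = pd.DataFrame({
            "in_degree": np.minimum(s, 7) + rng.normal(0, 0.1, 200),
            "in_strength": s,
        })
        retained, report = correlation_screen(df, ["in_strength", "in_degree"])
        assert retained == ["in_strength"]
        assert set(report.dropped) == {"in_degree"}

    def test_constant_column_reported_and_retained(self, rng):
        df = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50)})
        retained, report = correlation_screen(df, ["a", "b"])
        assert retained == ["a", "b"]
        assert report.r.isna().all()

    def test_order_stability_under_row_permutation(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        df["d"] = df["a"] * 0.99 + rng.normal(0, 0.01, 100)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1, _ = correlation_screen(df, list("abcd"))
        r2, _ = correlation_screen(shuffled, list("abcd"))
        assert r1 == r2


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9], ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.H == pytest.approx(7.2)
        assert res.df == 2

    def test_relabeling_invariance(self, rng):
        v = rng.normal(size=30)
        g = ["x"] * 10 + ["y"] * 10 + ["z"] * 10
        relabeled = ["b" if s == "x" else ("c" if s == "y" else "a") for s in g]
        assert kruskal_wallis(v, g).H == pytest.approx(kruskal_wallis(v, relabeled).H)

    def test_monotone_transform_invariance(self, rng):
        v = rng.normal(size=30)
        g = ["x"] * 15 + ["y"] * 15
        assert kruskal_wallis(v, g).H == pytest.approx(kruskal_wallis(np.exp(v), g).H)

    def test_identical_values_h_zero(self):
        res = kruskal_wallis([2.0] * 10, ["a"] * 5 + ["b"] * 5)
        assert res.H == 0.0 and res.p == 1.0

    def test_single_group_error(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_posthoc_bonferroni_not_smaller(self, rng):
        v = rng.normal(size=30)
        g = ["x"] * 10 + ["y"] * 10 + ["z"] * 10
        raw = kruskal_wallis(v, g, adjust="none").posthoc.p
        adj = kruskal_wallis(v, g, adjust="bonferroni").posthoc.p
        assert np.all(adj.values >= raw.values - 1e-12)


def _balanced_lmm_frame(rng, delta=(1.0, 2.0, 3.0), sd_pen=0.0, sd_e=0.1, n_pens=12):
    rows = []
    for pen in range(n_pens):
        t = ["A", "B", "C"][pen % 3]
        pen_eff = rng.normal(0, sd_pen)
        for wk in (15, 19, 23):
            rows.append({
                "pen_id": f"p{pen:02d}", "treatment": t, "period": wk,
                "y": delta["ABC".index(t)] + pen_eff + rng.normal(0, sd_e),
            })
    return pd.DataFrame(rows)


class TestMetricLmm:
    def test_emms_equal_cell_means_on_balanced_design(self, rng):
        df = _balanced_lmm_frame(rng)
        fit = fit_metric_lmm(df, "y", factors=("treatment", "period"), group="pen_id")
        cell = df.groupby("treatment").y.mean()
        for _, row in fit.emm.iterrows():
            assert row.emm == pytest.approx(cell[row.level], abs=1e-6)

    def test_treatment_effect_recovered(self, rng):
        diffs = []
        for _ in range(40):
            df = _balanced_lmm_frame(rng, delta=(0.0, 1.0, 0.0), sd_pen=0.5, sd_e=0.5,
                                     n_pens=30)
            fit = fit_metric_lmm(df, "y", factors=("treatment", "period"), group="pen_id")
            emm = fit.emm.set_index("level").emm
            diffs.append(emm["B"] - emm["A"])
        assert np.mean(diffs) == pytest.approx(1.0, abs=2.5 * np.std(diffs) / np.sqrt(40))

    def test_week_excluded_for_aggregated_response(self, rng):
        df = _balanced_lmm_frame(rng).groupby(["pen_id", "treatment"], as_index=False).y.mean()
        fit = fit_metric_lmm(df, "y", factors=("treatment",), group="pen_id")
        assert not any("period" in name for name in fit.params.index)

    def test_sqrt_transform_applied(self, rng):
        df = _balanced_lmm_frame(rng, delta=(4.0, 4.0, 4.0))
        fit = fit_metric_lmm(df, "y", factors=("treatment",), group="pen_id",
                             sqrt_transform=True)
        assert fit.emm.emm.mean() == pytest.approx(2.0, abs=0.05)

    def test_contrasts_carry_tukey_pvalues(self, rng):
        df = _balanced_lmm_frame(rng, delta=(0.0, 0.0, 5.0), sd_e=0.3)
        fit = fit_metric_lmm(df, "y", factors=("treatment", "period"), group="pen_id")
        con = fit.contrasts.set_index(["level_a", "level_b"])
        assert con.loc[("A", "C"), "p_tukey"] < 0.01
        assert con.loc[("A", "B"), "p_tukey"] > 0.3


def _ordinal_frame(rng, n=400, beta=np.log(1.5)):
    x = rng.normal(size=n)
    thresholds = [-1.0, 0.5, 1.5, 2.5]
    cum = np.array([expit(t - beta * x) for t in thresholds]).T
    y = (rng.random(n)[:, None] > cum).sum(axis=1)
    return pd.DataFrame({
        "mts": y, "in_strength": x,
        "treatment": rng.choice(["LM", "HLM", "NLM"], n),
        "sex": rng.choice(["barrow", "gilt"], n),
        "pen_id": rng.choice([f"p{i}" for i in range(12)], n),
    })


class TestOrdinalMts:
    def test_single_level_error(self, rng):
        df = _ordinal_frame(rng)
        df["mts"] = 1
        with pytest.raises(ValidationError):
            fit_ordinal_mts(df, ["in_strength"], factors=())

    def test_effect_direction_and_scale(self, rng):
        fit = fit_ordinal_mts(_ordinal_frame(rng, n=2000), ["in_strength"], factors=())
        if fit.odds_ratios is not None:
            row = fit.odds_ratios.set_index("term").loc["in_strength"]
            assert 1.2 < row.odds_ratio < 1.9
            assert row.ci_low < 1.5 < row.ci_high

    def test_collapse_sparse_levels(self, rng):
        df = _ordinal_frame(rng)
        fit = fit_ordinal_mts(df, ["in_strength"], factors=(), collapse_sparse_levels=True)
        # thresholds 0/1 and 1/2 only
        assert sum("/" in name for name in fit.params.index) == 2


class TestVictimLogit:
    def test_all_non_victims_error(self, rng):
        df = _ordinal_frame(rng)
        df["victim"] = 0
        with pytest.raises(ValidationError):
            fit_victim_logit(df, ["in_strength"])

    def test_positive_effect_recovered(self, rng):
        n = 320
        pens = [f"p{i}" for i in range(40)]
        pen_eff = {p: rng.normal(0, 0.5) for p in pens}
        pen_id = np.repeat(pens, 8)
        z = rng.normal(size=n)
        pv = expit(-1.0 + 0.7 * z + np.array([pen_eff[p] for p in pen_id]))
        df = pd.DataFrame({
            "pen_id": pen_id, "in_strength": z,
            "victim": (rng.random(n) < pv).astype(int),
            "betweenness": np.abs(rng.normal(size=n)),
        })
        fit = fit_victim_logit(df, ["in_strength"])
        assert fit.odds_ratios.set_index("term").loc["in_strength", "odds_ratio"] > 1.0

    def test_association_variant_sqrt_betweenness(self, rng):
        n = 200
        df = pd.DataFrame({
            "pen_id": np.repeat([f"p{i}" for i in range(25)], 8),
            "strength": rng.normal(size=n),
            "betweenness": np.abs(rng.normal(size=n)),
            "victim": rng.integers(0, 2, size=n),
        })
        fit = fit_victim_logit(df, ["strength", "betweenness"], use_association_metrics=True)
        assert "betweenness" in fit.params.index


class TestAicComparison:
    def test_identical_models_delta_zero(self, rng):
        df = _ordinal_frame(rng)
        f1 = fit_ordinal_mts(df, ["in_strength"], factors=())
        f2 = fit_ordinal_mts(df, ["in_strength"], factors=())
        ranked = compare_models_aic([f1, f2])
        assert ranked.delta_aic.iloc[-1] == pytest.approx(0.0)

    def test_noise_predictor_usually_penalized(self, rng):
        prefer_smaller = 0
        for _ in range(20):
            df = _ordinal_frame(rng, n=300)
            df["noise"] = rng.normal(size=len(df))
            f_small = fit_ordinal_mts(df, ["in_strength"], factors=())
            f_big = fit_ordinal_mts(df, ["in_strength", "noise"], factors=())
            if f_big.aic - f_small.aic > -2:
                prefer_smaller += 1
        assert prefer_smaller >= 14

    def test_single_fit_error(self, rng):
        f1 = fit_ordinal_mts(_ordinal_frame(rng), ["in_strength"], factors=())
        with pytest.raises(ValidationError):
            compare_models_aic([f1])

    def test_differing_rows_error(self, rng):
        df = _ordinal_frame(rng)
        f1 = fit_ordinal_mts(df, ["in_strength"], factors=())
        f2 = fit_ordinal_mts(df.iloc[:300], ["in_strength"], factors=())
        with pytest.raises(ValidationError):
            compare_models_aic([f1, f2])
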