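"""Expression filtering, condition averaging, Pearson machinery and intersections."""

import numpy as np
import pandas as pd
import pytest

from sleepermeta.correlation import (
    NEGATIVE,
    NONE,
    POSITIVE,
    condition_means,
    correlate_history,
    correlate_rebound,
    filter_low_expression,
    history_rebound_intersections,
    pearson,
)
from sleepermeta.correlation import _pearson_genes


def pearson_oracle(x, y):
    """Definitional covariance-formula Pearson."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())


class TestFilterLowExpression:
    def test_majority_low_excluded(self):
        tpm = pd.DataFrame([np.r_[np.full(14, 0.5), np.full(13, 5.0)]],
                           index=["g"], columns=[f"s{i}" for i in range(27)])
        assert filter_low_expression(tpm).empty  # 14/27 > 0.5

    def test_exactly_half_low_retained(self):
        tpm = pd.DataFrame([[0.5, 0.5, 5.0, 5.0]], index=["g"],
                           columns=list("abcd"))
        assert list(filter_low_expression(tpm).index) == ["g"]

    def test_matches_predicate_oracle(self, rng):
        tpm = pd.DataFrame(rng.uniform(0, 3, (60, 9)),
                           index=[f"g{i}" for i in range(60)],
                           columns=[f"s{i}" for i in range(9)])
        got = set(filter_low_expression(tpm).index)
        want = {g for g in tpm.index if (tpm.loc[g] < 1).sum() <= 4.5}
        assert got == want


class TestConditionMeans:
    def test_mean_then_log_with_pseudocount(self):
        tpm = pd.DataFrame([[3.0, 3.0, 3.0], [0.0, 0.0, 0.0]],
                           index=["g1", "g2"], columns=["c1_r1", "c1_r2", "c1_r3"])
        ce = condition_means(tpm, {"c1_r1": "c1", "c1_r2": "c1", "c1_r3": "c1"})
        assert ce.loc["g1", "c1"] == pytest.approx(2.0)  # log2(3+1)
        assert ce.loc["g2", "c1"] == pytest.approx(0.0)  # log2(0+1)

    def test_average_precedes_log(self, rng):
        tpm = pd.DataFrame(rng.uniform(0, 50, (5, 6)),
                           index=[f"g{i}" for i in range(5)],
                           columns=[f"{c}_r{r}" for c in ("a", "b") for r in (1, 2, 3)])
        mapping = {s: s.split("_")[0] for s in tpm.columns}
        ce = condition_means(tpm, mapping)
        for g in tpm.index:
            want = np.log2(tpm.loc[g, ["a_r1", "a_r2", "a_r3"]].mean() + 1)
            assert ce.loc[g, "a"] == pytest.approx(want, abs=1e-12)

    def test_unmapped_sample_rejected(self):
        tpm = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            condition_means(tpm, {"s1": "c1"})


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_example(self):
        r, _ = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_matches_definitional_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0, 1, 12)
            assert pearson(x, y)[0] == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_affine_invariance_and_sign_flip(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        r = pearson(x, y)[0]
        assert pearson(3 * x + 5, y)[0] == pytest.approx(r, abs=1e-10)
        assert pearson(-2 * x + 1, y)[0] == pytest.approx(-r, abs=1e-10)

    @pytest.mark.parametrize("x,y", [
        ([1, 2], [1, 2]),                  # too short
        ([1, 1, 1], [1, 2, 3]),            # zero variance
        ([1, 2, 3], [1, 2]),               # length mismatch
    ])
    def test_invalid_inputs(self, x, y):
        with pytest.raises(ValueError):
            pearson(x, y)

    def test_vectorised_matches_scalar(self, rng):
        X = rng.normal(0, 1, (20, 9))
        y = rng.normal(0, 1, 9)
        r_vec, p_vec = _pearson_genes(X, y)
        for i in range(20):
            r, p = pearson(X[i], y)
            assert r_vec[i] == pytest.approx(r, abs=1e-12)
            assert p_vec[i] == pytest.approx(p, rel=1e-9)


def windows_frame(values_by_condition):
    return pd.DataFrame.from_dict(values_by_condition, orient="index",
                                  columns=list(range(1, 13)))


class TestCorrelateHistory:
    def _history(self, rng, n_cond=9):
        base = np.sort(rng.uniform(0, 60, n_cond))
        return windows_frame(
            {f"c{i}": np.cumsum(rng.uniform(0, 60, 12) + base[i] / 12) for i in range(n_cond)}
        )

    def test_gene_equal_to_window_metric_is_perfect(self, rng):
        hist = self._history(rng)
        ce = pd.DataFrame([hist[12].to_numpy()], index=["g"], columns=hist.index)
        res = correlate_history(ce, hist)
        row = res.long[(res.long["gene_id"] == "g") & (res.long["window_hours"] == 12)]
        assert row["r"].iloc[0] == pytest.approx(1.0)
        assert res.summary["summary_sign"].iloc[0] == POSITIVE

    def test_constant_gene_is_skipped(self, rng):
        hist = self._history(rng)
        ce = pd.DataFrame([[5.0] * 9], index=["g"], columns=hist.index)
        res = correlate_history(ce, hist)
        assert res.long["r"].isna().all()
        assert res.summary["summary_sign"].iloc[0] == NONE

    def test_needs_three_conditions(self):
        hist = windows_frame({"c0": np.arange(12), "c1": np.arange(12)})
        ce = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["c0", "c1"])
        with pytest.raises(ValueError):
            correlate_history(ce, hist)

    def test_planted_linear_genes_recovered(self, rng):
        hist = self._history(rng, n_cond=12)
        n_genes, planted = 300, 30
        z = (hist[6] - hist[6].mean()) / hist[6].std()
        expr = rng.normal(5, 1, (n_genes, 1)) + rng.normal(0, 0.25, (n_genes, 12))
        expr[:planted] += 2.0 * z.to_numpy()
        ce = pd.DataFrame(expr, index=[f"g{i}" for i in range(n_genes)],
                          columns=hist.index)
        res = correlate_history(ce, hist)
        sig = res.significant_genes(POSITIVE)
        hits = sum(f"g{i}" in sig for i in range(planted))
        assert hits / planted >= 0.9
        nulls_sig = len(res.significant_genes()) - len(
            res.significant_genes() & {f"g{i}" for i in range(planted)}
        )
        assert nulls_sig / (n_genes - planted) <= 0.05


class TestCorrelateRebound:
    def test_excluded_conditions_dropped(self, rng):
        reb = windows_frame({f"c{i}": rng.normal(0, 50, 12) for i in range(6)})
        ce = pd.DataFrame(rng.normal(5, 1, (4, 6)),
                          index=[f"g{i}" for i in range(4)], columns=reb.index)
        res = correlate_rebound(ce, reb, exclude={"c0", "c1"})
        assert res.n_conditions == 4

    def test_all_excluded_rejected(self, rng):
        reb = windows_frame({f"c{i}": rng.normal(0, 50, 12) for i in range(3)})
        ce = pd.DataFrame(rng.normal(5, 1, (2, 3)), index=["a", "b"], columns=reb.index)
        with pytest.raises(ValueError):
            correlate_rebound(ce, reb, exclude=set(reb.index))


class TestIntersections:
    def _results(self, signs, target):
        from sleepermeta.correlation import CorrelationResults

        summary = pd.DataFrame(
            {
                "gene_id": list(signs),
                "summary_sign": list(signs.values()),
                "best_window": 1,
                "best_q": 0.01,
                "mixed_sign": False,
            }
        )
        return CorrelationResults(target, pd.DataFrame(), summary, 9)

    def test_sign_pattern_partition(self):
        hist = self._results({"a": POSITIVE, "b": NEGATIVE, "c": POSITIVE, "d": NONE},
                             "history")
        reb = self._results({"a": NEGATIVE, "b": POSITIVE, "c": POSITIVE, "d": NEGATIVE},
                            "rebound")
        cells = history_rebound_intersections(hist, reb)
        assert cells["pos_neg"] == {"a"}
        assert cells["neg_pos"] == {"b"}
        assert cells["pos_pos"] == {"c"}
        assert cells["neg_neg"] == set()

    def test_partition_is_disjoint_and_conserved(self, rng):
        choices = [POSITIVE, NEGATIVE, NONE]
        h = {f"g{i}": choices[rng.integers(3)] for i in range(200)}
        r = {f"g{i}": choices[rng.integers(3)] for i in range(200)}
        cells = history_rebound_intersections(
            self._results(h, "history"), self._results(r, "rebound")
        )
        union = set().union(*cells.values())
        both = {g for g in h if h[g] != NONE and r[g] != NONE}
        assert union == both
        assert sum(len(v) for v in cells.values()) == len(union)
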