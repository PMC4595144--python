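"""QC: worked examples, scipy cross-checks, bookkeeping invariants."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexdiff import qc
from coexdiff.simulate import SimulationConfig, generate_dataset

from conftest import log2_expr


def _meta(rin, ratio):
    return pd.DataFrame({"rin": rin, "ratio_260_280": ratio},
                        index=[f"S{i}" for i in range(len(rin))])


class TestLabQuality:
    def test_worked_example(self):
        meta = _meta([5.0, 6.0, 7.0], [1.9, 1.7, 1.9])
        excl = qc.filter_lab_quality(meta)
        assert {(e.id, e.reason) for e in excl} == {
            ("S0", "low_rin"), ("S1", "low_purity")}

    def test_thresholds_are_strict_below(self):
        meta = _meta([6.0, 5.99], [1.8, 1.8])
        excl = qc.filter_lab_quality(meta)
        assert [(e.id, e.reason) for e in excl] == [("S1", "low_rin")]

    def test_missing_values_raise(self):
        meta = _meta([np.nan, 7.0], [1.9, 1.9])
        with pytest.raises(ValueError, match="rin"):
            qc.filter_lab_quality(meta)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            qc.filter_lab_quality(_meta([7], [1.9]), rin_min=0)


class TestPcOutliers:
    def test_shifted_sample_flagged(self, rng):
        x = rng.normal(0, 1, (50, 61))
        x[:, 60] += 10.0  # one sample far from the cloud on PC1
        expr = pd.DataFrame(x, index=[f"P{i}" for i in range(50)],
                            columns=[f"S{i}" for i in range(61)])
        excl = qc.detect_pc_outliers(expr)
        assert [(e.id, e.reason) for e in excl] == [("S60", "pc_outlier")]

    def test_clean_data_unflagged(self, rng):
        x = rng.normal(0, 1, (50, 60))
        expr = pd.DataFrame(x, index=[f"P{i}" for i in range(50)],
                            columns=[f"S{i}" for i in range(60)])
        assert qc.detect_pc_outliers(expr) == []

    def test_too_few_samples(self):
        expr = pd.DataFrame(np.ones((5, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            qc.detect_pc_outliers(expr)

    def test_constant_matrix_raises(self):
        expr = pd.DataFrame(np.ones((5, 4)),
                            columns=["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="constant"):
            qc.detect_pc_outliers(expr)


class TestSexConcordance:
    def _build(self, rng, n=24, n_probes=8, effect=6.0, swap=()):
        half = n // 2
        reported = ["F"] * half + ["M"] * half
        for i in swap:  # record says the opposite of the expression
            reported[i] = "M" if reported[i] == "F" else "F"
        meta = pd.DataFrame({"reported_sex": reported},
                            index=[f"S{i}" for i in range(n)])
        x = rng.normal(0, 1, (n_probes, n))
        x[:, half:] += effect  # true males high on every sex probe
        expr = pd.DataFrame(x, index=[f"X{i}" for i in range(n_probes)],
                            columns=meta.index)
        annot = pd.DataFrame({"is_sex_check_probe": True}, index=expr.index)
        return expr, annot, meta

    def test_swapped_sample_flagged(self, rng):
        expr, annot, meta = self._build(rng, swap=(3,))
        excl = qc.check_sex_concordance(expr, annot, meta)
        assert [(e.id, e.reason) for e in excl] == [("S3", "sex_mismatch")]

    def test_concordant_data_clean(self, rng):
        expr, annot, meta = self._build(rng)
        assert qc.check_sex_concordance(expr, annot, meta) == []

    def test_single_discordant_probe_not_enough(self, rng):
        expr, annot, meta = self._build(rng)
        # corrupt one probe's value for one sample: 1 < min_discordant = 2
        expr.iloc[0, 0] += 6.0
        assert qc.check_sex_concordance(expr, annot, meta) == []

    def test_too_few_probes_raise(self, rng):
        expr, annot, meta = self._build(rng, n_probes=1)
        with pytest.raises(ValueError, match="sex-check probes"):
            qc.check_sex_concordance(expr, annot, meta)


class TestDuplicates:
    def test_triple_keeps_earliest(self, rng):
        base = rng.normal(0, 1, 200)
        cols = {
            "S0": rng.normal(0, 1, 200),
            "S1": base,
            "S2": base + rng.normal(0, 0.01, 200),
            "S3": base + rng.normal(0, 0.01, 200),
        }
        expr = pd.DataFrame(cols)
        excl = qc.detect_duplicates(expr)
        assert {(e.id, e.reason) for e in excl} == {
            ("S2", "duplicate"), ("S3", "duplicate")}

    def test_independent_samples_kept(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (100, 6)),
                            columns=list("abcdef"))
        assert qc.detect_duplicates(expr) == []

    def test_r_min_validation(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (10, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            qc.detect_duplicates(expr, r_min=1.0)


class TestProbeFilters:
    def test_counts_and_priority(self):
        n = 100
        annot = pd.DataFrame({
            "chromosome": ["1"] * n,
            "is_specific": [True] * n,
            "is_retired": [False] * n,
        }, index=[f"P{i}" for i in range(n)])
        annot.iloc[:10, annot.columns.get_loc("is_specific")] = False
        annot.iloc[10:15, annot.columns.get_loc("chromosome")] = "X"
        annot.iloc[15:18, annot.columns.get_loc("is_retired")] = True
        # overlap: nonspecific AND X -> recorded as nonspecific
        annot.iloc[0, annot.columns.get_loc("chromosome")] = "Y"
        excl = qc.filter_probes(annot)
        reasons = pd.Series([e.reason for e in excl]).value_counts()
        assert reasons["nonspecific"] == 10
        assert reasons["non_autosomal"] == 5
        assert reasons["retired"] == 3
        assert excl[0].reason == "nonspecific"

    def test_mt_probes_excluded(self):
        annot = pd.DataFrame({"chromosome": ["MT", "22"],
                              "is_specific": True, "is_retired": False},
                             index=["P0", "P1"])
        excl = qc.filter_probes(annot)
        assert [(e.id, e.reason) for e in excl] == [("P0", "non_autosomal")]

    def test_unknown_chromosome_raises(self):
        annot = pd.DataFrame({"chromosome": ["banana"], "is_specific": True,
                              "is_retired": False}, index=["P0"])
        with pytest.raises(ValueError, match="banana"):
            qc.filter_probes(annot)


class TestQuantileNormalization:
    def test_three_by_three_worked_example(self):
        expr = pd.DataFrame({"a": [1.0, 2, 3], "b": [4.0, 5, 6],
                             "c": [7.0, 8, 9]}, index=["p1", "p2", "p3"])
        out = qc.quantile_normalize_log2(expr)
        expected = np.log2([4.0, 5.0, 6.0])
        for col in expr.columns:
            np.testing.assert_allclose(out[col].to_numpy(), expected)

    def test_columns_share_distribution(self, rng):
        expr = pd.DataFrame(rng.gamma(2, 50, (40, 6)),
                            columns=list("abcdef"))
        out = qc.quantile_normalize_log2(expr)
        ref = np.sort(out["a"].to_numpy())
        for col in "bcdef":
            np.testing.assert_allclose(np.sort(out[col].to_numpy()), ref)

    def test_idempotent(self, rng):
        expr = pd.DataFrame(rng.gamma(2, 50, (30, 5)),
                            columns=list("abcde"))
        once = qc.quantile_normalize_log2(expr)
        twice = qc.quantile_normalize_log2(2.0 ** once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(),
                                   rtol=1e-10)

    def test_order_preserved_within_column(self, rng):
        expr = pd.DataFrame(rng.gamma(2, 50, (30, 4)), columns=list("abcd"))
        out = qc.quantile_normalize_log2(expr)
        for col in expr.columns:
            assert (np.argsort(expr[col].to_numpy())
                    == np.argsort(out[col].to_numpy())).all()

    def test_ties_get_average(self):
        expr = pd.DataFrame({"a": [1.0, 1.0, 3.0], "b": [2.0, 4.0, 8.0]})
        out = qc.quantile_normalize_log2(expr)
        # column a ranks: the two tied values share ranks 1-2
        rank_means = np.sort(expr.to_numpy(), axis=0).mean(axis=1)
        np.testing.assert_allclose(
            out["a"].to_numpy()[:2],
            np.log2((rank_means[0] + rank_means[1]) / 2.0) * np.ones(2))

    def test_transformer_matches_function(self, rng):
        expr = pd.DataFrame(rng.gamma(2, 50, (25, 5)), columns=list("abcde"))
        func = qc.quantile_normalize_log2(expr)
        est = qc.QuantileNormalizer().fit(expr.to_numpy().T)
        out = est.transform(expr.to_numpy().T).T
        np.testing.assert_allclose(out, func.to_numpy(), rtol=1e-10)

    def test_nonpositive_raises(self):
        expr = pd.DataFrame({"a": [-4.0, 1.0], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            qc.quantile_normalize_log2(expr)


class TestSplit:
    def test_two_thirds_one_third_per_stratum(self):
        meta = pd.DataFrame({"is_case": [True] * 107 + [False] * 103},
                            index=[f"S{i}" for i in range(210)])
        labels = qc.split_discovery_replication(meta, seed=0)
        tab = pd.crosstab(meta["is_case"], labels)
        assert tab.loc[True, "replication"] == 107 // 3 == 35
        assert tab.loc[False, "replication"] == 103 // 3 == 34
        assert tab.loc[True, "discovery"] == 72
        assert tab.loc[False, "discovery"] == 69

    def test_tiny_strata(self):
        meta = pd.DataFrame({"is_case": [True] * 3 + [False] * 3},
                            index=list("abcdef"))
        labels = qc.split_discovery_replication(meta, seed=1)
        assert (labels == "replication").sum() == 2

    def test_deterministic_and_seed_sensitive(self):
        meta = pd.DataFrame({"is_case": [True] * 30 + [False] * 30},
                            index=[f"S{i}" for i in range(60)])
        a = qc.split_discovery_replication(meta, seed=5)
        b = qc.split_discovery_replication(meta, seed=5)
        c = qc.split_discovery_replication(meta, seed=6)
        assert a.equals(b)
        assert not a.equals(c)

    def test_stratum_too_small(self):
        meta = pd.DataFrame({"is_case": [True, True, False]}, index=list("abc"))
        with pytest.raises(ValueError):
            qc.split_discovery_replication(meta, seed=0)


class TestWilcoxon:
    def test_rank_sum_worked_example(self):
        w, p = qc._wilcoxon_rank_sum(np.array([1.0, 2, 3]),
                                     np.array([10.0, 11, 12]))
        assert w == 6.0
        # scipy oracle: U + n1(n1+1)/2 = W; same asymptotic p
        res = stats.mannwhitneyu([1, 2, 3], [10, 11, 12],
                                 method="asymptotic")
        assert res.statistic + 3 * 4 / 2 - 6 == 0
        np.testing.assert_allclose(p, res.pvalue, rtol=1e-10)

    def test_all_ties_p_one(self):
        w, p = qc._wilcoxon_rank_sum(np.array([5.0, 5, 5]),
                                     np.array([5.0, 5, 5, 5]))
        assert p == 1.0

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(25):
            a = rng.normal(0, 1, rng.integers(4, 20))
            b = rng.normal(0.3, 1, rng.integers(4, 20))
            _, p = qc._wilcoxon_rank_sum(a, b)
            oracle = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
            np.testing.assert_allclose(p, oracle, rtol=1e-9)

    def test_leukocyte_comparison(self, rng):
        n = 40
        meta = pd.DataFrame({
            "is_case": [True] * 20 + [False] * 20,
            "count_neutrophils": rng.gamma(16, 0.25, n),
            "count_lymphocytes": np.r_[rng.gamma(16, 0.20, 20),
                                       rng.gamma(16, 0.05, 20)],
        }, index=[f"S{i}" for i in range(n)])
        out = qc.compare_leukocyte_counts(meta)
        assert set(out.index) == {"neutrophils", "lymphocytes"}
        assert out.loc["lymphocytes", "p"] < 0.01
        assert out.loc["neutrophils", "p"] > 0.01

    def test_no_count_columns_raises(self):
        meta = pd.DataFrame({"is_case": [True, False]}, index=["a", "b"])
        with pytest.raises(ValueError, match="count_"):
            qc.compare_leukocyte_counts(meta)


class TestRunQc:
    def test_recovers_planted_defects(self, small_dataset):
        cfg, ds = small_dataset
        expr, meta, report = qc.run_qc(ds.expression, ds.metadata, ds.annotation)
        excluded = {e.id: e.reason for e in report.excluded_samples}
        for sid, t in ds.truth_samples.items():
            if t["is_duplicate"]:
                assert excluded.get(sid) == "duplicate", sid
            elif t["is_outlier"]:
                assert excluded.get(sid) == "pc_outlier", sid
            elif t["is_low_quality"]:
                assert excluded.get(sid) == "low_rin", sid
            else:
                assert sid not in excluded, (sid, excluded.get(sid))

    def test_bookkeeping_accounts_for_everything(self, small_dataset):
        cfg, ds = small_dataset
        expr, meta, report = qc.run_qc(ds.expression, ds.metadata, ds.annotation)
        assert (report.n_samples_retained + len(report.excluded_samples)
                == ds.expression.shape[1])
        assert (report.n_probes_retained + len(report.excluded_probes)
                == ds.expression.shape[0])
        assert expr.shape == (report.n_probes_retained,
                              report.n_samples_retained)
        assert list(meta.index) == list(expr.columns)
        # sex-check probes (non-autosomal) are gone from the output
        assert not any(ds.annotation.loc[p, "is_sex_check_probe"]
                       for p in expr.index)

    def test_rerun_identical(self, small_dataset):
        cfg, ds = small_dataset
        a = qc.run_qc(ds.expression, ds.metadata, ds.annotation)
        b = qc.run_qc(ds.expression, ds.metadata, ds.annotation)
        pd.testing.assert_frame_equal(a[0], b[0])
        assert a[2].to_dict() == b[2].to_dict()

    def test_output_is_log2_of_common_distribution(self, small_dataset):
        cfg, ds = small_dataset
        expr, _, _ = qc.run_qc(ds.expression, ds.metadata, ds.annotation)
        cols = expr.columns[:2]
        np.testing.assert_allclose(np.sort(expr[cols[0]].to_numpy()),
                                   np.sort(expr[cols[1]].to_numpy()))

    def test_nonpositive_raw_raises(self, small_dataset):
        cfg, ds = small_dataset
        bad = ds.expression.copy()
        bad.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="positive"):
            qc.run_qc(bad, ds.metadata, ds.annotation)
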