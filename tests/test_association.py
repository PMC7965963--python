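"""Correlation, heritability, Fisher exact test, and marker association."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

import oracles
import shootarch as sa
from shootarch.association import (
    UntestableTableError,
    contingency_tables_from_csv,
    fisher_exact_2x2,
    heritability_table,
    load_published_marker_tables,
    trait_correlation_cluster,
)


class TestPearsonFisherZ:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert sa.pearson_fisher_z(x, x).r == 1.0
        assert sa.pearson_fisher_z(x, -x).r == -1.0

    def test_hand_computed_example(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        # sum formula: r = 10 / sqrt(10 * 14.8); p from z = atanh(r)*sqrt(n-3)
        r_expected = 10.0 / math.sqrt(10.0 * 14.8)
        res = sa.pearson_fisher_z(x, y)
        assert res.r == pytest.approx(r_expected, abs=1e-12)
        from scipy.stats import norm

        p_expected = 2 * norm.sf(abs(math.atanh(r_expected)) * math.sqrt(2))
        assert res.p == pytest.approx(p_expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            sa.pearson_fisher_z([1.0] * 6, np.arange(6.0))

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [1.0, 2.0, 3.0, 4.0, 5.0, np.nan]
        assert sa.pearson_fisher_z(x, y).n == 4

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(300):
            x, y = rng.standard_normal((2, 89))
            ps.append(sa.pearson_fisher_z(x, y).p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestReplicateConcordance:
    def image_table(self, front, back, trait="PH"):
        rows = []
        for i, (f, b) in enumerate(zip(front, back)):
            for side, v in (("front", f), ("back", b)):
                rows.append({
                    "accession_id": f"A{i}", "replicate_id": "r1",
                    "side": side, trait: v,
                })
        return pd.DataFrame(rows)

    def test_identical_sides_give_unit_correlation(self):
        vals = np.linspace(30, 80, 20)
        out = sa.replicate_concordance(self.image_table(vals, vals), ["PH"])
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_pure_noise_gives_near_zero_correlation(self):
        rng = np.random.default_rng(4)
        signal = np.full(100, 50.0)
        front = signal + rng.standard_normal(100) * 20
        back = signal + rng.standard_normal(100) * 20
        out = sa.replicate_concordance(self.image_table(front, back), ["PH"])
        assert abs(out.iloc[0]["r"]) < 0.3

    def test_one_sided_trait_skipped(self, caplog):
        table = self.image_table(np.arange(6.0), np.arange(6.0))
        table.loc[table["side"] == "back", "PH"] = np.nan
        with caplog.at_level("WARNING"):
            out = sa.replicate_concordance(table, ["PH"])
        assert out.empty


class TestTraitCorrelationCluster:
    def test_duplicated_traits_are_adjacent_leaves(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        df = pd.DataFrame({"t1": a, "t2": a.copy(), "t3": b})
        corr, order = trait_correlation_cluster(df, ["t1", "t2", "t3"])
        assert corr.loc["t1", "t2"] == pytest.approx(1.0)
        assert abs(order.index("t1") - order.index("t2")) == 1

    def test_negated_trait_has_maximal_row_distance(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        df = pd.DataFrame({"t1": a, "neg": -a, "t3": b})
        corr, _ = trait_correlation_cluster(df, ["t1", "neg", "t3"])
        rows = corr.values
        d = lambda i, j: np.linalg.norm(rows[i] - rows[j])  # noqa: E731
        assert d(0, 1) == max(d(0, 1), d(0, 2), d(1, 2))

    def test_two_latent_blocks_split_first(self):
        rng = np.random.default_rng(10)
        f1, f2 = rng.standard_normal((2, 60))
        df = pd.DataFrame({
            f"a{i}": f1 + 0.2 * rng.standard_normal(60) for i in range(3)
        } | {
            f"b{i}": f2 + 0.2 * rng.standard_normal(60) for i in range(3)
        })
        _, order = trait_correlation_cluster(df, list(df.columns))
        groups = ["a" if t.startswith("a") else "b" for t in order]
        # block members contiguous in the leaf order
        assert groups in (["a"] * 3 + ["b"] * 3, ["b"] * 3 + ["a"] * 3)

    def test_constant_trait_excluded(self, caplog):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({
            "t1": rng.standard_normal(20),
            "t2": rng.standard_normal(20),
            "flat": np.ones(20),
        })
        with caplog.at_level("WARNING"):
            corr, order = trait_correlation_cluster(df, list(df.columns))
        assert "flat" not in corr.columns
        assert "excluded" in caplog.text


class TestHeritability:
    def test_zero_residual_gives_full_heritability(self):
        df, _ = sa.simulate_trait(10, 3, 50.0, 4.0, 0.0, seed=1)
        vc = sa.heritability(df["value"], df["accession_id"])
        assert vc.H2 > 0.999
        assert vc.sigma2_e == pytest.approx(0.0, abs=1e-6)

    def test_balanced_design_recovers_expected_h2(self):
        # 24 accessions x 3 reps, sigma2_g = 9, sigma2_e = 3 -> E[H2] = 0.9
        ests = [
            sa.heritability(*_sim(24, 3, 3.0, math.sqrt(3.0), seed)).H2
            for seed in range(200)
        ]
        assert np.mean(ests) == pytest.approx(0.9, abs=0.03)

    def test_null_genetic_variance_estimates_near_zero(self):
        # zero-truncated REML has a small positive bias under the null;
        # a reference mixed-model fit (statsmodels MixedLM) lands at the
        # same mean (~0.11) on this design
        ests = [
            sa.heritability(*_sim(24, 3, 0.0, 1.0, seed)).H2
            for seed in range(200)
        ]
        assert np.mean(ests) < 0.15
        assert np.median(ests) < 0.1

    def test_harmonic_mean_replicates_unbalanced(self):
        df, _ = sa.simulate_trait(3, [2, 3, 6], 0.0, 1.0, 1.0, seed=0)
        vc = sa.heritability(df["value"], df["accession_id"])
        assert vc.r_bar == pytest.approx(3.0 / (1 / 2 + 1 / 3 + 1 / 6))

    def test_agrees_with_statsmodels_reml(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        df, _ = sa.simulate_trait(24, [(2, 3, 4)[i % 3] for i in range(24)],
                                  50.0, 3.0, 1.0, seed=42)
        vc = sa.heritability(df["value"], df["accession_id"])
        fit = smf.mixedlm("value ~ 1", df, groups=df["accession_id"]).fit(
            reml=True
        )
        assert vc.sigma2_g == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert vc.sigma2_e == pytest.approx(float(fit.scale), rel=1e-3)

    def test_single_replicate_design_rejected(self):
        df, _ = sa.simulate_trait(5, 1, 0.0, 1.0, 1.0, seed=0)
        with pytest.raises(ValueError, match="unidentifiable"):
            sa.heritability(df["value"], df["accession_id"])

    def test_table_over_traits(self):
        df, _ = sa.simulate_trait(8, 2, 50.0, 3.0, 1.0, seed=3)
        df["PH"] = df["value"]
        out = heritability_table(df, ["PH", "absent"])
        assert list(out["trait"]) == ["PH"]
        assert 0 <= out.iloc[0]["H2"] <= 1


def _sim(n_acc, reps, g_sd, e_sd, seed):
    df, _ = sa.simulate_trait(n_acc, reps, 50.0, g_sd, e_sd, seed)
    return df["value"], df["accession_id"]


class TestClassifyPodNumber:
    def test_mean_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert list(sa.classify_pod_number(s)) == ["low", "low", "high", "high"]

    def test_all_equal_is_all_low(self):
        s = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        assert list(sa.classify_pod_number(s)) == ["low"] * 3

    def test_skewed_values(self):
        s = pd.Series([10.0, 20.0, 90.0], index=list("abc"))
        assert list(sa.classify_pod_number(s)) == ["low", "low", "high"]

    def test_median_split_option(self):
        s = pd.Series([1.0, 2.0, 3.0, 100.0], index=list("abcd"))
        assert list(sa.classify_pod_number(s, split="median")) == [
            "low", "low", "high", "high",
        ]


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [((11, 1, 0, 12), 9.6e-06), ((6, 6, 12, 0), 1.4e-02),
         ((1, 1, 1, 1), 1.0)],
    )
    def test_reference_tables(self, table, expected):
        p = fisher_exact_2x2(*table)
        assert p == pytest.approx(expected, rel=0.05)

    def test_matches_exact_rational_oracle_small_tables(self):
        for a, b, c, d in oracles.all_tables_up_to(16):
            got = fisher_exact_2x2(a, b, c, d)
            want = float(oracles.fisher_two_sided_exact(a, b, c, d))
            assert got == pytest.approx(want, rel=1e-10), (a, b, c, d)

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                continue
            ours = fisher_exact_2x2(a, b, c, d)
            theirs = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-9)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.tuples(*[st.integers(0, 20)] * 4))
    def test_invariant_to_simultaneous_row_and_column_swap(self, table):
        a, b, c, d = table
        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_exact_2x2(d, c, b, a), rel=1e-12
        )

    def test_empty_marginal_untestable(self):
        with pytest.raises(UntestableTableError):
            fisher_exact_2x2(0, 0, 5, 5)

    def test_published_marker_tables_reproduce_reported_p(self):
        df = load_published_marker_tables()
        assert len(df) == 7
        for _, row in df.iterrows():
            p = fisher_exact_2x2(
                row["high_nr"], row["high_ref"], row["low_nr"], row["low_ref"]
            )
            assert p == pytest.approx(row["reported_p"], rel=0.05), row["marker_id"]

    def test_contingency_csv_path(self, tmp_path):
        src = tmp_path / "tables.csv"
        pd.DataFrame([
            {"high_nr": 11, "high_ref": 1, "low_nr": 0, "low_ref": 12},
            {"high_nr": 0, "high_ref": 0, "low_nr": 5, "low_ref": 5},
        ]).to_csv(src, index=False)
        out = contingency_tables_from_csv(src)
        assert out.iloc[0]["p"] == pytest.approx(9.6e-06, rel=0.05)
        assert math.isnan(out.iloc[1]["p"])


class TestMarkerWindowMatch:
    def markers(self, positions, chrom="Gm11"):
        return pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(len(positions))],
            "chrom": chrom, "pos": positions,
        })

    def test_inclusive_window_boundary(self):
        published = pd.DataFrame({"chrom": ["Gm11"], "pos": [100_000]})
        hit = sa.marker_window_match(published, self.markers([150_000]))
        assert len(hit) == 1
        miss = sa.marker_window_match(published, self.markers([150_001]))
        assert miss.empty

    def test_multiple_matches_sorted_by_distance(self):
        published = pd.DataFrame({"chrom": ["Gm11"], "pos": [100_000]})
        out = sa.marker_window_match(
            published, self.markers([140_000, 110_000])
        )
        assert list(out["distance_bp"]) == [10_000, 40_000]

    def test_unknown_chromosome_rejected(self):
        published = pd.DataFrame({"chrom": ["Gm99"], "pos": [1]})
        with pytest.raises(ValueError, match="Gm99"):
            sa.marker_window_match(published, self.markers([10]))
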