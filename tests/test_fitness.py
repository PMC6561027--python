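"""Expansion-fitness estimator, essential calling, bins, rank correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predfit import fitness as ft


class TestExpansionFitness:
    @pytest.mark.parametrize(
        "f1,f2,d,expected",
        [
            (0.01, 0.01, 50.0, 1.0),          # neutrality identity
            (0.01, 0.0, 100.0, 0.0),          # dead-mutant convention
            (0.01, 0.02, 100.0, np.log(200) / np.log(98.9899)),  # ~1.153
        ],
    )
    def test_point_values(self, f1, f2, d, expected):
        assert ft.expansion_fitness(f1, f2, d) == pytest.approx(expected, abs=1e-4)

    def test_worked_value_magnitude(self):
        assert ft.expansion_fitness(0.01, 0.02, 100.0) == pytest.approx(1.153, abs=1e-3)

    def test_absent_from_input_is_an_error(self):
        with pytest.raises(ValueError, match="absent from input"):
            ft.expansion_fitness(0.0, 0.01, 100.0)

    def test_invalid_d_is_an_error(self):
        with pytest.raises(ValueError, match="d must be"):
            ft.expansion_fitness(0.01, 0.01, 1.0)

    @given(
        f=st.floats(1e-6, 0.1),
        d=st.floats(1.5, 1000.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_neutral_identity_property(self, f, d):
        assert ft.expansion_fitness(f, f, d) == pytest.approx(1.0, abs=1e-9)

    @given(
        f1=st.floats(1e-5, 0.05),
        d=st.floats(2.0, 500.0),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_increasing_in_f2(self, f1, d, data):
        """Strictly increasing wherever W is positive; the dead-mutant floor
        pins extreme depletion (an absolute decline beyond d-fold) at 0."""
        f2a = data.draw(st.floats(1e-7, 0.4))
        f2b = data.draw(st.floats(1e-7, 0.4))
        lo, hi = sorted((f2a, f2b))
        if hi - lo < 1e-9:
            return
        w_lo = ft.expansion_fitness(f1, lo, d)
        w_hi = ft.expansion_fitness(f1, hi, d)
        assert w_lo <= w_hi
        if w_lo > 0:
            assert w_lo < w_hi


class TestGeneFitness:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "replicate", "W", "weight"],
            index=[f"s{i}" for i in range(len(rows))],
        )

    def test_equal_weights_single_replicate(self):
        df = self._frame(
            [("g", 1, 0.9, 10.0), ("g", 1, 1.0, 10.0), ("g", 1, 1.1, 10.0)]
        )
        rec = ft.gene_fitness(df)
        assert rec.loc["g", "W"] == pytest.approx(1.0)
        assert rec.loc["g", "sd"] == 0.0

    def test_read_weighted_mean(self):
        df = self._frame([("g", 1, 0.5, 100.0), ("g", 1, 1.0, 300.0)])
        assert ft.gene_fitness(df).loc["g", "W"] == pytest.approx(0.875)
        assert ft.gene_fitness(df, weighted=False).loc["g", "W"] == pytest.approx(0.75)

    def test_identical_replicates_zero_sd(self):
        df = self._frame([("g", r, 1.0, 50.0) for r in (1, 2, 3)])
        rec = ft.gene_fitness(df)
        assert rec.loc["g", "sd"] == 0.0
        assert rec.loc["g", "n_replicates"] == 3

    def test_sd_is_sample_sd_over_replicates(self):
        df = self._frame([("g", 1, 0.8, 1.0), ("g", 2, 1.0, 1.0), ("g", 3, 1.2, 1.0)])
        assert ft.gene_fitness(df).loc["g", "sd"] == pytest.approx(0.2)


class TestCallEssentials:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((0, 0, 0), "essential_zero"),
            ((1, 1, 0), "putative_lt1"),
            ((5, 4, 6), "nonessential"),
            ((1, 1, 1), "nonessential"),
        ],
    )
    def test_categories(self, counts, expected):
        df = pd.DataFrame([counts], index=["g"], columns=[1, 2, 3])
        assert ft.call_essentials(df).loc["g", "category"] == expected

    def test_mean_insertions_reported(self):
        df = pd.DataFrame([(1, 1, 0)], index=["g"], columns=[1, 2, 3])
        out = ft.call_essentials(df)
        assert out.loc["g", "mean_insertions"] == pytest.approx(2 / 3)


class TestThresholdBins:
    @pytest.mark.parametrize(
        "w,expected",
        [
            (0.05, "defective"),
            (0.1, "borderline"),
            (0.3, "borderline"),
            (0.5, "neutral"),
            (1.0, "neutral"),
            (2.0, "neutral"),
            (2.5, "high"),
            (3.5, "improved"),
        ],
    )
    def test_bin_edges(self, w, expected):
        bins, _ = ft.threshold_bins(pd.Series({"g": w}))
        assert bins["g"] == expected

    def test_counts_partition_and_overlap_reported(self):
        w = pd.Series([0.05, 0.3, 1.0, 2.5, 3.5, 4.0])
        _, counts = ft.threshold_bins(w)
        partition = sum(counts[k] for k in ft.BIN_ORDER)
        assert partition == counts["total"] == 6
        assert counts["high_total"] == 3  # every W > 2, improved included


class TestConditionCorrelation:
    def test_identical_vectors(self):
        w = pd.Series([0.1, 0.5, 1.0, 2.0], index=list("abcd"))
        assert ft.condition_correlation(w, w) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        b = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        assert ft.condition_correlation(a, b) == pytest.approx(-1.0)

    def test_single_swap_rho(self):
        """rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 12/60 = 0.8 for one
        adjacent rank swap among four."""
        a = pd.Series([1, 2, 3, 4], index=list("abcd"), dtype=float)
        b = pd.Series([1, 3, 2, 4], index=list("abcd"), dtype=float)
        assert ft.condition_correlation(a, b) == pytest.approx(0.8)

    def test_shared_gene_alignment(self):
        a = pd.Series([1.0, 2.0, 3.0, 9.0], index=list("abcx"))
        b = pd.Series([2.0, 4.0, 6.0, -1.0], index=list("abcy"))
        assert ft.condition_correlation(a, b) == pytest.approx(1.0)

    def test_too_few_shared_genes(self):
        a = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError, match="shared genes"):
            ft.condition_correlation(a, a)


class TestModelOnSimulatedData:
    def test_essential_genes_never_scored(self, recovery_world):
        res = recovery_world["results"]
        assert not set(recovery_world["essential"]) & set(res.gene_table.index)

    def test_weighted_and_unweighted_modes_close_on_good_data(self, recovery_world):
        from predfit import ExpansionFitnessModel

        res_u = ExpansionFitnessModel(
            recovery_world["table"],
            d=100.0,
            genes=recovery_world["genes"]["gene_id"],
            weighted=False,
        ).fit()
        diff = (res_u.W - recovery_world["results"].W).abs()
        assert diff.median() < 0.05

    def test_pseudocount_mode_lifts_zero_output(self):
        from predfit import ExpansionFitnessModel
        from predfit.tables import CountTable, make_samples

        sites = pd.DataFrame(
            {"position": [10, 20, 30], "strand": "+", "ta_valid": True,
             "gene_id": ["gA", "gB", "gC"]},
            index=pd.Index(["s1", "s2", "s3"], name="site_id"),
        )
        counts = pd.DataFrame(
            {"input_r1": [50, 1000, 950], "out_r1": [0, 1200, 800]}, index=sites.index
        )
        samples = make_samples(
            [("input_r1", "input", 1, "reference"), ("out_r1", "vcpl", 1, "selected")]
        )
        table = CountTable(sites=sites, counts=counts, samples=samples)
        dead = ExpansionFitnessModel(table, d=100.0).fit()
        assert dead.gene_table.loc["gA", "W"] == 0.0
        lifted = ExpansionFitnessModel(table, d=100.0, pseudocount=True).fit()
        assert lifted.gene_table.loc["gA", "W"] > 0.0

    def test_summary_mentions_key_quantities(self, recovery_world):
        text = recovery_world["results"].summary()
        assert "genes scored" in text and "essential" in text
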