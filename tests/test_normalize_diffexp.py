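"""Normalization, dispersion estimation, NB Wald test, class enrichment."""

import numpy as np
import pandas as pd
import pytest

from exomir.annotate_quantify import CountMatrix
from exomir.normalize_diffexp import (SizeFactors, bh_adjust,
                                      class_enrichment_test,
                                      differential_expression,
                                      estimate_dispersions,
                                      mirna_derived_size_factors,
                                      nb_wald_test, pirna_specific_pipeline,
                                      size_factors_median_of_ratios,
                                      spikein_normalize, spikein_size_factors)


def make_matrix(counts, classes=None, total=None, spikes=None):
    df = pd.DataFrame(counts)
    cls = pd.Series(classes if classes is not None else "miRNA",
                    index=df.index)
    tot = pd.Series(total if total is not None
                    else {s: float(df[s].sum()) for s in df.columns})
    spk = pd.Series(spikes if spikes is not None
                    else {s: 100.0 for s in df.columns})
    return CountMatrix(df, cls, tot, spk)


class TestSpikeinNormalize:
    def test_equal_spikes_and_depths_rescale_uniformly(self):
        m = make_matrix({"s1": {"a": 10.0, "b": 20.0},
                         "s2": {"a": 30.0, "b": 5.0}},
                        total={"s1": 1000, "s2": 1000},
                        spikes={"s1": 50, "s2": 50})
        n = spikein_normalize(m)
        ratio = n.counts / m.counts
        assert np.allclose(ratio.values, ratio.values[0, 0])

    def test_doubled_depth_duplicate_sample_normalizes_equal(self):
        m = make_matrix({"a": {"x": 10.0, "y": 40.0},
                         "b": {"x": 20.0, "y": 80.0}},
                        total={"a": 1000, "b": 2000},
                        spikes={"a": 60, "b": 120})
        n = spikein_normalize(m)
        assert np.allclose(n.counts["a"], n.counts["b"])

    def test_zero_spikein_is_hard_error_naming_sample(self):
        m = make_matrix({"s1": {"a": 1.0}, "s2": {"a": 1.0}},
                        spikes={"s1": 10, "s2": 0})
        with pytest.raises(ValueError, match="s2"):
            spikein_size_factors(m)


class TestMedianOfRatios:
    def test_hand_computed_two_by_two(self):
        # geometric means (8, 2); ratio medians 0.5 and 2.0
        sf = size_factors_median_of_ratios(
            pd.DataFrame({"s1": [4.0, 1.0], "s2": [16.0, 4.0]}))
        assert sf.values["s1"] == pytest.approx(0.5)
        assert sf.values["s2"] == pytest.approx(2.0)

    def test_proportional_columns_give_proportional_factors(self):
        base = np.array([5.0, 50.0, 500.0, 20.0])
        df = pd.DataFrame({"s1": base, "s2": 2 * base, "s3": 0.5 * base})
        sf = size_factors_median_of_ratios(df).values
        assert np.allclose(sf / sf["s1"], [1.0, 2.0, 0.5])

    def test_single_sample_factor_is_one(self):
        sf = size_factors_median_of_ratios(pd.DataFrame({"s1": [3.0, 7.0]}))
        assert sf.values["s1"] == pytest.approx(1.0)

    def test_no_all_positive_species_is_error(self):
        df = pd.DataFrame({"s1": [0.0, 5.0], "s2": [3.0, 0.0]})
        with pytest.raises(ValueError):
            size_factors_median_of_ratios(df)

    def test_zero_containing_species_excluded_from_reference(self):
        df = pd.DataFrame({"s1": [4.0, 0.0], "s2": [16.0, 99.0]})
        sf = size_factors_median_of_ratios(df).values
        assert sf["s1"] == pytest.approx(0.5) and sf["s2"] == pytest.approx(2.0)


def two_group_condition(n=3, samples=None):
    samples = samples or [f"s{i}" for i in range(2 * n)]
    return pd.Series(["control"] * n + ["EtOH"] * n, index=samples)


class TestEstimateDispersions:
    def test_poisson_counts_shrink_small(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(np.log(200), 1.0, 2000)
        counts = pd.DataFrame(rng.poisson(mu[:, None], (2000, 12)).astype(float),
                              columns=[f"s{i}" for i in range(12)])
        cond = pd.Series(["a"] * 6 + ["b"] * 6, index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersions(counts, sf, cond)
        assert disp["final_dispersion"].median() < 0.05

    def test_nb_dispersion_recovered_by_moments(self):
        rng = np.random.default_rng(1)
        alpha, mu, n = 0.2, 500.0, 20
        lam = rng.gamma(1 / alpha, alpha * mu, (500, n))
        counts = pd.DataFrame(rng.poisson(lam).astype(float),
                              columns=[f"s{i}" for i in range(n)])
        cond = pd.Series(["a"] * 10 + ["b"] * 10, index=counts.columns)
        disp = estimate_dispersions(counts, pd.Series(1.0, index=counts.columns),
                                    cond)
        assert 0.1 <= disp["raw_dispersion"].mean() <= 0.3

    def test_constant_counts_have_zero_raw_dispersion(self):
        counts = pd.DataFrame(np.full((5, 6), 40.0),
                              columns=[f"s{i}" for i in range(6)])
        cond = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        disp = estimate_dispersions(counts, pd.Series(1.0, index=counts.columns),
                                    cond)
        assert (disp["raw_dispersion"] == 0.0).all()
        assert (disp["final_dispersion"] > 0).all()


class TestNbWaldTest:
    def _null_counts(self, n_species=50, n=3, seed=2, mu=300.0, alpha=0.05):
        rng = np.random.default_rng(seed)
        lam = rng.gamma(1 / alpha, alpha * mu, (n_species, 2 * n))
        counts = pd.DataFrame(rng.poisson(lam).astype(float),
                              index=[f"g{i}" for i in range(n_species)],
                              columns=[f"s{i}" for i in range(2 * n)])
        return counts

    def test_constant_species_has_zero_log2fc(self):
        counts = pd.DataFrame(np.full((3, 6), 25.0),
                              columns=[f"s{i}" for i in range(6)])
        cond = two_group_condition(3, list(counts.columns))
        sf = pd.Series(1.0, index=counts.columns)
        res = nb_wald_test(counts, cond, sf)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)

    def test_baseline_relabel_flips_sign_only(self):
        counts = self._null_counts()
        counts.iloc[0, 3:] *= 4  # planted change in the second group
        cond = two_group_condition(3, list(counts.columns))
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersions(counts, sf, cond)
        a = nb_wald_test(counts, cond, sf, disp, baseline="control")
        b = nb_wald_test(counts, cond, sf, disp, baseline="EtOH")
        assert np.allclose(a["log2fc"], -b["log2fc"], atol=1e-6)
        assert np.allclose(a["p_value"], b["p_value"], atol=1e-9)

    def test_agrees_with_statsmodels_glm(self):
        import statsmodels.api as sm

        counts = self._null_counts(n_species=30, seed=5)
        cond = two_group_condition(3, list(counts.columns))
        sf = pd.Series(np.r_[0.8, 1.1, 1.0, 1.3, 0.9, 1.2],
                       index=counts.columns)
        disp = pd.Series(0.07, index=counts.index)
        res = nb_wald_test(counts, cond, sf, disp)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        for sid in counts.index[:10]:
            fit = sm.GLM(counts.loc[sid].values, X,
                         family=sm.families.NegativeBinomial(alpha=0.07),
                         offset=np.log(sf.values)).fit()
            assert res.loc[sid, "log2fc"] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-4)
            assert res.loc[sid, "se"] == pytest.approx(
                fit.bse[1] / np.log(2), rel=1e-3)

    def test_all_zero_species_marked_untested(self):
        counts = self._null_counts(n_species=5)
        counts.iloc[2] = 0.0
        cond = two_group_condition(3, list(counts.columns))
        res = nb_wald_test(counts, cond, pd.Series(1.0, index=counts.columns))
        assert not res.iloc[2]["tested"]
        assert np.isnan(res.iloc[2]["p_value"])

    def test_bh_q_monotone_in_p(self):
        counts = self._null_counts(n_species=200, seed=7)
        cond = two_group_condition(3, list(counts.columns))
        res = nb_wald_test(counts, cond, pd.Series(1.0, index=counts.columns))
        srt = res.dropna(subset=["p_value"]).sort_values("p_value")
        assert (np.diff(srt["q_value"].values) >= -1e-12).all()

    def test_candidate_flag_follows_raw_p(self):
        counts = self._null_counts(n_species=100, seed=8)
        counts.iloc[0, 3:] *= 8
        cond = two_group_condition(3, list(counts.columns))
        res = nb_wald_test(counts, cond, pd.Series(1.0, index=counts.columns))
        assert (res["candidate"] == (res["p_value"] < 0.05)).all()


class TestPirnaPipeline:
    def test_mirna_derived_factors_proportional(self):
        base = np.array([10.0, 100.0, 40.0])
        counts = pd.DataFrame({"s1": np.r_[base, 500.0, 900.0],
                               "s2": np.r_[3 * base, 500.0, 900.0]},
                              index=["m1", "m2", "m3", "p1", "p2"])
        m = make_matrix(counts,
                        classes=["miRNA"] * 3 + ["piRNA"] * 2)
        sf = mirna_derived_size_factors(m).values
        assert sf["s2"] / sf["s1"] == pytest.approx(3.0)

    def test_no_mirna_rows_is_hard_error(self):
        m = make_matrix({"s1": {"p1": 5.0}, "s2": {"p1": 6.0}},
                        classes={"p1": "piRNA"})
        with pytest.raises(ValueError, match="miRNA"):
            mirna_derived_size_factors(m)

    def test_no_pirna_rows_warns_and_returns_empty(self):
        m = make_matrix({"s1": {"m1": 5.0}, "s2": {"m1": 6.0}},
                        classes={"m1": "miRNA"})
        sheet = pd.DataFrame({"sample": ["s1", "s2"],
                              "condition": ["control", "EtOH"],
                              "batch": ["b", "b"], "timepoint": ["E16"] * 2})
        with pytest.warns(UserWarning, match="piRNA"):
            res = pirna_specific_pipeline(m, sheet)
        assert res.empty

    def test_pirna_tested_with_mirna_reference(self, default_run):
        genome, anns, spikes, sim = default_run
        cls = pd.Series({a.species_id: a.rna_class for a in anns})
        m = CountMatrix(sim.truth.counts, cls,
                        sim.truth.counts.sum(axis=0),
                        sim.truth.spike_counts)
        res = pirna_specific_pipeline(m, sim.sheet, timepoint="E16")
        assert set(res["rna_class"]) == {"piRNA"}
        # most planted piRNA effects are recovered with the right sign
        planted = {"pir-0001": 1, "pir-0002": 1, "pir-0003": -1}
        hits = sum(res.loc[s, "p_value"] < 0.05
                   and np.sign(res.loc[s, "log2fc"]) == sign
                   for s, sign in planted.items())
        assert hits >= 2


class TestClassEnrichment:
    def test_identical_class_totals_give_null_result(self):
        m = make_matrix({"s1": {"m": 10.0, "p": 10.0},
                         "s2": {"m": 4.0, "p": 4.0},
                         "s3": {"m": 7.0, "p": 7.0}},
                        classes={"m": "miRNA", "p": "piRNA"})
        res = class_enrichment_test(m)
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        m = make_matrix({"s1": {"m": 1.0, "p": 4.0},
                         "s2": {"m": 2.0, "p": 5.0},
                         "s3": {"m": 3.0, "p": 6.0}},
                        classes={"m": "miRNA", "p": "piRNA"})
        with pytest.warns(UserWarning, match="degenerate"):
            res = class_enrichment_test(m)
        assert res.p_value <= np.finfo(float).tiny
        assert res.t_stat == np.inf

    def test_richness_statistic_counts_detected_species(self):
        m = make_matrix({"s1": {"m1": 1.0, "m2": 0.0, "p1": 2.0, "p2": 3.0},
                         "s2": {"m1": 1.0, "m2": 5.0, "p1": 2.0, "p2": 0.0}},
                        classes={"m1": "miRNA", "m2": "miRNA",
                                 "p1": "piRNA", "p2": "piRNA"})
        res = class_enrichment_test(m, statistic="richness")
        assert list(res.per_sample["piRNA"]) == [2.0, 1.0]
        assert list(res.per_sample["miRNA"]) == [1.0, 2.0]

    def test_single_sample_rejected(self):
        m = make_matrix({"s1": {"m": 1.0, "p": 2.0}},
                        classes={"m": "miRNA", "p": "piRNA"})
        with pytest.raises(ValueError):
            class_enrichment_test(m)

    def test_default_design_strongly_enriched(self, default_run):
        genome, anns, spikes, sim = default_run
        cls = pd.Series({a.species_id: a.rna_class for a in anns})
        m = CountMatrix(sim.truth.counts, cls,
                        sim.truth.counts.sum(axis=0),
                        sim.truth.spike_counts)
        res = class_enrichment_test(spikein_normalize(m))
        assert res.p_value < 0.01
        assert res.mean_difference > 0 and res.ci_low > 0


def test_bh_adjust_keeps_missing():
    p = pd.Series([0.01, np.nan, 0.5])
    q = bh_adjust(p)
    assert np.isnan(q.iloc[1]) and q.notna().sum() == 2


def test_size_factor_positivity_enforced():
    with pytest.raises(ValueError):
        SizeFactors(pd.Series({"s": 0.0}), "spikein")
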