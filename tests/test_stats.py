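"""Binning, relative frequencies, trend test, ANOVA/Tukey, sensitivity sweep."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from pharmscore.io import DrugStatus, reference_trend_counts
from pharmscore.simulate import SimulationConfig, simulate_cohort, simulate_status
from pharmscore.scoring import score_cohort, summarize_population
from pharmscore.stats import (
    anova_tukey,
    assign_bins,
    bin_labels,
    categorize_auc,
    cochran_armitage_trend,
    relative_frequencies,
    sensitivity_sweep,
    trend_table,
)


def exact_permutation_p(events, totals):
    """Exhaustive permutation oracle for the trend test on tiny tables.

    Enumerates every placement of the events among the N observations
    (bin sizes fixed) and returns P(|z| >= |z_obs|).
    """
    events = np.asarray(events)
    totals = np.asarray(totals)
    labels = np.repeat(np.arange(len(totals)), totals)
    z_obs = cochran_armitage_trend(events, totals).statistic
    hits = total = 0
    for pos in itertools.combinations(range(int(totals.sum())), int(events.sum())):
        counts = np.bincount(labels[list(pos)], minlength=len(totals))
        z = cochran_armitage_trend(counts, totals).statistic
        total += 1
        if abs(z) >= abs(z_obs) - 1e-12:
            hits += 1
    return hits / total


class TestAssignBins:
    @pytest.mark.parametrize(
        "auc,expected",
        [(0.05, 1), (0.10, 1), (0.1000001, 2), (0.0, 1), (1.0, 10), (0.95, 10)],
    )
    def test_right_closed_edges(self, auc, expected):
        assert assign_bins(auc) == expected

    def test_vectorized(self):
        out = assign_bins(np.array([0.05, 0.55, 1.0]), n_bins=10)
        assert out.tolist() == [1, 6, 10]

    def test_labels(self):
        assert bin_labels(10)[0] == "~0.1"
        assert bin_labels(10)[-1] == "~1"


class TestRelativeFrequencies:
    def test_direct_division(self):
        out = relative_frequencies([1, 4], [5, 14])
        assert out[0] == pytest.approx(0.2)
        assert out[1] == pytest.approx(4 / 14)

    def test_all_events(self):
        assert relative_frequencies([3, 7], [3, 7]).tolist() == [1.0, 1.0]

    def test_zero_total_is_nan_not_zero(self):
        out = relative_frequencies([0, 2], [0, 4])
        assert math.isnan(out[0]) and out[1] == 0.5


class TestTrend:
    def test_null_by_construction(self):
        """Events exactly proportional to totals give statistic 0, p = 1."""
        res = cochran_armitage_trend([1, 2, 3], [10, 20, 30])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_tables_flagged_not_raised(self):
        assert cochran_armitage_trend([0, 0, 0], [5, 5, 5]).degenerate
        assert cochran_armitage_trend([5, 5, 5], [5, 5, 5]).degenerate
        assert cochran_armitage_trend([0, 1], [0, 10]).degenerate  # 1 non-empty bin
        assert cochran_armitage_trend([0, 0, 0], [5, 5, 5]).p_value == 1.0

    def test_score_reversal_flips_sign_keeps_p(self):
        ev, tot = [1, 3, 8], [10, 10, 10]
        fwd = cochran_armitage_trend(ev, tot, scores=[1, 2, 3])
        rev = cochran_armitage_trend(ev, tot, scores=[3, 2, 1])
        assert rev.statistic == pytest.approx(-fwd.statistic, rel=1e-12)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-12)

    def test_affine_invariance_of_scores(self):
        ev, tot = [2, 5, 9, 12], [20, 20, 20, 20]
        base = cochran_armitage_trend(ev, tot, scores=[1, 2, 3, 4])
        scaled = cochran_armitage_trend(ev, tot, scores=[10, 30, 50, 70])
        assert scaled.statistic == pytest.approx(base.statistic, rel=1e-12)
        midpoints = cochran_armitage_trend(ev, tot, scores=[0.05, 0.15, 0.25, 0.35])
        assert midpoints.p_value == pytest.approx(base.p_value, rel=1e-12)

    def test_two_bin_equals_two_proportion_z(self):
        """On 2 bins the squared trend statistic is the pooled chi-square."""
        for ev, tot in [([3, 9], [12, 15]), ([1, 7], [10, 10]), ([5, 2], [8, 11])]:
            res = cochran_armitage_trend(ev, tot)
            p1, p2 = ev[0] / tot[0], ev[1] / tot[1]
            pooled = sum(ev) / sum(tot)
            z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / tot[0] + 1 / tot[1]))
            assert res.statistic**2 == pytest.approx(z**2, abs=1e-10)
            assert res.p_value == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-10)

    @pytest.mark.parametrize(
        "events,totals,exact_expected",
        [
            # frozen from the exhaustive permutation oracle
            ((0, 2, 3), (4, 4, 4), 16 / 198),
            ((1, 2, 4), (5, 4, 4), 0.02564102564102564),
            ((0, 1, 3), (4, 4, 4), 0.06868686868686869),
        ],
    )
    def test_small_table_agrees_with_permutation_oracle(
        self, events, totals, exact_expected
    ):
        """Asymptotic p within 0.06 of the exact permutation p at n = 12–13."""
        exact = exact_permutation_p(events, totals)
        assert exact == pytest.approx(exact_expected, rel=1e-12)
        asym = cochran_armitage_trend(events, totals).p_value
        assert asym == pytest.approx(exact, abs=0.06)

    def test_reference_table_p_values(self):
        """Printed single-source rows reproduce to printed precision."""
        tt = trend_table(reference_trend_counts())
        assert tt.loc["withdrawn_un", "p_value"] == pytest.approx(0.001, abs=5e-4)
        assert tt.loc["withdrawn_ema", "p_value"] == pytest.approx(0.007, abs=5e-4)
        assert tt.loc["withdrawn_drugbank", "p_value"] == pytest.approx(0.053, abs=5e-4)
        # trend direction: withdrawal proportion falls as AUC rises
        assert (tt["statistic"] < 0).all()


class TestAnovaTukey:
    def test_identical_groups_no_signal(self):
        g = [0.4, 0.5, 0.6, 0.7]
        comp = anova_tukey({"a": g, "b": list(g)})
        assert comp.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert (comp.pairwise["p_adj"].astype(float) > 0.9).all()

    def test_full_separation(self):
        comp = anova_tukey({"a": [0.0, 0.0, 0.0], "b": [1.0, 1.0, 1.0]})
        assert comp.p_value < 1e-6

    def test_means_reproduce_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=10)
        b = rng.uniform(size=7)
        comp = anova_tukey({"a": a, "b": b})
        assert comp.summary.loc["a", "mean"] == pytest.approx(a.mean())
        assert comp.summary.loc["a", "sd"] == pytest.approx(a.std(ddof=1))
        shuffled = anova_tukey({"a": a[rng.permutation(10)], "b": b})
        assert shuffled.f_statistic == pytest.approx(comp.f_statistic, rel=1e-10)

    def test_pairwise_covers_all_pairs(self):
        comp = anova_tukey({"a": [0.1, 0.2], "b": [0.3, 0.4], "c": [0.5, 0.6]})
        pairs = {
            frozenset((r.group1, r.group2)) for r in comp.pairwise.itertuples()
        }
        assert pairs == {frozenset(p) for p in itertools.combinations("abc", 2)}

    def test_small_category_excluded_with_warning(self):
        comp = anova_tukey({"a": [0.1, 0.2, 0.3], "b": [0.4, 0.5], "tiny": [0.9]})
        assert comp.excluded == ["tiny"]
        assert "tiny" not in comp.summary.index

    def test_too_few_categories_raise(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [0.1, 0.2], "tiny": [0.9]})

    def test_group_separation_recovered_at_reference_sizes(self):
        """Safe-category drugs separate from the three flagged categories.

        Groups are drawn at the reference category means/SDs and sample sizes
        (withdrawn 0.558±0.170 n=154, Beers 0.549±0.153 n=90, FDA 0.542±0.145
        n=96, other 0.635±0.187 n=752).  Stochastic property: per seed the
        'other' mean is the largest and the overall ANOVA rejects at 0.001;
        jointly all three other-vs-flagged Tukey comparisons reach 0.05 in
        the large majority of seeds and 0.001 in an appreciable fraction.
        """
        specs = {
            "withdrawn": (0.558, 0.170, 154),
            "beers": (0.549, 0.153, 90),
            "fda": (0.542, 0.145, 96),
            "other": (0.635, 0.187, 752),
        }
        n_rep = 20
        joint_05 = joint_001 = 0
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            groups = {
                name: np.clip(rng.normal(mu, sd, size=n), 0.001, 1.0)
                for name, (mu, sd, n) in specs.items()
            }
            comp = anova_tukey(groups)
            assert comp.summary["mean"].idxmax() == "other"
            assert comp.p_value < 0.001
            pw = comp.pairwise
            other_p = pw[(pw["group1"] == "other") | (pw["group2"] == "other")][
                "p_adj"
            ].astype(float)
            joint_05 += (other_p < 0.05).all()
            joint_001 += (other_p < 0.001).all()
        assert joint_05 >= 15
        assert joint_001 >= 4


class TestSensitivitySweep:
    def test_threshold_sweep_monotone_and_consistent_sign(self):
        cfg = SimulationConfig(
            n_individuals=120, n_genes=150, n_drugs=120,
            genes_per_drug_min=1, genes_per_drug_extra_mean=6.0, seed=21,
        )
        geno, anns, dmap = simulate_cohort(cfg)
        scores = score_cohort(geno, anns, dmap, keep_gene_scores=False)
        summ = summarize_population(scores)
        status = simulate_status(summ.frame["auc"], 1.25, -6.0, seed=22)
        frame, comps = sensitivity_sweep(
            geno, anns, dmap, status, min_genes_range=range(1, 8)
        )
        counts = frame["n_drugs"].tolist()
        assert counts == sorted(counts, reverse=True)
        # injected effect: withdrawn mean AUC below 'other' mean at every threshold
        for k, comp in comps.items():
            if {"withdrawn", "other"} <= set(comp.summary.index):
                assert (
                    comp.summary.loc["withdrawn", "mean"]
                    < comp.summary.loc["other", "mean"]
                )


def test_categorize_auc_groups_overlap():
    import pandas as pd

    frame = pd.DataFrame({"auc": [0.2, 0.8, 0.5]}, index=["d1", "d2", "d3"])
    status_frame = pd.DataFrame(
        {
            "withdrawn_UN": [True, False, False],
            "withdrawn_EMA": [False, False, False],
            "withdrawn_DrugBank": [False, False, False],
            "precaution_Beers": [True, False, False],
            "precaution_FDA": [False, False, False],
        },
        index=pd.Index(["d1", "d2", "d3"], name="drug_id"),
    )
    groups = categorize_auc(frame, DrugStatus(status_frame))
    assert groups["withdrawn"] == [0.2]
    assert groups["beers"] == [0.2]  # same drug in two categories
    assert sorted(groups["other"]) == [0.5, 0.8]
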