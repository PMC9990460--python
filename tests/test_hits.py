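import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from gliascreen.hits import (
    HitSelectionWarning,
    Thresholds,
    call_hits,
    classify_lps_dependence,
    compute_ssmd,
    hedges_g,
    hit_percentages,
    score_genes,
    validation_concordance,
)

values = st.lists(st.floats(-50, 50), min_size=2, max_size=10)


class TestComputeSSMD:
    def test_identical_distributions_score_zero(self):
        assert compute_ssmd([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_two_sd_separation(self):
        # means 2 vs 0, both SD 1 -> 2/sqrt(1+1)
        s = [1.0, 2.0, 3.0]
        c = [-1.0, 0.0, 1.0]
        assert compute_ssmd(s, c) == pytest.approx(2 / math.sqrt(2), abs=1e-12)

    def test_single_value_group_is_rejected(self):
        with pytest.raises(ValueError):
            compute_ssmd([1.0], [0.0, 1.0])

    def test_zero_variance_equal_means_is_zero(self):
        assert compute_ssmd([2.0, 2.0], [2.0, 2.0]) == 0.0

    def test_zero_variance_unequal_means_gives_signed_infinity_sentinel(self):
        with pytest.warns(HitSelectionWarning):
            up = compute_ssmd([3.0, 3.0], [1.0, 1.0])
        with pytest.warns(HitSelectionWarning):
            down = compute_ssmd([1.0, 1.0], [3.0, 3.0])
        assert up == math.inf and down == -math.inf

    @given(values, values)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_group_swap(self, a, b):
        x = compute_ssmd(a, b)
        y = compute_ssmd(b, a)
        if math.isfinite(x):
            assert x == pytest.approx(-y, abs=1e-9)

    @given(values, values, st.floats(-10, 10), st.floats(0.1, 10))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_common_positive_affine_transform(self, s, c, a, b):
        x = compute_ssmd(s, c)
        y = compute_ssmd([a + b * v for v in s], [a + b * v for v in c])
        if math.isfinite(x):
            assert y == pytest.approx(x, abs=max(1e-9, 1e-9 * abs(x)))

    def test_umvue_variant_matches_closed_form(self):
        s = np.array([1.0, 2.0, 3.0, 2.5])
        c = np.array([-1.0, 0.0, 1.0])
        k = len(s) + len(c) - 2
        ss = (len(s) - 1) * s.var(ddof=1) + (len(c) - 1) * c.var(ddof=1)
        expected = (
            math.exp(gammaln(k / 2) - gammaln((k - 1) / 2))
            * (s.mean() - c.mean())
            / math.sqrt(ss)
        )
        assert compute_ssmd(s, c, umvue=True) == pytest.approx(expected, abs=1e-12)


class TestCallHits:
    TH = Thresholds()

    @pytest.mark.parametrize(
        ("fc", "ssmd", "expected"),
        [
            (0.6, 1.7, "increased"),
            (0.6, 1.0, "none"),  # SSMD below cutoff forces none
            (-0.5, -1.65, "decreased"),  # boundaries are inclusive
            (0.5, 1.65, "increased"),
            (0.49, 5.0, "none"),
            (-0.6, 1.7, "none"),  # signs must agree
            (0.6, -1.7, "none"),
            (0.0, 0.0, "none"),
            (2.0, math.inf, "increased"),  # zero-variance sentinel is extreme, not invalid
            (-2.0, -math.inf, "decreased"),
        ],
    )
    def test_dual_flashlight_categories(self, fc, ssmd, expected):
        assert call_hits(fc, ssmd, self.TH) == expected

    def test_nan_input_is_rejected(self):
        with pytest.raises(ValueError):
            call_hits(float("nan"), 1.0, self.TH)

    @given(
        fc=st.floats(-3, 3),
        ssmd=st.floats(-5, 5),
        dfc=st.floats(0, 1),
        dssmd=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_both_inputs(self, fc, ssmd, dfc, dssmd):
        """Raising FC and SSMD never demotes an 'increased' call."""
        if call_hits(fc, ssmd, self.TH) == "increased":
            assert call_hits(fc + dfc, ssmd + dssmd, self.TH) == "increased"
        if call_hits(fc, ssmd, self.TH) == "decreased":
            assert call_hits(fc - dfc, ssmd - dssmd, self.TH) == "decreased"


class TestLPSDependence:
    def test_threefold_stronger_under_lps_is_dependent(self):
        assert classify_lps_dependence(3.0, 1.0)

    def test_equal_fold_changes_are_independent(self):
        assert not classify_lps_dependence(2.0, 2.0)

    def test_ratio_exactly_at_threshold_is_independent(self):
        assert not classify_lps_dependence(1.5, 1.0)

    def test_decreased_phenotype_uses_magnitude_ratio(self):
        # knockdown halves the phenotype under LPS but not untreated
        assert classify_lps_dependence(0.5, 1.0)
        assert not classify_lps_dependence(0.5, 0.5)

    def test_nonpositive_fold_change_is_rejected(self):
        with pytest.raises(ValueError):
            classify_lps_dependence(1.0, 0.0)


class TestHedgesG:
    def test_identical_groups_with_spread_are_negligible(self):
        g, label = hedges_g([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert g == 0.0 and label == "negligible"

    def test_small_sample_correction_at_n3(self):
        # mean difference 2, pooled SD 1, df = 4 -> J = 1 - 3/15 = 0.8, g = 1.6
        s = [1.0, 2.0, 3.0]
        c = [-1.0, 0.0, 1.0]
        g, label = hedges_g(s, c)
        assert g == pytest.approx(1.6, abs=1e-12)
        assert label == "large"

    def test_zero_pooled_sd_is_rejected(self):
        with pytest.raises(ValueError):
            hedges_g([1.0, 1.0], [0.0, 0.0])

    @pytest.mark.parametrize(
        ("delta", "label"),
        # pooled SD 1, df 4 -> g = 0.8 * delta
        [(1.2, "large"), (-1.2, "large"), (0.75, "moderate"), (0.3, "small"), (0.1, "negligible")],
    )
    def test_magnitude_labels(self, delta, label):
        c = [-1.0, 0.0, 1.0]
        s = [v + delta for v in c]
        g, got = hedges_g(s, c)
        assert g == pytest.approx(0.8 * delta, abs=1e-12)
        assert got == label

    def test_converges_to_cohens_d_for_large_samples(self, rng):
        s = rng.normal(0.5, 1.0, 1000)
        c = rng.normal(0.0, 1.0, 1000)
        df = len(s) + len(c) - 2
        pooled = math.sqrt(
            ((len(s) - 1) * s.var(ddof=1) + (len(c) - 1) * c.var(ddof=1)) / df
        )
        d = (s.mean() - c.mean()) / pooled
        g, _ = hedges_g(s, c)
        assert abs(g - d) < 0.01


class TestValidationConcordance:
    def test_full_agreement(self):
        calls = {"a": "increased", "b": "decreased", "c": "increased", "d": "increased"}
        conc, fpr, n = validation_concordance(calls, calls)
        assert (conc, fpr, n) == (100.0, 0.0, 4)

    def test_one_of_four_disagreements_is_25_percent(self):
        screen = {"a": "increased", "b": "decreased", "c": "increased", "d": "increased"}
        valid = dict(screen, d="none")
        conc, fpr, n = validation_concordance(screen, valid)
        assert fpr == 25.0 and conc == 75.0 and n == 4

    def test_non_hits_are_not_compared(self):
        screen = {"a": "increased", "b": "none"}
        valid = {"a": "increased", "b": "decreased"}
        conc, fpr, n = validation_concordance(screen, valid)
        assert n == 1 and fpr == 0.0

    def test_disjoint_gene_sets_are_rejected(self):
        with pytest.raises(ValueError):
            validation_concordance({"a": "increased"}, {"b": "increased"})


class TestHitPercentages:
    def test_zero_and_full_library(self):
        out = hit_percentages({"none_found": 0, "all": 623}, 623)
        assert out == {"none_found": 0.0, "all": 100.0}

    def test_count_above_library_size_is_rejected(self):
        with pytest.raises(ValueError):
            hit_percentages({"x": 624}, 623)

    def test_round_half_even_at_exact_halves(self):
        # 1/8 of 200 = 0.625% -> banker's rounding to 0.6
        assert hit_percentages({"x": 5}, 4000) == {"x": 0.1}
        assert hit_percentages({"x": 25}, 2000) == {"x": 1.2}  # 1.25 -> 1.2
        assert hit_percentages({"x": 35}, 2000) == {"x": 1.8}  # 1.75 -> 1.8


def test_score_genes_flags_lps_dependent_hits():
    """A gene shifted only under LPS is called a hit there and marked dependent."""
    rows = []
    rng = np.random.default_rng(5)
    for cond in ("LPS", "PBS"):
        for rep in (1, 2):
            plate = f"S{rep}_{cond}_R1_M1"
            for i in range(3):
                rows.append(
                    dict(plate_id=plate, well=f"H0{i+1}", role="neg_control_siRNA",
                         gene_id="", condition=cond, screen_repeat=rep, assay="no",
                         value=10.0 * math.exp(rng.normal(0, 0.02)))
                )
            shift = 2.0 if cond == "LPS" else 1.0
            for i in range(3):
                rows.append(
                    dict(plate_id=plate, well=f"A0{i+1}", role="library",
                         gene_id="KIN0001", condition=cond, screen_repeat=rep, assay="no",
                         value=10.0 * shift * math.exp(rng.normal(0, 0.02)))
                )
    stats = score_genes(pd.DataFrame(rows))
    lps_row = stats[(stats.condition == "LPS") & (stats.gene_id == "KIN0001")].iloc[0]
    assert lps_row.category == "increased"
    assert lps_row.n_wells == 6
    assert lps_row.lps_dependent is True or lps_row.lps_dependent == True  # noqa: E712
    pbs_row = stats[(stats.condition == "PBS") & (stats.gene_id == "KIN0001")].iloc[0]
    assert pbs_row.category == "none"
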