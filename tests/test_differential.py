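"""Roll-up, duplicate averaging, and the differential-abundance statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from matriquant.differential import (average_duplicates, bh_adjust, cohens_d,
                                     curate, differential_analysis,
                                     error_weighted_anova, fit_error_curve,
                                     rollup, signed_fold_change)
from matriquant.io import merge_fractions
from matriquant.model import ValidationError


def pep_matrix(cells):
    """cells: {(peptide, accession): {sample: value}}"""
    frame = pd.DataFrame(cells).T
    frame.index.names = ["peptide", "accession"]
    return frame


class TestRollup:
    def test_sum_per_protein(self):
        mat = pep_matrix({("A", "P1"): {"s1": 100.0}, ("B", "P1"): {"s1": 200.0},
                          ("C", "P1"): {"s1": 300.0}})
        rolled = rollup(mat)
        assert rolled.intensity.loc["P1", "s1"] == 600.0
        assert rolled.peptide_counts.loc["P1", "s1"] == 3

    def test_absent_protein_is_missing_not_zero(self):
        mat = pep_matrix({("A", "P1"): {"s1": 10.0, "s2": np.nan},
                          ("B", "P2"): {"s1": 5.0, "s2": 7.0}})
        rolled = rollup(mat)
        assert np.isnan(rolled.intensity.loc["P1", "s2"])
        assert rolled.intensity.loc["P2", "s2"] == 7.0

    def test_conservation(self, noisy_dataset):
        matrix = merge_fractions(noisy_dataset.records).matrix
        rolled = rollup(matrix)
        assert rolled.intensity.sum().sum() == pytest.approx(
            matrix.sum().sum(), rel=1e-12)


class TestAverageDuplicates:
    def _meta(self):
        return pd.DataFrame({
            "tissue": ["ACL", "ACL"], "sex": ["M", "M"], "donor": [3, 3],
            "replicate": [1, 2], "injected_mass_ug": 3.0,
            "spike_fmol_per_ug": 25.0,
        }, index=pd.Index(["ACL_M3_r1", "ACL_M3_r2"], name="sample_id"))

    def test_mean_of_duplicates(self):
        mat = pd.DataFrame({"ACL_M3_r1": [600.0], "ACL_M3_r2": [800.0]},
                           index=["P1"])
        out = average_duplicates(mat, self._meta())
        assert out.loc["P1", "ACL_M3"] == 700.0

    def test_missing_cell_falls_back_to_present_run(self):
        mat = pd.DataFrame({"ACL_M3_r1": [np.nan], "ACL_M3_r2": [800.0]},
                           index=["P1"])
        out = average_duplicates(mat, self._meta())
        assert out.loc["P1", "ACL_M3"] == 800.0

    def test_no_duplicates_identity(self):
        meta = self._meta().iloc[:1]
        mat = pd.DataFrame({"ACL_M3_r1": [5.0]}, index=["P1"])
        out = average_duplicates(mat, meta)
        assert out.loc["P1", "ACL_M3"] == 5.0


class TestSignedFoldChange:
    @pytest.mark.parametrize("num,den,expected", [
        (2.0, 1.0, 2.0),
        (1.0, 5.0, -5.0),       # ratio 0.2 prints as −5
        (1.0, 1.0, 1.0),
    ])
    def test_convention(self, num, den, expected):
        assert signed_fold_change(num, den) == pytest.approx(expected)

    def test_undefined_flagged_nan(self):
        assert np.isnan(signed_fold_change(0.0, 1.0))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_antisymmetry(self, a, b):
        fwd, rev = signed_fold_change(a, b), signed_fold_change(b, a)
        assert abs(fwd) >= 1 and abs(abs(fwd) - abs(rev)) < 1e-9


class TestErrorWeightedAnova:
    def test_identical_groups(self):
        f, p = error_weighted_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_unit_weights_match_textbook_anova(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(3)]
            f, p = error_weighted_anova(groups)
            ref = stats.f_oneway(*groups)
            assert f == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_weight_scale_invariance(self):
        groups = [[1.0, 2.0, 4.0], [3.0, 5.0, 6.0]]
        w1 = [np.ones(3), np.ones(3)]
        w7 = [np.full(3, 7.0), np.full(3, 7.0)]
        assert error_weighted_anova(groups, w1) == pytest.approx(
            error_weighted_anova(groups, w7))

    def test_degenerate_zero_variance(self):
        f, p = error_weighted_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(f) and p == np.finfo(float).tiny

    def test_needs_two_per_group(self):
        with pytest.raises(ValidationError):
            error_weighted_anova([[1.0], [2.0, 3.0]])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        # step-up: p(i) × n/i then cummin from the largest rank
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_adjust([0.001, 0.01, 0.9]),
                                   [0.003, 0.015, 0.9])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_dominates_raw_and_capped(self, ps):
        adj = bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)

    def test_hochberg_variant(self):
        adj = bh_adjust([0.01, 0.04], method="hochberg")
        assert adj[0] == pytest.approx(0.02) and adj[1] == pytest.approx(0.04)


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_value(self):
        # pooled SD 1, mean difference −2
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_zero_pooled_sd_signed_infinity(self):
        assert cohens_d([1.0, 1.0], [2.0, 2.0]) == -np.inf


class TestCurate:
    def _results(self):
        return pd.DataFrame({
            "fold_change": [2.0, 3.0, -2.5],
            "p_adj": [0.04, 0.04, 0.01],
            "cohen_d": [0.5, 2.0, -3.0],
        }, index=pd.Index(["P1", "P2", "P3"], name="accession"))

    def test_rule_application(self):
        counts = pd.Series({"P1": 5, "P2": 5, "P3": 1})
        out = curate(self._results(), counts)
        # P1 fails |d|, P3 fails peptide count
        assert list(out.index) == ["P2"]

    def test_empty(self):
        out = curate(self._results().iloc[0:0], pd.Series(dtype=float))
        assert out.empty


class TestDifferentialAnalysis:
    def test_programmed_effect_recovered_exact(self, clean_dataset):
        records, meta, truth = clean_dataset
        rolled = rollup(merge_fractions(records).matrix)
        res = differential_analysis(rolled.intensity, meta, "ACL")
        assert res.loc["ALBU_HUMAN", "fold_change"] == pytest.approx(2.0, rel=1e-9)
        assert res.loc["LUM_HUMAN", "fold_change"] == pytest.approx(1.0, rel=1e-9)
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()

    def test_error_curve_fit_from_duplicates(self):
        from matriquant.simulate import SimulationConfig, simulate_dataset
        records, meta, _ = simulate_dataset(SimulationConfig(), seed=13)
        rolled = rollup(merge_fractions(records).matrix)
        t_meta = meta[meta["tissue"] == "ACL"]
        cols = [c for c in rolled.intensity.columns if c in t_meta.index]
        curve = fit_error_curve(rolled.intensity[cols], t_meta)
        assert curve is not None
        v = curve(np.array([10.0, 20.0]))
        assert np.all(v > 0)

    def test_no_duplicates_falls_back_to_unit_weights(self, clean_dataset):
        records, meta, _ = clean_dataset
        singles = meta[meta["replicate"] == 1]
        rolled = rollup(merge_fractions(
            records[records["sample_id"].isin(singles.index)]).matrix)
        assert fit_error_curve(rolled.intensity, singles) is None
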