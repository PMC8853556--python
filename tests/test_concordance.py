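"""Sign calls, Cohen's kappa, the resampling null, BH adjustment, and
regulatory classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxcord.concordance import (
    SignMatrix,
    bh_adjust,
    classify_reactions,
    cohens_kappa,
    empirical_null_pvalues,
    kappa_series,
    ordered_pairs,
    pairwise_sign_matrix,
    variation_sign,
)


def _matrix(rows: dict, pairs=(("A", "B"), ("A", "C"), ("B", "C")), tag="x"):
    data = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"{a}|{b}" for a, b in pairs])
    return SignMatrix(tag=tag, data=data, pairs=tuple(pairs))


class TestVariationSign:
    def test_identical_vectors_no_change(self):
        x = np.array([1.0, 2.0, 3.0])
        assert variation_sign(x, x, "samples") == 0

    def test_distribution_twenty_percent_up(self):
        rng = np.random.default_rng(0)
        a = 12.0 + 0.05 * rng.standard_normal(2000)
        b = 10.0 + 0.05 * rng.standard_normal(2000)
        assert variation_sign(a, b, "distribution") == 1

    def test_samples_down_at_ratio_below_point_eight(self):
        a = np.array([10.0, 10.05, 9.95])
        b = np.array([13.0, 13.05, 12.95])     # 10/13 ~ 0.769 <= 0.8
        assert variation_sign(a, b, "samples") == -1

    def test_significant_but_small_fold_is_zero(self):
        rng = np.random.default_rng(1)
        a = 11.0 + 0.05 * rng.standard_normal(5000)
        b = 10.0 + 0.05 * rng.standard_normal(5000)   # ratio 1.1 < 1.2
        assert variation_sign(a, b, "distribution") == 0

    def test_single_value_group_warns_zero(self):
        with pytest.warns(UserWarning):
            assert variation_sign([1.0], [2.0, 3.0], "samples") == 0

    def test_zero_denominator_with_signal(self):
        a = np.array([5.0, 5.2, 4.8])
        b = np.zeros(3)
        b[0] = 1e-12
        assert variation_sign(a, b, "samples") in (0, 1)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            variation_sign([1.0, 2.0], [1.0, 2.0], "fancy")


class TestPairEnumeration:
    @pytest.mark.parametrize("n_groups, n_pairs", [(2, 1), (3, 3), (5, 10)])
    def test_pair_counts(self, n_groups, n_pairs):
        groups = [f"g{i}" for i in range(n_groups)]
        rng = np.random.default_rng(0)
        data = {
            g: pd.DataFrame(rng.lognormal(0, 0.1, size=(4, 3)),
                            index=[f"r{k}" for k in range(4)])
            for g in groups
        }
        matrix = pairwise_sign_matrix(data, "samples")
        assert matrix.data.shape == (4, n_pairs)
        assert matrix.pairs == ordered_pairs(groups)


class TestKappa:
    def test_identical_nonconstant_is_one(self):
        v = [1, 1, 0, -1, 0, 1, -1, 0, 1, 1]
        assert cohens_kappa(v, v) == 1.0

    def test_opposite_balanced_two_category_is_minus_one(self):
        a = [1] * 5 + [-1] * 5
        b = [-x for x in a]
        assert cohens_kappa(a, b) == -1.0

    def test_worked_contingency_example(self):
        # p_o = 3/4, p_e = 0.3125 -> kappa = 7/11
        assert cohens_kappa([1, 1, 0, -1], [1, 0, 0, -1]) == pytest.approx(0.636363636)

    def test_degenerate_constants(self):
        assert cohens_kappa([0, 0, 0], [0, 0, 0]) == 1.0
        assert cohens_kappa([1, 1, 1], [-1, -1, -1]) == -1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa([], [])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.sampled_from([-1, 0, 1]), min_size=10, max_size=10),
        b=st.lists(st.sampled_from([-1, 0, 1]), min_size=10, max_size=10),
    )
    def test_symmetry_and_relabeling_invariance(self, a, b):
        k = cohens_kappa(a, b)
        assert cohens_kappa(b, a) == pytest.approx(k)
        # apply the same category permutation to both raters
        relabel = {-1: 1, 0: -1, 1: 0}
        assert cohens_kappa([relabel[x] for x in a], [relabel[x] for x in b]) == pytest.approx(k)

    def test_matches_sklearn_on_random_vectors(self):
        sklearn_kappa = pytest.importorskip("sklearn.metrics").cohen_kappa_score
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = rng.integers(-1, 2, size=10)
            b = rng.integers(-1, 2, size=10)
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                continue      # sklearn returns nan for double-constant input
            assert cohens_kappa(a, b) == pytest.approx(sklearn_kappa(a, b), abs=1e-12)


class TestBh:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEmpiricalNull:
    def test_degenerate_pool_gives_add_one_minimum(self):
        rps = _matrix({"r1": [0, 0, 0], "r2": [0, 0, 0]})
        ffd = _matrix({"r1": [1, -1, 0], "r2": [1, 1, -1]})
        observed = pd.Series({"r1": 0.5, "r2": 0.5})
        p = empirical_null_pvalues(rps, ffd, observed, n_resamples=1000, seed=0)
        # all null kappas are 0 (all-zero draws) -> observed beats them all
        assert np.allclose(p, 1 / 1001)

    def test_observed_below_every_null_gives_one(self):
        rps = _matrix({"r1": [1, -1, 1]})
        ffd = _matrix({"r1": [1, -1, 1]})
        observed = pd.Series({"r1": -2.0})     # below any possible kappa
        p = empirical_null_pvalues(rps, ffd, observed, n_resamples=200, seed=0)
        assert p.loc["r1"] == 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        rows = {f"r{i}": rng.integers(-1, 2, size=3).tolist() for i in range(6)}
        rps, ffd = _matrix(rows), _matrix(rows)
        observed = kappa_series(rps, ffd)
        p1 = empirical_null_pvalues(rps, ffd, observed, n_resamples=300, seed=5)
        p2 = empirical_null_pvalues(rps, ffd, observed, n_resamples=300, seed=5)
        pd.testing.assert_series_equal(p1, p2)

    def test_empty_pool_rejected(self):
        empty = SignMatrix("RPS", pd.DataFrame(columns=["A|B"]), (("A", "B"),))
        ffd = _matrix({"r1": [1]}, pairs=(("A", "B"),))
        with pytest.raises(ValueError):
            empirical_null_pvalues(empty, ffd, pd.Series(dtype=float))


class TestClassification:
    @pytest.mark.parametrize(
        "k_rps_ffd, k_rps_ras, k_ras_ffd, expected",
        [
            (0.5, 0.5, 0.1, "concerted"),
            (0.5, -0.1, 0.1, "metabolic_only"),
            (0.5, np.nan, np.nan, "metabolic_only"),   # missing activity score
            (-0.3, -0.3, 0.7, "transcriptional_only"),
            (-0.5, 0.5, 0.1, "other"),                 # second quadrant
            (0.1, 0.1, 0.1, "inconclusive"),
        ],
    )
    def test_quadrants(self, k_rps_ffd, k_rps_ras, k_ras_ffd, expected):
        kappas = pd.DataFrame(
            {
                "kappa_rps_vs_ffd": [k_rps_ffd],
                "kappa_rps_vs_ras": [k_rps_ras],
                "kappa_ras_vs_ffd": [k_ras_ffd],
            },
            index=["r"],
        )
        assert classify_reactions(kappas).loc["r"] == expected

    def test_no_signal_overrides(self):
        kappas = pd.DataFrame(
            {"kappa_rps_vs_ffd": [0.9], "kappa_rps_vs_ras": [0.9],
             "kappa_ras_vs_ffd": [0.9]},
            index=["r"],
        )
        labels = classify_reactions(kappas, no_signal=pd.Series({"r": True}))
        assert labels.loc["r"] == "inconclusive"

    def test_sign_matrix_value_domain_enforced(self):
        with pytest.raises(ValueError):
            _matrix({"r1": [2, 0, 0]})
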