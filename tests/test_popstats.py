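"""Population statistics: prevalence/co-occurrence vs brute-force row scans,
KS vs scipy to 1e-6, LDA vs the closed-form two-class discriminant and
sklearn, and the synthetic population generator."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from retrosite.popstats import (
    GenotypeMatrix,
    STATES,
    burden,
    cooccurrence,
    encode_states,
    generate_population,
    ks_two_sample,
    lda_fit,
    nearest_centroid_loo_accuracy,
    prevalence,
    prevalence_table,
)


def matrix_from_states(state_rows, populations, ratios=None):
    individuals = [f"i{n}" for n in range(len(state_rows))]
    loci = [f"L{j}" for j in range(len(state_rows[0]))]
    states = pd.DataFrame(state_rows, index=individuals, columns=loci)
    if ratios is None:
        ratios = (states == "provirus").astype(float)
    else:
        ratios = pd.DataFrame(ratios, index=individuals, columns=loci)
    return GenotypeMatrix(individuals, populations, loci, states, ratios)


class TestPrevalence:
    def test_39_of_40_is_97_5_percent(self):
        rows = [["provirus"]] * 39 + [["absence"]]
        gm = matrix_from_states(rows, ["ELGL"] * 40)
        assert prevalence(gm, "ELGL", "L0") == pytest.approx(97.5)

    def test_zero_carriers(self):
        gm = matrix_from_states([["absence"]] * 10, ["P"] * 10)
        assert prevalence(gm, "P", "L0") == 0.0

    def test_7_of_51_rounds_to_13_7(self):
        rows = [["provirus"]] * 7 + [["solo_LTR"]] * 44
        gm = matrix_from_states(rows, ["LGL"] * 51)
        assert round(prevalence(gm, "LGL", "L0"), 1) == 13.7

    def test_solo_ltr_not_a_carrier(self):
        gm = matrix_from_states([["solo_LTR"], ["provirus"]], ["P", "P"])
        assert prevalence(gm, "P", "L0") == 50.0

    def test_empty_population_raises(self):
        gm = matrix_from_states([["provirus"]], ["P"])
        with pytest.raises(ValueError):
            prevalence(gm, "Q", "L0")

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_row_scan(self, data):
        n = data.draw(st.integers(2, 15))
        d = data.draw(st.integers(1, 5))
        rows = data.draw(
            st.lists(st.lists(st.sampled_from(STATES), min_size=d, max_size=d), min_size=n, max_size=n)
        )
        gm = matrix_from_states(rows, ["P"] * n)
        for j in range(d):
            brute = 100.0 * sum(r[j] == "provirus" for r in rows) / n
            assert prevalence(gm, "P", f"L{j}") == pytest.approx(brute)


class TestCooccurrence:
    def test_single_locus_combo_reduces_to_prevalence(self):
        rows = [["provirus", "absence"], ["absence", "provirus"], ["provirus", "provirus"]]
        gm = matrix_from_states(rows, ["P"] * 3)
        assert cooccurrence(gm, ["L0"], "P") == prevalence(gm, "P", "L0")

    def test_disjoint_carriers_give_zero(self):
        rows = [["provirus", "absence"], ["absence", "provirus"]]
        gm = matrix_from_states(rows, ["P"] * 2)
        assert cooccurrence(gm, ["L0", "L1"], "P") == 0.0

    def test_unknown_locus_raises(self):
        gm = matrix_from_states([["provirus"]], ["P"])
        with pytest.raises(ValueError):
            cooccurrence(gm, ["L9"], "P")

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_row_scan(self, data):
        n = data.draw(st.integers(2, 20))
        rows = data.draw(
            st.lists(st.lists(st.sampled_from(STATES), min_size=3, max_size=3), min_size=n, max_size=n)
        )
        gm = matrix_from_states(rows, ["P"] * n)
        combo = ["L0", "L1", "L2"]
        brute = 100.0 * sum(all(x == "provirus" for x in r) for r in rows) / n
        assert cooccurrence(gm, combo, "P") == pytest.approx(brute)


class TestBurden:
    def test_all_absence_gives_zero_counts(self):
        gm = matrix_from_states([["absence"] * 4] * 3, ["P"] * 3)
        counts, hist = burden(gm)
        assert (counts == 0).all()

    def test_count_of_14_of_20_loci(self):
        row = ["provirus"] * 14 + ["solo_LTR"] * 6
        gm = matrix_from_states([row], ["P"])
        counts, _ = burden(gm)
        assert counts.iloc[0] == 14

    def test_histogram_sums_to_individuals(self, rng):
        rows = [[STATES[rng.integers(0, 3)] for _ in range(8)] for _ in range(25)]
        gm = matrix_from_states(rows, ["P"] * 25)
        _, hist = burden(gm)
        assert hist["nIndividuals"].sum() == 25


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        assert ks_two_sample([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_disjoint_supports_give_d_one(self):
        d, p = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0 and p < 0.2

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_matches_scipy_to_1e6_continuous(self):
        """20 random continuous sample pairs, exact and asymptotic branches."""
        rng = np.random.default_rng(8)
        for trial in range(20):
            if trial % 2:
                m, n = rng.integers(5, 60, 2)  # exact branch (m*n <= 1e4)
            else:
                m, n = 40, 505  # asymptotic branch
            a = rng.normal(size=m)
            b = rng.normal(rng.uniform(0, 1), size=n)
            d, p = ks_two_sample(a, b)
            method = "exact" if m * n <= 10_000 else "asymp"
            ref = scipy.stats.ks_2samp(a, b, method=method)
            assert d == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_statistic_on_tied_integer_data_matches_scipy(self):
        rng = np.random.default_rng(9)
        a = rng.integers(7, 19, size=40)
        b = rng.integers(9, 17, size=60)
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(scipy.stats.ks_2samp(a, b).statistic)


class TestLda:
    def test_constant_groups_project_to_separated_point_masses(self):
        X = np.array([[0.0, 1.0]] * 5 + [[2.0, 0.0]] * 5)
        res = lda_fit(X, ["A"] * 5 + ["B"] * 5)
        pa = res.projections[:5, 0]
        pb = res.projections[5:, 0]
        assert np.ptp(pa) == pytest.approx(0) and np.ptp(pb) == pytest.approx(0)
        assert pa[0] != pb[0]

    def test_matches_closed_form_two_class_direction(self, rng):
        X = rng.normal(size=(40, 5))
        X[20:] += rng.normal(size=5)
        y = ["A"] * 20 + ["B"] * 20
        res = lda_fit(X, y)
        mu_a, mu_b = X[:20].mean(0), X[20:].mean(0)
        Sw = np.zeros((5, 5))
        for grp in (X[:20], X[20:]):
            c = grp - grp.mean(0)
            Sw += c.T @ c
        w = np.linalg.solve(Sw, mu_a - mu_b)
        v = res.scalings[:, 0]
        cos = abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn_eigen_solver(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(60, 4))
        y = np.repeat(["A", "B", "C"], 20)
        X[20:40] += [1, 0, -1, 0.5]
        X[40:] += [-1, 1, 0, 0]
        res = lda_fit(X, y)
        sk = LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
        for c in range(2):
            v = res.scalings[:, c] / np.linalg.norm(res.scalings[:, c])
            u = sk.scalings_[:, c] / np.linalg.norm(sk.scalings_[:, c])
            assert abs(abs(v @ u) - 1) < 1e-6

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(30, 4))
        X[15:] += 1.0
        y = ["A"] * 15 + ["B"] * 15
        res1 = lda_fit(X, y)
        perm = rng.permutation(30)
        res2 = lda_fit(X[perm], [y[i] for i in perm])
        assert np.allclose(np.sort(res1.projections[:, 0]), np.sort(res2.projections[:, 0]))

    def test_common_positive_rescaling_leaves_projections_proportional(self, rng):
        X = rng.normal(size=(30, 4))
        X[15:] += 1.0
        y = ["A"] * 15 + ["B"] * 15
        res1 = lda_fit(X, y)
        res2 = lda_fit(X * 3.0, y)
        r = res2.projections[:, 0] / res1.projections[:, 0]
        assert np.allclose(r, r[0])

    def test_singleton_group_raises(self):
        with pytest.raises(ValueError):
            lda_fit(np.zeros((3, 2)), ["A", "A", "B"])

    def test_ratio_encoding_separates_better_than_states(self):
        """Groups sharing state frequencies but differing in allele
        divergence are distinguishable only in ratio space."""
        freqs = {"A": [0.1, 0.2, 0.7], "B": [0.1, 0.2, 0.7]}
        gm = generate_population(
            {"A": 30, "B": 30}, [f"L{i}" for i in range(10)], freqs,
            allele_noise={"A": 0.02, "B": 0.5}, seed=42,
        )
        sep_ratio = lda_fit(gm, encoding="ratio").separation()
        sep_state = lda_fit(gm, encoding="state").separation()
        assert sep_ratio > sep_state

    def test_recovery_on_well_separated_populations(self):
        """Five populations with large between-group shifts in both state
        frequency and allele divergence are recovered in ratio space."""
        loci = [f"L{i}" for i in range(50)]
        freqs = {
            "AFR": [0.1, 0.1, 0.8], "EUR": [0.6, 0.2, 0.2], "EAS": [0.3, 0.6, 0.1],
            "SAS": [0.8, 0.1, 0.1], "LGL": [0.05, 0.05, 0.9],
        }
        gm = generate_population(
            {g: 25 for g in freqs}, loci, freqs,
            allele_noise={"AFR": 0.05, "EUR": 0.25, "EAS": 0.5, "SAS": 0.75, "LGL": 0.95},
            seed=7,
        )
        res = lda_fit(gm, encoding="ratio")
        assert nearest_centroid_loo_accuracy(res) >= 0.9


class TestGeneratePopulation:
    def test_zero_noise_proviruses_have_ratio_one(self):
        gm = generate_population({"P": 10}, ["L0"], {"P": [0, 0, 1.0]}, allele_noise=0.0, seed=1)
        assert (gm.ratios["L0"] == 1.0).all()
        assert (gm.states["L0"] == "provirus").all()

    def test_seed_determinism(self):
        kw = dict(n_per_group={"A": 8}, loci=["L0", "L1"], group_state_freqs={"A": [0.3, 0.3, 0.4]}, seed=11)
        g1, g2 = generate_population(**kw), generate_population(**kw)
        assert g1.states.equals(g2.states) and g1.ratios.equals(g2.ratios)

    def test_empirical_frequencies_converge(self):
        gm = generate_population({"A": 10_000}, ["L0"], {"A": [0.2, 0.3, 0.5]}, seed=3)
        for state, f in zip(STATES, (0.2, 0.3, 0.5)):
            emp = (gm.states["L0"] == state).mean()
            assert abs(emp - f) < 3 * np.sqrt(f * (1 - f) / 10_000)

    def test_invalid_frequencies_raise(self):
        with pytest.raises(ValueError):
            generate_population({"A": 5}, ["L0"], {"A": [0.5, 0.5, 0.5]}, seed=1)

    def test_tsv_round_trip(self, tmp_path):
        gm = generate_population({"A": 5, "B": 4}, ["L0", "L1"], {"A": [0.3, 0.3, 0.4], "B": [0.1, 0.1, 0.8]}, seed=2)
        p = tmp_path / "gm.tsv"
        gm.to_tsv(p)
        back = GenotypeMatrix.from_tsv(p)
        assert back.states.equals(gm.states)
        assert back.populations == gm.populations
        assert np.allclose(back.ratios.values, gm.ratios.values)


def test_encode_states_ordinal_and_onehot():
    df = pd.DataFrame({"L0": ["absence", "solo_LTR", "provirus"]})
    assert encode_states(df).ravel().tolist() == [0.0, 1.0, 2.0]
    oh = encode_states(df, one_hot=True)
    assert oh.shape == (3, 3) and (oh.sum(axis=1) == 1).all()


def test_prevalence_table_shape_and_rounding():
    rows = [["provirus", "absence"]] * 3 + [["absence", "provirus"]] * 4
    gm = matrix_from_states(rows, ["X"] * 3 + ["Y"] * 4)
    table = prevalence_table(gm)
    assert table.loc["L0", "X"] == 100.0
    assert table.loc["L0", "Y"] == 0.0
    assert table.loc["L1", "Y"] == 100.0
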