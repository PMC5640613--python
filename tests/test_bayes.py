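import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonedriver import bayes
from conftest import make_cohort


class TestEvidenceMass:
    def test_one_mutated_one_unmutated_patient(self):
        df = make_cohort([("A", "P1", "missense", 0.5, 1.0, 40)])
        df["ccf"], df["damage"] = 1.0, 1.0
        m, n = bayes.evidence_mass(df, "A", n_patients=2)
        assert (m, n) == (1.0, 2)

    def test_no_mutations(self):
        df = make_cohort([])
        m, _ = bayes.evidence_mass(df, "A", n_patients=5)
        assert m == 0.0

    def test_upper_bound_all_patients_full_weight(self):
        rows = [("A", f"P{i}", "missense", 0.5, 1.0, 40) for i in range(6)]
        df = make_cohort(rows)
        df["ccf"], df["damage"] = 1.0, 1.0
        m, n = bayes.evidence_mass(df, "A", n_patients=6)
        assert m == n == 6

    def test_per_patient_collapse_takes_highest_ccf(self):
        df = make_cohort(
            [("A", "P1", "missense", 0.5, 1.0, 40), ("A", "P1", "missense", 0.2, 1.0, 40)]
        )
        df["ccf"] = [0.9, 0.3]
        df["damage"] = [0.5, 1.0]
        m, _ = bayes.evidence_mass(df, "A", n_patients=1)
        assert m == pytest.approx(0.9 * 0.5)

    def test_silent_ignored(self):
        df = make_cohort([("A", "P1", "silent", 0.5, 1.0, 3)])
        df["ccf"], df["damage"] = 1.0, 1.0
        m, _ = bayes.evidence_mass(df, "A", n_patients=1)
        assert m == 0.0


class TestHazardPosterior:
    def test_uninformative_evidence_returns_prior(self):
        # L == bmp -> posterior equals the incidence prior
        post = bayes.hazard_posterior(m=2.0, n=100, bmp=0.02, incidence=0.07)
        assert post == pytest.approx(0.07, abs=1e-12)

    def test_zero_bmp_certainty(self):
        assert bayes.hazard_posterior(1.0, 10, 0.0, 0.01) == 1.0

    def test_no_evidence_defined_zero(self):
        assert bayes.hazard_posterior(0.0, 10, 0.0, 0.01) == 0.0

    def test_worked_value(self):
        # independent exact-rational oracle for L=0.5, bmp=0.01, pi=0.001
        L, b, pi = Fraction(1, 2), Fraction(1, 100), Fraction(1, 1000)
        oracle = (L * pi) / (L * pi + b * (1 - pi))
        post = bayes.hazard_posterior(0.5, 1, 0.01, 0.001)
        assert post == pytest.approx(float(oracle), rel=1e-12)
        assert post == pytest.approx(0.0477, abs=5e-4)


class TestDriverPriorLikelihood:
    def test_prior_ratio(self):
        params = bayes.BayesParams(driver_genes=tuple(f"D{i}" for i in range(200)))
        assert bayes.driver_prior(params) == pytest.approx(0.01)

    def test_prior_guards(self):
        with pytest.raises(ValueError):
            bayes.BayesParams(driver_genes=())
        with pytest.raises(ValueError):
            bayes.BayesParams(driver_genes=("A",), n_genes=1)

    def test_likelihood_arithmetic(self):
        drivers = tuple(f"D{i}" for i in range(10))
        rows = [(f"D{i % 10}", f"P{j}", "missense", 0.5, 1.0, 30) for j in range(50) for i in range(2)]
        df = make_cohort(rows)
        params = bayes.BayesParams(driver_genes=drivers)
        # 100 driver mutations / (50 patients * 10 drivers)
        assert bayes.driver_likelihood(df, params, n_patients=50) == pytest.approx(0.2)

    def test_no_driver_mutations_warns_and_zero(self, caplog):
        df = make_cohort([("X", "P1", "missense", 0.5, 1.0, 30)])
        params = bayes.BayesParams(driver_genes=("D1",), n_genes=100)
        with caplog.at_level("WARNING"):
            assert bayes.driver_likelihood(df, params, n_patients=1) == 0.0
        assert any("no nonsilent" in r.message for r in caplog.records)

    def test_override_bypasses_estimate(self):
        df = make_cohort([])
        params = bayes.BayesParams(driver_genes=("D1",), p_ns_given_d_override=0.42)
        assert bayes.driver_likelihood(df, params, n_patients=10) == 0.42


class TestDriverPosterior:
    def test_coincident_channels_return_prior(self):
        for m, n in [(0.0, 10), (3.7, 50), (50.0, 50)]:
            post = bayes.driver_posterior(m, n, p_ns_d=0.05, bmp=0.05, prior_d=0.01)
            assert post == pytest.approx(0.01, abs=1e-9)

    def test_absence_of_mutations_is_evidence_against(self):
        post = bayes.driver_posterior(0.0, 100, p_ns_d=0.2, bmp=0.01, prior_d=0.01)
        assert post < 0.01

    def test_log_space_matches_naive_arithmetic(self):
        # naive (non-log) oracle, valid while nothing underflows
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(1, 51))
            m = rng.uniform(0, n)
            p_d = rng.uniform(1e-4, 0.5)
            b = rng.uniform(1e-4, 0.5)
            prior = rng.uniform(1e-4, 0.5)
            num = p_d**m * (1 - p_d) ** (n - m) * prior
            den = num + b**m * (1 - b) ** (n - m) * (1 - prior)
            assert bayes.driver_posterior(m, n, p_d, b, prior) == pytest.approx(
                num / den, rel=1e-9
            )

    def test_strictly_increasing_in_m(self):
        posts = [
            bayes.driver_posterior(m, 100, 0.2, 0.01, 0.01) for m in np.arange(0, 20, 1.0)
        ]
        assert np.all(np.diff(posts) > 0)

    def test_extreme_probabilities_clamped(self):
        post = bayes.driver_posterior(5.0, 10, p_ns_d=1.0, bmp=0.0, prior_d=0.5)
        assert 0.0 <= post <= 1.0


class TestMonotonicityProperties:
    @settings(derandomize=True, max_examples=300)
    @given(
        n=st.integers(2, 500),
        frac=st.floats(0.0, 0.99),
        bmp=st.floats(1e-6, 0.5),
        pi=st.floats(1e-4, 0.9),
        delta=st.floats(1e-3, 1.0),
    )
    def test_hazard_increasing_in_m_decreasing_in_bmp(self, n, frac, bmp, pi, delta):
        m = frac * n
        lo = bayes.hazard_posterior(m, n, bmp, pi)
        hi = bayes.hazard_posterior(min(m + delta, n), n, bmp, pi)
        assert hi > lo or (hi == lo == 1.0)
        worse = bayes.hazard_posterior(m, n, bmp * (1 + delta), pi)
        assert worse < lo or (worse == lo == 0.0)

    @settings(derandomize=True, max_examples=300)
    @given(
        n=st.integers(2, 500),
        frac=st.floats(0.0, 0.99),
        bmp=st.floats(1e-6, 0.4),
        p_d=st.floats(1e-6, 0.4),
        prior=st.floats(1e-4, 0.5),
        delta=st.floats(1e-3, 1.0),
    )
    def test_driver_increasing_in_m_decreasing_in_bmp(self, n, frac, bmp, p_d, prior, delta):
        if abs(p_d - bmp) < 1e-9:
            return
        m = frac * n
        sign = 1.0 if p_d > bmp else -1.0
        lo = bayes.driver_posterior(m, n, p_d, bmp, prior)
        hi = bayes.driver_posterior(min(m + delta, n), n, p_d, bmp, prior)
        # more evidence mass moves toward the channel with higher likelihood
        assert sign * (hi - lo) >= 0
        # raising bmp hurts the gene only while its evidence rate m/n
        # exceeds bmp (below that, a larger background explains the data
        # better under the passenger channel and the posterior rises)
        bmp_hi = min(bmp * (1 + delta), 0.999)
        if m / n > bmp_hi:
            worse = bayes.driver_posterior(m, n, p_d, bmp_hi, prior)
            assert worse <= lo + 1e-12


class TestRanking:
    def _results(self, posts):
        return pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(len(posts))],
                "m": [1.0] * len(posts),
                "n": 10,
                "posterior_hazard": [0.5] * len(posts),
                "posterior_driver": posts,
            }
        )

    def test_descending_by_driver_posterior(self):
        ranked = bayes.rank_genes(self._results([0.5, 0.9]))
        assert ranked.loc[0, "gene"] == "G1" and ranked.loc[0, "rank"] == 1

    def test_full_tie_alphabetical(self):
        df = self._results([0.5, 0.5, 0.5])
        df["gene"] = ["C", "A", "B"]
        ranked = bayes.rank_genes(df)
        assert list(ranked["gene"]) == ["A", "B", "C"]

    def test_permutation_invariance(self):
        df = self._results(list(np.random.default_rng(0).uniform(size=20)))
        a = bayes.rank_genes(df)
        b = bayes.rank_genes(df.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(a, b.reset_index(drop=True))

    def test_rank_is_permutation(self, small_sim):
        cohort, truth, ctx = small_sim
        from clonedriver import compute_background

        backgr = compute_background(cohort, ctx)
        params = bayes.BayesParams(driver_genes=tuple(truth["driver_genes"]))
        res = bayes.score_genes(cohort, backgr, params)
        assert sorted(res["rank"]) == list(range(1, len(res) + 1))
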