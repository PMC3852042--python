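"""Retention PMF, mixture likelihood, MLE fitting and score prediction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from polyfrac.retention import (
    RetentionCounts,
    RetentionModel,
    RetentionParams,
    load_rosid_counts,
    mixture_pmf,
    predict_score_distribution,
    retention_pmf,
)
from polyfrac.simulate import SimConfig, simulate_fractionation
from polyfrac.homology import GenomeGroup


def enumeration_pmf(p, q):
    """Independent oracle: enumerate every 2-phase outcome of 3 copies."""
    probs = np.zeros(4)
    for phase1 in itertools.product([0, 1], repeat=3):
        pr1 = math.prod((1 - p) if s else p for s in phase1)
        for phase2 in itertools.product([0, 1], repeat=3):
            pr2 = 1.0
            k = 0
            for s1, s2 in zip(phase1, phase2):
                if s1:
                    pr2 *= (1 - q) if s2 else q
                    k += s2
                elif s2:
                    pr2 = 0.0
            probs[k] += pr1 * pr2
    return probs  # index = surviving copies


class TestRetentionPMF:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            (0.0, 0.0, (1.0, 0.0, 0.0, 0.0)),
            (1.0, 0.3, (0.0, 0.0, 0.0, 1.0)),
            (0.5, 0.5, (0.015625, 0.140625, 0.421875, 0.421875)),
        ],
    )
    def test_examples(self, p, q, expected):
        pmf = retention_pmf(p, q)
        assert (pmf.P3, pmf.P2, pmf.P1, pmf.P0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_and_binomial(self, seed):
        rng = np.random.default_rng(seed)
        for p, q in rng.random((250, 2)):
            pmf = retention_pmf(p, q)
            arr = pmf.as_array()
            assert abs(arr.sum() - 1.0) < 1e-12
            oracle = enumeration_pmf(p, q)
            assert np.allclose(arr, oracle[::-1], atol=1e-12)
            s = (1 - p) * (1 - q)
            binom = stats.binom.pmf([3, 2, 1, 0], 3, s)
            assert np.allclose(arr, binom, atol=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        p=st.floats(0, 1, allow_nan=False),
        q=st.floats(0, 1, allow_nan=False),
    )
    def test_normalised_and_binomial_for_arbitrary_rates(self, p, q):
        pmf = retention_pmf(p, q)
        arr = pmf.as_array()
        assert abs(arr.sum() - 1.0) < 1e-12
        s = (1 - p) * (1 - q)
        assert np.allclose(arr, stats.binom.pmf([3, 2, 1, 0], 3, s), atol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            retention_pmf(-0.1, 0.5)
        with pytest.raises(ValueError):
            retention_pmf(0.5, 1.2)


class TestMixturePMF:
    def params(self, **kw):
        base = dict(p=0.2, q=(0.3, 0.4), theta=0.5, alpha=0.5, n_ancestral=100)
        base.update(kw)
        return RetentionParams(**base)

    def test_theta_one_degenerates_to_single_class(self):
        par = self.params(theta=1.0)
        assert np.allclose(
            mixture_pmf(par, 0).as_array(), retention_pmf(0.2, 0.3).as_array()
        )

    def test_alpha_one_makes_classes_identical(self):
        par = self.params(alpha=1.0, theta=0.37)
        assert np.allclose(
            mixture_pmf(par, 1).as_array(), retention_pmf(0.2, 0.4).as_array()
        )

    def test_hand_mixture_of_two_oracles(self):
        par = self.params()
        expected = 0.5 * enumeration_pmf(0.2, 0.3)[::-1] + 0.5 * enumeration_pmf(
            0.1, 0.15
        )[::-1]
        assert np.allclose(mixture_pmf(par, 0).as_array(), expected, atol=1e-12)

    def test_alpha_constraint_enforced(self):
        with pytest.raises(ValueError):
            self.params(alpha=1.5, q=(0.9, 0.9))


class TestLogLikelihood:
    def test_certain_outcome_has_zero_loglik(self):
        counts = RetentionCounts(("sp1",), n2=(0,), n3=(1,))
        model = RetentionModel(counts, n_ancestral=1)
        par = RetentionParams(p=0.0, q=(0.0,), theta=1.0, alpha=1.0, n_ancestral=1)
        assert model.loglike(par) == pytest.approx(0.0, abs=1e-12)

    def test_matches_multinomial_enumeration(self):
        counts = RetentionCounts(("sp1",), n2=(1,), n3=(1,))
        model = RetentionModel(counts, n_ancestral=2)
        par = RetentionParams(p=0.2, q=(0.3,), theta=0.6, alpha=0.5, n_ancestral=2)
        pmf = mixture_pmf(par, 0)
        # direct multinomial mass with factorials: 2!/(1!1!0!) * P3 * P2
        expected = math.log(math.factorial(2) * pmf.P3 * pmf.P2)
        assert model.loglike(par) == pytest.approx(expected, rel=1e-12)

    def test_label_switching_symmetry(self):
        counts = load_rosid_counts()
        model = RetentionModel(counts, n_ancestral=7500)
        par = RetentionParams(
            p=0.5, q=(0.4, 0.5, 0.55, 0.6, 0.7, 0.8), theta=0.3, alpha=0.6,
            n_ancestral=7500,
        )
        assert model.loglike(par) == pytest.approx(model.loglike(par.swapped()), rel=1e-12)

    def test_impossible_outcome_is_minus_inf(self):
        counts = RetentionCounts(("sp1",), n2=(0,), n3=(1,))
        model = RetentionModel(counts, n_ancestral=1)
        par = RetentionParams(p=1.0, q=(0.0,), theta=1.0, alpha=1.0, n_ancestral=1)
        assert model.loglike(par) == -math.inf

    def test_counts_exceeding_n_rejected(self):
        counts = RetentionCounts(("sp1",), n2=(800,), n3=(300,))
        with pytest.raises(ValueError, match="n_ancestral"):
            RetentionModel(counts, n_ancestral=1000)


def _simulate_counts(params, seed):
    group = GenomeGroup("sim", tuple(f"G{i}" for i in range(params.n_species)))
    sim = simulate_fractionation(
        SimConfig(params=params, group=group, seed=seed, emit_edges=False)
    )
    return RetentionCounts.from_dataframe(sim.counts)


class TestFit:
    def test_single_class_data_fits_as_single_class(self):
        true = RetentionParams(
            p=0.3, q=(0.4, 0.5, 0.6), theta=1.0, alpha=1.0, n_ancestral=20000
        )
        counts = _simulate_counts(true, seed=10)
        res = RetentionModel(counts, n_ancestral=20000).fit(seed=0)
        # whatever the mixture labels, the fitted category probabilities
        # must match the single-class truth closely in every species
        for i in range(3):
            got = mixture_pmf(res.params, i)
            want = retention_pmf(true.p, true.q[i])
            assert got.P3 == pytest.approx(want.P3, abs=0.004)
            assert got.P2 == pytest.approx(want.P2, abs=0.008)

    def test_fit_is_local_maximum(self):
        counts = load_rosid_counts()
        model = RetentionModel(counts, n_ancestral=7500)
        res = model.fit(seed=2)
        best = model.loglike(res.params)
        assert best == pytest.approx(res.llf, rel=1e-9)
        rng = np.random.default_rng(0)
        x = np.array(
            [res.params.p, *res.params.q, res.params.theta, res.params.alpha]
        )
        for _ in range(20):
            delta = rng.normal(scale=0.02, size=len(x))
            xp = np.clip(x + delta, 1e-9, 1 - 1e-9)
            perturbed = RetentionParams(
                p=xp[0], q=tuple(xp[1:-2]), theta=xp[-2], alpha=xp[-1],
                n_ancestral=7500,
            )
            assert model.loglike(perturbed) <= best + 1e-6

    def test_multistart_table_and_summary(self):
        res = RetentionModel(load_rosid_counts(), n_ancestral=7500).fit(
            seed=3, n_starts=8
        )
        assert len(res.starts) == 8
        assert res.starts["loglike"].max() == pytest.approx(res.llf)
        text = res.summary()
        assert "alpha" in text and "larger class share" in text

    def test_rmse_shrinks_with_more_data(self):
        """Estimator consistency: (theta, alpha) RMSE falls as N grows."""
        true = dict(p=0.4, q=(0.5, 0.54, 0.58, 0.62, 0.66, 0.7), theta=0.7, alpha=0.6)
        rmse = {}
        for N in (2000, 50000):
            errs = []
            for rep in range(4):
                par = RetentionParams(n_ancestral=N, **true)
                counts = _simulate_counts(par, seed=100 + rep)
                res = RetentionModel(counts, n_ancestral=N).fit(seed=rep, n_starts=16)
                errs.append(
                    (res.params.theta - true["theta"]) ** 2
                    + (res.params.alpha - true["alpha"]) ** 2
                )
            rmse[N] = np.sqrt(np.mean(errs))
        assert rmse[50000] < rmse[2000]


class TestProfileOverN:
    def test_n_below_species_total_rejected(self):
        counts = load_rosid_counts()
        res = RetentionModel(counts, n_ancestral=7500).fit(seed=1, n_starts=4)
        with pytest.raises(ValueError, match="n_ancestral"):
            res.profile_over_n([1000])

    def test_profile_returns_row_per_n(self):
        counts = load_rosid_counts()
        res = RetentionModel(counts, n_ancestral=7500).fit(seed=1, n_starts=4)
        table = res.profile_over_n([7500, 9000])
        assert list(table["N"]) == [7500, 9000]
        assert {"p", "theta", "alpha"} <= set(table.columns)


class TestScoreDistribution:
    def base_params(self, **kw):
        base = dict(
            p=0.3, q=(0.4, 0.5, 0.6), theta=0.6, alpha=0.5, n_ancestral=1000
        )
        base.update(kw)
        return RetentionParams(**base)

    def counts3(self):
        return RetentionCounts(("a", "b", "c"), n2=(5, 5, 5), n3=(2, 2, 2))

    def test_no_loss_puts_all_mass_at_top_score(self):
        par = self.base_params(p=0.0, q=(0.0, 0.0, 0.0))
        df = predict_score_distribution(self.counts3(), par)
        for _, sub in df.groupby("class"):
            top = sub.loc[sub["score"] == 3, "probability"].iloc[0]
            assert top == pytest.approx(1.0)

    def test_near_total_species_loss_concentrates_at_zero(self):
        par = self.base_params(p=0.2, q=(1 - 1e-6,) * 3)
        df = predict_score_distribution(self.counts3(), par)
        prone = df[df["class"] == "prone"]
        assert prone.loc[prone["score"] == 0, "probability"].iloc[0] > 1 - 1e-4

    def test_matches_exhaustive_pattern_enumeration(self):
        par = self.base_params()
        df = predict_score_distribution(self.counts3(), par)
        for label, p_eff, q_eff in (
            ("prone", par.p, par.q),
            ("resistant", par.alpha * par.p, tuple(par.alpha * v for v in par.q)),
        ):
            m = []
            for qi in q_eff:
                pmf = retention_pmf(p_eff, qi)
                m.append((pmf.P3 + pmf.P2) / (pmf.P3 + pmf.P2 + pmf.P1))
            expected = np.zeros(4)
            for pattern in itertools.product([0, 1], repeat=3):
                pr = math.prod(
                    m[i] if b else 1 - m[i] for i, b in enumerate(pattern)
                )
                expected[sum(pattern)] += pr
            got = (
                df[df["class"] == label].sort_values("score")["probability"].to_numpy()
            )
            assert np.allclose(got, expected, atol=1e-12)

    def test_per_class_probabilities_sum_to_one(self):
        df = predict_score_distribution(self.counts3(), self.base_params())
        sums = df.groupby("class")["probability"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_total_species_loss_is_conditioning_error(self):
        par = self.base_params(q=(1.0, 0.5, 0.5))
        with pytest.raises(ZeroDivisionError):
            predict_score_distribution(self.counts3(), par)

    def test_species_subset(self):
        df = predict_score_distribution(
            self.counts3(), self.base_params(), species=["a", "c"]
        )
        assert df["score"].max() == 2
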