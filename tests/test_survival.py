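"""Survival measures: product-limit blocks, kernels, weighting, EV."""

import numpy as np
import pandas as pd
import pytest

import necsuff as ns
from necsuff.errors import (
    DegenerateTimeError,
    EstimationImpossibleError,
    NoEventsError,
)


def _step(eval_times, values, u):
    """Right-continuous step lookup: value at largest eval_time <= u."""
    pos = np.searchsorted(eval_times, u, side="right") - 1
    return 1.0 if pos < 0 else values[pos]


def brute_force_sh_ev(sample, curves, tau=None):
    """Double-loop Schemper-Henderson EV, one subject at a time."""
    keep = (
        np.ones(curves.event_times.size, dtype=bool)
        if tau is None
        else curves.event_times <= tau
    )
    et = curves.event_times[keep]
    w = (curves.G_inv_weights * curves.d)[keep]
    S_unc = 1.0 - curves.F_uncond[keep]
    profiles = (
        np.arange(len(sample))
        if curves.subject_profiles is None
        else curves.subject_profiles
    )
    num = den = 0.0
    for j, t in enumerate(et):
        m = mx = 0.0
        for i in range(len(sample)):
            ti, ev = sample.times[i], sample.events[i]
            S_c = 1.0 - curves.F_cond[profiles[i], keep]
            for S_curve, acc in ((S_unc, "m"), (S_c, "mx")):
                S_t = S_curve[j]
                if ti > t:
                    contrib = 1.0 - S_t
                elif ev == 1:
                    contrib = S_t
                else:
                    S_i = _step(et, S_curve, ti)
                    ratio = S_t / S_i
                    contrib = ratio * (1.0 - S_t) + (1.0 - ratio) * S_t
                if acc == "m":
                    m += contrib
                else:
                    mx += contrib
        num += w[j] * mx / len(sample)
        den += w[j] * m / len(sample)
    return 1.0 - num / den


class TestKaplanMeierCdf:
    def test_uncensored_is_empirical_cdf(self):
        s = ns.SurvivalSample(times=[1.0, 2.0, 3.0], events=[1, 1, 1])
        et, d, F = ns.km_cdf(s)
        assert np.allclose(et, [1, 2, 3])
        assert np.allclose(d, 1)
        assert np.allclose(F, [1 / 3, 2 / 3, 1.0])

    def test_censored_hand_product_limit(self):
        # S(1) = 2/3; at t=3 risk set is {3} so S(3) = 2/3 * 0 = 0
        s = ns.SurvivalSample(times=[1.0, 2.0, 3.0], events=[1, 0, 1])
        et, d, F = ns.km_cdf(s)
        assert np.allclose(et, [1, 3])
        assert F[0] == pytest.approx(1 / 3)
        assert F[1] == pytest.approx(1.0)

    def test_monte_carlo_consistency(self, rng):
        t = rng.exponential(1.0, size=10_000)
        s = ns.SurvivalSample(times=t, events=np.ones_like(t, dtype=int))
        et, _, F = ns.km_cdf(s)
        sup = np.max(np.abs(F - (1 - np.exp(-et))))
        assert sup < 0.02

    def test_no_events_rejected(self):
        with pytest.raises(NoEventsError):
            ns.SurvivalSample(times=[1.0, 2.0], events=[0, 0])


class TestCensoringKm:
    def test_uncensored_weights_are_one(self):
        s = ns.SurvivalSample(times=[1.0, 2.0, 3.0], events=[1, 1, 1])
        _, G, w = ns.censoring_km(s)
        assert np.allclose(G, 1.0)
        assert np.allclose(w, 1.0)

    def test_hand_reverse_product_limit(self):
        # censoring at 2 with risk set {2, 3}: G(3-) = 1/2, weight 2 at t=3
        s = ns.SurvivalSample(times=[1.0, 2.0, 3.0], events=[1, 0, 1])
        _, G, w = ns.censoring_km(s)
        assert w[0] == pytest.approx(1.0)  # t=1: no earlier censoring
        assert w[1] == pytest.approx(2.0)

    def test_tied_events_precede_censorings(self):
        # event and censoring tied at t=2: the event leaves the risk set
        # first, so the censoring hazard at 2 is 1/3 (risk set 4 minus 1)
        s = ns.SurvivalSample(times=[2.0, 2.0, 3.0, 4.0], events=[1, 0, 1, 1])
        _, G, w = ns.censoring_km(s)
        assert G[0] == pytest.approx(2 / 3)
        # left limit: the weight at the tied event time itself is 1
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(1.5)

    def test_weights_at_least_one(self, rng):
        t = rng.exponential(1.0, 500)
        e = rng.integers(0, 2, 500)
        e[0] = 1
        s = ns.SurvivalSample(times=t, events=e)
        _, _, w = ns.censoring_km(s)
        assert np.all(w >= 1.0)


class TestDnDsAtTime:
    def test_noninformative(self):
        m = ns.dn_ds_at_time(0.4, [0.4, 0.4, 0.4])
        assert (m.dn1, m.ds1, m.dn2, m.ds2) == (0.0, 0.0, 0.0, 0.0)
        assert m.n_less == m.n_greater == 0

    def test_two_group_kernels(self):
        m = ns.dn_ds_at_time(0.4, [0.2, 0.6])
        assert m.dn1 == pytest.approx(0.5)
        assert m.dn2 == pytest.approx(0.5)
        assert m.ds1 == pytest.approx(1 / 3)
        assert m.ds2 == pytest.approx(1 / 3)

    def test_counts_weighting(self):
        # duplicating a profile must act like repeating subjects
        a = ns.dn_ds_at_time(0.4, [0.2, 0.1, 0.6], counts=[3, 1, 2])
        b = ns.dn_ds_at_time(0.4, [0.2, 0.2, 0.2, 0.1, 0.6, 0.6])
        assert a.dn1 == pytest.approx(b.dn1)
        assert a.ds2 == pytest.approx(b.ds2)

    def test_degenerate_time_rejected(self):
        with pytest.raises(DegenerateTimeError):
            ns.dn_ds_at_time(1.0, [0.2])


class TestDnDsSurvival:
    def test_identical_curves_give_zero(self, small_survival):
        et, d, F = ns.km_cdf(small_survival)
        curves = ns.curves_from_matrix(
            small_survival, np.tile(F, (len(small_survival), 1))
        )
        m = ns.dn_ds_survival(curves)
        assert (m.dn1, m.dn2, m.ds1, m.ds2) == (0.0,) * 4

    def test_dichotomous_variants_coincide(self, small_survival):
        curves = ns.stratified_km_curves(
            small_survival, small_survival.covariates["group"].to_numpy()
        )
        table = ns.per_time_table(curves)
        assert np.allclose(table["dn1_t"], table["dn2_t"])
        assert np.allclose(table["ds1_t"], table["ds2_t"])
        m = ns.dn_ds_survival(curves)
        assert m.dn1 == pytest.approx(m.dn2)
        assert m.ds1 == pytest.approx(m.ds2)

    def test_time_transform_bit_invariance(self, rng):
        s = ns.gen_exponential_survival(
            500, 10, 0.5, "administrative", 4.9, seed=rng
        )
        g = s.covariates["group"].to_numpy()
        m1 = ns.survival_measures(s, ns.stratified_km_curves(s, g), tau=4.9)
        s2 = ns.SurvivalSample(
            times=s.times**3, events=s.events, covariates=s.covariates
        )
        m2 = ns.survival_measures(s2, ns.stratified_km_curves(s2, g), tau=4.9**3)
        assert (m1.dn1, m1.dn2, m1.ds1, m1.ds2, m1.ev) == \
            (m2.dn1, m2.dn2, m2.ds1, m2.ds2, m2.ev)

    def test_tau_restricts_event_times(self, small_survival):
        curves = ns.stratified_km_curves(
            small_survival, small_survival.covariates["group"].to_numpy()
        )
        early = ns.per_time_table(curves, tau=4.0)
        assert early["time"].max() <= 4.0
        with pytest.raises(EstimationImpossibleError):
            ns.dn_ds_survival(curves, tau=0.5)

    def test_matches_population_at_large_n(self, rng):
        s = ns.gen_exponential_survival(40_000, 10, 0.5, "none", seed=rng)
        curves = ns.stratified_km_curves(s, s.covariates["group"].to_numpy())
        m = ns.dn_ds_survival(curves)
        pop = ns.pop_measures_survival(ns.SurvivalScenario(10, 0.5))
        assert m.dn1 == pytest.approx(pop.dn, abs=0.02)
        assert m.ds1 == pytest.approx(pop.ds, abs=0.02)


class TestShExplainedVariation:
    def test_identical_curves_give_zero(self, small_survival):
        et, d, F = ns.km_cdf(small_survival)
        curves = ns.curves_from_matrix(
            small_survival, np.tile(F, (len(small_survival), 1))
        )
        assert ns.sh_explained_variation(small_survival, curves) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        s = ns.gen_exponential_survival(
            60, 5, 0.4, "administrative", 3.0, seed=rng
        )
        curves = ns.stratified_km_curves(s, s.covariates["group"].to_numpy())
        fast = ns.sh_explained_variation(s, curves)
        slow = brute_force_sh_ev(s, curves)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_oracle_agreement_with_tau_and_cox(self, rng):
        s = ns.gen_exponential_survival(
            50, 8, 0.5, "administrative", 4.0, seed=rng
        )
        curves = ns.cox_cdf_adapter(s)
        fast = ns.sh_explained_variation(s, curves, tau=2.5)
        slow = brute_force_sh_ev(s, curves, tau=2.5)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_matches_population_at_large_n(self, rng):
        s = ns.gen_exponential_survival(40_000, 10, 0.5, "none", seed=rng)
        curves = ns.stratified_km_curves(s, s.covariates["group"].to_numpy())
        ev = ns.sh_explained_variation(s, curves)
        pop = ns.pop_measures_survival(ns.SurvivalScenario(10, 0.5))
        assert ev == pytest.approx(pop.ev, abs=0.02)


class TestCoxAdapter:
    def test_agrees_with_stratified_km(self, rng):
        """Cox and group-wise KM curves give the same DN/DS for one factor."""
        s = ns.gen_exponential_survival(
            5000, 10, 0.5, "administrative", 4.9, seed=rng
        )
        g = s.covariates["group"].to_numpy()
        m_km = ns.dn_ds_survival(ns.stratified_km_curves(s, g), tau=4.9)
        m_cox = ns.dn_ds_survival(ns.cox_cdf_adapter(s), tau=4.9)
        assert m_cox.dn1 == pytest.approx(m_km.dn1, abs=0.02)
        assert m_cox.ds1 == pytest.approx(m_km.ds1, abs=0.02)

    def test_permuted_covariate_near_zero(self, rng):
        s = ns.gen_exponential_survival(2000, 10, 0.5, "none", seed=rng)
        perm = s.covariates.sample(frac=1.0, random_state=7).reset_index(drop=True)
        s_null = ns.SurvivalSample(times=s.times, events=s.events, covariates=perm)
        m = ns.dn_ds_survival(ns.cox_cdf_adapter(s_null))
        assert m.dn1 < 0.1
        assert m.ds1 < 0.1

    def test_requires_covariates(self, small_survival):
        bare = ns.SurvivalSample(
            times=small_survival.times, events=small_survival.events
        )
        with pytest.raises(EstimationImpossibleError):
            ns.cox_cdf_adapter(bare)


class TestCurveValidation:
    def test_decreasing_f_cond_rejected(self, small_survival):
        et, _, F = ns.km_cdf(small_survival)
        bad = np.tile(F, (len(small_survival), 1))
        bad[0, -1] = 0.0
        with pytest.raises(EstimationImpossibleError):
            ns.curves_from_matrix(small_survival, bad)

    def test_profile_counts(self, small_survival):
        curves = ns.stratified_km_curves(
            small_survival, small_survival.covariates["group"].to_numpy()
        )
        assert curves.n_subjects == len(small_survival)
        assert curves.profile_counts.sum() == len(small_survival)
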