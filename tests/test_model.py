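import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

import admixkit as ak
from admixkit.model import (
    InfeasibleParametersError,
    FitFailureError,
    TractModel,
    ancestry_chain,
    build_migration_schedule,
    expected_tract_spectrum,
    markov_chain,
    poisson_loglik,
    schedule_proportions,
)

PROPS = {"EUR": 0.60, "NAT": 0.35, "AFR": 0.05}


class TestBuildMigrationSchedule:
    def test_base_closed_form_pinning(self):
        sch = build_migration_schedule("base", {"t0": 12, "t_afr": 8}, PROPS)
        assert sch.rates[8, 2] == pytest.approx(0.05)
        assert sch.rates[12, 0] == pytest.approx(0.60 / 0.95)

    def test_zero_pulse_reduces_to_base(self):
        base = build_migration_schedule("base", {"t0": 12, "t_afr": 6}, PROPS)
        ext = build_migration_schedule(
            "base+eur_pulse", {"t0": 12, "t_afr": 6, "t_pulse": 4, "m_pulse": 0.0}, PROPS
        )
        np.testing.assert_allclose(ext.rates, base.rates, atol=1e-12)

    def test_pulse_time_at_founding_infeasible(self):
        with pytest.raises(InfeasibleParametersError):
            build_migration_schedule("base", {"t0": 12, "t_afr": 12}, PROPS)

    def test_pulse_magnitude_exceeding_proportion_infeasible(self):
        with pytest.raises(InfeasibleParametersError):
            build_migration_schedule(
                "base+afr_pulse",
                {"t0": 12, "t_afr": 6, "t_pulse": 3, "m_pulse": 0.2},
                PROPS,  # AFR total is only 0.05
            )

    @given(
        t0=st.floats(4.0, 20.0),
        ta_frac=st.floats(0.05, 0.9),
        tp_frac=st.floats(0.05, 0.9),
        m=st.floats(0.0, 0.25),
        model=st.sampled_from(["base", "base+eur_pulse", "base+afr_pulse"]),
    )
    @settings(max_examples=120, deadline=None)
    def test_round_trip_identity(self, t0, ta_frac, tp_frac, m, model):
        """schedule_proportions inverts the closed-form magnitude solve to
        1e-10 for every feasible parameter draw."""
        params = {"t0": t0, "t_afr": 2.0 + ta_frac * (t0 - 2.5)}
        if model != "base":
            params["t_pulse"] = 2.0 + tp_frac * (t0 - 2.5)
            params["m_pulse"] = m
        try:
            sch = build_migration_schedule(model, params, PROPS)
        except InfeasibleParametersError:
            return
        got = schedule_proportions(sch)
        for pop, want in PROPS.items():
            assert abs(got[pop] - want) < 1e-10


class TestAncestryChain:
    def test_stationarity_and_generator_rows(self, base_schedule):
        for depth in (0, 1):
            anc, pi, Q = ancestry_chain(base_schedule, depth=depth)
            assert pi.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            np.testing.assert_allclose(pi @ Q, 0.0, atol=1e-12)

    def test_state_weights_match_entry_probabilities(self, base_schedule):
        states, pi, _ = markov_chain(base_schedule)
        a = base_schedule.entry_weights()
        for (t, p), w in zip(states, pi):
            assert w == pytest.approx(a[t, p])

    def test_pair_construction_exact_at_t0_3(self):
        # T0 = 3: the sampled haplotype toggles between two founder
        # gametes; whole-chromosome probability has a closed form
        f, L = 0.65, 1.5
        sch = ak.MigrationSchedule.from_pulses(("EUR", "NAT"), 3, {"EUR": f, "NAT": 1 - f})
        chroms = ak.ChromosomeSet.uniform(1, 100 * L)
        exact = f * f + f * (1 - f) * math.exp(-L)
        exp = expected_tract_spectrum(sch, chroms, np.array([0.2]), 1, depth=1)
        assert exp.full_mu[0, 0] == pytest.approx(exact, abs=1e-12)
        # the plain Markov chain underestimates it
        exp0 = expected_tract_spectrum(sch, chroms, np.array([0.2]), 1, depth=0)
        assert exp0.full_mu[0, 0] < exact


class TestExpectedSpectrum:
    def test_single_source_degenerates_to_whole_chromosomes(self, chroms_small):
        sch = ak.MigrationSchedule.from_pulses(("EUR", "NAT"), 5, {"EUR": 1.0})
        exp = expected_tract_spectrum(sch, chroms_small, np.array([0.2, 10.0]), 10)
        assert exp.full_mu[0].sum() == pytest.approx(10 * len(chroms_small))
        assert exp.mu.sum() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("depth", [0, 1])
    def test_length_conservation(self, base_schedule, chroms10, depth):
        """Expected total tract length per ancestry equals the schedule
        proportion x genome length x haplotypes to 1e-6 relative."""
        edges = ak.default_bin_edges(chroms10, 50)
        exp = expected_tract_spectrum(base_schedule, chroms10, edges, 2000, depth=depth)
        target = schedule_proportions(base_schedule)
        for i, pop in enumerate(exp.ancestries):
            want = target[pop] * chroms10.total_cM * 2000
            assert abs(exp.length_mass[i] - want) / want < 1e-6

    def test_length_conservation_over_random_schedules(self, chroms_small):
        rng = np.random.default_rng(5)
        edges = ak.default_bin_edges(chroms_small, 20)
        for _ in range(30):
            t0 = rng.uniform(4, 18)
            params = {"t0": t0, "t_afr": rng.uniform(2.1, t0 - 1)}
            try:
                sch = build_migration_schedule("base", params, PROPS)
            except InfeasibleParametersError:
                continue
            exp = expected_tract_spectrum(sch, chroms_small, edges, 50)
            target = schedule_proportions(sch)
            for i, pop in enumerate(exp.ancestries):
                want = target[pop] * chroms_small.total_cM * 50
                assert abs(exp.length_mass[i] - want) < 1e-6 * max(want, 1.0)

    def test_exact_regime_matches_forward_simulation(self):
        """Oracle equivalence where the analytic chain is exact
        (2 + depth >= T0): per-bin agreement within 4 Poisson SD and a
        chi-square that does not reject at alpha = 0.01."""
        from scipy.stats import chi2

        props = {"EUR": 0.62, "NAT": 0.33, "AFR": 0.05}
        sch = build_migration_schedule("base", {"t0": 4, "t_afr": 3}, props)
        chroms = ak.ChromosomeSet.uniform(6, 150.0)
        edges = ak.default_bin_edges(chroms, 30)
        counts = None
        full = None
        reps, n_ind = 10, 100
        for r in range(reps):
            cohort = ak.simulate_pedigree_tracts(
                sch, chroms, n_ind, seed=900 + r, pedigree_size=50000
            )
            s = ak.TractLengthSpectrum.from_cohort(cohort, edges)
            counts = s.counts if counts is None else counts + s.counts
            full = s.full_counts if full is None else full + s.full_counts
        n_h = 2 * n_ind * reps
        exp = expected_tract_spectrum(sch, chroms, edges, n_h, depth=2)
        z = (counts - exp.mu) / np.sqrt(np.maximum(exp.mu, 1e-12))
        assert np.all(np.abs(z[exp.mu > 1.0]) < 4.0)
        zf = (full.sum(1) - exp.full_mu.sum(1)) / np.sqrt(np.maximum(exp.full_mu.sum(1), 1e-12))
        assert np.all(np.abs(zf[exp.full_mu.sum(1) > 1.0]) < 4.0)
        o, m = counts.ravel(), exp.mu.ravel()
        mask = m >= 5
        stat = float(((o[mask] - m[mask]) ** 2 / m[mask]).sum())
        assert chi2.sf(stat, int(mask.sum())) > 0.01


class TestPoissonLoglik:
    def test_all_zero_observed_unit_means(self, chroms_small):
        spec = ak.TractLengthSpectrum(
            edges=np.array([1.0, 2.0]),
            ancestries=("EUR",),
            counts=np.zeros((1, 2), dtype=int),
            full_counts=np.zeros((1, 4), dtype=int),
            n_haplotypes=1,
            chromosomes=chroms_small,
        )
        exp = ak.ExpectedSpectrum(
            edges=np.array([1.0, 2.0]),
            ancestries=("EUR",),
            mu=np.ones((1, 2)),
            full_mu=np.ones((1, 4)),
            length_mass=np.zeros(1),
            n_haplotypes=1,
            chromosomes=chroms_small,
            proportions={"EUR": 1.0},
        )
        assert poisson_loglik(spec, exp) == pytest.approx(-6.0)

    def test_matches_direct_pmf_summation(self, chroms_small):
        rng = np.random.default_rng(0)
        mu = rng.uniform(0.2, 8.0, size=(2, 3))
        full_mu = rng.uniform(0.1, 2.0, size=(2, 4))
        o = rng.poisson(mu)
        of = rng.poisson(full_mu)
        spec = ak.TractLengthSpectrum(
            edges=np.array([1.0, 2.0, 3.0]), ancestries=("EUR", "NAT"),
            counts=o, full_counts=of, n_haplotypes=1, chromosomes=chroms_small,
        )
        exp = ak.ExpectedSpectrum(
            edges=np.array([1.0, 2.0, 3.0]), ancestries=("EUR", "NAT"),
            mu=mu, full_mu=full_mu, length_mass=np.zeros(2), n_haplotypes=1,
            chromosomes=chroms_small, proportions={},
        )
        want = poisson.logpmf(o, mu).sum() + poisson.logpmf(of, full_mu).sum()
        assert poisson_loglik(spec, exp) == pytest.approx(want)

    def test_zero_mean_with_observation_is_impossible(self, chroms_small):
        spec = ak.TractLengthSpectrum(
            edges=np.array([1.0]), ancestries=("EUR",),
            counts=np.array([[3]]), full_counts=np.zeros((1, 4), dtype=int),
            n_haplotypes=1, chromosomes=chroms_small,
        )
        exp = ak.ExpectedSpectrum(
            edges=np.array([1.0]), ancestries=("EUR",),
            mu=np.zeros((1, 1)), full_mu=np.zeros((1, 4)), length_mass=np.zeros(1),
            n_haplotypes=1, chromosomes=chroms_small, proportions={},
        )
        assert poisson_loglik(spec, exp) == -math.inf


class TestFastPathEquivalence:
    def test_numba_likelihood_matches_reference(self, base_schedule, chroms_small):
        cohort = ak.simulate_pedigree_tracts(base_schedule, chroms_small, 30, seed=77)
        edges = ak.default_bin_edges(chroms_small, 20)
        spec = ak.TractLengthSpectrum.from_cohort(cohort, edges)
        props = dict(zip(cohort.populations, cohort.ancestry_fractions().mean(0)))
        rng = np.random.default_rng(1)
        for model in ("base", "base+eur_pulse", "base+afr_pulse"):
            fast = TractModel(spec, model, props, depth=0)
            ref = TractModel(spec, model, props, depth=0)
            ref._fast = None
            assert fast._fast is not None
            for _ in range(15):
                t0 = rng.uniform(4, 20)
                x = [t0, rng.uniform(2.1, t0 - 0.8)]
                if model != "base":
                    x += [rng.uniform(2.1, t0 - 0.8), rng.uniform(0.005, 0.3)]
                a, b = fast.loglike(np.array(x)), ref.loglike(np.array(x))
                if math.isfinite(a) or math.isfinite(b):
                    assert a == pytest.approx(b, abs=1e-6), (model, x)


class TestFit:
    def test_nestedness_of_maximised_likelihoods(self, base_schedule, chroms_small):
        cohort = ak.simulate_pedigree_tracts(base_schedule, chroms_small, 40, seed=13)
        edges = ak.default_bin_edges(chroms_small, 20)
        spec = ak.TractLengthSpectrum.from_cohort(cohort, edges)
        props = dict(zip(cohort.populations, cohort.ancestry_fractions().mean(0)))
        base = TractModel(spec, "base", props).fit(n_starts=4, seed=0)
        warm = [np.append(base.x, [3.5, 0.002])]
        alt = TractModel(spec, "base+eur_pulse", props).fit(
            n_starts=2, seed=0, warm_starts=warm
        )
        assert alt.llf >= base.llf - 1e-6

    def test_empty_spectrum_fails(self, chroms_small):
        spec = ak.TractLengthSpectrum(
            edges=np.array([1.0, 2.0]), ancestries=("EUR", "NAT", "AFR"),
            counts=np.zeros((3, 2), dtype=int), full_counts=np.zeros((3, 4), dtype=int),
            n_haplotypes=0, chromosomes=chroms_small,
        )
        with pytest.raises(FitFailureError):
            TractModel(spec, "base", {"EUR": 0.6, "NAT": 0.35, "AFR": 0.05})

    def test_results_summary_and_serialisation(self, base_schedule, chroms_small):
        cohort = ak.simulate_pedigree_tracts(base_schedule, chroms_small, 30, seed=14)
        spec = ak.TractLengthSpectrum.from_cohort(cohort, ak.default_bin_edges(chroms_small, 20))
        props = dict(zip(cohort.populations, cohort.ancestry_fractions().mean(0)))
        res = TractModel(spec, "base", props).fit(n_starts=3, seed=1)
        text = res.summary()
        assert "t0" in text and "log-likelihood" in text
        payload = res.to_json()
        assert '"model": "base"' in payload
        assert np.isfinite(res.bic())
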