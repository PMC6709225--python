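"""Fuzzy-truncated objectives and the evolutionary search machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leechheart as lh
from leechheart.errors import SpecificationError, ValidationError
from leechheart.metrics import METRIC_NAMES
from leechheart.optimize import (
    ParameterDescriptor,
    SearchSpec,
    fuzzy_fitness,
    pareto_front,
    rho_descriptors,
    run_search,
    sigma_descriptors,
    toy_evaluator,
    toy_two_sigma_problem,
)


class TestFuzzyFitness:
    @pytest.mark.parametrize(
        "err,expected", [(0.0, 1.0), (1.0, 1.0), (-1.0, 1.0), (2.0, 4.0),
                         (-3.0, 9.0), (0.5, 1.0)]
    )
    def test_values(self, err, expected):
        assert fuzzy_fitness(err) == expected

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.floats(-5, 5))
    def test_even_with_flat_unit_floor(self, e):
        f = fuzzy_fitness(e)
        assert f == fuzzy_fitness(-e)
        if abs(e) <= 1:
            assert f == 1.0
        else:
            assert f == e * e > 1.0

    def test_monotone_in_magnitude(self):
        e = np.linspace(0, 4, 200)
        f = fuzzy_fitness(e)
        assert np.all(np.diff(f) >= 0)

    def test_smooth_variant_close_to_hard_floor(self):
        e = np.linspace(-3, 3, 101)
        hard = fuzzy_fitness(e)
        smooth = fuzzy_fitness(e, mode="smooth")
        assert np.all(np.abs(smooth - hard) < 0.15)
        with pytest.raises(ValidationError):
            fuzzy_fitness(0.0, mode="bogus")


def _brute_force_front(F):
    n = F.shape[0]
    keep = []
    for i in range(n):
        dominated = False
        for j in range(n):
            if j != i and np.all(F[j] <= F[i]) and np.any(F[j] < F[i]):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return np.array(keep)


class TestParetoFront:
    def test_all_ones_dominates(self):
        F = np.vstack([np.ones(18), np.full(18, 2.0)])
        assert list(pareto_front(F)) == [0]

    def test_incomparable_vectors_both_on_front(self):
        F = np.array([[1.0, 2.0], [2.0, 1.0]])
        assert sorted(pareto_front(F)) == [0, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.uniform(1, 4, size=(50, 18))
        # duplicate some rows to exercise tie handling
        F[10] = F[3]
        np.testing.assert_array_equal(
            np.sort(pareto_front(F)), np.sort(_brute_force_front(F))
        )


class TestSearchSpec:
    def test_budget_below_population_rejected(self):
        with pytest.raises(SpecificationError):
            SearchSpec(parameters=sigma_descriptors(), budget=10,
                       population_size=50)

    def test_degenerate_space_rejected(self):
        flat = [ParameterDescriptor("sigma.HE8", "sigma", 1.0, 1.0)]
        with pytest.raises(SpecificationError):
            SearchSpec(parameters=flat, budget=100, population_size=10)

    def test_conductance_snapping(self):
        d = ParameterDescriptor("neurite.P", "conductance", 2, 100)
        assert d.snap(37.3) == 38.0
        assert d.snap(150.0) == 100.0
        assert d.snap(-5.0) == 2.0

    def test_rho_bounds_follow_measured_sd(self, phys_profile):
        descs = {d.name: d for d in rho_descriptors(phys_profile)}
        d = descs["rho.HN3.HE8"]  # w=0.5, sd=0.15
        assert d.low == pytest.approx(0.35 / 0.5)
        assert d.high == pytest.approx(0.65 / 0.5)


class TestRunSearch:
    def test_pure_random_sampling_accounting(self):
        params, err = toy_two_sigma_problem()
        spec = SearchSpec(parameters=params, budget=30, batches=3, seed=0,
                          population_size=30)
        res = run_search(spec, evaluator=toy_evaluator(err, True))
        assert res.n_evaluated == 90
        assert len(res.batch_seeds) == 3

    def test_reproducible_given_seed(self):
        params, err = toy_two_sigma_problem()
        spec = SearchSpec(parameters=params, budget=120, batches=2, seed=11,
                          population_size=20)
        r1 = run_search(spec, evaluator=toy_evaluator(err, True))
        r2 = run_search(spec, evaluator=toy_evaluator(err, True))
        assert [i.params for i in r1.individuals] == [i.params for i in r2.individuals]
        assert [i.mae for i in r1.individuals] == [i.mae for i in r2.individuals]

    def test_good_subset_and_ratio(self):
        params, err = toy_two_sigma_problem()
        spec = SearchSpec(parameters=params, budget=200, batches=1, seed=3,
                          population_size=20)
        res = run_search(spec, evaluator=toy_evaluator(err, True))
        assert 0 <= res.r_g <= 1
        assert all(i.is_good for i in res.good)
        assert len(res.good) == int(round(res.r_g * res.n_evaluated))


class TestCircuitEvaluation:
    def test_self_target_scores_all_objectives_at_floor(self, fast_pattern,
                                                        phys_profile, self_target):
        obj, ev = lh.evaluate_individual(
            {}, fast_pattern, phys_profile, self_target.targets,
            duration=22.0, step=2e-4,
        )
        assert ev is not None and ev.mae == 0.0
        np.testing.assert_array_equal(obj, np.ones(18))

    def test_silent_model_returns_sentinel(self, fast_pattern, phys_profile,
                                           self_target):
        """Removing all inhibition leaves one unbroken spike train: no
        bursts, no metrics — encoded as a worst-case objective vector."""
        obj, ev = lh.evaluate_individual(
            {"sigma.HE8": 0.0, "sigma.HE12": 0.0},
            fast_pattern, phys_profile, self_target.targets,
            duration=22.0, step=2e-4,
        )
        assert ev is None
        assert np.all(obj >= 1e6)

    def test_sigma_he8_perturbation_is_local(self, fast_pattern, phys_profile,
                                             self_target):
        """Scaling only HE(8)'s inputs leaves every HE(12) metric unchanged
        (the two segments' neurons are not coupled) while changing HE(8)
        metrics and the progressions."""
        base = lh.make_circuit_evaluator(
            fast_pattern, phys_profile, self_target.targets,
            duration=22.0, step=2e-4,
        )
        _, _, _, errs0 = base({})
        _, _, _, errs1 = base({"sigma.HE8": 1.2})
        assert errs1 is not None, "perturbed model must still burst"
        for k in METRIC_NAMES:
            if k.startswith("HE12."):
                assert errs1[k] == errs0[k], k
        changed = [k for k in METRIC_NAMES if errs1[k] != errs0[k]]
        assert any(k.startswith("HE8.") for k in changed)
        assert any(k.endswith("m_delta_phi") for k in changed)
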