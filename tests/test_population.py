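"""Population-level analyses: SSI, cross-animal tests, correlations, KW."""

import numpy as np
import pytest

import leechheart as lh
from leechheart.circuit import ConductanceParameterSet, REFERENCE_PERCENTAGES
from leechheart.errors import (
    DegenerateRegressionError,
    InputError,
    StatisticsError,
    UndefinedSSIError,
)
from leechheart.population import (
    compare_weight_distributions,
    conductance_correlation,
    cross_animal_test,
    max_progression_protocol,
    ssi,
)
from leechheart.profiles import CONNECTIONS, SynapticProfile


def _profile(overrides=None):
    w = {k: 1.0 for k in CONNECTIONS}
    w.update(overrides or {})
    return SynapticProfile(w)


class TestSSI:
    def test_equal_weights_give_two(self):
        assert ssi(_profile()) == pytest.approx(2.0)

    def test_printed_formula_arithmetic(self):
        prof = _profile({
            ("HN4", "HE8"): 0.6, ("HN4", "HE12"): 0.2,
            ("HN7", "HE12"): 0.5, ("HN7", "HE8"): 0.25,
        })
        assert ssi(prof) == pytest.approx(5.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(UndefinedSSIError):
            ssi(_profile({("HN4", "HE12"): 0.0}))

    def test_global_rescaling_leaves_ssi_unchanged(self):
        rng = np.random.default_rng(2)
        w = {k: float(rng.uniform(0.1, 1.0)) for k in CONNECTIONS}
        a = ssi(SynapticProfile(w))
        b = ssi(SynapticProfile({k: 3.7 * v for k, v in w.items()}))
        assert a == pytest.approx(b)


class TestConductanceCorrelation:
    def _models(self, xs, ys):
        base = dict(REFERENCE_PERCENTAGES)
        out = []
        for x, y in zip(xs, ys):
            d = dict(base)
            d["neurite.K2"] = x
            d["neurite.P"] = y
            out.append(d)
        return out

    def test_collinear_set_has_unit_r_squared(self):
        xs = np.arange(2, 42, 2)
        models = self._models(xs, xs)  # P == K2 exactly
        res = conductance_correlation(models)
        assert res.r_squared == pytest.approx(1.0)
        assert res.n_models == 20

    @pytest.mark.parametrize("seed", range(5))
    def test_independent_samples_have_negligible_r_squared(self, seed):
        rng = np.random.default_rng(seed)
        xs = 2 * rng.integers(1, 51, 500)
        ys = 2 * rng.integers(1, 51, 500)
        res = conductance_correlation(self._models(xs, ys))
        assert res.r_squared < 0.05

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(0)
        xs = 2.0 * rng.integers(1, 41, 200)
        ys = 0.8 * xs + rng.normal(0, 2.0, xs.size)
        res = conductance_correlation(self._models(xs, ys))
        assert res.slope == pytest.approx(0.8, rel=0.10)
        assert res.p_value < 1e-6

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(DegenerateRegressionError):
            conductance_correlation(self._models([10] * 12, range(2, 26, 2)))

    def test_too_few_models_rejected(self):
        with pytest.raises(InputError):
            conductance_correlation(self._models([2, 4], [2, 4]))


class TestWeightDistributions:
    def _profiles(self, values):
        rng_order = list(CONNECTIONS)
        out = []
        for vals in values:
            out.append(SynapticProfile({k: v for k, v in zip(rng_order, vals)}))
        return out

    def test_identical_groups_not_distinguished(self):
        vals = [np.linspace(0.1, 1.0, 8)] * 3
        h, p = compare_weight_distributions(self._profiles(vals), self._profiles(vals))
        assert p > 0.9

    def test_disjoint_support_detected(self):
        lo = [np.linspace(0.05, 0.3, 8) + 0.01 * i for i in range(3)]
        hi = [np.linspace(0.6, 1.0, 8) + 0.01 * i for i in range(3)]
        h, p = compare_weight_distributions(self._profiles(lo), self._profiles(hi))
        assert p < 0.01

    def test_fitted_within_one_sd_indistinguishable(self):
        """rho-adjusted weights within +-1 SD of the measured averages are
        statistically indistinguishable from them in most seeded draws."""
        rng_master = np.random.default_rng(42)
        n_ok = 0
        for _ in range(10):
            w = {k: float(rng_master.uniform(0.3, 1.0)) for k in CONNECTIONS}
            sd = {k: 0.1 for k in CONNECTIONS}
            measured = SynapticProfile(w, sd)
            rho = {
                k: float(np.clip(1 + rng_master.uniform(-1, 1) * sd[k] / w[k],
                                 0, None))
                for k in CONNECTIONS
            }
            fitted = measured.with_rho(rho)
            _, p = compare_weight_distributions([measured], [fitted])
            n_ok += p > 0.05
        assert n_ok >= 9

    def test_degenerate_all_identical_rejected(self):
        vals = [np.full(8, 0.5)] * 3
        with pytest.raises(StatisticsError):
            compare_weight_distributions(self._profiles(vals), self._profiles(vals))


class TestMaxProgression:
    def test_synchronous_like_pattern_gives_near_zero_progression(self):
        pat = lh.generate_premotor_pattern(
            lh.PatternSpec(period=4.0, n_cycles=6, pm_delta_phi=0.0,
                           jitter_sd=0.0, rate_cv=0.0, rate_spread=0.0)
        )
        md = max_progression_protocol(pat, duration=22.0, step=2e-4)
        assert abs(md) <= 0.05


@pytest.fixture(scope="module")
def animals(phys_profile):
    """Two synthetic animals sharing the planted reference solution."""
    truth = ConductanceParameterSet.reference()
    out = []
    for label, seed, dphi in (("A", 0, 0.10), ("B", 3, 0.14)):
        pat = lh.generate_premotor_pattern(
            lh.PatternSpec(period=4.0, n_cycles=6, pm_delta_phi=dphi,
                           jitter_sd=0.0, rate_cv=0.0, rate_spread=0.0,
                           seed=seed)
        )
        out.append(
            lh.generate_target_profile(truth, phys_profile, pat,
                                       duration=22.0, step=2e-4, label=label)
        )
    return out


class TestCrossAnimal:
    def test_planted_solution_good_in_both_animals(self, animals):
        truth = ConductanceParameterSet.reference()
        res = cross_animal_test([truth], animals, duration=22.0, step=2e-4)
        for label in ("A", "B"):
            assert res[label]["n_good"] == 1
            assert res[label]["ratio_percent"] == 100.0
            assert res[label]["mae_min"] < 1.0

    def test_impossible_targets_give_zero_ratio(self, animals):
        import copy

        truth = ConductanceParameterSet.reference()
        far = copy.deepcopy(animals[0])
        for k in far.targets.targets:
            far.targets.targets[k] += 50 * far.targets.ranges[k]
        res = cross_animal_test([truth], [far], duration=22.0, step=2e-4)
        assert res["A"]["ratio_percent"] == 0.0

    def test_empty_model_set_rejected(self, animals):
        with pytest.raises(InputError):
            cross_animal_test([], animals)
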