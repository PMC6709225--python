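"""Cross-animal and ensemble analyses over populations of good models.

Once ensembles of functional ("good", MAE < 1) model instances exist for
individual animals, the questions move to the population level: do the
intrinsic conductance sets found for one animal also work in the others
when each animal's own fitted synaptic strengths and premotor pattern are
used (cross-animal generalization)?  How large can the peristaltic motor
phase progression get at all, given a premotor pattern (the theoretical
maximum-progression protocol)?  Is the preference structure of the synaptic
weight pattern (the synaptic strength index, SSI) preserved?  Do fitted
weight distributions differ from measured ones (Kruskal-Wallis)?  And do
intrinsic conductances co-vary across good models the same way in every
animal (e.g. the neurite K2 vs P correlation)?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .circuit import (
    ConductanceParameterSet,
    apply_parameter_set,
    build_ensemble,
    set_synaptic_strengths,
)
from .engine import simulate
from .errors import (
    DegenerateRegressionError,
    InputError,
    LeechHeartError,
    StatisticsError,
    UndefinedSSIError,
)
from .metrics import (
    compute_metric_vector,
    detect_spikes,
    metric_errors,
    phase_of_trains,
    segment_bursts,
)
from .profiles import SynapticProfile

__all__ = [
    "AnimalProfile",
    "CorrelationResult",
    "ssi",
    "cross_animal_test",
    "max_progression_protocol",
    "conductance_correlation",
    "compare_weight_distributions",
]


@dataclass
class AnimalProfile:
    """Everything the pipeline knows about one animal: its premotor pattern,
    its (measured or fitted) synaptic profile and its metric targets."""

    label: str
    pattern: object  # PremotorPattern
    synapses: SynapticProfile
    targets: object  # TargetProfile

    def target_m_delta_phi(self, coordination: str = "peristaltic") -> float:
        return self.targets.targets[f"{coordination}.m_delta_phi"]


@dataclass(frozen=True)
class CorrelationResult:
    """Linear-regression summary for one conductance pair."""

    pair: tuple
    r_squared: float
    p_value: float
    n_models: int
    slope: float
    intercept: float


def ssi(profile: SynapticProfile, use_fitted: bool = False) -> float:
    """Synaptic strength index: the summed preference of HN(4) for HE(8)
    and of HN(7) for HE(12),

        SSI = w_HN4->HE8 / w_HN4->HE12 + w_HN7->HE12 / w_HN7->HE8.
    """
    w = profile.fitted_weights() if use_fitted else profile.w
    d1 = w[("HN4", "HE12")]
    d2 = w[("HN7", "HE8")]
    if d1 <= 0 or d2 <= 0:
        raise UndefinedSSIError(
            "SSI undefined: w_HN4->HE12 and w_HN7->HE8 must be positive"
        )
    return w[("HN4", "HE8")] / d1 + w[("HN7", "HE12")] / d2


def _simulate_mae(params, animal: AnimalProfile, config, duration, step,
                  metric_kwargs):
    circuit = apply_parameter_set(build_ensemble(config), params)
    circuit = set_synaptic_strengths(circuit, animal.synapses)
    sim = simulate(circuit, animal.pattern, duration=duration, step=step)
    mv = compute_metric_vector(sim, animal.pattern, **(metric_kwargs or {}))
    return metric_errors(mv, animal.targets).mae


def cross_animal_test(
    good_models,
    animals,
    config: dict = None,
    duration: float = None,
    step: float = 2e-4,
    metric_kwargs: dict = None,
) -> dict:
    """Test intrinsic-conductance sets from one animal on other animals.

    Each model carries only intrinsic + coupling parameters; for every
    target animal the synaptic strengths are replaced by that animal's own
    fitted values (its profile's w*rho*sigma) and the model is simulated
    with that animal's premotor pattern and scored against its targets.

    Returns, per animal label: the min-max MAE range, the number of good
    models (MAE < 1) and their percentage.
    """
    if not good_models:
        raise InputError("empty model set")
    out = {}
    for animal in animals:
        dur = duration if duration is not None else 8 * animal.pattern.period
        maes = []
        for params in good_models:
            if not isinstance(params, ConductanceParameterSet):
                params = ConductanceParameterSet(dict(params))
            try:
                mae = _simulate_mae(
                    params, animal, config, dur, step, metric_kwargs
                )
            except LeechHeartError:
                mae = float("inf")
            maes.append(mae)
        maes = np.asarray(maes)
        finite = maes[np.isfinite(maes)]
        n_good = int(np.sum(maes < 1.0))
        out[animal.label] = {
            "mae_min": float(finite.min()) if finite.size else float("inf"),
            "mae_max": float(finite.max()) if finite.size else float("inf"),
            "n_good": n_good,
            "ratio_percent": 100.0 * n_good / len(good_models),
            "maes": maes,
        }
    return out


def max_progression_protocol(
    pattern,
    params: ConductanceParameterSet = None,
    config: dict = None,
    rho_value: float = 4.0,
    duration: float = None,
    step: float = 2e-4,
    threshold: float = -20.0,
    transient_cycles: int = 2,
) -> float:
    """Estimate the attainable upper bound of the peristaltic motor phase
    progression for a premotor pattern.

    All synapses are silenced except the earliest input to HE(8) and the
    latest input to HE(12) — HN(3)->HE(8) and HN(7)->HE(12) — which are set
    to ``rho_value`` times the unitary strength.  Driving each motor neuron
    with a single input at opposite ends of the premotor phase spread
    maximally separates their burst phases, so the resulting mdphi tracks
    (and cannot exceed) the premotor phase progression.
    """
    if params is None:
        params = ConductanceParameterSet.reference()
    weights = {k: 0.0 for k in SynapticProfile.uniform().w}
    weights[("HN3", "HE8")] = 1.0
    weights[("HN7", "HE12")] = 1.0
    rho = {k: 1.0 for k in weights}
    rho[("HN3", "HE8")] = rho_value
    rho[("HN7", "HE12")] = rho_value
    profile = SynapticProfile(weights, rho=rho)

    if duration is None:
        duration = 8 * pattern.period
    circuit = set_synaptic_strengths(
        apply_parameter_set(build_ensemble(config), params), profile
    )
    sim = simulate(circuit, pattern, duration=duration, step=step)

    side = next(s for s, c in sim.assignment.items() if c == "peristaltic")
    t_discard = sim.t[0] + transient_cycles * pattern.period
    ref = segment_bursts(pattern.train("HN4", "peristaltic"),
                         max_isi=0.2 * pattern.period).median_times
    medians = {}
    for he in ("HE8", "HE12"):
        v = sim.soma_voltage(side, he)
        st, hh = detect_spikes(v, fs=sim.fs, threshold=threshold)
        bursts = segment_bursts(st + sim.t[0], heights=hh).after(t_discard)
        medians[he] = bursts.median_times
    _, _, mdphi = phase_of_trains(medians["HE8"], medians["HE12"], ref,
                                  pattern.period)
    return mdphi


def conductance_correlation(
    good_models,
    pair=("neurite.K2", "neurite.P"),
    min_models: int = 10,
) -> CorrelationResult:
    """Ordinary least-squares correlation between two conductance parameters
    across an ensemble of good models; the second is regressed on the first
    (R^2 is symmetric in the pair)."""
    if len(good_models) < min_models:
        raise InputError(
            f"need >= {min_models} good models, got {len(good_models)}"
        )

    def _pct(m, name):
        if isinstance(m, ConductanceParameterSet):
            return m.percentages[name]
        return m[name]

    x = np.array([_pct(m, pair[0]) for m in good_models], dtype=float)
    y = np.array([_pct(m, pair[1]) for m in good_models], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateRegressionError(f"zero variance in predictor {pair[0]}")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return CorrelationResult(
        pair=tuple(pair),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue) if x.size > 2 else float("nan"),
        n_models=int(x.size),
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
    )


def compare_weight_distributions(measured, fitted) -> tuple:
    """Kruskal-Wallis comparison of pooled relative synaptic weights.

    ``measured`` and ``fitted`` are iterables of
    :class:`~leechheart.profiles.SynapticProfile`; the eight relative
    weights of every profile are pooled per group (measured uses ``w``,
    fitted uses the rho-adjusted ``w * rho``).  Returns ``(H, p)``.
    """
    a = np.concatenate([list(p.w.values()) for p in measured])
    b = np.concatenate([list(p.fitted_weights().values()) for p in fitted])
    if a.size < 3 or b.size < 3:
        raise StatisticsError("need at least 3 values per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise StatisticsError("degenerate input: all weights are identical")
    try:
        h, p = stats.kruskal(a, b)
    except ValueError as exc:
        raise StatisticsError(str(exc)) from None
    return float(h), float(p)
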