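"""Conduct of a single dose-escalation trial under the three designs.

Three designs share the same escalation machinery:

``baseline``
    Homogeneous-population design: the two-parameter model is fitted to the
    pooled pseudo+trial data and one dose is advised for everybody.

``method1``
    Subgroup-covariate design: the four-parameter model is fitted throughout
    and each subgroup is advised its own dose.  A subgroup with no safe dose
    stops for safety; the survivor continues under the two-parameter model
    fitted to its own data.

``method2``
    Spike-and-slab design: each cohort update first runs the variable
    selection chain to choose which subgroup terms enter the model, then
    refits the chosen model by MAP and advises doses as above.

Cohorts have size 2 (one patient per subgroup while both are active; both
from the survivor after a one-sided stop).  Trials stop per subgroup for
safety, for reaching the per-subgroup patient cap, or optionally for
accuracy (enough patients at the advised dose and a narrow TD interval).
Final recommendations are frequentist: fitted to trial data only, never the
pseudo-data, and restricted to doses at or below the maximum administered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Protocol

import numpy as np
import pandas as pd

from .model import (
    FULL,
    POOLED,
    DoseGrid,
    DoseToxicityFit,
    EscalationPolicy,
    ModelSpec,
    ToxicityDataset,
    ToxicityRecord,
    fit_model,
    select_dose,
    td_interval,
)
from .prior import PseudoDataSpec, SlabPrior, derive_slab, expand_pseudo_data
from .spikeslab import SpikeSlabConfig, choose_model, run_chain

__all__ = [
    "TrialConfig",
    "TrialState",
    "TrialResult",
    "advise_next_doses",
    "check_accuracy_stop",
    "run_trial",
]

ACTIVE = "active"
STOP_SAFETY = "stopped_safety"
STOP_ACCURACY = "stopped_accuracy"
STOP_MAX = "stopped_max"

VERDICT_NO_EFFECT = 0
VERDICT_EFFECT = 1
VERDICT_DEFAULTED = 2


class DoseToxicityTruth(Protocol):
    """Anything that can return a true DLT probability per (subgroup, dose)."""

    def prob(self, subgroup: int, dose: float) -> float: ...


@dataclass(frozen=True)
class TrialConfig:
    grid: DoseGrid
    policy: EscalationPolicy
    pseudo: PseudoDataSpec
    method: str = "baseline"
    cohort_size: int = 2
    max_patients: int = 60
    accuracy_stop: bool = False
    accuracy_min_at_dose: int = 5
    accuracy_ci_level: float = 0.95
    accuracy_width_bound: float = 5.0  # mg/m^2, strict inequality
    spike_slab: SpikeSlabConfig = field(default_factory=SpikeSlabConfig)
    slab_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("baseline", "method1", "method2"):
            raise ValueError(f"unknown method: {self.method!r}")
        if self.cohort_size != 2:
            raise ValueError("cohorts of size 2 (one patient per subgroup)")
        if self.max_patients < 2 or self.max_patients % 2:
            raise ValueError("max_patients must be a positive even number")

    @property
    def max_per_subgroup(self) -> int:
        return self.max_patients // 2


@dataclass
class CohortLog:
    cohort: int
    spec: ModelSpec
    w2: Optional[float]
    w3: Optional[float]
    advised: dict[int, Optional[float]]
    treated: list[tuple[int, float, int]] = field(default_factory=list)


@dataclass
class TrialState:
    """Mutable escalation state: accumulated data, statuses and the log."""

    data: ToxicityDataset
    status: dict[int, str] = field(default_factory=lambda: {0: ACTIVE, 1: ACTIVE})
    treated: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 0})
    dlts: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 0})
    max_dose: dict[int, Optional[float]] = field(default_factory=lambda: {0: None, 1: None})
    count_at_dose: dict[tuple[int, float], int] = field(default_factory=dict)
    one_sided_safety: bool = False
    fallbacks: int = 0
    log: list[CohortLog] = field(default_factory=list)

    def active(self) -> list[int]:
        return [g for g in (0, 1) if self.status[g] == ACTIVE]

    def treat(self, subgroup: int, dose: float, outcome: int) -> None:
        self.data.add(
            ToxicityRecord(dose, subgroup, float(outcome), float(1 - outcome))
        )
        self.treated[subgroup] += 1
        self.dlts[subgroup] += outcome
        prev = self.max_dose[subgroup]
        self.max_dose[subgroup] = dose if prev is None else max(prev, dose)
        key = (subgroup, dose)
        self.count_at_dose[key] = self.count_at_dose.get(key, 0) + 1

    def trajectory_frame(self) -> pd.DataFrame:
        rows = []
        for entry in self.log:
            for g, dose, outcome in entry.treated:
                rows.append(
                    {
                        "cohort": entry.cohort,
                        "subgroup": g,
                        "dose": dose,
                        "outcome": outcome,
                        "include_beta2": entry.spec.include_beta2,
                        "include_beta3": entry.spec.include_beta3,
                        "w2": entry.w2,
                        "w3": entry.w3,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one trial: recommendations, verdict, totals, stop reasons."""

    recommended: dict[int, Optional[float]]
    verdict: int
    n_patients: dict[int, int]
    n_dlts: dict[int, int]
    stop_reasons: dict[int, str]
    fallbacks: int
    seed: int
    trajectory: Optional[pd.DataFrame] = None

    @property
    def total_patients(self) -> int:
        return self.n_patients[0] + self.n_patients[1]

    @property
    def total_dlts(self) -> int:
        return self.n_dlts[0] + self.n_dlts[1]

    def dlt_proportion(self, subgroup: Optional[int] = None) -> float:
        if subgroup is None:
            return self.total_dlts / self.total_patients if self.total_patients else float("nan")
        n = self.n_patients[subgroup]
        return self.n_dlts[subgroup] / n if n else float("nan")

    def to_json(self) -> str:
        payload = {
            "recommended": {str(g): self.recommended[g] for g in (0, 1)},
            "verdict": self.verdict,
            "n_patients": {str(g): self.n_patients[g] for g in (0, 1)},
            "n_dlts": {str(g): self.n_dlts[g] for g in (0, 1)},
            "stop_reasons": {str(g): self.stop_reasons[g] for g in (0, 1)},
            "fallbacks": self.fallbacks,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# escalation advice


@dataclass
class _Advice:
    doses: dict[int, Optional[float]]
    fits: dict[int, Optional[DoseToxicityFit]]
    spec: ModelSpec
    w2: Optional[float] = None
    w3: Optional[float] = None


def _survivor_fit(state: TrialState, config: TrialConfig, g: int) -> DoseToxicityFit:
    """Two-parameter fit to one subgroup's own pseudo + trial data."""
    return fit_model(state.data.subgroup(g), POOLED, config.grid)


def advise_next_doses(
    state: TrialState,
    config: TrialConfig,
    slab: Optional[SlabPrior] = None,
    mcmc_seed: Optional[int] = None,
) -> _Advice:
    """Per-subgroup advised dose for the next cohort (None = safety stop).

    Model choice follows the design: pooled two-parameter (baseline),
    four-parameter (method1), or the spike-and-slab-selected model (method2,
    which needs ``slab`` and ``mcmc_seed``).  After a one-sided safety stop
    the survivor is advised from the two-parameter model fitted to its own
    pseudo + trial data.  A non-converged fit triggers the repeat-last-dose
    fallback, logged via ``state.fallbacks``.
    """
    active = state.active()
    doses: dict[int, Optional[float]] = {}
    fits: dict[int, Optional[DoseToxicityFit]] = {}
    spec = POOLED
    w2 = w3 = None

    one_sided = state.one_sided_safety and len(active) == 1

    if config.method == "baseline":
        fit = fit_model(state.data, POOLED, config.grid)
        for g in active:
            fits[g] = fit
            doses[g] = _advise_one(state, config, fit, g)
    elif one_sided:
        g = active[0]
        fit = _survivor_fit(state, config, g)
        fits[g] = fit
        doses[g] = _advise_one(state, config, fit, g)
    elif config.method == "method1":
        spec = FULL
        fit = fit_model(state.data, FULL, config.grid)
        for g in active:
            fits[g] = fit
            doses[g] = _advise_one(state, config, fit, g)
    else:  # method2
        if slab is None or mcmc_seed is None:
            raise ValueError("method2 advice needs a slab prior and an MCMC seed")
        posterior = run_chain(
            state.data, slab, config.grid, config.spike_slab.with_seed(mcmc_seed)
        )
        w2, w3 = posterior.w2, posterior.w3
        spec = choose_model(posterior, config.spike_slab)
        fit = fit_model(state.data, spec, config.grid)
        for g in active:
            fits[g] = fit
            doses[g] = _advise_one(state, config, fit, g)

    return _Advice(doses=doses, fits=fits, spec=spec, w2=w2, w3=w3)


def _advise_one(
    state: TrialState, config: TrialConfig, fit: DoseToxicityFit, g: int
) -> Optional[float]:
    if not fit.converged:
        # pseudo-data keeps escalation fits identifiable in practice; if a fit
        # still fails, repeat the subgroup's last administered dose
        state.fallbacks += 1
        last = state.max_dose[g]
        return last if last is not None else config.grid.doses[0]
    return select_dose(fit, config.grid, config.policy, subgroup=g)


def check_accuracy_stop(
    state: TrialState,
    config: TrialConfig,
    subgroup: int,
    fit: Optional[DoseToxicityFit],
    advised_dose: Optional[float],
) -> bool:
    """Accuracy stopping rule for one subgroup.

    True iff at least ``accuracy_min_at_dose`` of the subgroup's patients
    have been treated at the advised dose and the ``accuracy_ci_level``
    delta-method interval for the TD100theta estimate is strictly narrower
    than ``accuracy_width_bound`` mg/m^2.  An undefined interval never stops.
    """
    if not config.accuracy_stop or advised_dose is None or fit is None:
        return False
    if state.count_at_dose.get((subgroup, advised_dose), 0) < config.accuracy_min_at_dose:
        return False
    try:
        lo, hi = td_interval(
            fit, config.policy.theta, subgroup, level=config.accuracy_ci_level
        )
    except ValueError:
        return False
    return (hi - lo) < config.accuracy_width_bound


# ---------------------------------------------------------------------------
# full trial simulation


def run_trial(
    config: TrialConfig,
    truth: DoseToxicityTruth,
    seed: int,
    keep_trajectory: bool = False,
) -> TrialResult:
    """Simulate one complete trial: cohorts, stopping, final recommendation.

    The root seed splits into independent streams for patient outcomes and
    per-cohort MCMC, so results are reproducible bit-for-bit.
    """
    out_ss, mcmc_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(out_ss)
    mcmc_rng = np.random.default_rng(mcmc_ss)

    pseudo = expand_pseudo_data(config.pseudo, pooled=config.method == "baseline")
    state = TrialState(data=ToxicityDataset(list(pseudo.records)))
    slab = (
        derive_slab(
            pseudo, config.grid, config.slab_scale, config.spike_slab.prior_inclusion
        )
        if config.method == "method2"
        else None
    )

    cohort = 0
    while state.active():
        advice = _stable_advice(state, config, slab, mcmc_rng)
        active = state.active()
        if not active:
            break

        # accuracy stopping (methods with per-subgroup escalation)
        if config.accuracy_stop:
            for g in list(active):
                if check_accuracy_stop(
                    state, config, g, advice.fits.get(g), advice.doses.get(g)
                ):
                    state.status[g] = STOP_ACCURACY
            active = state.active()
            if not active:
                break

        entry = CohortLog(
            cohort=cohort, spec=advice.spec, w2=advice.w2, w3=advice.w3,
            advised={g: advice.doses.get(g) for g in active},
        )
        allocation = 1 if len(active) == 2 else config.cohort_size
        for g in active:
            dose = advice.doses[g]
            room = config.max_per_subgroup - state.treated[g]
            for _ in range(min(allocation, room)):
                outcome = int(rng.random() < truth.prob(g, dose))
                state.treat(g, dose, outcome)
                entry.treated.append((g, dose, outcome))
        state.log.append(entry)
        for g in active:
            if state.treated[g] >= config.max_per_subgroup:
                state.status[g] = STOP_MAX
        cohort += 1

    result = _finalise(state, config, slab, mcmc_rng, seed)
    if keep_trajectory:
        result = TrialResult(
            **{**result.__dict__, "trajectory": state.trajectory_frame()}
        )
    return result


def _stable_advice(state, config, slab, mcmc_rng) -> _Advice:
    """Advise doses, applying safety stops and re-advising survivors until
    the set of active subgroups is stable."""
    while True:
        active = state.active()
        if not active:
            return _Advice({}, {}, POOLED)
        seed = int(mcmc_rng.integers(2**31)) if config.method == "method2" else None
        advice = advise_next_doses(state, config, slab, seed)
        stopped = [g for g in active if advice.doses.get(g) is None]
        if not stopped:
            return advice
        if config.method == "baseline":
            # single pooled model: a safety stop ends the whole trial
            for g in active:
                state.status[g] = STOP_SAFETY
            return _Advice({}, {}, POOLED)
        for g in stopped:
            state.status[g] = STOP_SAFETY
        if len(stopped) < len(active):
            state.one_sided_safety = True
        # survivors (if any) are re-advised under their post-stop model


# ---------------------------------------------------------------------------
# final recommendation


def _intercept_only_fallback(
    state: TrialState, config: TrialConfig, subgroups: tuple[int, ...], cap: float
) -> Optional[float]:
    """Intercept-only recommendation used when the final frequentist fit is
    rank deficient (all relevant patients at a single dose): the estimated
    DLT probability is the pooled observed fraction at every dose, so all
    allowed doses tie in patient gain and the tie breaks to the lowest —
    mirroring how standard GLM software drops aliased columns and carries
    on.  No recommendation when the pooled fraction is not below delta."""
    state.fallbacks += 1
    trial = state.data.trial_only()
    y1 = y = 0.0
    for r in trial.records:
        if r.subgroup in subgroups:
            y1 += r.dlt_weight
            y += r.dlt_weight + r.no_dlt_weight
    if y == 0 or y1 / y >= config.policy.delta:
        return None
    allowed = [d for d in config.grid.doses if d <= cap]
    return min(allowed) if allowed else None


def _recommend(
    state: TrialState,
    config: TrialConfig,
    data: ToxicityDataset,
    spec: ModelSpec,
    subgroup: int,
    cap: Optional[float],
    screen_groups: tuple[int, ...],
) -> Optional[float]:
    if cap is None:
        return None
    fit = fit_model(data, spec, config.grid)
    allowed = [d for d in config.grid.doses if d <= cap]
    if not allowed:
        return None
    if not fit.converged:
        return _intercept_only_fallback(state, config, screen_groups, cap)
    return select_dose(fit, config.grid, config.policy, subgroup, allowed)


def _finalise(
    state: TrialState,
    config: TrialConfig,
    slab: Optional[SlabPrior],
    mcmc_rng: np.random.Generator,
    seed: int,
) -> TrialResult:
    trial = state.data.trial_only()
    safety_stopped = [g for g in (0, 1) if state.status[g] == STOP_SAFETY]
    recommended: dict[int, Optional[float]] = {0: None, 1: None}

    if config.method == "baseline":
        verdict = VERDICT_NO_EFFECT
        if not safety_stopped:
            cap = min(
                d for d in (state.max_dose[0], state.max_dose[1]) if d is not None
            ) if any(d is not None for d in state.max_dose.values()) else None
            dose = _recommend(state, config, trial, POOLED, 0, cap, (0, 1))
            recommended = {0: dose, 1: dose}
    elif config.method == "method1":
        if len(safety_stopped) == 2:
            verdict = VERDICT_DEFAULTED if state.one_sided_safety else VERDICT_EFFECT
        elif len(safety_stopped) == 1:
            verdict = VERDICT_DEFAULTED
            g = 1 - safety_stopped[0]
            recommended[g] = _recommend(
                state, config, trial.subgroup(g), POOLED, g, state.max_dose[g], (g,)
            )
        else:
            verdict = VERDICT_EFFECT
            for g in (0, 1):
                recommended[g] = _recommend(
                    state, config, trial, FULL, g, state.max_dose[g], (g,)
                )
    else:  # method2
        if len(safety_stopped) == 1 or (
            len(safety_stopped) == 2 and state.one_sided_safety
        ):
            verdict = VERDICT_DEFAULTED
            survivors = [g for g in (0, 1) if g not in safety_stopped]
            for g in survivors:
                recommended[g] = _recommend(
                    state, config, trial.subgroup(g), POOLED, g, state.max_dose[g], (g,)
                )
        elif len(safety_stopped) == 2:
            # both subgroups ruled every dose unsafe at the same update: no
            # dose anywhere, and no evidence of a *differential* effect
            verdict = VERDICT_NO_EFFECT
        else:
            posterior = run_chain(
                state.data, slab, config.grid,
                config.spike_slab.with_seed(int(mcmc_rng.integers(2**31))),
            )
            final_spec = choose_model(posterior, config.spike_slab)
            if not final_spec.uses_subgroup:
                verdict = VERDICT_NO_EFFECT
                if not safety_stopped:
                    cap = min(
                        d for d in (state.max_dose[0], state.max_dose[1]) if d is not None
                    ) if any(d is not None for d in state.max_dose.values()) else None
                    dose = _recommend(state, config, trial, POOLED, 0, cap, (0, 1))
                    recommended = {0: dose, 1: dose}
            else:
                verdict = VERDICT_EFFECT
                for g in (0, 1):
                    if g not in safety_stopped:
                        recommended[g] = _recommend(
                            state, config, trial, FULL, g, state.max_dose[g], (g,)
                        )

    return TrialResult(
        recommended=recommended,
        verdict=verdict,
        n_patients=dict(state.treated),
        n_dlts=dict(state.dlts),
        stop_reasons=dict(state.status),
        fallbacks=state.fallbacks,
        seed=seed,
    )
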