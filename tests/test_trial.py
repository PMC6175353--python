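"""Trial conduct: escalation, stopping rules, recommendations, invariants."""

import numpy as np
import pytest

import subdose as sd
from subdose.model import POOLED
from subdose.trial import STOP_MAX, STOP_SAFETY, TrialState, advise_next_doses


class _FlatTruth:
    """Constant DLT probability per subgroup, for controlled simulations."""

    def __init__(self, p0: float, p1: float):
        self._p = {0: p0, 1: p1}

    def prob(self, subgroup: int, dose: float) -> float:
        return self._p[subgroup]


class TestAdvice:
    def test_prior_only_advises_start_dose_all_methods(
        self, trial_config, pseudo_data, slab
    ):
        for method in ("baseline", "method1", "method2"):
            config = trial_config(method)
            state = TrialState(data=sd.ToxicityDataset(list(pseudo_data.records)))
            advice = advise_next_doses(state, config, slab, mcmc_seed=1)
            assert advice.doses == {0: 100.0, 1: 100.0}

    def test_no_dlt_path_never_skips_a_dose(self, trial_config, scenarios):
        """Escalation under the chosen prior is paced: on a DLT-free path the
        advised dose never jumps more than one grid level per cohort."""
        config = trial_config("baseline")
        result = sd.run_trial(config, _FlatTruth(0.0, 0.0), seed=0, keep_trajectory=True)
        doses = list(config.grid.doses)
        advised = result.trajectory.groupby("cohort")["dose"].first().tolist()
        assert advised[0] == 100.0
        # every dose first administered exactly one level above the running
        # maximum: escalation reaches the top without skipping a level
        seen_max = 0
        for dose in advised:
            level = doses.index(dose)
            assert level <= seen_max + 1
            seen_max = max(seen_max, level)
        assert seen_max == len(doses) - 1

    def test_method2_forced_pooled_matches_baseline_advice(
        self, trial_config, pseudo_data, grid
    ):
        """With both subgroup terms forced out of the model, the
        spike-and-slab design reduces to the homogeneous baseline."""
        slab0 = sd.derive_slab(pseudo_data, grid, prior_inclusion=(0.0, 0.0))
        config2 = trial_config(
            "method2",
            spike_slab=sd.SpikeSlabConfig(2_000, 200, prior_inclusion=(0.0, 0.0)),
        )
        config_base = trial_config("baseline")
        state = TrialState(data=sd.ToxicityDataset(list(pseudo_data.records)))
        state.treat(0, 100.0, 0)
        state.treat(1, 100.0, 1)
        a2 = advise_next_doses(state, config2, slab0, mcmc_seed=3)
        ab = advise_next_doses(state, config_base)
        assert a2.spec == POOLED
        assert a2.doses == ab.doses


class TestAccuracyStop:
    def _state_with(self, pseudo_data, n_at_dose: int) -> TrialState:
        state = TrialState(data=sd.ToxicityDataset(list(pseudo_data.records)))
        for i in range(n_at_dose):
            state.treat(0, 150.0, 0)
        return state

    def test_requires_minimum_patients_at_advised_dose(
        self, trial_config, pseudo_data, grid
    ):
        config = trial_config("method1", accuracy_stop=True)
        state = self._state_with(pseudo_data, 4)
        fit = sd.fit_model(state.data, POOLED, grid)
        assert not sd.check_accuracy_stop(state, config, 0, fit, 150.0)

    def test_width_bound_is_strict(self, trial_config, pseudo_data, grid):
        config = trial_config("method1", accuracy_stop=True)
        state = self._state_with(pseudo_data, 6)
        fit = sd.fit_model(state.data, POOLED, grid)
        lo, hi = sd.td_interval(fit, config.policy.theta, 0)
        width = hi - lo
        exactly = trial_config(
            "method1", accuracy_stop=True, accuracy_width_bound=width
        )
        assert not sd.check_accuracy_stop(state, exactly, 0, fit, 150.0)
        above = trial_config(
            "method1", accuracy_stop=True, accuracy_width_bound=width + 1e-6
        )
        assert sd.check_accuracy_stop(state, above, 0, fit, 150.0)

    def test_accuracy_stop_shortens_trials(self, trial_config, scenarios):
        """With a width bound the delta-method interval can actually reach,
        the accuracy rule ends trials before the patient cap."""
        config = trial_config(
            "method1", accuracy_stop=True, accuracy_width_bound=150.0
        )
        plain = trial_config("method1")
        n_acc = [
            sd.run_trial(config, scenarios[0], s).total_patients for s in range(10)
        ]
        n_plain = [
            sd.run_trial(plain, scenarios[0], s).total_patients for s in range(10)
        ]
        assert np.mean(n_acc) < np.mean(n_plain)
        assert any(n < 60 for n in n_acc)


class TestRunTrial:
    def test_seed_determinism(self, trial_config, scenarios):
        config = trial_config("method2", spike_slab=sd.SpikeSlabConfig.fast())
        a = sd.run_trial(config, scenarios[2], seed=9)
        b = sd.run_trial(config, scenarios[2], seed=9)
        assert a == b

    @pytest.mark.parametrize("method", ["baseline", "method1", "method2"])
    @pytest.mark.parametrize("scenario_idx", [0, 4, 5])
    def test_trial_invariants(self, trial_config, scenarios, method, scenario_idx):
        """Structural invariants on simulated trials: patient caps respected,
        advised doses on the grid, recommendations never above the subgroup's
        maximum administered dose, stopped subgroups never dosed again."""
        kwargs = (
            {"spike_slab": sd.SpikeSlabConfig.fast()} if method == "method2" else {}
        )
        config = trial_config(method, **kwargs)
        for seed in range(3):
            result = sd.run_trial(
                config, scenarios[scenario_idx], seed, keep_trajectory=True
            )
            assert result.total_patients <= config.max_patients
            for g in (0, 1):
                assert result.n_patients[g] <= config.max_per_subgroup
                sub = result.trajectory[result.trajectory.subgroup == g]
                if len(sub):
                    assert set(sub.dose) <= set(config.grid.doses)
                    if result.recommended[g] is not None:
                        assert result.recommended[g] <= sub.dose.max()
                else:
                    assert result.recommended[g] is None
                # max administered dose nondecreasing over cohorts
                running = sub.groupby("cohort").dose.max().cummax()
                assert (running.diff().dropna() >= 0).all()

    def test_full_enrolment_without_early_stops(self, trial_config):
        """With a tolerable, flat truth and no accuracy rule, exactly the
        maximum number of patients is treated."""
        config = trial_config("method1")
        result = sd.run_trial(config, _FlatTruth(0.1, 0.1), seed=3)
        assert result.total_patients == config.max_patients
        assert result.stop_reasons == {0: STOP_MAX, 1: STOP_MAX}

    def test_intolerable_truth_stops_for_safety(self, trial_config):
        """When every dose is far too toxic in both subgroups the safety rule
        ends the trial early with no recommendation."""
        config = trial_config("method1")
        result = sd.run_trial(config, _FlatTruth(0.8, 0.8), seed=1)
        assert result.stop_reasons[0] == STOP_SAFETY
        assert result.stop_reasons[1] == STOP_SAFETY
        assert result.recommended == {0: None, 1: None}
        assert result.total_patients < config.max_patients

    def test_one_sided_stop_switches_to_survivor_cohorts(
        self, trial_config, scenarios
    ):
        """Scenario with no safe dose in the positive subgroup: the positive
        arm stops for safety, after which cohorts of two come from the
        negative arm, which runs to its cap."""
        config = trial_config("method1")
        hits = 0
        for seed in range(6):
            result = sd.run_trial(config, scenarios[4], seed, keep_trajectory=True)
            if result.stop_reasons[1] == STOP_SAFETY and result.stop_reasons[0] == STOP_MAX:
                hits += 1
                assert result.verdict == 2
                assert result.n_patients[0] == config.max_per_subgroup
                assert result.recommended[1] is None
                # after the positive arm stopped, no further positive patients
                pos = result.trajectory[result.trajectory.subgroup == 1]
                neg = result.trajectory[result.trajectory.subgroup == 0]
                assert neg.cohort.max() > pos.cohort.max()
        assert hits >= 3  # the dominant outcome in this scenario

    def test_baseline_verdict_always_no_effect(self, trial_config, scenarios):
        config = trial_config("baseline")
        for seed in range(4):
            assert sd.run_trial(config, scenarios[3], seed).verdict == 0
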