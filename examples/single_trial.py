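"""Simulate one complete spike-and-slab escalation trial.

Runs the full design (cohorts of two, one patient per subgroup, cap of 60)
under the scenario with a three-dose-level subgroup effect, printing each
cohort's model choice and dosing, then the final verdict and per-subgroup
recommended doses.
"""

import subdose as sd
from subdose.model import POOLED

grid = sd.default_grid()
policy = sd.default_policy()
pooled_fit = sd.fit_model(sd.nicholson_data(), POOLED, grid)
truth = sd.build_scenarios(pooled_fit, grid)[3]  # medium effect, 3 dose levels
print(truth.label)
print("true DLT probabilities, negative:", truth.prob_table(0).round(2))
print("true DLT probabilities, positive:", truth.prob_table(1).round(2))

config = sd.TrialConfig(
    grid=grid,
    policy=policy,
    pseudo=sd.default_pseudo_spec(),
    method="method2",
    spike_slab=sd.SpikeSlabConfig.fast(),
)
result = sd.run_trial(config, truth, seed=7, keep_trajectory=True)

print("\ncohort log (dose per subgroup, DLT outcomes, inclusion probabilities):")
for cohort, block in result.trajectory.groupby("cohort"):
    doses = {int(r.subgroup): f"{r.dose:g}{'*' if r.outcome else ''}" for r in block.itertuples()}
    w2, w3 = block.w2.iloc[0], block.w3.iloc[0]
    ws = f"w2={w2:.2f}  w3={w3:.2f}" if w2 == w2 else "(two-parameter survivor model)"
    print(f"  cohort {cohort:2d}:  neg {doses.get(0, '-'):>5}  pos {doses.get(1, '-'):>5}   {ws}")

print("\n* marks a DLT")
print("verdict:", result.verdict, "(0 none, 1 subgroup effect, 2 defaulted after one-sided stop)")
print("recommended doses:", {g: result.recommended[g] for g in (0, 1)}, "mg/m^2")
print("patients treated:", result.n_patients, " DLTs:", result.n_dlts)
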