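"""Rest-task statistics on a synthetic state-dependent recording.

Channels carry heterogeneous resting timescales that double during the
task state. The analysis recovers (i) longer tau in task windows, (ii)
positive percent change in nearly all channels, and (iii) the negative
correlation between resting tau variability and the rest-to-task change.
"""

import numpy as np

from intflex import stats
from intflex.synthetic import gen_state_recording
from intflex.timescales import windowed_int

rng = np.random.default_rng(0)
n_ch = 40
tau_rest = 0.3 * np.exp(rng.normal(0.0, 0.25, n_ch))

rec = gen_state_recording(
    [("rest", 400.0), ("task", 400.0)],
    {"rest": tau_rest, "task": 2.0 * tau_rest},
    n_channels=n_ch, fs=20.0, seed=1,
)
table = windowed_int(rec)
summary = stats.rest_task_summary(table, "rest", "task")

conv = table[table["converged"]]
effect = stats.compare_groups(
    conv.loc[conv.state == "task", "tau_s"].to_numpy(),
    conv.loc[conv.state == "rest", "tau_s"].to_numpy(),
)
rho, p, df = stats.variability_change_correlation(summary)

print(f"channels with positive tau change: "
      f"{(summary['pct_change'] > 0).mean():.0%}")
print(f"task vs rest rank test: z = {effect.z:.2f}, p = {effect.p:.2g}, "
      f"rank-biserial r = {effect.effect_r:.2f}")
print(f"rest variability vs percent change: Spearman rho({df}) = {rho:.2f}, "
      f"p = {p:.2g}")
print()
print("The negative rho arises because channels with longer (more variable)")
print("resting timescales gain proportionally less from rest to task.")
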