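"""The noncompetitive dual-task variant: PM responses alongside
ongoing responses.

Decoupling the pathways — no lateral inhibition between output units,
separate response thresholds for the ongoing (Left-vs-Right difference)
and PM (absolute activation) responses — simulates instructions to make
an ongoing response on every trial plus an additional PM response on
targets.  A target trial can then record both responses with separate
RTs.  With the competition removed, the mechanisms behind the
intention-superiority effect and the CV ordering no longer apply.
"""

from pmnet import preset, run_dual_task_condition
from pmnet.rt_stats import cv

table = run_dual_task_condition(preset("standard"),
                                n_per_nontarget=2000, n_per_target=4000,
                                seed=31)
targets = table[table.is_target]
nontargets = table[~table.is_target]
both = targets.pm_response & targets.ongoing_rt_cycles.notna()

print(f"targets with a PM response: {100 * targets.pm_response.mean():.1f}% "
      f"(of which {100 * both.sum() / max(targets.pm_response.sum(), 1):.1f}% "
      f"also made the ongoing response)")
print(f"false PM responses on nontargets: "
      f"{100 * nontargets.pm_response.mean():.2f}%")

ongoing_rt = nontargets.ongoing_rt_cycles.dropna().to_numpy(dtype=float)
miss_rt = targets.loc[~targets.pm_response, "ongoing_rt_cycles"] \
    .dropna().to_numpy(dtype=float)
print(f"ongoing RT {ongoing_rt.mean():.1f} cyc (CV {cv(ongoing_rt):.2f});"
      f" PM-miss ongoing RT {miss_rt.mean():.1f} cyc (CV {cv(miss_rt):.2f})")
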