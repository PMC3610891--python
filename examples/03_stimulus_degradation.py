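"""Stimulus degradation: slower ongoing RTs and fewer PM hits at once.

Lowers the stimulus input clamp from 1.0 to 0.9 (degraded perceptual
input) and contrasts the two input levels.  Degradation hurts the
indirect PM pathway (input -> detector -> PM output) more than the
direct ongoing pathway, so a single manipulation simultaneously raises
ongoing RT and lowers the PM hit rate — the opposite covariation from
the monitoring manipulation.  The maintenance cost (vs a no-monitoring
baseline at the same input level) survives degradation.
"""

from pmnet import preset, degradation_experiment

res = degradation_experiment(preset("standard"),
                             degraded_input_activation=0.9,
                             n_per_nontarget=2000, n_per_target=4000,
                             seed=11)
for label in ("standard", "degraded"):
    s = res[label]["summary"]
    eff = res[label]["effects"]
    print(f"{label:<9} input: hit={100 * s.hit_rate:5.1f}%  "
          f"ongoing RT={s.mean_ongoing_rt:5.1f} cyc  "
          f"maintenance cost={eff.maintenance_cost_cycles:4.1f} cyc")
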