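"""Run single trials of the network and watch the response competition.

Builds the 19-unit model with its calibrated standard parameters, runs
one noise-free trial of a nontarget ("A c") and a PM target ("a A"),
and prints the winning response, the RT in processing cycles, and the
peak activation reached by the competing output units.  On the target
trial both the PM output and the correct ongoing output become active
before the threshold is met — the response competition at the heart of
the model.
"""

import numpy as np

from pmnet import preset, run_trial
from pmnet.stimuli import Stimulus
from pmnet.network import standard_geometry

params = preset("standard").replace(noise_sd=0.0)  # deterministic dynamics
geom = standard_geometry()
left, right, pm = geom.output_idx

for label in ("A c", "a A"):
    stim = Stimulus.from_label(label)
    result = run_trial(stim, params, record_trajectory=True)
    traj = result.trajectory
    print(f"stimulus {label!r} (target={stim.is_target}): "
          f"response={result.response.value}, rt={result.rt_cycles} cycles")
    print(f"  peak activations  Left={traj[:, left].max():+.3f}  "
          f"Right={traj[:, right].max():+.3f}  PM={traj[:, pm].max():+.3f}")

# with noise, the same target stimulus sometimes misses
rng = np.random.default_rng(0)
outcomes = [run_trial(Stimulus.from_label("a A"), preset("standard"),
                      rng=rng).response.value for _ in range(20)]
print("20 noisy target trials:", " ".join(outcomes))
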