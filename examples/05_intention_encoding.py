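"""Hebbian encoding of a new intention, and its later deactivation.

The single-detector variant has no hard-wired target knowledge: on
each repetition a random stimulus is encoded by one-shot Hebbian
learning (input->detector weights set to the product of the perturbed
input pattern and the detector activation of 1).  At test, every
trial's input is freshly perturbed; the correlation between encoding
and test input patterns (encoding-retrieval similarity) is higher on
PM hits than misses, because a closer perceptual match sends more
activation through the learned weights.  Afterwards a post-PM block
(monitoring off) probes deactivation: the intact trace still produces
commission errors, halving the weights almost eliminates them, yet
previous targets keep slowing ongoing responses.
"""

from pmnet import preset, EncodingConfig, run_encoding_experiment
from pmnet.intention import deactivation_experiment

params = preset("standard")
res = run_encoding_experiment(params, EncodingConfig(),
                              n_reps=150, n_per_nontarget=25, seed=9)
print(f"hit rate {100 * res['hit_rate']:.1f}%   "
      f"false alarms {100 * res['false_alarm_rate']:.2f}%   "
      f"ongoing accuracy {100 * res['ongoing_accuracy']:.1f}%")
print(f"ongoing RT {res['ongoing_rt']:.1f} cyc vs PM-miss RT "
      f"{res['pm_miss_rt']:.1f} cyc (intention superiority)")
print(f"CV ongoing/miss/hit = {res['cv_ongoing']:.2f}/"
      f"{res['cv_pm_miss']:.2f}/{res['cv_pm_hit']:.2f}")
print(f"encoding-retrieval similarity: hits r={res['similarity_hits']:.3f} "
      f"> misses r={res['similarity_misses']:.3f}")

for decay in (1.0, 0.5):
    d = deactivation_experiment(params, EncodingConfig(), decay,
                                n_reps=150, n_per_nontarget=25, seed=13)
    print(f"post-PM block, weights x{decay}: commission errors "
          f"{100 * d['commission_rate']:.2f}% "
          f"(false alarms {100 * d['false_alarm_rate']:.2f}%), "
          f"previous-target RT {d['previous_target_rt']:.1f} vs "
          f"nontarget {d['nontarget_rt']:.1f} cyc")
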