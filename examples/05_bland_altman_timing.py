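"""Bland-Altman agreement of sensor-derived vs ground-truth completion time.

Correlation alone cannot establish that two timing methods agree; the
Bland-Altman limits of agreement give the interval expected to contain
95 % of their disagreements. Here the 'two methods' are the sensor-derived
sit-to-stand total time and the trial's construction-time ground truth
(standing in for a stopwatch).
"""

import mobilikit as mk
from mobilikit.pipeline import process_position

pairs = []
for seed in range(30):
    trial = mk.simulate_sts(mk.SimulationConfig(seed=200 + seed))
    feats = mk.extract_features(process_position(trial.position_vt), "STS")
    truth_total = float(trial.true_phases.descent_offsets[-1]
                        - trial.true_phases.rise_onsets[0])
    pairs.append((feats.total_time, truth_total))

ba = mk.bland_altman(pairs)
print(f"n pairs            : {ba.n_pairs}")
print(f"mean difference    : {ba.mean_diff:+.3f} s   (systematic timing bias)")
print(f"limits of agreement: [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}] s")
print("95 % of sensor-vs-truth timing disagreements are expected inside the limits.")

ci = mk.summarize_ci([a - b for a, b in pairs])
print(f"bias 95% CI        : [{ci.ci_low:+.3f}, {ci.ci_high:+.3f}] s over n={ci.n}")
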