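"""Extract clinical mobility features from both test types.

The feature set mirrors what clinicians time with a stopwatch, plus the
kinematic maxima only a sensor can provide.
"""

import mobilikit as mk
from mobilikit.pipeline import process_position

for task in ("STS", "TUG"):
    trial = mk.simulate(mk.SimulationConfig(task=task, seed=4))
    kin = process_position(trial.position_vt)
    feats = mk.extract_features(kin, task)
    print(f"--- {task} ---")
    for key, value in feats.as_dict().items():
        if value is not None and key != "task":
            print(f"  {key:24s}: {value:7.3f}" if isinstance(value, float) else f"  {key}: {value}")
    truth_total = float(trial.true_phases.descent_offsets[-1]
                        - trial.true_phases.rise_onsets[0])
    print(f"  ground-truth total time : {truth_total:7.3f}  "
          f"(sensor error {feats.total_time - truth_total:+.3f} s)")
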