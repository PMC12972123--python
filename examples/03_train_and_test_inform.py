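"""Train the unified InFoRM network and test it closed-loop.

One reservoir simultaneously emits the movement goal (recognition), the
muscle activations (inverse function) and the predicted proprioceptive
feedback (forward function).  Training overwrites all output feedback
with noisy targets; at test time only the goal is external and the
efference/afference circulate as output feedback.
"""

import numpy as np

import informrc as rc
from informrc.runner import default_reservoir_configs, default_train_config

dataset = rc.generate_dataset(seed=42)
series = rc.prepare_series(dataset, seed=0)

spec = rc.build_architecture("InFoRM",
                             configs=default_reservoir_configs("InFoRM"))
trained = rc.train_teacher_forced(spec, series.train,
                                  default_train_config("InFoRM"),
                                  params=rc.init_architecture(spec, 42))

for split in ("basic", "morphing"):
    test, mask = series.tests[split][0]
    gw = series.goal_window(test)
    outputs, eval_mask = rc.run_test_closed_loop(
        trained, test.goal, gw, init_prefix_len=int(np.argmax(mask)))
    norm = series.normalizer
    for group in ("efference", "afference"):
        pred = norm.inverse_group(group, outputs[group])
        tgt = norm.inverse_group(group, test.group(group))
        rs = [rc.pearson_r(pred[c], tgt[c], eval_mask)
              for c in range(pred.shape[0])]
        es = [rc.rrmse(pred[c], tgt[c], eval_mask)
              for c in range(pred.shape[0])]
        print(f"{split:9s} {group:9s}: r = {np.mean(rs):.3f}, "
              f"rRMSE = {np.mean(es):.3f}")

print("\nBasic = held-out cycles of trained directions (should be ~perfect);")
print("Morphing = untrained intermediate directions the network interpolates.")
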