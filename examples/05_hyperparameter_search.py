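"""Bayesian hyperparameter search for one architecture.

Minimises the validation rRMSE (held-out cycles 7-8 of the trained
directions) with a Gaussian-process surrogate and expected improvement.
The two efficiency-relevant optima — total neuron count and number of
training iterations — are reported alongside the best configuration.
A small budget keeps this illustrative; raise it for real use.
"""

import informrc as rc
from informrc.runner import Param

cfg = rc.ExperimentConfig(data_seed=42)
series = rc.prepare_experiment_series(cfg)

space = {
    "n_iterations": Param(1, 20, integer=True),
    "spectral_radius": Param(0.5, 1.2),
    "noise_scale": Param(1e-3, 0.1, log=True),
}
res = rc.hyperopt("InFoRM", series, cfg, space=space, budget=10,
                  n_instances=2, seed=0)

print(f"best validation rRMSE: {res['best_objective']:.4f}")
print(f"best parameters      : {res['best_params']}")
print(f"selected n_iterations: {res['n_iterations']}")
print("\ntrace (one row per evaluation; the incumbent never worsens):")
print(res["trace"][["n_iterations", "spectral_radius", "noise_scale",
                    "objective"]].round(4).to_string(index=False))
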