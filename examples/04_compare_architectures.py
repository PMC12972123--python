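"""Matched-seed comparison of the five architectures (reduced size).

Runs the analogue experiment at a reduced instance count so it finishes
in about two minutes: every architecture is trained and tested with the
same instance seeds, then contrasted with paired signed-rank tests under
Holm correction.  For the full ten-seed experiment use
``inform-rc reproduce`` or ``scripts/acceptance.py``.
"""

import informrc as rc

cfg = rc.ExperimentConfig(n_instances=5, data_seed=42)
out = rc.run_experiment(cfg, splits=("basic", "morphing"))

print(out["architecture_summary"].to_string(index=False))
print()
rep = out["comparison"]
key = rep[(rep.split == "morphing") & (rep.metric == "correlation")
          & (rep.arch_a == "Control") & (rep.arch_b == "InFoRM")]
print(key.to_string(index=False))
print("\n'better' names the architecture with the higher morphing correlation;")
print("p_adjusted is the Holm-corrected paired signed-rank p-value.")
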