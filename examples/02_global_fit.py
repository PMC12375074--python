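"""Global chi-square fit of a multi-experiment synthetic study.

Generates the slow-exchange study (CEST at two saturation fields, EXSY,
inversion recovery and a 1D spectrum) at the published generating values
p_E = 0.26, k_ex = 35 /s, then fits all datasets simultaneously starting 8%
away from the truth.
"""

import numpy as np

import loopex.synth as sy
from loopex import fit_global

preset = sy.preset_exo10_apo()
data = sy.generate_dataset(preset, seed=11)
rng = np.random.default_rng(5)
start = {k: v * (1 + rng.uniform(-0.08, 0.08)) for k, v in preset.truth.items()}

fit = fit_global(data, preset.graph(), start=start)
print(f"chi2/dof = {fit.reduced_chi2:.3f} over {fit.n_points} points "
      f"({fit.n_free} free parameters)\n")
print(f"{'parameter':<12}{'true':>10}{'recovered':>12}")
for name in ("pE_exo10", "kex_exo10", "omega_E", "R1_exo10", "R2_exo10"):
    print(f"{name:<12}{preset.truth[name]:>10.4g}{fit.params[name]:>12.4g}")
print("\nThe closed-state population is pinned by the EXSY auto/cross "
      "ratios; the rate by the cross-peak build-up time.")
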