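"""Double-Lorentzian deconvolution of an overlapped 19F resonance.

A main resonance with a 25%-population shoulder is deconvoluted; the fixed
peak shapes are then used to extract per-component R1 rates from an
inversion-recovery series.
"""

import numpy as np

from loopex import (IRSchedule, SpectrumGrid, deconvolve_double_lorentzian,
                    deconvolve_ir_fixed)
from loopex.deconvolution import _lorentzian

x = np.linspace(-1000, 1000, 1501)
rng = np.random.default_rng(1)
clean = (_lorentzian(x, -200.0, 40.0, 0.75 / (np.pi * 40.0))
         + _lorentzian(x, 300.0, 80.0, 0.25 / (np.pi * 80.0)))
spec = SpectrumGrid(offsets=x,
                    intensities=clean + rng.normal(0, clean.max() / 50, x.size))

fit = deconvolve_double_lorentzian(spec)
for c in fit.components:
    print(f"component at {c.center:+7.1f} Hz, HWHH {c.hwhm:5.1f} Hz, "
          f"area fraction {c.area_fraction:.3f}")

delays = np.array([0.001, 0.05, 0.1, 0.25, 0.5, 0.8, 1.5, 3, 5])
spectra = [clean * (1 - 2 * np.exp(-0.9 * t)) for t in delays]
rates = deconvolve_ir_fixed(spectra, x, fit.components,
                            IRSchedule(delays=delays))
for c, r in zip(fit.components, rates):
    print(f"component at {c.center:+7.1f} Hz: R1 = {r.R1:.3f} /s")
print("Both components recover the generating R1 of 0.9 /s: with shapes "
      "fixed, only per-delay amplitudes are fit.")
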