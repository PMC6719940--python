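"""Fit a single-pole Debye model to sampled complex permittivity.

Synthesizes permittivity samples for a grey-matter-like medium over the
0.1--3 GHz band, fits a Debye model over the 0.5--1.5 GHz operating band,
and compares the recovered parameters with the truth.
"""

import numpy as np

from mwdetect import DebyeModel, eval_debye, fit_debye

truth = DebyeModel(eps_static=55.0, eps_inf=12.0, sigma=0.9, tau=1.2e-11)
freqs = np.linspace(0.1e9, 3.0e9, 80)

eps = eval_debye(truth, freqs)
fitted, rms = fit_debye(list(zip(freqs, eps)))

print(f"{'parameter':>12} {'truth':>10} {'fitted':>10}")
for name in ("eps_static", "eps_inf", "sigma", "tau"):
    t, f = getattr(truth, name), getattr(fitted, name)
    print(f"{name:>12} {t:10.4g} {f:10.4g}")
print(f"in-band rms modulus error: {rms:.3e}")

# the e^{+j omega t} convention makes lossy permittivity Im(eps) <= 0
assert np.all(eval_debye(fitted, freqs).imag <= 0.0)
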