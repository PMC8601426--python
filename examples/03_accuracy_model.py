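"""The exponential accuracy model and its fit.

Reconstruction accuracy rises with the number of contacts per bead x as
accuracy(x) = (1 - A exp(-x / beta)) * A_max. This script evaluates the
model at its fitted constants (A = 0.642, beta = 0.239, A_max = 93.7),
then refits the three constants from noisy synthetic points — the same
way a new accuracy curve measured with this package would be summarized.
"""

import numpy as np

from chromdpd import expected_accuracy, fit_accuracy_curve, imj_random_baseline

print(f"random-baseline IMJ (Monte Carlo): "
      f"{imj_random_baseline(500, reps=5, seed=0):.4f}  "
      f"(analytic sqrt(1/7) = {np.sqrt(1/7):.4f})")

for x in (0.0, 0.1, 0.3, 1.0, 3.0):
    print(f"x = {x:4.1f} contacts per bead -> expected accuracy "
          f"{expected_accuracy(x):5.1f}%")

rng = np.random.default_rng(1)
x = np.linspace(0.02, 2.0, 25)
noisy = expected_accuracy(x) + rng.normal(scale=1.5, size=x.size)
A, beta, a_max = fit_accuracy_curve(x, noisy)
print(f"refit from noisy points: A = {A:.3f}, beta = {beta:.3f}, "
      f"A_max = {a_max:.1f}%")
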