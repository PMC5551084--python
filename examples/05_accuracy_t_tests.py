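"""Accuracy testing against a reference surface: one-sample t-tests.

Emulates the accuracy protocol for an artificial reef of known structure:
repeated in-water measurements of SR are compared to the reference SR with a
two-tailed one-sample t-test, at each link size. In-water photogrammetry
systematically under-resolves fine relief, so measured SR sits below the
reference.
"""

import numpy as np

from reefrugosity import one_sample_t

rng = np.random.default_rng(5)

# reference SR by link size, and an under-resolving in-water measurement
reference = {0.025: 1.63, 0.05: 1.59, 0.10: 1.48, 0.25: 1.20}
shortfall = 0.12  # fraction of relief-above-flat lost in water

print("link size   ref SR   measured mean   t      p")
for link, ref in reference.items():
    measured = ref - shortfall * (ref - 1.0) + rng.normal(0, 0.03, 8)
    res = one_sample_t(measured, ref)
    print(f"{100 * link:7.1f} cm  {ref:6.3f}   {measured.mean():8.3f}   "
          f"{res.t:+6.2f}  {res.p:.2e}")
print("\nNegative t throughout: the in-water estimate underestimates the")
print("reference at every scale, and 8 repeats are enough to make the")
print("offset statistically unambiguous.")
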