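"""Multiscale rugosity of a synthetic reef-like surface.

Builds a fractal heightfield (12 m site, 2.5 cm resolution), fits the
site-level reference plane, cuts 2 x 2 m virtual quadrats, and computes the
surface rugosity index SR at link sizes from 2.5 to 25 cm. SR = 1 means flat;
coarser link sizes smooth relief, so SR declines with link size.
"""

import numpy as np

from reefrugosity import SurfaceSpec, gen_surface, multiscale_sr

hf, _ = gen_surface(
    SurfaceSpec("spectral_fractal", extent=12.0, cell_size=0.025,
                amplitude=0.10, spectral_exponent=3.0, seed=42)
)
table = multiscale_sr(hf)

print("per-quadrat SR by link size (first quadrats):")
wide = table.pivot(index="quadrat_id", columns="link_size_m", values="SR")
print(wide.head(6).round(4))
print()
means = wide.mean(axis=0)
print("site-mean SR by link size:")
for link, sr in means.items():
    print(f"  {100 * link:5.1f} cm  SR = {sr:.4f}")
print()
print("The monotone decline with link size mirrors what chain-and-tape")
print("surveys see with longer chain links: fine relief stops counting.")
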