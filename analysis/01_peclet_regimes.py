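#!/usr/bin/env python
"""Péclet-number regime analysis: passive diffusion vs actuated rapid release.

Compares the convective and diffusive transport rates over a representative
L = 1 mm delivery length (the scale of membrane/tissue deflection) using the
free-fluid insulin diffusivity D = 855 μm²/s.  Passive transport is driven by
interstitial flow (0.1–2 μm/s); actuation drives ~0.06 mm/s flow adjacent to
the membrane.  Writes results/peclet_regimes.csv.
"""

from pathlib import Path

import pandas as pd

from captrans.drug_transport import peclet

OUT = Path(__file__).resolve().parents[1] / "results"

L = 1e-3          # m
D = 855e-12       # m²/s

rows = []
for label, u in [
    ("interstitial_low", 0.1e-6),
    ("interstitial_high", 2e-6),
    ("actuated_rapid_release", 0.06e-3),
]:
    rows.append({"scenario": label, "u_m_per_s": u, "peclet": peclet(u, L, D)})

df = pd.DataFrame(rows)
OUT.mkdir(exist_ok=True)
df.to_csv(OUT / "peclet_regimes.csv", index=False)
print(df.to_string(index=False))
print(
    "\nPassive transport sits at Pe ~ 2.3 (diffusion-dominated even at the "
    "fastest interstitial flow); a single actuation cycle raises Pe to ~70, "
    "firmly convection-dominated."
)
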