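# captrans

Transport modelling and quantitative analysis for drug delivery across the
**fibrous capsule (FC)** — the dense collagenous layer the foreign body
response deposits around an implanted drug reservoir.  The package targets
researchers studying implantable delivery devices whose membrane can be
pneumatically actuated: it quantifies how much the capsule throttles passive
diffusion, how much on-demand convective actuation recovers, and how both are
measured in vivo and ex vivo.

Four pillars, each a library module with synthetic ground-truth generators:

1. **Transport model** (`model_config`, `porous_flow`, `drug_transport`) — a
   2D three-domain model (reservoir / capsule / outer fluid).  Flow under an
   actuation pressure pulse obeys the penalized Stokes–Brinkman equations

   (μ/ε) ∇²**u** − (μ/k) **u** − ∇p = 0, ∇·**u** = 0,

   with capsule permeability k = 8.9·10⁻¹⁶ m² and porosity ε = 0.8; drug
   concentration obeys the transient advection–diffusion equation
   ∂c/∂t = ∇·(D∇c) − **u**·∇c with D = 855 μm²/s in free fluid and
   50 μm²/s in the capsule.
2. **Péclet regime analysis** (`drug_transport.peclet`) — Pe = uL/D comparing
   convective and diffusive rates over a representative L = 1 mm.
3. **ITT pharmacodynamics** (`itt_analysis`) — insulin-tolerance-test metrics
   from blood-glucose series: maximum % drop below baseline, interpolated
   time to a 30% drop (censored at 120 min), area under the %-of-baseline
   curve, cumulative incidence, and pooled t-tests with Levene's check and
   Bonferroni correction (α/m).
4. **Capsule quantification** (`capsule_quant`) — stereological point
   counting, unbiased counting-frame vessel density with the forbidden-line
   rule, structure-tensor collagen coherency (λ₁−λ₂)/(λ₁+λ₂), wall thickness
   of segmented capsule bands, and background-subtracted radiodensity.

`synthetic_data` generates seeded inputs with known ground truth for every
stage; `cli_io` + the `captrans` CLI handle configuration, tabular/image IO
and run manifests.  The `analysis/` directory contains the numbered study
drivers (simulation → actuation → ITT → quantification) that write their
tables under `results/`.

## Worked example

Passive release vs capsule thickness, then one actuation cycle:

```python
from captrans import TransportParams, peclet
from captrans.scenarios import desk_release

for th in (50, 100, 200):
    curve = desk_release(th, n_cycles=0, t_end=200.0)
    print(th, round(100 * curve.released_at(200.0), 1))

rr = desk_release(100, n_cycles=1, t_end=200.0)
passive = desk_release(100, n_cycles=0, t_end=200.0)
print("RR fold:", round(rr.outside_at(200.0) / passive.outside_at(200.0), 2))
print("Pe passive:", round(peclet(2e-6, 1e-3, 855e-12), 2))
print("Pe actuated:", round(peclet(0.06e-3, 1e-3, 855e-12), 2))
```

prints

```
50 34.2
100 27.2
200 25.1
RR fold: 1.49
Pe passive: 2.34
Pe actuated: 70.18
```

i.e. after 200 s a 50 μm capsule has let 34.2% of the dose out of the
reservoir but a 200 μm capsule only 25.1%; a single 2 psi actuation cycle
moves ~1.5× more drug past a 100 μm capsule than diffusion alone (five
cycles ~4.6×); and the Péclet number jumps from ~2.3 (diffusion-dominated)
to ~70 (convection-dominated) under actuation.

The same pipeline end-to-end on synthetic glucose data:

```bash
captrans synth bg --seed 3 --out out/
captrans itt --in out/bg_table.csv --drop 30 --out out/metrics.csv
captrans report --in out/metrics.csv
```

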