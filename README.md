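# chitinmech

Single-molecule elasticity and conformation analysis for pH-responsive
polysaccharides such as chitin.

When a single chitin chain is stretched between an AFM tip and a substrate,
its force–extension (F–E) curve encodes how strongly the chain is hydrated:
water (or hydronium) molecules bridge adjacent saccharide rings and shorten
the effective unit length, and pulling the chain out of the bridged state
costs a per-unit free energy ΔG. This package implements the quantitative
machinery for that analysis — a two-state freely-jointed-chain elasticity
model with fitting, curve normalization, and complementary conformational
metrics for solvated-chain configurations — for researchers analysing
single-molecule force spectroscopy (SMFS) and simulation data of
polysaccharides.

## The model

The entropic backbone is the freely jointed chain (FJC): the fractional
extension at force *F* is the Langevin function

    z_FJC(F) = [L(F)/L0] · [coth(F·l_k/k_BT) − k_BT/(F·l_k)]

with Kuhn length *l*ₖ = 0.514 nm for chitin (the backbone is inextensible by
default, L(F) = L0, with an optional linear modulus). Each saccharide unit
additionally occupies one of two states: a short, water-bridged state of
length *l*ᵤ = 0.45 nm or a long, force-stretched state *l*_f = 0.54 nm. With
ΔL = *l*_f − *l*ᵤ and the per-unit free-energy gap ΔG (in k_BT), the
population-averaged unit length follows Fermi weights,

    l(F) = l_u / (1 + e^{(F·ΔL − ΔG·k_BT)/k_BT}) + l_f / (1 + e^{(ΔG·k_BT − F·ΔL)/k_BT})

and the two-state FJC (TSQM-FJC) extension is z_TS(F) = [l(F)/l_u]·z_FJC(F).
The transition force ΔG·k_BT/ΔL marks the shoulder-like plateau seen in
F–E curves of hydrated chains. Curves are normalized by their extension at
1500 pN (where elasticity is backbone-dominated), so the contour length
cancels and ΔG (and optionally *l*_f) can be fitted across an ensemble.

Conformation metrics: mass-weighted radius of gyration R_g, end-to-end
distance, and the characteristic viscosity η = (10π·N_A/3)·R_g³·ρ/M, whose
ratio between conditions tracks chain spreading vs collapse. Hydrogen bonds
are detected geometrically (donor–acceptor ≤ 3.5 Å, D–H···A ≥ 130°) and
classified as intramolecular (within the chain) or intermolecular
(chain–water/ion).

Because no raw AFM or trajectory data are distributed, a seeded synthetic
generator produces both retraction curves (adhesion spike, two-state elastic
rise, Gaussian force noise, abrupt detachment) and solvated chain frames with
controllable compactness and an exact number of water bridges.

## Worked example

Run the end-to-end pipeline on synthetic data (the built-in default
configuration: three aqueous environments with 20 noisy curves each, plus
solvated-chain frame series for three morphology conditions):

```
chitinmech reproduce --seed 1 --outdir demo/out
```

Output (fit and metrics sections; runs in ~2 s):

```
DI: dG = 1.5144 kBT/unit = 3.7861 kJ/(mol·unit), l_f = 0.5391 nm, rms = 4.75e-03
pH3: dG = 5.5244 kBT/unit = 13.8110 kJ/(mol·unit), l_f = 0.5401 nm, rms = 3.72e-03
pH5: dG = 3.4339 kBT/unit = 8.5848 kJ/(mol·unit), l_f = 0.5407 nm, rms = 4.72e-03
...
          pH5           pH3   -5.226190             62
pH11: Rg = 5.53 ± 0.36 Å, H-bonds intra/inter = 3.0/4.0
pH3: Rg = 11.63 ± 0.34 Å, H-bonds intra/inter = 1.0/16.2
water: Rg = 6.53 ± 0.29 Å, H-bonds intra/inter = 2.0/8.0
normalized eta [pH11] = 0.402
normalized eta [pH3] = 2.151
normalized eta [water] = 1.000
```

The ensembles were generated with ΔG = 1.50, 3.412 and 5.53 k_BT/unit for
DI water, pH 5 and pH 3; at σ = 10 pN force noise the fits recover those
values to within ~1% (3.79, 8.58 and 13.81 kJ/(mol·unit)), and the fitted
pH 5 energy is 62% of the pH 3 value (comparison table row shown). The
frame metrics show the conformational side of the same story: the strongly
hydrated acidic chain is spread (large R_g, chain–water hydrogen bonds
dominate at 16:1, high normalized viscosity), while the alkaline chain is
collapsed (small R_g, internal hydrogen bonds catch up, low viscosity).

The same steps are available as library calls:

```python
from chitinmech import (SyntheticCurveSpec, TwoStateParameters, generate_fec,
                        normalize_curve, segment_curve, fit_tsqm_fjc)

spec = SyntheticCurveSpec(params=TwoStateParameters(bridge_energy=5.53),
                          force_noise=0.0, n_curves=5, seed=2)
norms = [normalize_curve(c, segment_curve(c)) for c in generate_fec(spec)]
result = fit_tsqm_fjc(norms)
print(result.bridge_energy_kbt)     # 5.5192 (generating value 5.53)
print(result.bridge_energy_kj_mol)  # 13.798
```

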