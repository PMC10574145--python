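# Methods

## Two-state chain elasticity

The elasticity layer models a 1,4-linked polysaccharide stretched along its
contour. The entropic response is the freely jointed chain, z_FJC(F) =
[L(F)/L0]·[coth(x) − 1/x] with x = F·l_k/k_BT. On top of it, every
saccharide unit is a two-level system: a short state of length l_u
(stabilised by a water bridge between adjacent rings, free energy ΔG per
unit below the long state at zero force) and a long state l_f reached under
tension. Force tilts the balance through the mechanical work F·ΔL,
ΔL = l_f − l_u, giving Fermi-weight populations and the population-averaged
unit length l(F) ∈ (l_u, l_f). The two-state extension is
z_TS(F) = [l(F)/l_u]·z_FJC(F), measured relative to the zero-force contour
length N·l_u. The force at which the two populations are equal,
F_t = ΔG·k_BT/ΔL, is the analytic location of the shoulder-like plateau in
the F–E curve and is exposed as `transition_force`.

Conventions adopted where more than one transcription is in circulation:
the long state carries the weight that *grows* with force (l(∞) = l_f — a
chain under high force is in its stretched state), and ΔL = l_f − l_u > 0.
With the defaults (l_u = 0.45, l_f = 0.54, l_k = 0.514 nm, T = 298 K) the
transition force for ΔG = 5.53 k_BT/unit lands at 252.8 pN, consistent with
the ~250 pN plateau regime these parameters describe.

### Parameters

| parameter | symbol | default | units | meaning |
|---|---|---|---|---|
| `kuhn_length` | l_k | 0.514 | nm | entropic segment length (chitin) |
| `unit_length_free` | l_u | 0.45 | nm | bridged (short) unit length |
| `unit_length_forced` | l_f | 0.54 | nm | stretched (long) unit length |
| `bridge_energy` | ΔG | — | k_BT/unit | hydration strength readout |
| `temperature` | T | 298 | K | room temperature |
| `backbone_modulus` | K_seg | None | pN | optional linear enthalpic stretch |

The backbone enthalpic factor L(F)/L0 defaults to 1 (inextensible). The
ring-strain elasticity of the glycosidic backbone is a quantum-mechanical
quantity we do not recompute; an optional linear modulus (L(F)/L0 =
1 + F/K_seg) is provided for sensitivity studies, and every shipped
analysis uses the inextensible default.

### Energy units

Per-unit free energies are reported both in k_BT and in kJ/(mol·unit). The
exact thermal energy at 298 K is 4.114 pN·nm = 2.478 kJ/mol, but the
conventional reporting factor in this literature is 2.5 kJ/mol per k_BT
(1.50 k_BT ↔ 3.75 kJ/mol); `convert_energy` therefore uses 2.5 for the
k_BT ↔ kJ/mol axis (configurable through `PhysicalConstants`) and the exact
k_B·T for anything mechanical (pN·nm).

## Curve processing

A retraction trace is segmented into adhesion spike, elastic stretch and
post-rupture baseline. Detachment is the first sample where force falls by
≥ 80% of the running maximum within a 3-sample window (rupture is abrupt);
traces whose peak force stays below 50 pN are flagged unruptured. The
adhesion region is terminated at the force valley between the initial
spike's peak and the global force maximum: the spike decays back onto the
rising elastic curve, so the valley is the spike end. A candidate spike
whose valley stays above half its peak is rejected (a monotone rise has no
adhesion peak). Both thresholds are configurable.

Normalization divides stretch-region extensions by the extension
interpolated at 1500 pN, above which the response is backbone-dominated and
environment-independent; normalized curves of one polymer then overlay
regardless of contour length. Interpolation of extension at a given force
needs a monotone force axis. Extension — the piezo ramp — is the noise-free
coordinate, so retrograde force samples are monotonized by isotonic
regression of force on extension (PAVA; constant-force blocks collapse to
their mean extension). Re-sorting samples by noisy force was rejected: in
the flat low-force region the noise dominates the ordering, which distorts
the master curve and biased recovered ΔG upward by ~2% at σ = 10 pN, while
isotonic monotonization leaves ~0.1%; for noiseless curves the two
coincide. Curves that never reach the reference force cannot be normalized
and are excluded with a warning.

The overlay statistic is the RMS over a force grid of the across-curve
standard deviation of normalized extension. The regression bound used in
the tests (dispersion < 0.05 for 20 replicate curves at σ = 10 pN over a
50–500 pN grid; measured ≈ 0.007) was calibrated once against the generator
and frozen.

## Model fitting

Ensemble fits pool all normalized samples inside a 50–1500 pN window:
below ~50 pN the adhesion region can contaminate, above the reference force
the curves were normalized to agree by construction. The model prediction
is normalized by its own value at the reference force, mirroring the data
treatment, so no contour-length parameter exists. Residuals are taken in
normalized extension at the observed force. The optimizer is bounded
trust-region-reflective least squares (ΔG ∈ [0, 20] k_BT,
l_f ∈ (l_u, 0.7] nm) multi-started from ΔG = 1, 5, 10 k_BT to avoid the
shallow local minima the two-state surface can show; the best converged
start wins and non-convergence is flagged, not raised. Pooled fitting (one
fit per environment) is the default; per-curve fitting is available by
passing single-curve lists. Uncertainty comes from a seeded curve-level
bootstrap (resampling curves with replacement, percentile 95% interval),
which quantifies curve-to-curve variability of the ensemble estimate.

Noiseless round trips recover generating ΔG values to < 0.5% (the residual
error is linear-interpolation discretisation at the normalization point);
at σ = 10 pN with 20 curves recovery is within 5% and bootstrap intervals
cover the generating value in ≥ 90% of seeded repetitions.

## Conformation metrics

R_g is the mass-weighted RMS distance from the selection's centre of mass;
the test suite checks it against the independent pairwise-distance double
sum. End-to-end distance uses the first and last atoms of the solute
molecule in file order (generated chains name their backbone sites `SU`,
and the metrics pipeline restricts to those when present). The
characteristic viscosity is η = (10π·N_A/3)·R_g³·ρ/M with R_g in cm, the
cell density ρ in g/cm³ and M in g/mol. Absolute η values in this
convention are not calibrated intrinsic viscosities; only ratios between
conditions are reported, with the reference condition (pure water)
normalized to exactly 1. From rounded three-significant-figure inputs
(R_g = 7 Å) the alkaline ratio computes to 0.402; an unrounded R_g ≈ 7.12 Å
would give 0.424, so sub-percent agreement on that ratio cannot be expected
from rounded inputs.

## Hydrogen-bond analysis

A hydrogen bond is a (donor, H, acceptor) triple with donor–acceptor
distance ≤ 3.5 Å and D–H···A angle ≥ 130°; donors are N/O atoms with a
covalently bonded hydrogen, acceptors are any N/O, and the acceptor may not
be the donor itself or covalently bonded to it. These are conventional
geometric MD-analysis cutoffs, fully configurable; the tests use
constructed geometries so the conclusions are robust to the exact
criterion. Donor–hydrogen bonding comes from the frame's bond list when
present, otherwise from a 1.3 Å geometric inference; a hydrogen with no
resolvable heavy partner is an error instructing the caller to supply
bonds. Bonds are classified intramolecular (donor and acceptor in the same
solute molecule), intermolecular (chain–water, chain–ion, or two distinct
solute chains) or solvent–solvent (detected but excluded from both
counts). The per-frame counts are averaged over a series and the ratio is
reported as inter/intra, flagged infinite when the intramolecular mean is
zero.

## Synthetic data generator

The generator defines the study conditions for everything the tests and
the acceptance analysis measure.

**Curves.** Each retraction curve samples its unit count N uniformly within
±20% of the nominal 50 (molecular-weight variation between picked-up
chains), builds a uniform extension grid up to the detachment point,
inverts the two-state model for the force at each extension, adds a
triangular adhesion spike (300 pN high, 5 nm wide — only its exclusion
matters, the shape is arbitrary), adds i.i.d. Gaussian force noise
(default σ = 10 pN, a typical AFM force-noise scale), and ends with an
abrupt drop to baseline at 1800 pN (above the 1500 pN reference so curves
are normalizable). Ground-truth segmentation indices, N and the detachment
force are recorded in curve metadata. Everything derives from
`numpy.random.SeedSequence` spawns of the spec seed, so ensembles are
byte-reproducible.

**Frames.** The solute is a freely rotating chain of point saccharide
sites (mass 203 amu, the GlcNAc residue mass; spacing 4.5 Å) whose step
direction diffuses with an angular wiggle that grows with the compactness
parameter κ ∈ [0, 1], inside a confinement sphere that shrinks from
rod-like (κ = 0) to globule-scale ∝ N^{1/3} (κ = 1). Bridging waters are
placed 3.0 Å from two adjacent sites with both hydrogens aimed at them, so
each bridge contributes exactly two intermolecular hydrogen bonds under
the default criteria (the bridge geometry strains the H–O–H angle to
~97°; bulk waters use the rigid 104.5°/0.96 Å geometry). Optional internal
donor groups create exactly one intramolecular bond each. Placements keep
3.6 Å heavy-atom clearance from non-target atoms so no spurious bonds are
constructed, and bulk/ion waters are rejection-sampled with a 2 Å minimum
distance; impossible placements raise after bounded retries.

What the generator does *not* emulate: real force fields or thermodynamic
ensembles, periodic boundary conditions, solvent dynamics, baseline drift
or instrument artefacts other than a constant-shape adhesion spike, and
correlated noise. Passing tests therefore demonstrate that the estimators
recover known ground truth under the stated statistical structure — not
that real AFM or trajectory data meet that structure.

## Pipeline and problem sizes

One YAML config drives simulate → normalize → fit → metrics; reports carry
the config hash and all seeds, and identical config + seed reproduces
identical bytes. Default analysis sizes — 5–20 curves of 250–400 samples
per environment, 3–10 frames of a 10-unit chain with up to a few dozen
waters — were chosen so a full desk reproduction, including the property
suites, completes in seconds on one CPU while leaving the estimators'
statistical behaviour (noise levels, coverage, ordering properties)
clearly resolvable.

## Known limitations

- The two-state model assumes identical, independent units; cooperativity
  between neighbouring bridges is not modelled.
- The backbone enthalpic correction is at most linear; the true ring-strain
  elasticity is nonlinear at the highest forces.
- The alkaline collapsed-globule force plateau (~100 pN unfolding) has no
  functional form here; such curves simply deviate from the two-state fit.
- Hydronium bridging is represented geometrically (role `ion`), with no
  special energetics.
- Absolute characteristic viscosities are convention-bound; only ratios
  are meaningful.
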