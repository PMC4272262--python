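# Methods

This note documents the models, numerical choices and limitations behind
`g4shape`. Units: lengths in Å (CGS internally for transport), viscosity
in poise, masses in Da, s in Svedberg (10⁻¹³ s), relaxation times in ns.

## Sequence properties

Molecular weights use average monomer residue masses (A 313.21, C 289.18,
G 329.21, T 304.2) minus a single 61.96 Da terminal correction — the
free-acid convention vendors report — rounded to 0.1 Da. ε₂₆₀ uses the
classic nearest-neighbor scheme, ε = Σ ε(pair) − Σ ε(internal monomer),
with a Cantor–Warshaw-style parameter table shipped as
`data/nn_extinction_cantor.yaml`; the table path is an argument so an
alternate published set can be swapped in without code changes.

## CD spectra

Raw ellipticity θ (mdeg) becomes molar circular dichroism via
Δε = θ/(32980·c·l) with c in mol strand/L and l in cm. Composite spectra
of multi-domain models are pointwise weighted sums of molar component
spectra on a common 220–340 nm, 1-nm grid (linear resampling); for
all-parallel assemblies the amplitude is proportional to the number of
stacked quartets, so a 3-quartet reference rescales by n_target/n_ref.
The topology classifier requires a positive global maximum in 255–270 nm
plus a negative local minimum in 235–245 nm — windows set around the
canonical 260/240 landmarks of the parallel signature. No public spectra
exist for the exact components, so the bundled component fixtures are
parameterized Gaussians with canonical peak positions and magnitudes;
absolute-amplitude claims are therefore property-based, not numeric.

## Structure builders

Quartets are planar. The in-plane pose of the tetrad guanine is solved
(once, cached) by least squares against the two Hoogsteen bonds to its
90°-rotated neighbor (N1···O6 2.91 Å, N2···N7 2.86 Å) with a soft target
on the glycosidic radius; the solved quartet has the O6 ring at ~2.0 Å
from the axis and a C1′–C1′ diagonal of 16.1 Å. Stacking uses 3.3 Å rise
and 30° twist per quartet step; stacked units meet at a 3.4 Å coaxial
interface with twist continuation; B-form stems use 3.4 Å/36°; extended
single strands count 5.9 Å/nt.

Loops, linkers and flanks have no resolved conformation, so each such
nucleotide is "dressed" as its full heavy-atom complement packed on a
compact 2.5 Å sphere, placed along cubic Bezier arcs that bulge outside
the grooves. A deterministic relaxation pass translates arc residues away
from their worst steric contact until the model satisfies the 1.5 Å
non-bonded cutoff (intra-residue and chain-adjacent pairs are exempt,
being covalently constrained). Everything is deterministic given the
builder parameters; there is no RNG in the builders.

The three candidate folds of the 68-nt promoter strand all carry the full
68-residue complement (36 tetrad guanines in three 3-quartet units for
the quadruplex-only models) so they differ in shape, not material:
stacked (coaxial, 3-nt outside linkers, 2/3-nt flanks), beads-on-a-string
(same units, extended 3-nt linkers, terminal-quartet separation 17.7 Å >
10 Å, no stacking), and the hybrid (parallel unit + 8-bp hairpin +
antiparallel unit threaded on one axis at near-contact 3.5 Å gaps, as an
energy-relaxed flexibly tethered assembly would sit). The "antiparallel"
unit keeps the parallel tetrad core geometry with its loops laid edgewise
over the faces — an envelope-level idealization adequate for transport
properties, not a base-level antiparallel topology.

## Bead-shell hydrodynamics

Each heavy atom is inflated to the hydrated atomic element radius (AER,
default 2.8 Å for quadruplex DNA — fixed a priori, with a
`calibrate_aer` helper that can tune it against a reference structure
with known s). For each mini-bead radius σ the exposed surface of the
union of atom spheres is tiled: dense candidate points (~0.7σ spacing)
per atom sphere, rejection of points inside any neighboring atom, then a
deterministic greedy maximal-independent-set thinning to ~1.7σ spacing,
which guarantees no gaps wider than a bead diameter. The grand 3N×3N
mobility matrix uses the Rotne–Prager–Yamakawa tensor with the standard
overlap correction; the rigid-body 6×6 resistance is assembled by a
Cholesky solve against the six rigid modes, inverted, and referred to the
center of diffusion (coupling symmetrized). Transport properties are
extrapolated linearly in σ over ≥3 shell resolutions to σ→0; bead counts
are capped (default 2500) and a too-fine σ raises a resolution error.

Verification: a smooth sphere (dense atom shell) reproduces Stokes
translation within 1% and rotation within 2% after extrapolation; a
single bead gives 6πησ exactly; ≤10-bead rigid clusters agree with the
Kirkwood double-sum approximation within 5%; s ∝ 1/η and ρ ∝ η exactly.

Derived scalars: s = M(1−v̄ρ_s)/(N_A f) with v̄ = 0.55 cm³/g and solvent
water at 20 °C (η = 1.002 cP, ρ_s = 0.99823 g/cm³); s₂₀,w
standardization multiplies by (η_b/η₂₀,w)·(1−v̄ρ₂₀,w)/(1−v̄ρ_b); the
frictional ratio is reported under both the anhydrous (v̄ only) and
hydrated (v̄ + 0.3 g/g bound water) reference-sphere conventions, flagged
in the result, because the two bracket the conventional single number
usually quoted. Rotational relaxation uses the isotropic average,
ρ = 1/(2·mean(D_r)); the anisotropic eigenvalues are exposed for
diagnostics. The equivalent-sphere baseline is ρ₀ = 3ηMv̄/RT.

With these defaults the stacked fold predicts s₂₀,w ≈ 4.08 S and
ρ ≈ 31 ns; the unstacked chain ≈ 3.33 S and the duplex hybrid ≈ 3.23 S.
The discrimination — only the stacked fold within experimental error of
the measured 4.05 ± 0.04 S — is robust to builder details. The relative
order of the two rejected folds is not: they differ by ~0.1 S, less than
the geometric uncertainty of rigid idealizations of structures that were
originally defined by MD ensembles, so this package treats them as
hydrodynamically degenerate alternates rather than resolving their order.

## Fluorescence

Perrin analysis follows the graphical method: unweighted OLS of
(1/P − 1/3) on T/η (the source method states plain linear regression, so
no weights), P₀ = 1/(intercept + 1/3), and
ρ_ref = 3τ·(intercept/slope)·(η_ref/T_ref), reported at water/20 °C with
the raw slope/intercept echoed so any condition can be recomputed. A
non-positive slope is reported as ρ → ∞ (rigid limit) with a warning.
The relation φ = ρ/3 (Debye) is the default for the correlation time;
the inverted φ = 3ρ convention seen in parts of the polarization
literature is available behind a flag but never used internally.

Frequency-domain lifetimes use the closed-form S/C sums with phase =
atan(S/C) and modulation = √(S²+C²), fit by Levenberg–Marquardt with the
standard instrument weights (σ_phase = 0.2°, σ_mod = 0.004, both
configurable); two-component fits parameterize the fraction through a
logit to stay in (0,1), sort lifetimes ascending, and warn when the
components collapse (non-identifiable).

The bundled sucrose viscosity table (0–60 °C × 0–40%) is a smooth
handbook-anchored parameterization: the water column follows the
standard log₁₀ temperature correlation anchored at 1.002 cP/20 °C, and
the relative viscosity ln r = (0.02092 w + 0.000612 w²)(1 + 0.006(20−T))
is anchored at the 20% (1.945 cP) and 40% (6.16 cP) handbook values at
20 °C. Anchor agreement is ~2% across the table; `sucrose_viscosity`
interpolates bilinearly and refuses extrapolation.

## Synthetic data

Generators emulate the measurement designs: Perrin series on the 5–39 °C
grid at 2 °C steps in 20% sucrose (18 points) with multiplicative
Gaussian P noise (CV 2% default); defaults ρ = 30.9 ns, P₀ = 0.40,
τ = 2.0 ns — the large-complex regime. Lifetime curves are generated on
a 12-point log-spaced 10–200 MHz grid with 0.2°/0.004 Gaussian noise
(defaults τ = 1.5/4.5 ns, f = 0.4/0.6). CD mixtures are weighted sums of
the Gaussian component fixtures plus wavelength-independent noise. Jitter
ensembles displace loop/linker/flank atoms only (quartet and duplex cores
stay rigid), repair grazing contacts with the builders' deterministic
relaxation, and reject grossly distorted draws (clash count above 5% of
movable atoms); >50% rejection raises a parameter error. All generators
are seed-deterministic and echo their ground truth.

What the synthetic data do not emulate: instrument drift and wavelength-
dependent CD noise, dye photophysics and binding heterogeneity, true MD
conformational sampling (the jitter ensemble has no energetics), and
inter-molecular aggregation. Passing recovery tests therefore demonstrate
estimator correctness under the assumed error model, not robustness to
real-instrument systematics.

A note on attainable Perrin precision: at the study conditions the
T/η lever arm is modest, and with 2% P noise the OLS slope carries a
~13% median relative error onto ρ for a 31-ns complex with a 2-ns probe
lifetime (scanning τ up to 6 ns still leaves >6%). This matches the
±4.1 ns uncertainty quoted for the 30.9 ns measurement — the simulation
reproduces the information content of the experiment; sub-5% recovery is
not achievable in this design, only P₀ reaches ~1% precision.

## Problem sizes

Default shell ladders use σ = (2.5, 2.0, 1.6) Å (≈250–1000 mini-beads for
the 68-mer models, seconds per structure) and the ensemble demonstration
uses 8 snapshots — sizes chosen so the full pipeline runs interactively
on a laptop while the σ→0 extrapolation stays in its linear regime;
finer ladders and larger ensembles only tighten the same estimates.

## Known limitations

Rigid-body hydrodynamics only (no flexibility corrections); no
electrostatic/primary-charge effects; loop geometry is an envelope-level
idealization; the antiparallel unit is topology-labelled, not
base-accurate; CD component amplitudes are canonical fixtures, not
measured spectra; no Lamm-equation inversion (forward prediction and
standardization only); no melting analysis.
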