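# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Frame model and bead conventions

All analyses operate on `MembraneFrame` objects: one headgroup bead per
lipid — the phosphodiester PO4 bead for the six phospholipid/sphingomyelin
types, the hydroxy bead for cholesterol — plus backbone beads for any
protein dimers, in Å, with x/y wrapped into the half-open box `[0, L)`.
The bilayer midplane is defined per frame as the mean z of all *phosphate*
beads (cholesterol excluded, matching the phosphate-centric height
analyses) and shifted to z = 0; recentering is idempotent.  Leaflets are
assigned by the sign of the headgroup z.  Because deformations observed in
this class of systems stay well inside the ±20 Å leaflet offsets, the sign
rule is unambiguous; labels persist across frames unless a bead crosses
the midplane by more than 5 Å, which keeps thermal grazers stable while
registering genuine flips.  Graph- or normal-based leaflet detection was
deliberately not used: it costs more and adds nothing in this regime.

For per-protein analyses, lipids are compared to protein beads with the
3-D minimum-image distance to the *nearest* bead — the standard annular
shell convention — and the protein "center" is the xy centroid of its
backbone beads per frame.

## Synthetic generator

The generator's purpose is recoverability: every downstream estimator has
a planted answer.

**Undulations.**  Lipids sit on a near-square lattice (default 1024 per
leaflet on a 256 × 256 Å box, ≈ 64 Å² per lipid, the typical
coarse-grained area density) with uniform jitter of half a lattice spacing
— enough to kill the Bragg peaks of a perfect lattice while keeping the
density exactly uniform.  Each frame draws independent complex Fourier
coefficients with variance

    ⟨|h_q|²⟩ = kB T / (A (K q⁴ + σ q²)),

K in kBT (default 20, a typical fluid-membrane stiffness), σ in kBT/Å²
(default 0: tensionless ensemble), and evaluates the real field at the
lipid positions.  Modes are truncated at 0.3 × min(L)/spacing per axis,
comfortably below the sampling Nyquist of the lattice.  Both leaflets ride
the same field at z = ±20 Å + h(x, y): a bending undulation displaces the
leaflets together.  Frames are statistically independent rather than
time-correlated — equilibrium spectrum estimation does not need dynamics,
and independence sharpens every estimator's convergence.  For the same
reason each frame re-permutes the lattice-site assignment: consecutive
stored snapshots represent times long enough apart that lateral diffusion
has fully remixed the lipids, which is what makes annular-composition
statistics average correctly over frames.

**Composition.**  Default molar fractions POPC 0.27, POPE 0.13, POPG 0.04,
POPS 0.17, POPI 0.10, DPSM 0.12, CHOL 0.17 — the HEK-cell-like mixture of
the study systems — drawn multinomially once per system.

**Deformation templates.**  The elevation/depression pattern a C2 dimer
imprints on the membrane is not parameterized anywhere in the literature
this package follows; `DeformationTemplate` is an explicit invention: in
footprint-local polar coordinates the outer leaflet gains

    A · cos(m (φ − θ)) · exp(−(r − r0)²/(2 w²)) · exp(−max(0, r − r0)/λ)

with angular order m = 2 (two-fold symmetry), a Gaussian ring at r0 and an
exponential tail of decay length λ; the inner leaflet receives the
mirrored (sign-flipped) field, the simplest C2-consistent choice given
that both leaflets show similar patterns.  Superposition over templates is
exactly linear.  Lipids inside a footprint radius are *displaced*, not
deleted: the protein occupies that area, so they re-enter the bulk at
uniform positions outside every footprint at the flat leaflet level.  This
keeps the lipid count constant (required by the fixed-shape HDF5 layout
and by mass conservation) at the cost of a small dilution of undulation
power — the displaced few percent of lipids carry no local height signal —
which is identical across systems being compared and therefore cancels in
scaled moduli.

**Planted enrichment.**  Inside the contact cutoff of a footprint's beads,
lipid types are redrawn so the *realized* depletion–enrichment index
equals the target in expectation.  Planting a local fraction f shifts the
bulk fraction itself (the annulus is part of the membrane), so the naive
f = e·b undershoots; the exact correction used is

    f = e b (N − n) / (N − e n)

for target index e, bulk fraction b, annulus size n and total N, applied
per frame with that frame's n.  Types not named in the target share the
leftover probability in proportion to their bulk fractions.  Infeasible
targets (local fraction above 1, or jointly above 1) are rejected with a
message.

**Rotating dimers.**  `AngularPotential` holds U(θ₁, θ₂) in kBT on a
periodic grid with bilinear interpolation; `sample_rotating_dimers` runs
Metropolis Monte Carlo with Gaussian proposals (default step 20°, warning
outside the 0.1–0.9 acceptance window) and is bitwise reproducible for a
fixed seed.

**Orientation-dependent stiffness (interference suite).**  A static
cos(2φ) deformation pattern cannot by itself reproduce the empirically
observed ordering of membrane stiffness across dimer-pair orientations:
the patterns at θ and θ + 90° are global sign flips of each other, hence
spectral twins, so no power-spectrum analysis can order them the way the
phenomenon demands.  The coupling of protein-imprinted deformation to
membrane elasticity is genuine physics that would require solving the
elastic problem with protein boundary conditions — out of scope for a
post-processing package.  The generator therefore *plants* the phenomenon:
`orientation_coupling(θ₁, θ₂)` is a smooth, 180°-periodic, swap- and
mirror-symmetric law with its minima at the matched 45°/45° and 135°/135°
pairs (deformation patterns in line → softest membrane) and its maximum
at 90°/90° (maximal mismatch → stiffest), and the suite draws each
configuration's undulations at K_eff = K₀(1 + λ·coupling) before
superposing the deformation templates and thermal noise.  What the
pipeline is tested on — and all it can honestly be tested on at desk
scale — is *recovering* the planted ordering from raw frames through the
full height-field → spectrum → fixed-slope-fit → scaled-moduli chain.

## Height maps, envelopes, diagnostics

Height maps average headgroup z per 2 × 2 Å bin (the last bin may be
short) over the analysis window.  Bins never visited are missing values,
never zero — a protein footprint must not alias as height 0 — and they
propagate as missing into the thickness map (outer minus inner).  Protein-
occupied bins are flagged separately: a bin is in the footprint mask if
its center lies within 2 Å of the xy projection of any protein bead on
that leaflet's side of the midplane.

Radial envelopes record the per-frame maximum and minimum headgroup z in
concentric rings (default width 5 Å — fine enough to resolve a ~10 nm
decay, coarse enough for occupancy) and then time-average the extremes,
rather than taking extremes over pooled samples; the average of per-frame
extremes reflects the typical instantaneous deformation range and is the
convention matched by the per-frame/then-average wording of the source
procedure.  Rings never populated stay absent (e.g. inner-leaflet rings
inside a footprint).  Note that the max–min width of a thermally
fluctuating membrane grows with ring population (extreme-value
statistics), so "no radial trend" is only expected between rings of
comparable population.

Diagnostics: membrane area is box_x · box_y per frame; z mass profiles
histogram the phosphate and hydroxy beads separately (1 Å bins) and are
scaled so each profile's maximum is 1.  Water beads are not part of the
frame model and are omitted.

## Depletion–enrichment statistics

The contact cutoff is 7 Å (closed bound: a lipid exactly at the cutoff
counts).  Local fractions use the ratio of time-averaged counts; bulk
fractions use every lipid in the membrane, both leaflets — the literal
printed definition, with no exclusion of the annulus from the denominator.
Per-leaflet contact series are also available since the counts are
leaflet-resolved.  The quoted uncertainty is the standard deviation of
per-snapshot indices; the standard error follows by dividing by √(number
of snapshots), which is valid here because frames are independent.  Both
fraction vectors sum to 1 at every time point, and the index is intensive
(invariant under duplicating the membrane).

## Fluctuation spectrum and bending modulus

**Height field.**  Phosphate beads only (cholesterol's hydroxy bead rides
the headgroup region too loosely; DPSM has a phosphodiester bead and is
included).  Lipids within the exclusion radius (default 7 Å; 0 and 14 Å
used for robustness checks) of any protein bead are dropped.  Per leaflet
the fluctuation is z minus that leaflet's mean; the default "undulation"
mode pools both leaflets as-is, because a bending mode displaces both
leaflets together — the mirrored deformation templates, being thickness
perturbations, cancel out of this field, which is exactly the behaviour
wanted when estimating the *bending* modulus.  A "peristaltic" mode
(inner-leaflet sign flipped) is exposed for inspecting thickness modes.
Empty and excluded bins take the field's zero level so the grid stays
regular for the FFT; the estimator errors out if more than half the bins
are unpopulated rather than silently transforming a mostly-imputed field.

**Spectrum.**  Per-mode intensity is defined as A·|FFT(h)/N|², so a
planted sine of amplitude a carries a²A/4 at its mode, Parseval reads
Σ I/A = spatial variance, and the Helfrich–Canham relation holds with no
extra box factor: with K in kBT, I(q) = 1/(K q⁴ + σ q²).  Absolute
intensities under other conventions differ by a constant factor, which
cancels in scaled moduli.  Bin-averaging the field attenuates mode
amplitudes by the sinc window of the bin; this mass-assignment window is
deconvolved per mode by default (disable `window_correction` to study the
raw transform — the Parseval and DFT-oracle tests do).  The zero mode and
the top 10% of wavenumbers (Nyquist-adjacent) are discarded and the rest
radially averaged onto logarithmic shells holding at least 3 modes each —
standard spectral hygiene.  Shell q is the geometric mean of its modes.

**Fit.**  Fixed-slope least squares in log–log space: slope −4 for the
free-undulation branch, −2 for the protrusion branch.  The crossover is
not judged by eye: every shell boundary leaving at least 4 shells per
branch (or no protrusion branch at all) is scanned and the split with the
smallest total squared residual wins, making the regime boundary
deterministic and testable.  Because the two contributions are additive,
shells just below the crossover carry comparable protrusion power and
would bias the undulation intercept; the intercept is therefore computed
from shells at least a factor 2 below the located crossover whenever
enough shells remain.  K in kBT is exp(−intercept); K in joule multiplies
by kB T at the configured temperature (default 310 K, the simulation
temperature of the systems this package targets).  σ is *not* extracted
from the −4 branch (the fixed slope ignores the σq² term); the −2 branch
intercept is reported as a protrusion proxy only.  Monotonically
increasing spectra and spectra with fewer than 4 shells are rejected.
`scale_moduli` divides each K by the maximum within its group, giving the
dimensionless values in (0, 1] used to compare systems.

## Orientation analysis

The dimer angle is atan2 of the protomer-A→B centroid axis projected on
xy, counterclockwise from +x, in [0°, 360°), with the C2-folded label
θ mod 180° alongside — both are first-class outputs, since raw angles are
what a time series shows while the physics is 180°-periodic.  Centroids
(not the inertia tensor) make the operator exactly equivariant under rigid
rotation and robust to internal fluctuations.  Which protomer is called A
flips θ by 180°; the folded angle is unaffected, and the synthetic writer
fixes the labeling so round trips are exact.

The free-energy landscape is G = −ln(P/P_max) in kBT on a periodic
(θ₁, θ₂) histogram (default 5° bins; the bin width must divide 360°), so
min G = 0 and unvisited bins stay masked.  Optional periodic Gaussian
smoothing is off by default and recorded in the output when used — minima
counts must be reproducible, not smoothing-dependent.  Minima are found by
persistence on the 8-connected periodic grid: processing cells in
ascending G with union-find, a basin dies where it first meets a deeper
one, and only basins whose saddle-to-minimum depth reaches the threshold
(default 1 kBT) are reported.  The global basin's depth is measured to the
landscape top, so a threshold above the deepest basin reports nothing.
Plateau and adjacent minima merge automatically.

## Pipeline

A single flat YAML config drives all stages (no workflow engine — this is
a desk-scale tool).  Stages run in dependency order, every table is TSV
with a fixed `%.6g` float format, and the JSON manifest records
parameters, the seed and SHA-256 checksums of all outputs; a rerun with
the same config and inputs is byte-identical.  Warnings (sparse spectrum
grids, sampler acceptance out of range, overlapping footprints) are
logged, never swallowed.

## What the generator does not emulate

* No time correlation: relaxation times, residence times and any kinetic
  quantity are outside what these frames can test.
* No protein internal structure: footprints are rigid placeholder bead
  columns; per-residue contacts are meaningless here.
* Displaced lipids re-enter at the flat leaflet level, slightly diluting
  undulation power in footprint-bearing systems (identical across
  compared systems).
* The orientation–stiffness coupling is planted, not derived (see above);
  passing the interference tests shows the *analysis chain* orders
  effective stiffness correctly, not that the elastic coupling emerges
  from the template model.
* Real force-field specifics (MARTINI energetics, barostat area
  fluctuations) are absent; the area time series of synthetic systems is
  constant by construction.

Passing tests on synthetic data therefore validates the estimators —
their conventions, normalizations and convergence — and the I/O contract
with real trajectory formats; it does not by itself validate any claim
about a particular biological membrane.

## Problem sizes used in the shipped checks

Equipartition recovery uses 256 × 256 Å boxes with 1024 lipids per leaflet
and 1000 frames per stiffness value; exclusion-shell robustness 400
frames; enrichment round trips 128 × 128 Å, 256 lipids per leaflet, 250
frames; the interference suite the full 4 × 4 orientation grid at
400 × 200 Å with 120 frames per configuration; landscape round trips
3–4 × 10⁵ Metropolis steps.  These sizes give each estimator comfortably
more than the precision the assertions require while keeping the whole
suite fast on a single CPU.
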