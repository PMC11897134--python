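# Methods

`phasekit` quantifies how short-peptide solutions partition between three
states — dispersed molecules, liquid condensate droplets formed by
liquid-liquid phase separation, and solid fibers — and fits the
droplet-scale readouts that characterize the liquid state.  This note
documents the models, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical choices that
affect results.

## Structural metrics

**Solvent-accessible surface area (SASA).**  Shrake–Rupley point sampling:
for each atom, test points are placed on the sphere of radius
`r_vdw + probe` (probe 0.14 nm, a water-sized sphere) and the accessible
fraction is the share of points not strictly inside any other atom's
expanded sphere.  The point set is a spherical Fibonacci lattice (default
960 points per atom), chosen over random sampling so results are
bit-stable across runs.  At 960 points the estimate agrees with the
analytic one- and two-sphere areas to better than 2%; this is also the
tolerance to quote for rotation invariance, since rotating a molecule
re-samples its spheres against a fixed lattice.  Translations are exact.
Radii default to Bondi van der Waals values and can be overridden per atom
in the input file.

**Aggregation propensity (AP).**  AP = (total SASA of the initial, fully
dissolved frame) / (mean total SASA of the last `tail_frames` frames), so
compaction gives AP > 1.  The reciprocal, relative SASA (final/initial),
is always reported alongside and `AP × relative_sasa = 1` holds exactly.
The reciprocal orientation is fixed by the equivalence between a relative
SASA of 0.85 and an AP of 1.2 at the condensate boundary; note that the
other published anchor (relative SASA 0.65 ↔ AP 1.6) is not an exact
reciprocal (1/0.65 ≈ 1.54), so 0.85 is the anchor used in tests and the
0.65 endpoint is treated as approximate.

**Clustering degree (CD).**  Two peptides are in contact iff any
inter-peptide heavy-atom distance is strictly below the contact cutoff
(default 0.5 nm — a conventional heavy-atom contact distance; the metric's
definition does not prescribe one, so it is exposed everywhere).  Clusters
are connected components of the contact graph; CD is the largest cluster
size over the number of peptides.  The neighbour-list implementation is
required by tests to reproduce the naive all-pairs definition exactly.

**Hydrogen-bond census.**  Geometric criterion: donor–acceptor distance
< 0.35 nm and donor-side angle < 30° between the D→H and D→A vectors, both
strict.  "Donor–acceptor angle" is construed at the donor (a common
analysis-tool convention); the supplement-angle convention can be obtained
by configuring the cutoffs.  Bonds are counted at most once per (D, H, A)
triple, intermolecular-only by default, and partitioned by the unordered
species pair of the two peptides — the cross-species versus same-species
split is what distinguishes a mixed condensate from a single-species
fiber precursor.  Donors flagged without a bonded hydrogen are skipped
with a logged warning rather than failing the run.

No periodic boundary conditions are applied by default (generated systems
are finite clusters); a minimum-image option exists when a box edge is
recorded.

## Phase classification

Two preset threshold sets on (AP, CD):

| preset | fiber | condensate |
|---|---|---|
| `all_atom_revised` (default) | AP > 1.6 and CD > 0.9 | 1.2 < AP < 1.6 and CD > 0.5 |
| `coarse_grained_cited` | AP > 3 and CD > 0.9 | 1 < AP < 3 and CD > 0.5 |

All inequalities are strict, so boundary values are excluded
deterministically.  The two rule regions do not tile the plane: inputs
failing the condensate lower bounds (AP ≤ 1.2 or CD ≤ 0.5) are
*dispersed*, and uncovered regions (e.g. AP > 1.6 with 0.5 < CD ≤ 0.9, or
metrics exactly on a bound) are labelled *ambiguous* rather than coerced
into a phase — forcing them would fabricate a claim the thresholds do not
make.  Exactly one label is produced for every finite input.

## Droplet imaging

Segmentation is global Otsu thresholding (or a fixed threshold), 8-connected
components, and removal of components below `min_area_px` (default 20).
The partition coefficient is K = F_droplet / F_background with F_droplet
the mean over droplet pixels after a 2-px mask erosion and F_background
the median over pixels outside a 2-px dilated exclusion zone — erosion and
exclusion keep edge blur out of both statistics, the median resists stray
bright pixels.  The background estimator is parameterized (median/mean)
since the definition K = F_droplet/F_background does not fix it.  K is a
ratio, so it is exactly invariant under intensity rescaling.  Otsu
assumes a bimodal image; for exclusion-regime dyes (K < 1, droplets darker
than background) use the fixed-threshold method or a known mask.

## Kinetic fits

**FRAP.**  Reaction-dominant single-exponential model on post-bleach
samples: `I(t) = P − (P − I0)·exp(−(t − t_b)/τ)`, nonlinear least squares
(parameter tolerance 1e-8), initialized from the first/last post-bleach
values and the half-gap crossing time.  Mobile fraction
`(P − I0)/(1 − I0)` clipped to [0, 1]; half-time `τ ln 2`.  Diffusion-model
FRAP and acquisition-bleaching correction are out of scope; traces are
assumed pre-normalized (the generator produces them so).  With zero noise
the fit recovers generator parameters to 1e-6; an immobile trace
(mobile fraction 0) leaves τ unidentifiable and is not a closure case.

**Coalescence.**  `τ = l·(η/γ)` with no intercept, so
`η/γ = Σ(τl)/Σ(l²)`; the standard error comes from residuals (undefined
for one event).  A free-intercept regression is reported as a diagnostic
only.  Only the ratio η/γ (inverse capillary velocity, s·µm⁻¹) is ever
reported — viscosity and interfacial tension are not separable from
coalescence data.

**Apparent rate constants.**  Ordinary least-squares slope of signal vs
time within a window (default: the full trace; the window is a parameter
because published linear fits rarely state one).  An optional
normalization to a completed-reaction plateau makes the slope a per-time
rate of a dimensionless progress variable; the raw slope is then reported
alongside.  Fold enhancement is the ratio of two rate constants, reported
both as the raw ratio and rounded to the nearest integer.

**Pseudo-first-order conversion.**  `f(t) = 1 − exp(−kt)`; one point gives
the closed form `k = −ln(1 − f)/t`, several give a through-origin fit of
`−ln(1 − f)` on `t`.  Fractions must be in [0, 1).

**Turbidity.**  Cycle metrics use the middle 50% of samples in each
half-cycle as the plateau estimate (avoiding transition edges); amplitude
is high-plateau minus low-plateau, reversibility is each amplitude over
the first.  The phase map marks a (pH, NaCl) cell phase-separated iff its
A600 strictly exceeds `blank_mean + 3·blank_sd` (k configurable); missing
cells are an error listing their coordinates.

## Synthetic data

Every generator is a pure function of its arguments and one seed
(bit-identical reruns) and writes its parameters as ground truth, so every
fitter can be validated by closure: zero-noise inputs recover generator
parameters to 1e-6 (nonlinear) or machine precision (linear/closed-form).

**Molecular configurations.**  Each peptide is a rigid 12-atom tripeptide
template — per residue an amide N (donor) with its H, a backbone C, and a
carbonyl O (acceptor) — enough geometry to exercise SASA, contacts and
donor/acceptor roles without a force field.  Dispersed states place
centroids with a minimum separation of contact cutoff + peptide diameter
(no contacts by construction).  Fibrils are straight 1D lattices (default
period 0.48 nm) with identical orientation, laid out so each N–H points at
the carbonyl O of the neighbour below: the H-bond criterion holds between
lattice neighbours by construction.  Droplets are rejection-packed into a
sphere sized from a packing fraction (default 0.4) with an effective
hydrated peptide radius of 0.42 nm and a centroid exclusion of 0.51
peptide diameters; these two constants were set once so that a packed
droplet reads as one connected cluster (CD ≥ 0.9) burying 25–35% of its
dispersed-state surface — i.e. inside the condensate window — across
seeds.  Bench concentrations are not converted to particle numbers;
packing fraction is the generator's concentration knob.  Trajectories are
morphs (linear interpolation of the dispersed start into the end state
plus seeded jitter on interior frames), not dynamics; endpoints exactly
reproduce the single-configuration generators.

**Images.**  Non-overlapping disks of intensity `K_true × background` on a
uniform background (default 80 counts of a 16-bit range), plus clipped
Gaussian noise.  Defaults of 5–30 px radii and ≤ ~20 droplets per
256×256 field are a plausible confocal field; droplet size/number
distributions of real samples are not modelled, nor are point-spread
functions or optics.  SNR here means background over noise-sd (the noiseless
disk mean over background median equals K_true exactly by construction).

**Traces.**  FRAP uses bleach depth 0.45 (photobleaching to 40–50% of the
initial level), exponential recovery as above; coalescence times get
multiplicative Gaussian noise (errors scale with τ); kinetic traces are
`k·t` or `1 − exp(−kt)` plus additive noise; turbidity series alternate
plateaus with a per-cycle amplitude decay factor.

Because the generators realize the model each fitter assumes, passing
recovery tests demonstrates correctness of the estimators, not robustness
to model mismatch (viscoelastic FRAP, non-exponential bleaching, uneven
illumination, aspherical droplets).

## Problem sizes

Defaults were chosen to keep every analysis interactive on one core:
64 peptides × 12 atoms per configuration (SASA ~1 s at 960 points per
atom), 256×256 images, 20–100-point traces, 200-configuration oracle
sweeps at 10–12 peptides.  All scale linearly or near-linearly upward.

## Known limitations

* SASA cost grows as O(atoms × points × neighbours); very dense systems
  with thousands of atoms will want fewer sphere points (the 2% analytic
  tolerance holds down to ~400).
* The classifier encodes fixed literature thresholds; it does not learn
  boundaries or give graded confidence.
* Otsu segmentation fails by design on constant images and can
  mis-threshold when droplets occupy either a vanishing or a dominant
  image fraction; the fixed-threshold path covers those cases.
* The H-bond census is geometric only; no energetic definition is offered.
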