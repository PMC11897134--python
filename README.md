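# phasekit

Quantitative analysis of liquid-liquid phase separation in short-peptide
systems: the metrics that tell a liquid condensate droplet from a solid
fiber, and the droplet-scale statistics that characterize the liquid state.

Short aromatic peptides (e.g. diphenylalanine tripeptides such as FFM and
MFF) readily phase-separate into micron-scale coacervate droplets — but
those droplets are often metastable and collapse into rigid fibers.
Deciding which state a simulated or imaged system is in, and quantifying
how liquid the droplets are, requires a consistent set of estimators.
`phasekit` provides them as a tested Python library for researchers working
on biomolecular condensates, peptide self-assembly, and synthetic cells.

## What it computes

**Structural metrics** (from molecular configurations/trajectories in a
plain-text extended-XYZ dialect):

- *Aggregation propensity* AP = SASA_initial / SASA_final, with SASA from a
  deterministic Shrake–Rupley estimator (probe 0.14 nm, Fibonacci point
  lattice). Compaction ⇒ AP > 1.
- *Clustering degree* CD = (largest contact-connected cluster) / (number of
  peptides), with contacts defined by a heavy-atom distance cutoff (0.5 nm).
- *Hydrogen-bond census* under the geometric criterion d(D···A) < 0.35 nm
  and donor-side angle < 30°, partitioned by peptide species pair.
- *Phase classification*: fibers are AP > 1.6 and CD > 0.9; condensates are
  1.2 < AP < 1.6 and CD > 0.5 (all-atom preset; a coarse-grained preset
  with AP boundaries at 3 is included). Inputs outside both regions are
  dispersed or, in uncovered corners, honestly ambiguous.

**Droplet statistics** (from 16-bit fluorescence images and TSV time series):

- *Partition coefficient* K = F_droplet / F_background from Otsu-segmented
  droplet fields, plus simple enhancement ratios.
- *FRAP*: single-exponential recovery fit giving τ, t½ = τ ln 2, and the
  mobile fraction.
- *Coalescence*: τ = l·(η/γ) through the origin, yielding the inverse
  capillary velocity η/γ (s·µm⁻¹).
- *Reaction kinetics*: apparent rate constants by OLS, fold enhancement
  between conditions, and pseudo-first-order conversion f(t) = 1 − e^(−kt).
- *Turbidity*: per-cycle reversibility ratios and boolean (pH, salt) phase
  maps against a blank threshold.

**Synthetic data** with recorded ground truth for every input class —
dispersed/droplet/fibril configurations built from a rigid 12-atom peptide
template, droplet images with prescribed true K, FRAP/kinetic/coalescence/
turbidity traces — all seeded and bit-reproducible, used throughout the
test suite for parameter-recovery validation.

## Worked example

`examples/classify_end_states.py` generates the three end-states and
classifies them:

```
dispersed  AP =  1.00  CD =  0.02  H-bonds =   0.0 (none)  ->  dispersed
droplet    AP =  1.52  CD =  0.97  H-bonds =   3.0 (FFM-FFM: 2, FFM-MFF: 1)  ->  condensate
fibril     AP =  1.84  CD =  1.00  H-bonds = 189.0 (FFM-FFM: 45, FFM-MFF: 96, MFF-MFF: 48)  ->  fiber
```

The dispersed state buries no surface (AP ≈ 1) and stays unclustered; the
droplet compacts moderately into one connected cluster with few
intermolecular H-bonds (liquid); the fibril compacts strongly, clusters
completely, and is stitched together by an extensive H-bond network.

`examples/partition_coefficient.py` measures K on a synthetic droplet field
with true K = 781 at SNR 10:

```
segmented droplets : 8
F_droplet (mean)   : 62479.9
F_background (med) : 80.0
K measured         : 781   (true 781, error 0.0%)
```

The other examples fit FRAP and coalescence data
(`examples/frap_and_coalescence.py`) and reaction/oxidation/turbidity
readouts (`examples/reaction_and_oxidation.py`), each printing the fitted
parameters next to the generator's ground truth.

A thin CLI mirrors the library for shell pipelines (`phasekit --help`):
`simulate-config`, `simulate-image`, `simulate-trace`, `metrics`,
`classify`, `partition`, `frap-fit`, `coalesce-fit`, `rate-fit`,
`oxidation-fit`, `cycles`, `phase-map`, and `run` (the full
generate → metrics → classify pipeline). Exit codes: 0 success, 2 usage,
3 data error, 4 fit failure.

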