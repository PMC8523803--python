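# Methods

This note documents the scientific and numerical choices in `fibrocv`:
what each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and the known discrepancies.

## Fibrosis quantification

Composition fractions are pixel counts of the three binary masks over the
region of interest; the non-myocyte fraction is their sum
(V_nm = V_e + V_f + V_mf). The ES mask excludes pixels claimed by the
fibroblast/myofibroblast masks, so the identity holds exactly and the
three classes partition the non-myocyte space. Fibrosis of an HF sample
is V_nm minus the donor-group mean V_nm (22.09% in the emulated cohort);
negative values are reported as-is.

Heterogeneity tiles are defined in physical units (default 50 µm),
anchored at the ROI origin, rasterized by nearest-pixel edges, with
incomplete edge tiles dropped; a 1 mm² ROI gives exactly 400 tiles.
σ_intra is the sample SD (n−1) of tile V_nm in percent — a subject-level
estimate from a sample of tiles. Tile histograms store probability per
bin over [0, 1] (20 bins).

Patch morphometry runs on the combined non-myocyte mask with 8-connected
components (preserves thin diagonal strands typical of stringy fibrosis),
keeps components strictly larger than 150 µm², and reports axes of the
second-central-moment ellipse. Two eccentricity conventions exist; the
major/minor *ratio* (≥ 1) is the default reported value (`mean_axis_ratio`)
because that is the convention used in this literature, with the standard
ellipse eccentricity in [0, 1) also emitted (`mean_eccentricity`).

## Etiology classification

Binary k-means with 50 restarts; each restart seeds Lloyd's algorithm
with a uniformly drawn pair of distinct subjects, the lowest
sum-of-squared-distances solution wins (ties by first occurrence), and a
`squared=False` option selects by plain summed distances instead, since
the verbal description "sum of Euclidean distances" admits both readings.
The lower-centroid cluster (summed over features) is labeled NIC, the
higher IC; for a single feature the centroid midpoint is the reported
discrimination threshold. Features are deliberately not standardized —
no standardization step exists in the emulated protocol — so
multi-feature runs on raw values let large-range features (patch areas)
dominate; the table builder flags constant features and skips them.
Scoring uses IC as the positive class. On cohorts drawn from the
published σ_intra group distributions (IC 27.1 ± 6.03 vs NIC
15.69 ± 5.76%), mean recovery accuracy over 200 seeded cohorts is ~84%,
consistent with the 81.25% reported for the real cohort. The real
study's exact 20.58% threshold depends on its unpublished per-subject
values and is not a reproduction target.

## Synthetic tissue generator

The generator emulates *segmented* microscopy — binary masks, not
fluorescence: no intensity noise, stitching artifacts, thresholding, or
manual mask editing. Myocytes are staggered rounded rectangles
(superellipse exponent 8) of 100 × 23 µm with 2-µm clefts, long axis
along X; the 25-µm row period divides the 50-µm tile so the bare lattice
contributes little tile-to-tile variance (σ_intra ≈ 1.3% at the
homogeneous limit). Fibrosis is added as pattern elements — interstitial
cleft widenings, short diffuse strands, long thin stringy strands,
patchy strand clusters, compact elliptical regions — drawn by normalized
pattern weights until the ES pixel count reaches the target V_nm (the
last element is truncated, so targets are met to well under one
percentage point). Fibroblast/myofibroblast blobs (~50 µm²) are then
carved out of the ES, leaving the combined non-myocyte mask unchanged.

Heterogeneity is controlled by one knob in [−1, 1]: positive values
rejection-sample element positions against a smooth random field raised
to an exponent (fibrosis concentrates in a few regions, raising σ_intra)
and simultaneously widen strands; negative values shrink elements and
stratify their placement over a jittered grid (the homogeneous limit).
`calibrate_generator` bisects this knob until the measured σ_intra hits
the target (the relation is monotone); the delivered image is the
winning calibration candidate bit-for-bit, so generation is deterministic
per (spec, seed) and the calibrated σ is exactly the image's σ.
Unreachable targets return the closest achieved value with a warning
rather than an exception. Per-pattern geometric parameters (strand
widths and lengths) are not constrained by any published measurement;
the defaults were chosen once to look like the published image panels
and to satisfy the printed aggregate statistics, and the cohort
generator draws per-subject (V_nm, σ_intra) targets independently from
the printed group means/SDs (their real-world correlation is not
imposed; it emerges partly through feasibility truncation).

What passing tests show: the quantification chain recovers known ground
truth, and group-level statistics of generated cohorts match the printed
ones. What they cannot show: behaviour on real stitched confocal data,
whose fibrosis geometry is richer than five pattern archetypes.

## Mesh and conductivities

Elements are 50 µm squares (2 500 µm² of image); fractions are mask
means over each element footprint, myocyte fraction is
V_myo = 1 − V_e − V_f − V_mf, and conductivities are diagonal tensors in
the (X = myocyte axis, Y) frame: σ_myo = V_myo σ̄_myo, σ_e = V_e σ̄_e with
anisotropy ratios 10 and 2. Fibroblast/myofibroblast fractions conduct
in neither domain. β_myo = V_myo / 41 073 µm³ converts per-myocyte
membrane current to a tissue current density. Elements with
V_myo < 1e−6 are passive: no membrane states, zero intracellular
conductivity, but still present in the extracellular system.

The source material states two inconsistent 100%-fraction myocyte
conductivities: 0.5 S/m (with the tensor definition) and 0.1 S/m (with
the space-constant evaluation). Both are presets
(`ConductivityParams.preset("tensor" | "evaluation")`); **evaluation is
the default** and is used for all conduction results here, because it
reproduces the published donor longitudinal CV (0.365 → 0.4 m/s) and the
published λ_l = 0.30 mm, whereas the tensor set gives 0.60/0.26 m/s.
Known discrepancy: with the evaluation set's transverse pair
(σ_myot = 0.01, σ_et = 0.5 S/m) the donor transverse CV is 0.12 m/s
(continuum cable estimate 0.118 m/s) and the anisotropy is ~3.0, while
the published donor values are 0.17 m/s and anisotropy ~2; those would
require an intracellular anisotropy near 5, which neither printed set
provides. We report what the stated equations and parameters produce.

Membrane capacitance per myocyte defaults to (surface-to-volume ratio
2e5 m⁻¹) × (cell volume) × 0.01 F/m² ≈ 82 pF; the printed per-myocyte
capacitance ("2e7 nF") is physically implausible and treated as a typo.
The value is configurable (`cm_per_myocyte`).

## Bidomain solver

Equations are split into an elliptic solve for φ_e,
∇·((σ_myo+σ_e)∇φ_e) = −∇·(σ_myo ∇V_m), and a forward-Euler parabolic
update for V_m driven by the divergence of the intracellular flux and
the ionic current. Spatial discretization is five-point finite volumes
with **harmonic-mean** face conductivities (a fully fibrotic element is
an intracellular insulator, consistent with replacement fibrosis) and
no-flux exterior faces. The elliptic operator is gauge-fixed at the
first conducting element (and rows of elements with neither domain
conducting are pinned to zero); being time-invariant it is factorized
once — the implementation precomputes the dense inverse and applies it
each step, which on these meshes (≤ a few thousand elements) leaves a
relative residual far below the 1e−12 tolerance contract, verified by a
conservation test.

The stimulus is a Dirichlet clamp of V_m = +1 mV on one edge for 2 ms
after 2 ms of equilibration, released afterwards; φ_e remains governed
by the elliptic equation everywhere and source densities are zero. The
15 ms total *includes* the 4 ms pre-propagation phases; activation times
are reported relative to stimulus onset. Clamped edge elements jump
across the −60…0 mV activation window between samples and are assigned
activation at stimulus onset by definition.

Ionic currents use the ten Tusscher–Panfilov 2006 model (the cited
"normal human ventricular myocyte"; the epicardial parameter set is the
default since no cell type is named, with endo/M variants available).
Gates update by exponential (Rush–Larsen) integration, concentrations by
forward Euler; a numba-compiled kernel shared by the tissue and
single-cell paths mirrors a readable NumPy formulation, and the two are
cross-checked to machine precision in the tests, with the single-cell
action potential verified against an independent adaptive-step
integration to < 0.2 mV sup-norm.

Time step: the reference protocol step is 1e−8 s; with Rush–Larsen
gating the scheme is stable and converged at far coarser steps (median
|CV| changes < 1% from 1e−6 to 1e−8 s, and < 3% under dt halving — the
convergence test). The test suite runs at 1e−6 s and the acceptance
script at 1e−7 s, with V_m recorded every 1 µs in all cases (enough to
resolve 200–300 V/s upstrokes). Simulated domains are 20 × 20 elements
(1 mm²), extended to 100 × 20 for the boundary-effect analysis.

## CV analysis

Activation is the time of maximal dV_m/dt restricted to samples with
V_m ∈ (−60, 0) mV and a minimum upstroke of 5 V/s (to exclude passive
depolarization creep); elements never meeting it are non-conductive, and
their 8-connected regions are reported as conduction blocks. CV vectors
are measured at four L-shaped triplets (corner + one neighbour along +x
and +y, spacing 50 µm). "Spread uniformly" does not fix the positions;
corners sit at n//4 and n−2−n//4 per axis, a centered 2 × 2 lattice
chosen so the sampled element gaps map onto themselves under domain
mirroring — opposite-direction runs on symmetric meshes then sample
identical locations and agree exactly. Tilt angles use a two-argument
arctangent with the direction-specific branch offsets (+x: θ; −x:
180°−θ; +y: 90°−θ; −y: 90°+θ), wrapped to (−180°, 180°]. A triplet
touching a non-conductive point yields a block-marked measurement, never
a number; tx = ty = 0 is undefined.

Boundary-effect errors compare matched triplets between the original and
the homogeneously extended 5-mm domain: mean signed error, and RMSE
normalized per point by the original magnitudes; angle RMSE is
normalized by the 90° tilt scale because planar-wave reference angles
are near zero (per-point normalization would be ill-posed). Space
constants are the closed form λ = √((R/β)·σ_myo σ_e/(σ_myo+σ_e)) with
R = 0.2 Ω·m², β = 2e5 m⁻¹; the transverse value evaluates to 0.099 mm
(sometimes quoted truncated as 0.09 mm).

## Statistics

Welch's unequal-variance t-test (Satterthwaite df), one-way ANOVA across
the three groups, two-sided variance-ratio F tests, and OLS fits
y = Ax + B scored by R² and the F-test against an intercept-only model
(identical to the slope t-test in the simple linear case). Significance
is fixed at 0.05 with no multiple-testing correction, matching the
emulated reporting. All tests delegate to scipy.stats.

## Known limitations

* 2D only; no transmural structure, mechanics, re-entry protocols, or
  fibroblast–myocyte electrical coupling (fibroblasts are non-conductive
  volume by construction).
* One conduction wave per run; no restitution or cycle-length effects.
* The homogeneous-mesh CV *increases* mildly with uniform V_nm under the
  linear fraction-scaled conductivities (the extracellular path improves
  and the membrane load per volume falls); CV slowing with fibrosis is a
  property of *heterogeneous* (patchy) meshes, not of the homogenized
  limit.
* The synthetic generator constrains aggregate statistics, not the full
  spatial statistics of real fibrosis.
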