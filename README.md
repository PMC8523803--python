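# fibrocv

Microscopy-based quantification of cardiac fibrosis and image-derived
bidomain modeling of ventricular conduction, for computational
electrophysiologists and cardiac image analysts studying how the
*pattern* of fibrosis — not just its amount — shapes electrical
propagation in end-stage heart failure (HF).

The pipeline mirrors a microscopy-to-model study design: segmented
confocal images of left-ventricular tissue (extracellular space via WGA,
myofibroblasts via α-SMA, fibroblasts via vimentin) are reduced to
composition and heterogeneity statistics, used to classify HF etiology
(ischemic, IC, vs nonischemic, NIC), and converted into 2D bidomain
meshes on which anisotropic conduction is simulated and measured. A
seeded synthetic-tissue generator stands in for the microscopy, so every
stage is testable without image downloads.

## The model in brief

**Fibrosis quantification.** For a region of interest, the non-myocyte
fraction is

&nbsp;&nbsp;&nbsp;&nbsp;*V*<sub>nm</sub> = *V*<sub>e</sub> + *V*<sub>f</sub> + *V*<sub>mf</sub>,

and fibrosis of an HF sample is *V*<sub>nm</sub> − mean(*V*<sub>nm,donor</sub>).
Intra-subject heterogeneity σ<sub>intra</sub> is the sample SD of
*V*<sub>nm</sub> over 50 µm × 50 µm tiles (400 tiles per mm²). Fibrotic
patches are 8-connected components of the non-myocyte mask larger than
150 µm², described by moment-matched ellipses. Subjects are clustered
into IC/NIC by best-of-50-restarts binary k-means (lower centroid → NIC);
for a scalar feature the centroid midpoint is the discrimination
threshold.

**Conduction.** Each 50-µm mesh element carries volume fractions from the
image; conductivities scale linearly, σ<sub>myo</sub> = *V*<sub>myo</sub>·σ̄<sub>myo</sub>
and σ<sub>e</sub> = *V*<sub>e</sub>·σ̄<sub>e</sub>, with
longitudinal:transverse anisotropy 10 (myocyte domain) and 2
(extracellular). Fibroblast/myofibroblast fractions conduct in neither
domain. The bidomain system is solved as an elliptic equation for φ<sub>e</sub>
and a parabolic update for *V*<sub>m</sub> (five-point finite volumes,
harmonic-mean face conductivities, no-flux boundaries, operator
splitting), with membrane currents from the ten Tusscher–Panfilov 2006
human ventricular myocyte model scaled by the myocyte density
β<sub>myo</sub> = *V*<sub>myo</sub>/41 073 µm³. A 1-mV edge clamp for
2 ms (after 2 ms equilibration) launches a planar wave; activation time
is the moment of maximal d*V*<sub>m</sub>/d*t* within −60…0 mV, and CV
vectors follow from activation-time differences at L-shaped grid
triplets: |CV| = *l*/√(*t*<sub>x</sub>² + *t*<sub>y</sub>²) with
direction-specific tilt-angle branches.

## Worked example

```bash
python examples/04_simulate_conduction.py
```

prints, for the homogeneous donor-mean mesh (V_e = 0.201, V_f + V_mf = 0.020):

```
space constants: lambda_l = 0.30 mm, lambda_t = 0.099 mm
longitudinal: activation completes 2.56 ms after stimulus onset; median |CV| = 0.365 m/s, tilt angles [0.0, 0.0, 0.0, 0.0] deg
transverse  : activation completes 8.01 ms after stimulus onset; median |CV| = 0.120 m/s, tilt angles [0.0, 0.0, 0.0, 0.0] deg
```

The longitudinal wave crosses 1 mm of donor-like tissue in ~2.6 ms
(0.365 m/s ≈ the 0.4 m/s donor mean when rounded to one decimal);
transverse conduction is ~3× slower under the printed anisotropies, and
the zero tilt angles confirm a planar wavefront. The other examples
cover tissue generation (`01`), fibrosis quantification (`02`), IC/NIC
clustering (`03`, a σ<sub>intra</sub> threshold near 23% classifies this
draw at 93.75%; ~84% on average over seeded cohorts), and the cohort
image→conduction→regression chain (`05`, where the IC mesh conducts
~27% slower than the donor mesh and median |CVL| falls with V_nm).

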