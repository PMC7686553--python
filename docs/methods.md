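# Methods notes

This note records the models, conventions and numerical choices behind
gliaquant, what the synthetic-data generator does and does not emulate,
and the limits of what passing tests demonstrate.

## Coordinate and measurement conventions

Physical coordinates are micrometres, `(x, y[, z])` with x along the
medial–distal axis (image columns).  Arrays are indexed `[z, y, x]`.
Pixel indices are 0-based; the physical position of pixel *i* is its
centre `(i + 0.5)·pitch`.  Default voxel size is 0.5 µm in-plane and
1 µm axially, matching typical confocal z-steps for this material.
Connected components use 8-connectivity in 2D and 26-connectivity in 3D
throughout; component counts depend on this choice, so it is fixed and
reported in output provenance.

## Nucleus detection and dual-threshold classing

Detection thresholds the projected activation channel with a configurable
auto-threshold (Otsu default; Li and triangle available; or a manual
level), labels 8-connected components, discards objects below an area
floor (default 20 µm², configurable — the floor used for counting weakly
stained nuclei is a free parameter, not a biological claim), and measures
the mean gray value on the *unthresholded* image over each object mask.
Class comparisons are strict (`>`): an object exactly at 200 µm² or at
mean gray 400 is c-Fos⁺, not c-Fos⁺⁺.  Raising either threshold can
therefore never increase the strong count (verified by a property test).

Layer bands are half-open `[start, start + width)` measured from the
pial/midline edge.  Where anatomical width ranges are quoted for this
cortex (layer I 120–140 µm, layer V 320–350 µm), the configuration
carries a single value, defaulting to the midpoint.  Nuclei past the last
band receive a `beyond_*` sentinel and are never silently dropped.

## Sholl analysis of the non-isolated network

A *crossing* at radius r is a maximal run of skeleton-foreground pixels
along the discretized circle of radius r: the midpoint-circle pixel ring,
traversed in angular order, with runs wrapping the 0°/360° seam merged.
This definition is explicit and exactly testable: an independent oracle
(separate ring construction by per-octant square-root rounding, run
counting by walking the ring neighbour-to-neighbour) must agree
per-radius on every tested skeleton.

Discretization caveats, inherent to any pixel-ring definition:

* the innermost rings (circumference comparable to the number of
  structures) cannot resolve arms that a true circle would separate — a
  "+"-shape yields one run at r = 1 px and four from r = 2 px on;
* an 8-connected skeleton branch can in principle cross an 8-connected
  ring diagonally without sharing a pixel.  This affects isolated exotic
  geometries, not the network statistics, and affects compared groups
  identically.

Defaults: radius step 1 µm, maximum 40 µm for soma-centred profiles
(covering the single-cell and inter-cellular zones), 15 µm for
neuron-centred profiles.  Profiles whose circles leave the image are
computed on the in-bounds arc and flagged per-radius.

The identity baseline subtracts the radius in µm from the crossing count;
it is a pure visual transformation — crossings are retained and the
operation inverts exactly.

Zone statistics take per-centre mean crossings over half-open radial
zones (defaults `[0, 20)` and `[20, 40)` µm) and compare two groups per
zone with a two-sided Mann–Whitney U test: exact null distribution when
both groups have ≤ 8 centres and no ties, tie-corrected normal
approximation otherwise.

## 3D shell analysis

The 3D variant runs on the thresholded membrane volume, not the skeleton
(membranous staining is what outlines branch volume in z), and counts
26-connected clusters of foreground voxels per spherical shell.  Shell k
spans `[k·dr − dr/2, k·dr + dr/2)` of Euclidean distance in µm, with
per-axis voxel sizes honoured, so every voxel between dr/2 and
r_max + dr/2 falls in exactly one shell; the sub-dr/2 core — the nucleus
at the centre — belongs to none.  A rod through the centre then yields
two clusters per shell and a plane one annulus per shell, which is the
behaviour the cluster-count reading requires.  Note that with coarse
axial sampling a shell's polar caps can detach from its equatorial band
purely through discretization; anisotropy correctness is therefore
asserted with equatorial structures (a rod in-plane), where the physics
of the comparison is discretization-free.

Analyses refuse volumes thinner than 2·r_max along z unless explicitly
told to accept border-truncated shells, and flag every truncated shell.

The soma-contact criterion dilates each nucleus mask by a contact margin
(default 0.5 µm ≈ 1 voxel — a manual "physical contact" judgement has no
numeric margin, so this is a declared convention) and tests overlap with
the soma mask; implemented via a Euclidean distance transform, which is
equivalent and exact.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not optics.  Nuclei are flat-top ellipses (constant fill intensity,
mild eccentricity) so that the thresholded-object measurements — pixel
area and mean gray — reproduce the generator's own draws exactly at zero
noise; ground-truth labels are assigned from the *rendered* object under
the standard dual cut and are sound by construction.  An intensity floor
(default 240) keeps immunopositive nuclei above the auto-threshold that
the background/foreground mix produces; the class intensity and area
distributions are free parameters of the simulation, not estimates of
real tissue.  Negative (NeuN-only) nuclei appear in the nuclear channel
only.

Microglia are rendered as somata on a jittered grid at a target density
(default 235 cells/mm², ≈ 65 µm spacing — typical cortical microglia
tiling, and wide enough that one cell's inter-cellular annulus does not
invade a neighbour's single-cell zone) plus random binary trees: primary
branches radiate from each soma and extend/branch with fixed probability,
confined to the 20 µm single-cell radius.  Inter-cellular territory is
populated separately by near-radial segments confined to the 20–40 µm
annulus, with count per soma proportional to `intercell_branch_density` —
the control knob for the zone-effect experiments.  Optional "attraction"
places short spokes wholly within a configurable radius (default 8 µm) of
each activated nucleus.

Noise is additive Gaussian clipped at zero; there is no PSF convolution,
bleaching, or autofluorescence — the analysis operates on thresholded
images, so photometric realism would add nothing the pipeline measures.
Consequently, passing recovery tests demonstrates correctness of the
measurement chain, not robustness to optical artefacts of real
microscopy.

All randomness flows from one integer seed, split into named substreams
(nuclei, somata, arbors, inter-cellular, attraction, noise).  Two runs
differing in one parameter share every draw of the unaffected components;
the paired-cohort experiments exploit this so that "cohorts differing
only in inter-cellular density" differ *only* there, making the 0–20 µm
zone an exact null.

Trajectories are either scripted (waypoints reproduced exactly, linear
interpolation at the frame rate) or bounded correlated random walks.  The
Y-maze has 30 cm arms, 7 cm width, 120° angles.  The release simulator
is a first-order washout: each 3-min sample releases a constant fraction
of the remaining pool, multiplied by a gain at the stimulated sample;
radioactivity is conserved to floating precision.

## Behavioural scoring choices

"Successful alternation" is the standard sliding-triplet definition
(three consecutive entries, three distinct arms) over entries; the
percentage denominator is entries − 2.  Whether historical analyses used
triplets over entries or over arm *changes* is ambiguous; with the
same-arm-collapse rule in force every consecutive entry pair is a change,
so the two coincide here.  Rotation counting (no published rule exists
for this readout) accumulates unwrapped heading change, scores one
unsigned rotation per 360° in a consistent direction, resets on >90°
reversals (seeding the new direction with the turning already made),
skips sub-0.5 cm displacements as tracking jitter, requires a minimum
loop radius, and for closed paths includes the turning across the closure
point so a circle traversed k times scores exactly k.

## Release bookkeeping

The only measurable anchor after a superfusion experiment is the residual
tissue content, so tissue-at-start of sample k is reconstructed backward:
`tissue(k) = tissue_after + Σ released[k:]`.  This makes fractional
release scale-invariant (multiplying all Bq by a constant changes
nothing) and makes uptake × mass recover the initial load exactly.  The
evoked-response window defaults to the stimulated sample plus the
following two; it is configuration, as no universal window exists.

## Statistics

All p-values are two-sided.  Unbalanced two-way layouts use Type-III sums
of squares with sum-to-zero contrasts.  Bonferroni adjustment multiplies
the raw p by the number of pairwise cell comparisons, capped at 1.  Under
a fully inert 2×2 design the family-wise error of the adjusted pairwise
Welch tests sits near 3 % (Bonferroni is conservative under the positive
dependence of comparisons sharing cells); the null-calibration check uses
2000 replicates because a 500-replicate window has a Monte-Carlo standard
error near one percentage point.  One-way ANOVA with Kruskal–Wallis/Dunn
follow-ups (used for some behavioural endpoints in this literature) is
out of scope; the two-group machinery covers those comparisons pairwise.

For imaging endpoints, "n" can mean animals or cells; analysing
per-cell values inflates effective sample size through pseudo-replication.
The reporting layer takes whatever rows it is given — callers should
aggregate to the animal level first when that is the inferential unit.

## Problem sizes used in validation

Oracle equivalence: 50 random skeletons up to 256² px (2D) and 30 random
volumes up to 28³ voxels (3D), every radius checked.  Classification
recovery: 20 seeds of a full four-layer field (~60 nuclei each), exact at
zero noise and within 5 % at the default noise.  Zone effect: 20 paired
replicates, +30 % inter-cellular density, 40 soma centres per cohort.
Attraction: 20 replicates each for effect (3 extra segments within 8 µm)
and null, ~32 neuron centres per field.  These sizes give the detection
rates headroom while keeping the whole validation run to a few minutes.

## Known limitations

* No watershed splitting of touching nuclei and no learned segmentation;
  the generator places nuclei disjointly, so real clumped material will
  need upstream splitting.
* Single-cell arbor reconstruction is deliberately absent (cut branches
  in thin slices make it unreliable); branch-order and tortuosity
  metrics are likewise out of scope.
* DAB material is handled as single-channel intensity; no colour
  deconvolution.
* The automated soma-finding convenience (largest blob cores) is a rough
  stand-in for curated soma centre lists and is not used in validation.
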