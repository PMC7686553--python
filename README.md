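# gliaquant

Quantitative image analysis of **layer-specific neuronal activation** and
**microglia–neuron interaction** in cortical immunofluorescence, with the
accompanying behavioural and superfusion-release arithmetic.  The package
replaces a manual FIJI-macro workflow with a tested, scriptable pipeline,
and ships a synthetic-data generator so every stage can be validated
against known ground truth.

## Who it is for

Groups quantifying immediate-early-gene activation (c-Fos) and microglial
morphology in tissue sections — e.g. medial prefrontal cortex of
pharmacological rodent models — where the questions are: how many strongly
activated nuclei per cortical layer, how is the microglial network arranged
around them, and how do behavioural and neurochemical readouts co-vary.

## What it computes

**Nucleus counting and classing** (`gliaquant.nuclei`).  A z-stack is
flattened (max projection for fluorescence, sum of slices for DAB), the
activation channel is auto-thresholded (Otsu by default) and connected
objects are measured: projected area *A* (µm²) and mean gray value *ḡ*
taken on the original image over the object mask.  Strongly activated
nuclei are classed by the dual threshold

    c-Fos⁺⁺  ⇔  A > 200 µm²  and  ḡ > 400,

with an alternative pair (100 µm², 1100) available for differently stained
material; everything else detected is c-Fos⁺.  Nuclei are binned into
consecutive cortical layer bands (I = 130, II/III = 80, V = 335,
VI = 280 µm by default) and reported as counts and densities per mm².

**Non-isolated Sholl analysis** (`gliaquant.microglia`).  Because cortical
microglia tile the tissue as an interlocking network, single-cell arbor
isolation in thin slices is unreliable.  Instead the whole-network
skeleton (1-pixel thinning of the thresholded membrane channel) is
analysed with soma-centred concentric circles: the crossing count *N(r)*
is the number of maximal skeleton runs along the discretized circle of
radius *r*.  *N(r)* grows roughly linearly with *r* as neighbouring cells'
branches enter larger circles, so the package also reports the
identity-adjusted curve *N(r) − r* and zone statistics comparing the
single-cell territory (0–20 µm) with the inter-cellular territory
(20–40 µm) between groups (Mann–Whitney U).

**Neuron-centred interaction** (`gliaquant.interaction3d`).  The same 2D
machinery centred on activated (c-Fos⁺) versus inactive (NeuN⁺/c-Fos⁻)
nuclei; a 3D variant counts 26-connected clusters of thresholded membrane
voxels per spherical shell (default radius 15 µm, anisotropic voxels
respected); and a soma-contact fraction: the proportion of activated
nuclei whose mask, dilated by a small margin, touches a microglial soma.

**Behaviour** (`gliaquant.behavior`).  Distance in 10-min bins, epoch
velocities, unsigned full-circle rotation counts, and Y-maze spontaneous
alternation with the standard rules: an arm entry requires the central
body point to pass 20 % of the arm length, consecutive same-arm entries
collapse to one exploration, and animals under 20 alternations are flagged
for exclusion.  Alternation % = triplets of three distinct arms over the
(entries − 2) sliding windows.

**Release arithmetic** (`gliaquant.release`).  Fractional release
FR(k) = released(k) / tissue-at-start-of-k × 100 with the tissue content
reconstructed backward from the residual; uptake (Bq/g); basal outflow
(mean FR of two drug-free samples); evoked net release (response-window
mean FR minus basal).

**Statistics** (`gliaquant.stats_report`).  Welch t, Mann–Whitney U
(exact for small n), and two-way ANOVA (Type-III) with Bonferroni-adjusted
pairwise cell comparisons.

## Worked example

```python
from gliaquant import (SimParams, generate_cortex_stack, default_mpfc_layout,
                       detect_nuclei, classify_activation, assign_layers,
                       layer_counts, ThresholdPair, binarize, skeletonize,
                       sholl_2d, identity_baseline)

layout = default_mpfc_layout(field_y_um=300.0)
stack, truth = generate_cortex_stack(SimParams(seed=1), layout, nz=1)

nuclei = detect_nuclei(stack.channel("cfos"), stack.pixel_size_um)
nuclei = classify_activation(nuclei, ThresholdPair(200.0, 400.0))
nuclei = assign_layers(nuclei, layout)
print(layer_counts(nuclei, layout, class_filter="cfos_plusplus"))

mask, level = binarize(stack.channel("microglia"))
skel = skeletonize(mask, stack.pixel_size_um)
profile = identity_baseline(sholl_2d(skel, tuple(truth.somata_um[5][:2])))
print("crossings at r=10,20,30 um:",
      [int(profile.crossings[r - 1]) for r in (10, 20, 30)])
```

prints

```
    layer  count  density_per_mm2
0       I      5       128.205128
1  II/III      2        83.333333
2       V      8        79.601990
3      VI      5        59.523810
crossings at r=10,20,30 um: [5, 5, 6]
```

— the per-layer density of strongly activated nuclei in the synthetic
field (counts match the generator's ground truth exactly at zero noise),
and a soma-centred network Sholl profile whose crossing count stays in the
single-cell range near the soma and rises as neighbouring arbors enter the
circle.

A `gliaquant` console command exposes the same stages on files
(`simulate`, `nuclei`, `sholl2d`, `interact`, `behavior`, `release`); run
`gliaquant --help`.

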