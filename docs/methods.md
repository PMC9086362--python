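# Methods

## Physical model

A TMV-like nanorod is a rigid helical nucleoprotein cylinder of external
diameter 18 nm whose length is proportional to the length of the
encapsidated RNA (three nucleotides per coat-protein subunit). The linear
scale is calibrated on the full virion, 300 nm for 6,395 nt, i.e.
0.04691 nm/nt. We deliberately use this printed pair rather than helical
rise constants (2.3 nm per turn of 16⅓ subunits, an indistinguishable
0.04694 nm/nt). No end-correction is applied for a partially occupied
final helix turn; the effect is sub-nanometre. End-to-end aggregation of a
unit rod of length `u` produces apparent classes at `k·u` — 49, 98,
147 nm for the subgenomic-RNA unit.

Note that this scale does not reproduce every published expectation: for a
unit rod carrying 1,640 extra nucleotides the linear scale predicts
≈126 nm where 129 nm is sometimes quoted (and ≈334 vs 339 nm for the long
class); the exact RNA lengths behind those quotes are not public, so the
package asserts only the arithmetic it can derive.

## Segmentation pipeline

Stages, in order, with defaults chosen for 4k micrographs at
0.3482 nm/px:

1. **Adaptive threshold.** Local Gaussian-weighted mean, block 301 px,
   offset 0; a pixel is foreground when strictly below its local
   threshold (dark objects; polarity is switchable). The comparison is
   invariant to affine intensity rescaling, so detector units never
   matter. With a zero offset roughly half of the *background* is also
   marked (any pixel below its local mean); this speckle is intentional
   input to the next stage, which is why stage order is load-bearing.
2. **Cleanup.** One binary erosion (3×3 cross) removes the speckle;
   connected components below 2000 px (8-connectivity) are removed; five
   dilations (3×3 cross) restore and slightly overshoot the rod
   footprint; interior holes below 500 px (4-connected, the topological
   dual) are filled. The structuring element is not specified by the
   measurement recipe itself; the 3×3 cross is the smallest reasonable
   choice and the scikit-image default.
3. **Watershed.** Markers are the connected components of
   {EDT ≥ 0.6 × (18 nm / 2)}, i.e. the "core spine" deeper than 60% of a
   rod half-width, flooding the negated distance transform within the
   mask; any foreground component with no core receives one marker. On an
   elongated rod the EDT ridge is a near-flat plateau, so peak-picking
   with a minimum separation would seed several markers along one rod and
   chop it transversally — fatal for a length measurement; the
   core-component rule keeps exactly one marker per rod regardless of
   length while still splitting objects joined by a *thin* neck (e.g.
   tip-to-tip contacts). A limitation follows from the geometry: two rods
   fused *laterally* have a junction EDT at least as high as a single
   rod's ridge, so no distance-based watershed can split them. Such
   side-by-side pairs survive as single wide objects (minor axis ≈ 34 nm,
   under the 40-nm filter) — the "rogue" measurements that the manual
   exclusion step exists to remove.
4. **Filter.** Objects with area < 500 nm² **or** minor axis > 40 nm are
   eliminated. The minor axis is the minor axis length of the ellipse
   with the same normalized second central moments as the object
   (standard regionprops definition). The disjunctive reading is the only
   one consistent with the filter's purpose (a conjunctive one would keep
   tiny debris).

The pipeline is fully deterministic; labels are assigned in raster order
of first pixel.

## Measurement

The maximum Feret diameter is computed over pixel **corners** (each pixel
a closed unit square): the maximum pairwise distance is attained on the
convex hull of the 4N corner points, and hull vertices are compared
exhaustively. The corner convention matches the "distance between the two
most distant corners" reading and avoids a systematic −1 px bias; a
single pixel has F = √2 px. Length is L = √(F² − W²) with W = 18 nm;
F < W yields an undefined (NaN) length — such objects cannot be rods of
the stated width and are excluded from histograms. Objects touching the
image border are measured but flagged `truncated` (their lengths are
lower bounds) and excluded from reports by default.

Two systematic biases are accepted rather than corrected, because the
published recipe applies no correction:

- the net erosion(1) + dilation(5) inflates each rod by ~3–4 px per end
  along its axis, adding ~2.5–3 nm to F; after the Pythagoras correction
  the measured 49-nm class comes out at ≈ 48.9 nm (the two effects nearly
  cancel at this length) and the 257-nm class at ≈ 259.5 nm (+1%);
- the ellipse-equivalent minor axis of a solid rod is (2/√3) ≈ 1.15×
  its physical width even for a perfect mask; combined with the dilation
  growth, 18-nm-wide rods measure ≈ 23 nm in mean minor axis. This
  quantity is a *shape filter*, not a width estimate; anyone needing the
  physical width should use F of a cross-section or reduce `n_dilations`.

## Reporting

Histograms use fixed 10-nm bins anchored at 0 ([0,10), [10,20), …);
only the bin width is conventionally fixed, the anchor at zero is the
simplest reproducible choice. The SD is the sample standard deviation
(n−1). Manual exclusion flips an `excluded` flag and never deletes rows,
so raw measurements remain auditable. Multimer classification assigns
k = round(L/u) (half-up; k=0 coerced to 1 and flagged), with residual
L − k·u.

## Synthetic scenes

The generator emulates exactly the features the pipeline is sensitive to:
dark capsules (stadium shape — rectangle plus semicircular caps — of true
tip-to-tip length L and width 18 nm) on a brighter background, additive
Gaussian noise, and a smooth illumination gradient. Defaults:
background 150, object contrast 60, noise SD 6 (10:1 contrast-to-noise),
gradient amplitude 15 (10% of background) — the regime where
negative-stain rods are unambiguous by eye, which is also the regime in
which micrographs are selected for measurement in practice. Edges are
anti-aliased with a 1-px linear coverage ramp. The 4-nm central channel
is not rendered (negative stain fills it only at rod ends) and no TEM
optics (CTF, defocus) or stain granularity are modelled; consequently
passing recovery tests demonstrates correctness of the geometry and
morphology chain, not robustness to every real-world staining artefact.

Placement uses a jittered grid sized by the largest object plus a minimum
gap (default 54 nm = 3 rod widths), guaranteeing isolation; an impossible
request raises a placement error rather than degrading silently. Physical
end-to-end aggregates are rendered as one capsule of k × unit length
(stacked cylinders join flush at full width) and recorded with
`multimer_k = k`; side-by-side "rogue" pairs are two staggered touching
capsules recorded individually. A fixed seed gives a bit-identical image.

## Problem sizes

The recovery experiments measure 216 rods of the 49-nm class in six
2048²-px scenes, 112–208 rods of the 257-nm class in 4096²-px scenes
(16 rods per scene at the isolation gap), and 108 mixed-length rods for
the width summary; these sizes give standard errors of the mean well
under 0.1 nm, far below the few-nm tolerances being checked.

## Known limitations

- Laterally fused rod pairs are not separable by any distance-transform
  watershed (see above); they are handled by manual exclusion.
- Crossing rods of equal width are likewise not split.
- The minor-axis statistic systematically exceeds the physical width by
  the moment-ellipse factor plus dilation growth (see Measurement).
- Border-truncated rods are flagged, not extrapolated.
- MRC support covers single-frame MRC2014 (modes 0/1/2/6); stacks are
  rejected rather than silently averaged.
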