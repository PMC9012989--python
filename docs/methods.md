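# Methods

`thermoapos` turns a whole-body infrared thermogram into a binary knowledge
representation and tests one clinical contrast derived from it. This note
documents the models and procedures each stage implements, the parameters
that matter, and the choices made where the method description leaves the
design open.

## Data model

A frame is a dense grid of skin/background temperatures in °C
(`TemperatureField`), 0-based `(row, col)` indexing, origin top-left,
default 256 rows x 336 columns. Frames move between stages in a small
lossless file dialect (`.tgrid`): an 8-byte little-endian header (rows,
cols as uint32) followed by row-major uint16 centi-degrees, so any
temperature in [0, 655.35] °C round-trips to 0.01 °C. Display
standardization maps temperature to gray via a 10 °C window anchored at the
frame's own maximum (`tfs = max − tfw`), with round-half-up quantization to
0–255; the window rule makes every frame's rendering comparable without
any per-frame manual adjustment. Clustering operates on temperatures, not
gray levels — the gray render exists for standardized display and export.

## Background filtering

An indoor frame's global temperature histogram is bimodal: a narrow ambient
mode near the room temperature and a broader skin mode several degrees
higher. The filter:

1. bins all pixels at `bin_width` (default 0.1 °C — raw precision is
   0.01 °C, a coarser bin stabilizes peak detection);
2. smooths the frequency curve with a normalized discrete Gaussian of odd
   size 5 (σ = size/5 = 1.0 bins, reflect boundary, which conserves total
   mass);
3. finds the two lowest-temperature local maxima whose prominence is at
   least 5% of the maximum frequency. The curve is zero-padded one bin at
   each end so a mode touching the covered range still counts. Bins at
   0 °C are excluded from the 5% floor: exact zero is the filter's own
   background sentinel, and without the exclusion an already-filtered
   frame's zero spike would drown out the skin mode and break idempotence;
4. thresholds at the midpoint of the two peak temperatures (the
   `segment-median` mode — the median of pixels strictly between the
   peaks — is selectable where a skewed valley argues for it);
5. zeroes every cell strictly below the threshold.

Retained values pass through unchanged, so the filter is idempotent and
preserves the retained multiset exactly. Fewer than two qualifying peaks
raises a unimodal-field error: the frame has no separable background.

## ROI segmentation

Twelve operator-marked landmarks (`Pur_1` right wrist … `Pur_12` crotch)
drive the geometry of 18 quadrilateral regions arranged in left/right
mirror pairs about the vertical midline (the mean column of the forehead,
chin, belly-button and crotch anchors). Validation enforces completeness,
bounds, distinctness and the forehead < chin < belly-button < crotch row
ordering; a landmark on a background cell only warns, since operators may
click just off the silhouette edge.

The exact vertex constructions are a per-ROI rule table, overridable
entry-by-entry. The defaults build axis-aligned rectangles from anchor
rows and silhouette scan runs on the zero-background field: palms extend
from the wrist to the last nonzero row of the wrist's column band;
forearms span elbow-to-wrist rows over the arm's scan run; the anterior
elbow is a square centered on the elbow anchor with side 0.5x the
wrist–elbow distance (`elbow_scale`, the single same-size-scale constant);
upper arms span shoulder-to-elbow rows; face halves span
forehead-to-chin rows split at the midline; clavicle fossae span
chin-to-shoulder rows between each shoulder anchor and the midline; the
chest spans armpit rows down to the armpit/belly midpoint row; upper and
lower abdomen continue to the belly-button and crotch rows. Scan runs
snap to the nearest silhouette run within 10 px; beyond that the body
part is treated as absent and segmentation fails naming the ROI.
Vertices are kept as floats (no rounding) so mirroring an input mirrors
every quad exactly.

Rasterization takes all cells whose centers satisfy a boundary-inclusive
even-odd test; filtered zeros inside a quad are retained at this stage
because the granulation step is defined to handle them.

## Granulation

Each ROI's temperature multiset is clustered by 1-D K-means with all
randomness removed: K = 4 when the ROI contains background zeros, else
K = 3; initial centers are fixed order statistics (0, nonzero min, nonzero
mean, nonzero max for K = 4; min, mean, max for K = 3). Lloyd iteration
runs to convergence (max center shift < 1e-6 °C, cap 300 sweeps) with
ties assigned to the lower-index center and emptied clusters keeping
their center. With these centers the zero-initialized cluster captures
exactly the zeros, so "nonzero clusters" is well defined. The deliberate
trade: reproducibility over global optimality — though on the separated
clumps ROIs actually produce, the run provably reaches the optimal
contiguous partition (checked against an exhaustive oracle in the tests).

Writing `T_roi` for an ROI's nonzero-cluster means, the whole-body
thresholds are the averages over the 18 ROIs of each ROI's smallest and
largest nonzero-cluster mean. An ROI gets the low attribute when
`min(T_roi) <= T̄_min` and the high attribute when `max(T_roi) >= T̄_max`,
both boundaries inclusive. "Largest cluster" is read as largest-mean
nonzero cluster, symmetric with the explicitly nonzero smallest; the
alternative reading (including the background cluster) would drag
`T̄_max` toward zero and light every high attribute, which contradicts the
rule's purpose. A cohort of subjects assembles into an N x 36 binary
formal context with fixed column order ROI1-H, ROI1-L, …, ROI18-L;
CSV and Burmeister `.cxt` serializations are provided.

## APOS knowledge graph

The attribute partial order structure is realized as a coverage-ordered
intent trie. Attributes are totally ordered by descending coverage
(objects possessed), ties broken lexicographically, zero-coverage
attributes dropped. Every object's intent, sorted in that order, is
inserted as a root-to-leaf path; objects with identical intents share a
branch, and node depth is the diagram level. This satisfies the
structure's stated generation principles: more-covering attributes sit
higher, coverage is non-increasing along every path, and each branch is
exactly one object's attribute set. The extent-containment partial order
(a ≤ b iff every object with a also has b) is computed alongside as the
namesake relation. Spatial placement of similar objects is a rendering
concern and is delegated to the DOT/GraphML consumer. Exports: JSON
(lossless round-trip), DOT (hand-emitted text), GraphML (networkx).

## Statistics

Per subject, face pools the nonzero pixels of both face ROIs and chest
those of both chest ROIs (a per-side-averaging alternative is behind a
flag); ΔTavg/ΔTmax/ΔTmin are face-minus-chest differences of mean, max
and min. The group contrast is case minus control. Both t-test variants
are computed — pooled (df = nA+nB−2) and Welch (Satterthwaite fractional
df) — because statistical packages conventionally print both rows, plus a
Levene-based selection helper. Confidence intervals are
`diff ± t_{df,(1+level)/2}·SE`, recomputable from printed summary triples
alone. Post-hoc power uses the noncentral-t distribution of the two-sided
two-sample test, with the between-subject SD recovered from the standard
error of the difference as `SE·sqrt(n/2)`; a zero effect returns exactly
alpha.

## Synthetic phantoms

The phantom is a parametric polygon silhouette (elliptical head, neck,
trunk, two arms with palms, joined by shoulder bridges with an air gap
below the armpits so arm scanlines are separable) at a 32.5 °C base over
a 25 °C room, pixel noise SD 0.25 °C. Zone offsets encode the expected
skin pattern — warm clavicle fossae (+1.5) and face (+1.2), mild chest
(+0.5), cooler distal arms (−0.3/−0.5) and palms (−1.0) — keeping the
whole-body spread within the few degrees typical of skin. Landmarks are
placed at the silhouette's true joints.

Cohorts draw per-subject zone offsets: SD 1.082 °C for the head and chest
zones (so the face-minus-chest mean difference has SD √2·1.082 ≈ 1.53 °C,
the value implied by a printed SE of 0.33 at 43 per group), SD 0.3 °C for
the remaining zones plus a whole-body shift of SD 0.3 °C that cancels in
any between-region difference. The case group receives a +2.74 °C head-zone
shift. Generation is a pure function of (spec, seed).

What the phantom does **not** emulate: anatomical silhouette realism,
posture variation, within-zone temperature gradients, vascular texture,
camera noise models, or operator variability in landmark placement.
Passing tests therefore demonstrate that the algorithms are correct and
deterministic under the stated statistical structure, not that the
clinical contrast reproduces on real participants — the participant
images are not redistributable, so the clinical finding itself is outside
what this package can verify.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full image pipeline at
the study's design size (43 + 43 subjects, 256x336 frames, ~10 s), the
K-means-vs-oracle comparison on instances of up to 200 values (the
exhaustive contiguous-partition oracle is cubic-ish in n and exponential
in K), APOS brute-force checks on contexts up to 6 objects x 6
attributes, feature-level parameter recovery over 100 simulated cohorts
and type-I calibration over 1000 null cohorts. Tolerances: cluster
convergence 1e-6 °C; CI reproduction ±0.02 °C (absorbing the 2-decimal
rounding of printed inputs); rasterization edge tests use 1e-9 slack for
collinearity. Degenerate inputs fail loudly and early: all-zero fields,
unimodal histograms, coincident anchors, empty polygons, all-background
ROIs and zero-variance groups each raise a dedicated error type.

## Known limitations

- The default ROI geometry is one concrete, documented reading of the
  anchor-to-region mapping; the original study's exact vertex formulas are
  not public, so the rule table is designed to be replaced wholesale.
- The trie realization of the knowledge graph is one consistent
  interpretation of the generation principles; a concept-lattice-reduced
  variant would merge more aggressively.
- Power and CI reproductions take printed summary statistics at face
  value; no access to per-participant data means no independent check of
  those summaries.
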