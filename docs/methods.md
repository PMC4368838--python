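# Methods

## The classification model

Differential echogenicity assigns each wall pixel a tissue class relative
to the brightness of the adventitia of the *same* pullback, which cancels
gain, transducer and coupling differences between acquisitions. Two
thresholds drive the labeling:

* the **reference median** *m* — the lower median of the pooled grey-level
  histogram of all accepted adventitial ring pixels of the pullback;
* the **high-intensity threshold** *h* — a three-stage iterated Otsu cut
  of the frame histogram, combined across frames.

Within the wall (inside the vessel contour, outside the lumen contour):
grey < *m* → hypoechogenic; *m* ≤ grey ≤ *h* → hyperechogenic;
grey > *h* → highly echogenic, resolved by shadow casting into
upperechogenic (no shadow) or calcified + unknown (the shadow itself).
Equality with the median is assigned to the hyperechogenic side so the two
classes partition the wall; the tie rule is flippable
(`median_tie_to_hyper`). The five classes tile the wall exactly by
construction — conservation is asserted in the tests as an exact pixel
count.

### Adventitial reference

The ring spans 0.01–0.21 mm outside the vessel (EEM) contour, measured as
Euclidean distance to the polygon boundary itself (shapely), not to a
circle fit, so irregular vessels get a ring of uniform thickness. Otsu's
threshold of the full-ring histogram is computed per frame (class 0 =
levels < t, class 1 = levels ≥ t, smallest maximizer on ties; degenerate
single-level histograms are an error, except in `build_reference`, where a
constant ring keeps all sectors). The ring is divided into 180 sectors of
2°, anchored at the catheter center with the angular origin on the
positive column axis, counterclockwise with row 0 at the top. A sector is
excluded when **strictly more than half** of its pixels are **strictly
below** the adaptive threshold (both strict by design — the convention the
oracle tests encode), when it has no ring pixels, or when it intersects
the user-supplied guidewire angular mask (automatic guidewire detection is
out of scope). Per-frame histograms of surviving sectors are summed; the
median is the lower median — the smallest grey level whose cumulative
count reaches ⌈N/2⌉ — so it is always a usable integer threshold.

### Iterated Otsu high threshold

Stage 1 thresholds the whole frame histogram; stages 2 and 3 re-threshold
the levels **strictly above** the previous cut. A degenerate restricted
histogram stops the iteration and returns the last valid stage with a
warning. Per-frame stage-3 values are combined across the pullback as
their lower median (robust to single outlier frames); a `pooled` mode that
runs the iteration once on the summed histogram is also exposed. If the
high threshold falls below the reference median (pathological frames) it
is clamped to the median with a warning by default (`clamp_high_to_median`).

### Shadow detection

The detector is deliberately simple and fully parameterized, since shadow
detection has no canonical form: highly echogenic pixels are grouped into
8-connected components per frame (no 3-D linking); for each component,
radial rays from the catheter center cover its angular extent in 1° bins;
the mean grey of the pixels up to `depth_mm` = 0.5 mm beyond the
component's per-bin outer radius is compared with `fraction` = 0.25 × the
reference median. Components touching the image border with no assessable
behind-region are reported shadowless with a warning. For a calcified
component the unknown label is applied to all wall pixels behind it in its
covered bins (not just the assessment depth), never overwriting other
highly echogenic components. The boundary behavior is exact: the decision
flips precisely where the behind-region mean crosses `fraction × m`.

### Volumetrics

Volumes integrate per-frame class areas by the rectangular rule
(area × frame spacing, default 0.5 mm — the standard analysis interval);
only frames with contours are integrated. Geometric volumes come from the
rasterized contour masks; neointima volume is exactly vessel − lumen.
Cohort summaries normalize every volume by (mean length / pullback
length), which weights each subject equally and leaves percentages
untouched. Rasterization uses the even-odd (crossing-number) rule at
pixel centers, which yields the half-open convention: an axis-aligned
square with corners (10, 10)–(20, 20) covers exactly 100 pixel centers.
Where the scaffold contour dips inside the lumen, clipped pixels belong to
neither annular compartment but stay in the total wall, so the partition
degrades gracefully.

## Statistics

Pearson correlation, OLS regression and one-way ANOVA are thin wrappers
over `scipy.stats` with explicit degenerate-input errors. ICC defaults to
the two-way random-effects, absolute-agreement, single-measure ICC(2,1)
(via `pingouin`), the standard choice for method agreement in imaging;
ICC(3,1) is selectable. Ward clustering is implemented in-package with
the Lance–Williams update on squared Euclidean distances so the tie rule
(merge the pair with the smallest cost, lowest index pair on exact ties)
is deterministic; the merge cost equals twice the increase in
within-cluster sum of squares, and the tests verify the full merge tree
against an exhaustive minimal-WSS-increase oracle. Post-hoc pairwise
comparisons use Bonferroni correction by default (Holm available).

## The phantom

The generator emulates the scenes the analyzer is designed for, not
ultrasound physics (no wave simulation): concentric layered circles
(blood 10, neointima 35, wall tissue 45, adventitial band 150, background
25 on a 160² grid at 0.025 mm/px; vessel radius 1.5 mm, 6 frames 0.5 mm
apart), with multiplicative Rayleigh speckle around the local mean —
`speckle_strength` blends between the noiseless mean (0) and full
Rayleigh (1, the default; CV ≈ 0.52, the fully developed speckle limit).
Strut blocks (8 × 16° × 0.15 mm) sit between the scaffold and vessel
contours with mean brightness `230 × Mw / 92.9 kDa`, the linear
brightness–molecular-weight stand-in (a sigmoid is not provided; the
mapping is a modeling device, not a physical law). The degradation cohort
renders one pullback per scaffold per timepoint over the default
nine-point schedule 92.9 → 0 kDa, with per-pullback sub-seeds, random
strut-pattern rotation and ±3 % geometry scaling. Frames within a
pullback share geometry (a straight vessel segment) and differ only in
speckle, which also lets the pipeline cache per-pullback geometry.

Two named scenarios fix the contrast for specific validations and are
deliberately easier than the default conditions:

* `wedge_scenario` — a 120° wedge at grey 15 over the adventitia with
  speckle 0.3, so the adaptive sector screen is dominated by the
  wedge/adventitia contrast: 60 ± 3 of 180 sectors excluded, and the
  screened reference histogram holds < 10 % of its mass below the
  adaptive threshold versus > 25 % for the naive full ring.
* `discrimination_scenario` — staggered layer means (60/110/170/250) and
  speckle 0.2 so the iterated-Otsu high threshold falls between the
  adventitia and the bright structures; per-class recall of
  upper/calcified/unknown then exceeds 90 % (≈ 99 % measured). A
  `noiseless_scenario` variant (speckle 0) makes the strut-block pixel
  count exactly recoverable.

What passing phantom tests do **not** show: performance on real IVUS with
contour inaccuracies, non-Rayleigh compounded speckle, reverberation and
side-lobe artifacts, eccentric catheters, or genuinely ambiguous
dense-tissue shadows. The phantom validates the algorithmic contracts,
not clinical accuracy.

## Numerical and design choices

* All algorithm constants (0.01/0.21 mm ring, 2° sectors, 0.5 mm frame
  spacing and shadow depth, 0.25 shadow fraction) are defaults, exposed in
  `AnalysisConfig`/`ShadowConfig` and serialized with every CLI run.
* Grey levels are 8-bit throughout; thresholds are integers in [0, 255].
* Contours are (row, col) vertex lists, implicitly closed, rasterized at
  pixel centers; self-intersecting or sub-3-vertex polygons are rejected.
* The degradation cohort uses scaled-down pullbacks (6 frames, 160² grid)
  so a 27-pullback cohort analyzes in a few seconds; all contracts are
  resolution-independent and tested at several grid sizes.
* With zero speckle the supra-median strut response is a step function of
  Mw (brightness falls below the adventitial median for the lower half of
  the schedule), which caps the noiseless cohort correlation near
  r ≈ 0.92; realistic speckle grades the response and raises r to ≈ 0.97.
  This is a property of adventitia-referenced thresholding under a convex
  degradation schedule, not an implementation artifact.

## Known limitations

Contours are inputs — no segmentation. Guidewire masks are user-supplied
angular intervals. No DICOM ingestion. Shadow detection is 2-D and
per-component; overlapping shadows from multiple components are labeled
independently. Volumes use the rectangular rule only (no Simpson
variant). The unknown class is restricted to the wall; shadow outside the
wall merely depresses the adventitial reference, which the sector screen
then discards.
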