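# Methods

## Conventions and data model

Images are 2-D arrays indexed `(row, col)`, 0-based. Binary value 0 is
black and marks structure; the black set `K(f)` is the object under
study. Grayscale thresholding blackens `g ≤ t`, so the sublevel-set
filtration darkens as `t` grows. Fluorescence micrographs are
bright-on-dark and must be inverted (`255 − g`) before analysis; the CLI
inverts `.tif/.tiff` input by default and exposes `--invert/--no-invert`
everywhere. RGB input is converted by BT.601 luma, deeper integer types
are rescaled linearly by their type maximum.

Black pixels are modelled as closed unit squares (T-construction). This
forces the connectivity conventions — black 8-connected, enclosed white
4-connected — and is what makes the 8-pixel ring of the worked example a
single component with a single hole. `β1` counts 4-connected white
regions that do not touch the image border.

## Morphology

Opening acts on the white set: a white pixel survives `O_{S_i}` iff some
all-white `(i+1)×(i+1)` window contains it. Pixels outside the frame
count as white, so the image border never seals a structure shut — a
region open to the frame edge is not a hole and stays that way under
opening. The position of the structuring element's origin is irrelevant
(opening is translation-invariant in the element), and the implementation
(separable min/max filters with an explicit anchor correction for
even-sided squares) is tested bit-exactly against a brute-force
window-placement oracle. The square family is a granulometry: openings
are idempotent, black-extensive, and monotone in `i`, which the test
suite asserts as laws.

The opening axis runs `i = 0..20` by default (`max_opening`), matching
the 20-bin size distribution; holes still white after `S_20` carry an
infinite level and are treated as essential classes.

## Persistence engine

Filtrations are integer-valued per-pixel level maps; `INF_LEVEL` marks
pixels outside the filtration. Dimension 0 is union-find over pixels in
increasing level with the elder rule. Dimension 1 uses planar duality:
holes of the black sublevel filtration are components of the white
complement in the superlevel direction, so union-find over pixels in
*decreasing* level — with a virtual node for the unbounded outside,
joined to every boundary pixel — yields each hole's birth (the level at
which it is sealed off from the outside, possibly by another hole) and
death (the level at which its last white pixel turns black). Zero-length
pairs are discarded. Within a level, processing order is arbitrary; the
diagram is level-wise well defined and the contract is the counting
identity

    #{(b,d) : b ≤ t < d} = β_k(sublevel image at t)   for all t, k ∈ {0,1},

which the suite verifies against independent component labeling on
hundreds of random images, alongside translation/rotation invariance and
shift-equivariance in the levels. Diagrams serialize to CSV
(`dim,birth,death`, `inf` for essential) and to Perseus-style text
(`birth death`, `-1` for infinity).

## Features

* `ρ1^{H,i}(t)` divides `β1(X_(t,i))` by the **total** number of
  dimension-1 points of the row diagram, essential pairs included (the
  normalizer is "all points of the diagram"); an empty diagram gives the
  zero curve.
* `D_t` keeps deaths of pairs born exactly at opening index 0 with
  finite death: the 20-bin histogram has no bin for ∞, and the
  connectivity index likewise excludes `(b, ∞)` pairs. Bin `d`
  corresponds to holes removed by `S_d`, i.e. of size about
  `(d+1)×(d+1)`; bins store raw death indices 1..20.
* `C_t` is the finite-lifespan share of pairs born after index 0. A
  column with no finite pairs is *missing* (NaN), propagated and skipped
  by all averaging — no signal is manufactured where there is no
  dimension-1 topology.

## Statistics

Per-image summaries are curve means over fixed ranges: thresholds
100–150 for `ρ` and `C_t`, size bins 5–15 for `φ(D_128)`. The two-sample
test permutes group labels with the difference of group means as
statistic, two-sided, add-one estimator `p = (1 + #{|s*| ≥ |s|})/(1+n)`
— conservative, never zero, deterministic per seed. An exact enumeration
mode over all `C(n_a+n_b, n_a)` assignments serves as the oracle for the
Monte-Carlo mode (and shows the floor for 5v5 is `2/252 ≈ 0.0079`).
Because a Monte-Carlo p-value is seed-dependent, the protocol repeats
the test over consecutive seeds (default 100 repeats × 1000 rounds) and
reports mean ± std. Undefined per-image summaries are dropped with a
logged warning rather than imputed. Type-I error at α = 0.05 is verified
to sit in [0.02, 0.09] over 500 null simulations. No multiple-testing
correction is applied across features; p-values are reported per
feature.

## Synthetic phantoms

The generators emulate the two morphology classes, not a microscope:

* **network** — bounded-curvature random-walk filaments (default 12
  walks, ~2.2×size steps, 3 px thick, reflecting at the frame) rendered
  dark; walks cross and run close to one another, so the black set forms
  loops and near-loops whose narrow mouths are sealed by small openings.
* **fragmented** — small disks (default 150 spots of radius 2 px)
  scattered uniformly; mostly isolated at the default density.

Both are rendered with foreground intensity 110 on background 200,
Gaussian blur σ = 1 px and Gaussian noise σ = 20 before clipping to
0..255, and are bit-deterministic per seed; ground-truth masks are
returned alongside. The intensity levels were chosen so that the
100–150 summary band straddles the structure intensity: thresholds in
that band binarize the structure while intensity noise creates small
transient holes, as in real data. Default image size is 256², which
keeps a full per-image feature run (3 rows + 51 columns) around five
seconds.

With these defaults the classes separate as intended: opening-born hole
lifespan dominates in the network class (mean `C_t` over 100–150 around
0.6) and threshold-born speckle dominates in the fragmented class
(around 0.1), and 5v5 permutation tests on `ρ` rows 3/5 and `C_t`
saturate the 5v5 significance floor. What the phantoms do **not**
emulate: PSF shape, shot noise, intensity gradients, out-of-focus
structure, and realistic spot/tubule size mixtures — in particular the
size-distribution summary (`φ` bins 5–15) does not separate these
phantoms, since neither class places much hole mass at sizes 6–16 px.
Passing phantom tests therefore demonstrates the pipeline's mechanics
and the features' discriminative design, not performance on real
micrographs.

`make_known_betti_image` lays out disjoint 7-px-high rectangles with
3×3 interior holes distributed round-robin, ≥2 px separation and a white
margin, giving arbitrary `(β0, β1)` by construction for oracle tests.

## Numerical choices and edge cases

* Integer levels throughout; `INF_LEVEL = 2^31 − 1` is the internal
  essential marker, never exposed (public output uses `inf`).
* Ties within a level: any stable order; diagrams depend only on levels.
* Empty inputs: all-white images yield empty diagrams and missing
  features; `threshold` rejects `t ∉ [0,255]`; bifiltration indices are
  range-checked.
* Horizontal maps evaluate openings only at intensities present in the
  image (the opening is constant between them); members are memoized —
  a dense 256×21 binary stack is never materialized.
* The dimension-0/1 kernels are numba-compiled at first use (pure-Python
  fallback if numba is unavailable).

## Limitations

Strictly 2-D (no z-stacks); axis-aligned paths through the bifiltration
only (no diagonal/staircase paths); squares are the only structuring
elements; features are resolution-dependent through the pixel-sized
structuring elements, so images compared against each other should share
acquisition scale.
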