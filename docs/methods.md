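# Methods

`zfscreen` classifies brightfield images of individual zebrafish larvae into
a multi-label vocabulary of 11 phenotype terms and turns per-concentration
phenotype counts into toxicological dose-response estimates. This note
documents the model, its assumptions, the tunable parameters, the synthetic
data used for validation, and the numerical choices made where the design
was genuinely open.

## Localization and cropping

Raw images are assumed to contain exactly one dark animal on a bright,
roughly uniform background. Localization is purely morphological:

1. grayscale conversion by unweighted channel mean (the animal is dark in
   every channel, so no luminance weighting is needed);
2. a neighborhood **variance filter** (radius 2 px by default) that turns
   object edges into bright ridges; the border ring where the window does
   not fit is zeroed;
3. **Otsu global thresholding** of the variance image;
4. two **3×3 binary dilations** to close the outline;
5. the largest **8-connected component** is taken to be the larva (ties on
   area break to the smallest bounding-box origin, for determinism);
6. a **square crop**: regions with bounding-box aspect ratio ≤ 1.2 (the
   circular case — chorionated or dead embryos) get their tight bounding
   square; elongated larvae get a square of side max(h, w) centered on the
   box. Near an image border the square is clipped to a rectangle, but the
   crop always contains the full detected bounding box.

The variance radius, dilation count and circularity cutoff are explicit
knobs (`CropParams`); the defaults above were chosen once from the geometry
of the problem, not fitted. Coordinates are 0-based half-open throughout.

## Subwindows and the TRGB encoding

An image is represented by `n_subwindows` square crops at uniform random
positions, with side length uniform on `[min_frac·m, max_frac·m]` where `m`
is the smaller image dimension. Squares relative to the min dimension avoid
anisotropic distortion; images are near-square after cropping anyway. Each
subwindow is resized bilinearly (pixel-center alignment, edge-clamped) to a
fixed 16×16×3 patch and standardized per RGB channel: subtract the channel
mean, divide by the channel *population* standard deviation; a constant
channel maps to zeros. The result is a 768-attribute vector in channel-
planar order (all R, then G, then B), which makes spatial neighbor indexing
inside a channel plane well defined. The patch is 16×16 because 768 total
attributes is the configuration under which K = 28 (≈ √768) is the standard
candidate-test count for color images; both values are module constants.

TRGB makes descriptors invariant to per-channel affine illumination changes
(verified by property test). Each image draws its subwindows from an RNG
substream derived from `(seed, image id)`, so per-image features do not
depend on processing order.

Defaults: `n_subwindows = 1000` per image, size range `0.5–0.95`. The large
default range reflects that most of the phenotypes here are whole-body
morphologies (curvature, tail length); a tuning grid (below) exists for
choosing the range per defect when budget allows.

## Extremely randomized trees

The classifier core is an ensemble of T extremely randomized trees over the
768 attributes. At each node, K candidate tests are drawn; each test picks
its attribute uniformly at random and its threshold uniformly in the open
interval between the node-local minimum and maximum of the tested quantity,
which guarantees a non-degenerate split. Two test families exist:

* **SIMPLETHRES** — threshold a single attribute (one pixel value);
* **DIFFNEIGHBOR** — threshold the difference between an attribute and one
  of its up-to-8 spatial neighbors in the same channel plane (edge pixels
  have fewer neighbors). Differences cancel constant channel offsets.

The best of the K candidates by **normalized Shannon information gain**,
`2·I(C;S) / (H_C + H_S)`, is kept; ties go to the first-drawn candidate. A
node becomes a leaf when it is smaller than `N_min`, class-pure, or no
non-degenerate test exists (certainty about the last case is obtained by an
exhaustive scan after 64 failed random draws). Leaves store raw class
counts; probabilities are computed lazily. Leaf ids are numbered
contiguously across the ensemble so they double as a bag-of-visual-words
vocabulary. Trees are grown on independent RNG substreams spawned from the
ensemble seed, so any growth schedule reproduces the same forest; models
serialize to versioned, diff-able JSON.

Defaults: T = 10, K = 28, `N_min` = 1 in C mode and 1000 in BAGS mode (the
recommended values for the two modes). The exact gain normalization is a
documented knob: only the criterion family, not its constant, affects
ranking in practice.

## Image-level decision modes

* **C mode** (direct voting): every subwindow is propagated through every
  tree; the image-level class distribution is the flat average of leaf
  class-frequency vectors over all (subwindow, tree) pairs; the argmax wins,
  ties broken by class order. The implementation is exactly this average
  (oracle-tested to 1e-12) and is invariant to subwindow order.
* **BAGS mode** (bag of leaves): the image descriptor counts how often its
  subwindows reach each leaf, normalized per tree by the subwindow count so
  each per-tree block sums to 1 and descriptors are image-size independent
  (raw counting is available as a flag). A linear SVM (C = 1.0,
  squared-hinge, one-vs-rest, primal solver for determinism) classifies the
  descriptor. Test-time subwindows use the training sampler parameters.

A practical scale constraint: with `N_min = 1000`, BAGS trees only split
while nodes hold ≥ 1000 subwindows, so the *total* number of training
subwindows (images × subwindows/image) must comfortably exceed `N_min` or
every tree collapses to a single leaf and descriptors carry no information.
The study drivers keep this product in the tens of thousands.

## Binary models, tuning, and the two-tier pipeline

Each phenotype term gets a one-vs-rest binary model trained on a balanced
sample: the majority side is undersampled to the minority size, seeded, and
**stratified** round-robin over the majority side's distinct label sets.
Stratification matters for the "Normal" model, whose negative class is the
union of all defects: a plain random undersample can nearly omit a defect
class and blinds the model to it. "Normal" is a directly trained model, not
the complement of the other calls — complementing accumulates the other
classifiers' errors. "Up Curved Tail/Fish" is likewise trained as its own
model rather than derived from its two constituents.

Hyperparameters (mode C/BAGS, subwindow size range, test family) are chosen
by randomized cross-validation: per grid point, `n_runs` random 2/3–1/3
splits of the task images, mean held-out accuracy, argmax with ties to the
first grid point. `n_runs` defaults to 25 (midpoint of the 5–75 range that
stabilizes such estimates), and all split draws are seeded.

The deployed classifier is **two-tier**. "Dead" and "Chorion" are exclusive
of all other terms, so a three-class gate (Chorion / Dead / Others) is
trained on the full learning set first; the per-defect binary models are
trained only on Dead/Chorion-free images. At prediction time a Dead or
Chorion gate call short-circuits to a singleton label set; an "Others" call
runs all nine remaining binary models and returns the union of positive
calls, closed under the curvature disjunction (Up Curved Tail or Fish ⇒
Up Curved Tail/Fish). An empty union is allowed and flags the image
unclassified. Gate misrouting between Dead and Chorion is accepted as-is;
there is no second-chance routing.

Per-defect confusion matrices over a test set account for gate carry-over:
an image wrongly gated out of "Others" is a false negative for every defect
it truly carries; an image wrongly gated in is scored by its binary calls;
Dead and Chorion themselves are scored from the gate decision. By
construction TP+FP+TN+FN equals the test-set size for every defect
(oracle-tested against an exhaustive per-image tally).

## Dose-response readout

For each concentration the survival fraction is `1 − dead/n` and the
teratogenicity response among survivors is `1 − normal/surviving`
(undefined, and dropped from the fit, where no embryo survives — which is
also why meaningful plates need doses below full lethality). Both responses
are fitted as increasing four-parameter log-logistic curves on log10
concentration:

    f(x) = bottom + (top − bottom) / (1 + 10^(hill·(log10 X50 − x)))

with asymptotes bounded to [0, 1], Hill slope positive and free, and the
control (concentration 0) mapped to a pseudo-log floor two decades below the
lowest dose. The fit is weighted least squares with binomial standard
errors per point (continuity-corrected so observed fractions of 0 or 1 keep
finite weight, `absolute_sigma`), solved by `scipy.optimize.curve_fit` from
up to three starting points; a fit that still fails returns NaN estimates
alongside the raw fraction table. LC50 is the survival-curve midpoint, EC50
the teratogenicity midpoint, and the teratogenicity index TI = LC50/EC50 —
exactly, since log10 TI is computed as the difference of the fitted log
midpoints. The standard error of log10 TI is the delta-method combination
`√(SE²_LC50 + SE²_EC50)` of the two independent fits. When a curve's
midpoint lies outside the tested dose range (a common situation for
teratogenicity, which can saturate below the lowest dose), its SE is
honestly large; recovery is then reported relative to that SE rather than
absolutely.

## The synthetic generator

The renderer is parametric-geometric, not learned, so labels and pixel
masks are exact by construction. A larva is an integrated-heading spine
(head at the left, mild pose jitter) with a tapering width profile, head
disk, eye and yolk ellipse, painted dark on a bright background with a mild
horizontal illumination gradient and Gaussian pixel noise (σ = 3 by
default). Classes modulate disjoint parameter ranges: tail bend −65…−40°
(down-curved) or +40…+65° (up-curved), whole-body arc 35…55° (up-curved
fish), tail length 40–55 % of normal (short tail), a near-black speckled
yolk (necrosis), a large pale halo at the anteroventral region (edema), a
saturated red pericardial spot (hemostasis), an irregular dark round mass
(dead), or a dark ring with a curled embryo inside (chorion — deliberately
near-circular so it exercises the circular-crop branch). Normal jitter
bands (±8° tail, ≤8° arc) sit well inside the defect thresholds (±30°,
25°), so ground-truth labels are unambiguous.

Plates simulate a toxicological run: at each concentration every embryo
dies with the survival-curve probability; survivors are abnormal with the
teratogenicity-curve probability, the defect drawn uniformly among the
non-lethal defect classes. The default plate emulates a caffeine-like
exposure — doses 0, 0.5, 1, 3, 5, 7 mM, 25 embryos per dose, true
log10 LC50 = 0.82, log10 EC50 = −0.9, steep lethality (Hill 6) and shallow
teratogenicity (Hill 1.5). Images can be rendered per embryo, but
label-level studies (curve recovery) skip rendering.

What the generator does *not* emulate: real optical texture, methylcellulose
artifacts, reflections, debris fields, focus variation, or the genuine
ambiguity of subtle phenotypes. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline and its statistical
machinery — not field performance on acquired images, which depends on
expert-annotated training data.

## Study sizes used in validation

The built-in end-to-end study uses all 11 classes with 40 training and 20
test images per class (disjoint generator streams tagged as separate
acquisition sessions), 100 subwindows per image, BAGS mode with the default
tree parameters; localization is validated on 200 images including
near-border placements; curve recovery uses 100 replicate 150-embryo
plates. These sizes were chosen as the smallest at which the BAGS
subwindow-count constraint above is comfortably met and binomial noise on
reported rates stays a few percent.

## Known limitations

* Single-animal assumption: multi-larva wells and overlapping debris larger
  than the animal defeat the largest-component rule.
* BAGS degenerates silently when images × subwindows approaches `N_min`;
  prefer C mode at small scale.
* The SVM layer reports margins, not calibrated probabilities.
* EC50 estimates extrapolate when teratogenicity saturates below the lowest
  tested dose; only the (large) reported SE signals this.
* The curvature disjunction is enforced on outputs in one direction only
  (constituents imply the joint term); a positive joint call with both
  constituents negative is kept as the model's own call for Table-style
  per-defect scoring.
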