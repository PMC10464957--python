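# Methods

## Problem and scope

`reddmap` maps salmonid spawning redds — dark, irregular patches of
cleaned gravel — in single RGB images taken by a UAV over lake spawning
grounds. The pipeline is pixel-based by design: every pixel is assigned to
one of K analyst-defined endmember classes from its three band intensities
alone, then spatial filters repair isolated misclassifications, and the
map is scored against ground-truth pixels. There is no object-based
segmentation, no georeferencing math (GeoTIFF geo-tags are passed through
opaquely), and no photogrammetry.

## Conventions

All modules share one spatial convention: 0-based `(row, col)` pixel
coordinates, row 0 at the top. ROI files that store `(x, y)` (GeoJSON) are
converted on read. Polygon ROIs are rasterized by pixel-centre
containment. Intensities are linearly rescaled to [0, 1] by the declared
bit depth (8- or 16-bit) before any statistics or classification, so
imagery from different cameras behaves identically. Label 0 is reserved
for "unclassified" everywhere.

## Training statistics

Each class's mean vector is the arithmetic band mean over its training ROI
pixels; the covariance is the unbiased (n−1) sample covariance — the
standard remote-sensing estimator. At least 4 pixels per class are
required (a 3×3 covariance is not estimable below that); classes with a
singular covariance (e.g. constant-colour training sets) are flagged and
regularized at classification time. A balance check reports per-class
counts and warns — advisory only — when the max/min ratio exceeds 2,
since heavily unequal training classes bias the classifier; the threshold
is a judgement call, as "similar counts" has no canonical number. The
intended sampling design is ~15 training samples of ~65 pixels per class
(~975 px), with a ground-truth set of similar size selected from
*different* pixels; training/ground-truth overlap is a hard error.

## Maximum-likelihood classifier

Pixel x goes to the class maximizing the Gaussian log-discriminant
g_c(x) = ln π_c − ½ ln|Σ_c| − ½ (x−μ_c)ᵀ Σ_c⁻¹ (x−μ_c). Choices:

* **Priors** π_c are equal by default — the classification should be
  driven by spectra, not by assumed class areas.
* **No probability threshold** by default: every pixel is classified. With
  a threshold t ∈ (0, 1), pixels whose best-class posterior (softmax over
  the discriminants) falls below t become unclassified.
* **Regularization**: singular covariances get a ridge of
  `eps · trace(Σ)/3` on the diagonal (eps = 1e-6, floored at eps when the
  trace is zero). This makes constant-colour classes usable and, in the
  equal-ridge limit, reduces MLC to nearest-mean classification.
* **Ties** break to the lowest class id (argmax convention); exact ties
  have measure zero on real imagery.

## Neural-network classifier

A multilayer perceptron with 3 inputs, one logistic hidden layer and K
logistic outputs, trained full-batch on one-hot targets. Defaults follow
the established settings for this application: logistic activation,
training rate 0.2, momentum 0.9, training threshold contribution 0.9, RMS
exit criterion 0.1, one hidden layer, 1000 iterations. Interpretations
this implementation fixes (the settings name values, not mechanisms):

* **Objective and step size.** The monitored loss is the RMS output
  error, so the descent direction is the gradient of the *mean* squared
  error: Δw(t) = −rate·∇E + momentum·Δw(t−1) with E averaged over
  training pixels and output units. Averaging makes the step size
  independent of training-set size; the summed-gradient alternative
  saturates all logistic units at realistic training sizes (thousands of
  pixels) and learns nothing.
* **Threshold contribution** multiplies the bias-weight updates by 0.9 —
  bias ("threshold") weights adapt slightly slower than connection
  weights. This is an interpretation of the conventional parameter name,
  documented as such.
* **Batch updates** (not per-sample) keep training deterministic and
  vectorizable; given the same seed, retraining is bit-identical.
* **Width**: hidden units default to K; **init**: uniform [−0.05, 0.05]
  from the seeded generator; **ties** in the output argmax break to the
  lowest class id; a non-convergent run returns the model with a warning
  after `max_iterations`, never hangs.

**Known limitation.** At the default 1000 iterations the net underfits a
6-class scene of ~5850 training pixels: training RMS is still ≈ 0.31 and
the smallest, darkest class (spawning redds) tends to be absorbed by deep
water. The RMS exit (0.1) is reached around 4000 iterations, at which
point per-class training accuracy is 100%. The defaults are kept because
they are the method's stated settings; users wanting a competitive NN on
scenes of this complexity should raise `max_iterations` (or `rms_exit`).
Batch logistic-MSE descent is simply slow from small symmetric-breaking
initial weights — consistent with maximum likelihood outperforming the
neural net in practice on this task.

## Post-classification operators

Applied in the order majority → sieve → clump (configurable; the operators
do not commute):

* **Majority/minority filter** (kernel 3, centre weight 1): each pixel
  takes the label with the largest vote in its kernel window, the centre's
  own label counted `center_weight` times; windows are clipped at borders.
  Tie rule: if the centre's label is among the winners it keeps it,
  otherwise the lowest class id wins. `center_weight ≥ kernel²` makes the
  filter the identity. Minority mode flips to the least-voted present
  label instead.
* **Sieve** (4-connectivity, minimum size 2): connected components are
  computed per class; components below the minimum size become
  *unclassified* (not reassigned to a neighbour) — this is the documented
  source of stray label-0 pixels in otherwise fully classified maps.
  "Minimum size two" removes exactly the singletons.
* **Clump** (size 3): per class, a morphological closing (dilate then
  erode) with a size×size *square* structuring element, masks padded with
  background. Classes are processed in descending pixel-count order
  (ascending id on ties); pixels gained by a closing adopt the class only
  where the input map holds 0 or an already-processed class, and a pixel
  changed once is never changed again — a deterministic precedence rule
  for the inter-class conflicts the operator definition leaves open.

The irregular shape of Arctic-charr redd clusters motivates these exact
parameter values; more regular spawning grounds would warrant re-tuning,
which is why every parameter is exposed.

## Accuracy assessment

The confusion matrix is (K+1)×K: rows are predictions with row 0 for
unclassified pixels, columns are true classes, so column totals equal the
per-class ground-truth ROI sizes. OA = trace/N with N the grand total
including unclassified predictions. Kappa uses
p_e = Σ_c row_c·col_c / N² over the K named classes only — the
unclassified row has no matching column and contributes no chance-
agreement term, but its pixels stay in N and in row totals. This
convention reproduces the published reference matrices' κ values exactly
(0.89/0.84/0.87/0.77 at 2 decimals). Kappa may be negative for
below-chance agreement; it is reported as-is even though thematic-mapping
practice usually describes it on a 0–1 scale. PA/UA for an empty
column/row are undefined (NaN with a warning), not zero. Display rounding
is half-up at 2 decimals, matching how such tables are printed.

## Synthetic scenes

`generate_scene` emulates the *structure* a redd-mapping pipeline relies
on, not any real lake's optics:

* horizontal zone bands (defaults: land 25%, shoreline 10%, shallow 40%,
  deep 25% of image height);
* redds as unions of 5 jittered discs per blob (20 blobs, radii 5–12 px,
  irregularity 0.5 — the jitter fraction of the radius), confined to the
  shallow zone; surface rocks likewise on land/shore;
* per-class Gaussian colour models (dark grey redds, green vegetation,
  light grey-cyan substrate, dark blue deep water, pale shoreline,
  yellow-brown surface rocks; sd 0.01 per band) plus global sensor noise
  (sd 0.02 in [0, 1] units), clipped and quantized to 8 bits;
* training (975 px/class) and ground-truth (1000 px/class) ROIs sampled
  without replacement from class interiors (1 px from borders, mimicking
  analyst-picked interior polygons), pixel-disjoint by construction —
  mirroring the ~15 × 65 px survey design.

Generation is pure given (config, seed). `corrupt_labels` applies
independent per-pixel label flips to uniformly random *other* classes —
the salt-and-pepper "spurious pixels" the cleanup chain targets.

What passing tests on these scenes shows: the estimators, classifiers,
operators and metrics are correct and the pipeline plumbing is sound. What
it does not show: performance on real drone imagery, where water-surface
reflection, ripples, turbidity, shadows and spectral overlap between redds,
aquatic vegetation and deep water make the problem genuinely hard; the
synthetic colour models are deliberately well separated (at the default
noise the maximum-likelihood map is near-perfect). Classifier skill claims
about real lakes must come from real ground truth.

## Problem sizes

Default test and acceptance runs use 512×512 scenes (~0.26 Mpx, seconds
per full pipeline run on one CPU) and 128–192 px scenes for stage-level
tests; the classifiers are vectorized over pixels, so megapixel
orthophotos scale linearly in time and memory.

## Known limitations

* Pixel-based only; no texture, context or object features beyond the
  three cleanup operators.
* The NN's "threshold contribution" semantics are an interpretation (see
  above); other software may implement the same-named parameter
  differently.
* Kappa conventions vary across software in how unclassified pixels enter
  p_e; the convention here is fixed by exact agreement with the reference
  matrices and documented above.
* GeoTIFF geo-tags are passed through but never interpreted; area
  estimates are in pixels, and converting to m² is the user's
  ground-sampling-distance calculation.
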