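# Methods

## Scope and data model

All rasters are 2-D with (row, col) pixel coordinates, 0-based, origin
top-left. A *boundary map* is binary: nonzero pixels are "marked"
(membrane), zero pixels "blank". A *segmentation* is an integer label
raster in which 0 means "not scored"; Rand-type measures exclude label-0
pixels from pair counting.

## Multi-scale fused boundary detection

The pyramid uses the separable 5×5 binomial kernel (1,4,6,4,1)/16 and
decimation by 2; level sizes round up (`a[::2]`), and an image must keep
a minimum side of 8 px at the coarsest level. LoG responses are computed
as a Gaussian blur at σ (default 1.0 per level — scale separation is
carried by the decimation, not by σ) followed by the 4-neighbour
Laplacian, with reflective padding.

Zero-crossing localisation: a 4-neighbour pair with opposite response
signs is a crossing; it is kept when the response difference across the
pair exceeds `grad_thresh` (default 0, i.e. ungated), and the
**positive-response pixel** of the pair is marked. For a dark band on a
bright background the Laplacian is positive inside the band, so the
mark lands on the membrane itself. The obvious alternative — marking
the pixel nearer the sub-pixel zero, i.e. the smaller-|response| one —
systematically places about half the marks on the bright cytoplasm side,
one to two pixels off the membrane, which contradicts the requirement
that detected pixels sit at the actual boundary centres; we therefore
use the sign rule. The outermost 1-px frame is never marked (it only
carries padding artefacts).

Coarse-level maps are upsampled by nearest-neighbour block replication
and dilated once with a 3×3 element, absorbing the ~1 px positional
drift between adjacent scales; level 1 is passed through unchanged.
Fusion weights default to resolution-proportional values normalised to
sum 1 (w ∝ 2^−(i−1): 4/7, 2/7, 1/7 at three levels), with α = 1,
β = 0 and threshold 0.5·α; marking uses ≥ (the printed inequality in
the voting rule is `<` for the negative case). With these defaults a
detection at the finest level alone (vote 4/7) carries the pixel, while
coarse-only votes (3/7) do not — the finest level decides location,
coarser levels only corroborate.

Noise behaviour: added image noise *creates* zero crossings, so with the
ungated default the detected set grows with noise and tolerant recall of
the true centerline can only rise. Degradation of detection by noise is
observable once crossings are gated; the packaged experiment uses
`grad_thresh = 0.15` and strict (0-px tolerance) recall, under which the
median recall over 10 phantoms is non-increasing across noise σ ∈
{0, 0.05, 0.15}.

## Curve-shape fitting

Segments are traced back from an open endpoint along marked
8-neighbours, stopping at branch points, up to 15 px (`neighborhood`),
and the 2 px nearest the gap (`ignore_near_gap`) are dropped as
unreliable; at least `theta_dim` points must remain. Near-vertical
segments have x and y exchanged (ties toward no swap) so the arm stays
function-like; the flag is stored on the model and undone transparently
when distances are evaluated in image coordinates.

The polynomial model (3 coefficients = quadratic, per the default θ
dimension) is learned by per-sample gradient descent on the squared
vertical residual, `θ ← θ + α (y − Gθ) G`, α = 0.1, cycling the traced
points farthest-first for up to 10 passes (instant mode) or in mean
batches of 5 (batch mode), stopping early when a full pass moves no
coefficient by more than 0.001.

Conditioning matters more than pass count: internally x is rescaled to
[0, 1] and y is centred and divided by the *same* span (so slopes stay
dimensionless and geometry is preserved), and the coefficients are
mapped back afterwards by polynomial composition. Without the ordinate
normalisation, image-coordinate intercepts of order 100–250 consume the
entire 10-pass budget on the constant term and the extrapolated curve —
which is always evaluated *beyond* the fitted range, since the gap lies
past the endpoint — veers by many pixels. With it, ten passes suffice
for the near-straight arms the walker actually encounters; given enough
passes the descent converges to the normal-equations least-squares
solution (verified to 1e-2 coefficient-wise in the tests, and the
summed squared residual is non-increasing pass over pass). The fit is
fully deterministic.

The per-point fit cost is the absolute vertical distance in the
oriented frame; an exact Euclidean point-to-curve distance is not used
because the descent is linear in the vertical form only.

## SARSA(λ) curve traveling

States are pixel positions, actions the 8 king moves. Q and the
eligibility trace e are sparse tables defaulting to 0. One backup is

δ = r + γ Q(s′, a′) − Q(s, a);  e(s, a) += 1;  Q += α δ e;  e ← γλ e,

with α = 0.1, γ = 0.95, λ = 0.9 (λ = 0 reduces exactly to one-step
SARSA; traces are pruned below 1e-12). Terminal states contribute
Q = 0.

Rewards follow the marked/blank rule — +1 (gain) on a marked pixel,
−10 (gap penalty) on a blank one — minus two shaping terms:

* `model_weight` (1.0) × the candidate pixel's fit cost against the
  curve model: the walk follows the curve's trend;
* `target_weight` (0.5) × the candidate's distance (Euclidean distance
  transform, computed once per gap) to the marked pixels *outside* the
  walker's own arm: the walk is drawn onto the opposite curve.

The second term realises the stated goal of minimising the connection
cost. It is deliberately weaker than the model term so that the
"connect to the nearest point" failure mode — attaching to a nearby but
wrong curve and corrupting the topology — stays suppressed; it is what
lets a track that extrapolates ~2 px parallel to the far arm actually
touch it, and it gives model-less stubs (arms too short to fit) a
sensible direction.

Action selection is ε-greedy (ε = 0.1, ×0.95 per episode) over
`Q(s, a) + shaped_reward(candidate)`. The one-step lookahead is
essential at the default single episode: a zero-initialised Q alone
would make the first walk uniform-random. Moves onto the walker's own
traced arm, off the canvas, or onto any already-visited pixel are
illegal (the arm exclusion prevents the trivial "success" of stepping
backwards onto one's own curve; the no-revisit rule prevents loops).

An episode ends in success when a marked pixel outside the arm is
reached, and in failure on dead ends, on step counts exceeding
`maximal_step` (default 40 × max_gap_len = 600), or when the chosen
action's Q drops below `q_threshold` (default −100, roughly ten
consecutive blank steps). Returning to the start is subsumed by the
no-revisit rule. On success the committed connection is a deterministic
walk greedy on the shaped immediate reward — not the exploratory
trajectory (whose ε-detours would be written into the map) and not a
greedy-on-Q rollout: after a single episode of negative blank rewards,
every (s, a) pair actually visited scores *below* the unvisited ones,
so a greedy-on-Q walk is repelled from the very path that succeeded.
The exploratory path is the fallback when the greedy walk fails, and
any committed path longer than 2 × max_gap_len is rejected as a
non-credible connection (a genuine closure needs at most ~max_gap_len
king steps). Q is reset per gap; nothing is transferred across gaps or
images.

The driver iterates endpoints in raster order. Per endpoint it traces
the arm, estimates the gap length as the king-move (Chebyshev) distance
to the nearest marked pixel of a different arm — the walker's own step
metric, under which a gap of g missing pixels has length ~g+1
regardless of orientation — and skips gaps longer than `max_gap_len`
(default 15, matching the amending neighbourhood). Passes repeat until
a pass closes nothing, an endpoint being retried only after the map has
changed: a closure that joins the opposite curve mid-arm leaves a short
stub endpoint that a single pass would strand. Marked pixels are never
removed, and a map without endpoints passes through unchanged. The
whole procedure is deterministic for a fixed (map, configs, seed).

## Evaluation metrics

* **Precision / recall / F**: pixel-level confusion counts; a zero
  denominator yields 0 (with a logged warning) rather than NaN so macro
  averages stay defined.
* **Pixel error**: 1 − max F over binarisations `pred > t`, t drawn
  from the distinct predicted values plus {0, 1}; for a binary
  prediction this is exactly 1 − F of that prediction.
* **Rand index / error**: regions are 4-connected components of
  non-boundary pixels (boundary pixels get label 0 and are excluded
  from pairs); the index is computed by pair counting
  (`sklearn.metrics.rand_score` backend) and the tests verify it
  against exhaustive O(n²) enumeration.
* **Warping error**: the reference is greedily deformed onto the
  candidate by flipping *simple points* — pixels whose flip preserves
  both the foreground (8-adjacency) and background (4-adjacency)
  component structure, decided by a precomputed 256-entry lookup table
  over the 3×3 neighbourhood — each flip targeting a disagreeing pixel
  (so the Hamming distance falls by 1), sweeping in raster order until
  no flip is possible. The residual normalised Hamming distance is the
  error. The warping mask is the whole image. Pure boundary jitter
  (e.g. a ring shifted by 1 px) warps to error 0; splits and merges
  cannot be removed. Greedy descent is a relaxation: it could in
  principle stop above the true optimum over all admissible warpings,
  which is acceptable because every property asserted about it (upper
  bounds, identity, topology preservation) holds regardless.
* **Macro averages**: unweighted arithmetic means across images.

## Phantom generator

The generator emulates the features of ssTEM neuropil that this
pipeline is sensitive to: bright cytoplasm compartments (background
0.85), dark membranes (intensity drop 0.6), organelle clutter (dark
ellipses, 0.15 per 1000 px², axes 1.5–4.5 px, placed strictly inside
cells), and additive Gaussian noise (default σ = 0.1), clipped to
[0, 1]. Cells are a Voronoi partition of uniformly sampled seeds with a
minimum-separation rejection rule (0.5·√(area/n)); membranes are
rendered at constant width (default 3 px) by thresholding the distance
transform of the label-change centerline — thresholding the
(d₂ − d₁) ridge function instead would make membranes widen far from
the seed pair. The ground-truth centerline is the morphological
skeleton of the membrane band, thinned on a replicate-padded canvas so
border-terminating membranes keep their border contact (thinning
retracts free line ends; a retracted skeleton no longer separates its
two cells). A canvas must offer at least 64 px² per cell.

Gap injection removes disjoint runs of interior curve pixels (every
removed pixel and both flanking pixels have exactly 2 marked
neighbours), so each gap creates exactly 2 endpoints; distinct gaps
keep ≥ 5 px apart; lengths are uniform on the requested range.
Everything is reproducible from the seed.

What the phantoms do *not* model: real EM texture (ribosomes, vesicle
fields), membrane contrast variation, staining artefacts, section-to-
section deformation, and junction-dense neuropil where membranes run
closer than the amending neighbourhood. Passing the packaged tests
therefore demonstrates the mechanics and the topology-repair behaviour
of the pipeline, not benchmark-grade performance on real ssTEM data;
the `evaluate` harness exists so that users with the real 30-section
benchmark can measure the latter themselves.

## Problem sizes and experiment conditions

The packaged experiments use 256×256 phantoms with 12 cells and noise
σ = 0.1 (50 phantoms with 8 gaps of 3–10 px each in the test suite, 30
in the acceptance script; the end-to-end pipeline section uses 5), and
128×128 6-cell phantoms for the noise-monotonicity experiment. These
sizes keep every stage exact — no algorithmic shortcuts depend on them.

On these conditions the amendment closes ≈ 85–90 % of injected gaps
under the committed-path quality gate and lowers the Rand error on
every phantom batch tried (typically from ~10–25 % degraded to ~0.1–2 %
amended), while pixel-level scores move little — the expected signature
of repairing topological defects. The end-to-end pipeline numbers on
noisy phantoms show a high pixel error: the detector marks band edges
within ±1–2 px of the 1-px centerline truth plus noise-induced
crossings (ungated default), and pixel error counts exact coincidences
only. This is precisely the over-sensitivity to small displacements
that motivates evaluating with Rand and warping error instead.

## Known limitations

* The warping-error descent is greedy (see above); exact minimisation
  over all topology-preserving warpings is combinatorial.
* A single learning episode (the default) gives the walker one attempt
  per gap; gaps in border pockets or with strongly curved arms can fail
  (observed failure modes: the walker walls itself in between its own
  arm and the canvas edge, or the quadratic extrapolates away from a
  high-curvature arc). Raising `episodes` helps marginally.
* `amend` on a dense, noisy *detected* map (as opposed to a degraded
  ground-truth map) spends most of its time rejecting spurious
  endpoints created by noise speckle.
* Axis orientation is a binary swap; arms near 45° with strong
  curvature are fitted in whichever frame, with no rotated (principal-
  axis) alternative.
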