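# Methods

This note documents the models, defaults and numerical choices behind
`rppkit`, and what its synthetic tests do and do not demonstrate about real
histological material.

## Radial porosity profiles

A mid-diaphyseal cross-section is represented as an integer class raster
(background 0, primary bone 1, primary vascular space 2, medullary cavity 3,
remodelled/secondary bone incl. CCCB 4, OCL 5, EL 6) with a physical pixel
size. Secondarily enlarged primary canals without secondary deposition are
class 2 by annotation — the package does not infer that distinction.

A measurement sector is bounded by two borders following the inner and outer
posthatching-cortex surfaces and two roughly radial sides. Quadrants a..d
(a innermost = oldest) arise by splitting each radial side at arc-length
fractions 1/4, 1/2, 3/4 — equal *arc* length, since sides may curve — and
joining corresponding split points. The joining curves blend the arc-length
parameterized inner and outer boundaries at fraction t and are warped
linearly so their endpoints coincide with the side split points; at t = 0 and
t = 1 they reduce exactly to the boundaries, so the four quadrant polygons
partition the sector exactly at polygon level (straight-chord separators are
available as a fallback). Quadrant a is defined as the quadrant adjacent to
the inner boundary regardless of input vertex orientation; flipped polylines
are re-oriented on construction.

Raster integration uses the pixel-centre rule: a pixel belongs to a polygon
iff its centre lies inside; areas are `count × pixel_size²`. This is
deterministic and unbiased in expectation for randomly placed structures,
with only O(perimeter) fluctuation. Coordinates are (x = column, y = row),
origin top-left.

Porosity per quadrant is `100 · V / (Q − E)` where E collects remodelled
bone, OCL and EL inside the quadrant (plus any non-cortex pixels). Excluding
OCL/EL from the denominator is the default and can be toggled
(`excluded_classes`), since treatments differ in whether lamellar boundary
layers are removed from the sampled area or merely not analysed. A quadrant
is reported missing when the excluded fraction exceeds 0.5
(`missing_threshold`, configurable) — the primary record is mostly or wholly
obliterated — mirroring how perimedullary remodelling deletes inner-cortex
information. The mean RPP averages each quadrant over the sectors where it is
present (available-case averaging; an entry is missing only if missing in
every sector). A trajectory with at least two of four points is analysable.
OCL and EL relative thicknesses are *area* percentages of the total cortex
area sampled by the sectors, not radial-thickness ratios.

Age from mass inverts the hatchling growth line `mass = 9.61 + 5.63 · age`
(grams, days posthatching) fitted for hoatzin chicks; masses at or below the
9.61 g intercept are rejected. The minimum-sample-size rule for d-parameter
clustering returns 2^d. (The worked examples sometimes quoted alongside this
rule — 32 and 64 elements for four and five quadrants — correspond to 2^5
and 2^6 and disagree with the stated formula; the implementation follows the
formula and surfaces the discrepancy here.)

## Synthetic sections

`generate_section` draws an annulus (default cavity radius 80 px, cortex
thickness 160 px) and fills the primary zone with non-overlapping disks
(mean radius 2.5 px, sd 0.6) whose per-depth-bin summed area meets the
blueprint's target pore fraction. Twelve depth bins (a multiple of the four
quadrants) keep the piecewise-constant realized profile aligned with
quadrant boundaries. When sequential adsorption jams before the bin target
is met, the candidate radius is halved in up to three stages so interstices
keep filling — targets up to 60 % area fraction are reached exactly in
analytic disk area, and pixel-counted fractions agree to ~0.1 porosity
points at the default resolution. Ground truth per quadrant integrates the
bin-level target weighted by annulus area over the primary zone.

What this emulates: radially varying primary vascularity, lamellar boundary
layers, remodelled wedges with missing-quadrant consequences, and the
area-sampling noise of small measurement sectors. What it does not: real
vascular-canal shapes (circular disks, not elongated or radial canals),
birefringence/texture, gradual remodelling fronts, or sector-placement
judgement. Passing round-trip tests therefore validates the geometry and
accounting of the measurement chain, not segmentation of real
photomicrographs (which is out of scope — classes are inputs).

`generate_rpp_dataset` draws, per element, three sector profiles = group
polynomial (over quadrant index 1..4) + independent Gaussian noise truncated
to [0, 100], then applies element-level missingness per quadrant. Inner
quadrants are coupled: b goes missing with probability 0.7 given a is
missing, with b's marginal rate preserved where feasible — emulating
perimedullary remodelling spreading outward. The default design has four
quadratic groups spanning 5–66 % porosity (a compact near-adult group, a
maturing precocial group, a rising mid-juvenile group, a highly porous
early-juvenile group) with sector noise sd 2 porosity points and 20 elements
per group; adjacent group curves sit ≥ 5 residual sd apart (the residual sd
of a 3-sector mean is 2/√3 ≈ 1.15). The two-group variant uses flat
trajectories at 10 vs 40 %.

## Trajectory distances

RPPs become 2-D point sequences (quadrant index 1–4, porosity %) with
missing points dropped, positions retained — no imputation, which is what
lets DTW/ED/LCSS absorb up to two missing values. Axes are not rescaled
(raw profiles); position normalization to [0, 1] is available as an option.

- DTW: unconstrained monotone warping, sum of Euclidean point distances,
  unnormalized.
- Edit distance: unit-cost Levenshtein; two points match iff both coordinate
  differences are ≤ eps (default 5).
- LCSS: longest eps-matching common subsequence maximized over a symmetric
  grid of 2·20+1 translations per dimension spanning ± the joint coordinate
  range; similarity = count / min length. LCSS results are known to be
  sensitive to eps and grid choices; defaults are explicit in the config and
  recorded in outputs, not claimed to be anyone else's settings.

All three dynamic programs are verified against brute-force enumeration
(all warping paths; recursive edit operations; subsequence search) for every
length ≤ 4.

## Grouping engines

**K-means** is hand-rolled Lloyd iteration (the within-cluster sum of
squares is asserted non-increasing every step, which off-the-shelf
implementations do not expose), 100 random restarts by default, centroids
initialized at k distinct profiles, empty clusters re-seeded at the
worst-fitted point, best-of-restarts by WSS, ties broken by first
appearance. K-means and GBTM accept only complete four-point RPPs;
incomplete profiles belong to the distance-based route.

**Hierarchical clustering** delegates to scipy's complete linkage (validated
against a naive O(n³) agglomerator in the tests); trees are cut after n − k
merges and serialized as Newick-like text for audit.

**GBTM** is a k-component mixture of polynomial mean curves over the
quadrant index with Gaussian residuals of shared variance, fitted by EM.
The criminology implementations this family of models descends from use
zero-inflated Poisson likelihoods for count outcomes; porosity is a
continuous percentage, so a Gaussian residual model is the appropriate
likelihood here and exact numerical agreement with ZIP-based software is not
expected. Initialization is k-means++ seeding with a hard-assignment warm
start; 100 restarts by default ("iterations" in the sense of independent
starts, each run to convergence at tol 1e-8, max 500 steps); σ is floored at
1e-6 so noiseless data converge cleanly; a component collapsing below half
an observation's weight is re-seeded at the worst-fitted profile (at most 3
times per run, then the start is abandoned). The log-likelihood is asserted
non-decreasing within a start. Components are ordered by increasing mean
fitted porosity so labels are reproducible. p = k(degree+1) + (k−1) + 1;
AIC = −2ℓ + 2p, BIC = −2ℓ + p·log n.

**CVE** is leave-one-element-out: the model is refitted on n−1 profiles
(warm-started from the full fit), and each point of the held-out profile is
predicted from the posterior computed on its other three points — the scored
point never informs its own group assignment, otherwise overfitted extra
components are rewarded. `gbtm_select` fits all (k ≤ 5, degree ∈ {1,2,3})
configurations in several independently seeded repetitions; AIC and BIC pick
their minima, while CVE applies the one-standard-error rule (most
parsimonious configuration within one fold-level SE of the minimum CVE,
preferring fewer groups before fewer parameters) because leave-one-out
scores of nested mixtures differ by less than their own noise — AIC is
expected, and observed, to overselect k on mixture data. The flagged best k
and degree are the modes across criteria and repetitions.

## Membership statistics

Label alignment solves the assignment problem on the k×k contingency table
(Hungarian algorithm), verified against exhaustive permutation search for
k ≤ 5. Consensus tiers are computed after aligning every method to a
designated reference (default K-means, configurable); the reference choice
can move tier percentages by a few points, which is why it is recorded in
the report. Unmatched groups under unequal k map to unique sentinel labels
that always count as disagreement.

Dissociation signatures list, per specimen, the ascending bone counts per
occupied group joined by hyphens ("0" when a single group holds all bones);
signatures are invariant under group relabelling and their counts always sum
to the specimen's bone count.

Multinomial logistic regression is maximum-likelihood softmax regression
(L-BFGS on the analytic gradient) with a fixed tiny ridge (1e-6) so
perfectly separable designs — easy to produce when a developmental strategy
aligns exactly with a group — stay finite; a separation warning flags
|coef| > 15. Reported log-likelihood, AIC = 2p − 2ℓ and
AICc = AIC + 2p(p+1)/(n−p−1) are unpenalized; standard errors come from the
analytic Hessian at the optimum (cross-checked against an established
maximum-likelihood implementation in the tests). Backward stepwise selection
drops whole predictors (all levels of a categorical at once), accepting the
drop that lowers AIC most until none does; every visited model is tabulated
with AIC, AICc and PM% (modal-class match rate). Note that a truly
uninformative predictor with q degrees of freedom survives backward AIC with
probability ≈ P(χ²_q > 2q) — about 13.5 % for q = 2 — so the stable
diagnostic for "noise is expendable" is that the first-ranked drop candidate
is the noise predictor, not that the drop is always accepted.

## Problem sizes and determinism

Synthetic study sizes throughout (20 elements/group, sections of
~500² px, 10-blueprint round trips, 20-replicate regression simulations)
were chosen so the full test suite and the acceptance script each run in
well under a minute to a few minutes on one CPU while leaving comfortable
statistical margins (round-trip errors ≤ ~1.5 porosity points against a
±2-point check; recovery ARIs at 1.0 against ≥ 0.9/0.95 checks). All
randomness flows through explicitly seeded `numpy` generators; identical
inputs and seeds give byte-identical artifacts.

## Known limitations

- No automatic tissue segmentation; class rasters are inputs.
- 2-D area-based porosity only; no 3-D/μCT volumes.
- Four quadrants are hard-wired into GBTM's design matrix (degree ≤ 3);
  other quadrant counts are supported in measurement but not in the mixture
  model.
- LCSS group memberships are parameter-sensitive by nature; they are
  computed but should be interpreted with its eps/grid settings in view.
- The multinomial fit offers no random effects; specimen enters only as a
  fixed categorical predictor.
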