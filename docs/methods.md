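# Methods

## Measurement model

The pipeline treats a flock as a set of binary blobs per overhead frame.
Segmentation is deliberately classical — crop to an object-free floor
polygon, Gaussian low-pass, global threshold, 8-connected component
labelling — because the downstream indexes only consume blob area,
perimeter and center of mass, and because the approach must run on
low-resolution (352 × 240 px) surveillance footage. Conventions are
fixed once and used everywhere:

* coordinates are 0-based, origin top-left, x = column, y = row; a
  pixel's coordinates are its center;
* the ROI polygon is rasterized by center-in-or-on-polygon inclusion
  (via shapely), and the crop offset is recorded so centroids map back
  to full-frame coordinates;
* blob **perimeter** is the count of pixel edges between foreground and
  background, hole boundaries included. A 10 × 10 square has perimeter
  40 exactly, which makes the convention directly testable; smoother
  estimators (Crofton etc.) would change index values by a roughly
  constant factor without changing any ordering;
* connectivity is 8: birds touching diagonally are one cluster;
* blobs under `min_area` (default 50 px², ≈0.06 % of the frame) are
  discarded as noise, with the discarded area still accounted for in
  the conservation test.

Otsu thresholding is the default because it adapts to the global
illumination differences expected between lighting treatments; a fixed
threshold and both polarities (bright or dark birds) are available per
run. The foreground convention is strictly-above-threshold; the dark
polarity is its exact complement.

## The indexes

The cluster index combines mean blob area Ā, mean perimeter P̄, mean
pairwise centroid distance D̄, blob count n_A and the cropped-frame
diagonal √(h² + w²); the unrest index is the symmetric Hausdorff
distance between consecutive frames' centroid sets, scaled to
centimeters by k = 2H·tan(α/2)/w. Numerical choices:

* the published cluster-index denominator is typographically ambiguous
  between (n_A − 1) and n_A⁻¹ scaling; both are implemented behind a
  `variant` switch (`n_minus_1` default) and every output labels the
  variant. Both are monotone the same way, so orderings are unaffected;
* the diagonal term is read as the length √(h² + w²) — the only
  dimensionally coherent reading;
* h and w are the **cropped** frame dimensions, since all measurements
  happen inside the crop;
* a frame with fewer than two blobs leaves D̄ (hence the cluster index)
  undefined; such frames are flagged invalid, never given a fabricated
  value, and counted in the log. Unrest needs only one centroid per
  frame; a missing/empty frame breaks the 1-s pair on both sides, with
  no interpolation;
* Hausdorff distances are computed on blob centroids (the centers of
  mass the method records), not contours, with an exact vectorized
  max–min over the pairwise distance matrix. The brute-force double
  loop and the scipy implementation serve as independent oracles in the
  tests;
* unrest is assembled strictly at 1 frame/s, the cadence the statistic
  is defined on.

## Thermal classification

THI = 0.8T + RH(T − 14.3)/100 + 46.3. Class limits (59 cold, 78 heat;
air-temperature limits 15/28 °C for the combined rule) are strict
inequalities per their "above"/"below" phrasing, so boundary values
classify as comfort. The default rule is THI-only; the T-or-THI rule is
available by configuration since the source prose supports either and
neither is asserted as the original choice. Hourly THI is the THI of
the hourly-mean T and RH (not the mean of per-record THI values); the
difference is second order but a convention had to be fixed. Recording
windows are labelled by the class of the mean hourly THI over the hours
they overlap; windows without coverage are labelled `missing`, logged,
and excluded downstream.

## Statistical comparison

The experimental unit is one recording mean, not a frame — frames 1 s
apart are heavily autocorrelated and would pseudo-replicate. Units are
compared by two-way OLS ANOVA (type II) on treatment × period or
treatment × comfort, followed by Tukey HSD pairwise comparisons
(statsmodels' Tukey–Kramer form, the standard unbalanced extension) run
across treatments within each level (lowercase letters) and across
levels within each treatment (uppercase letters). The compact letter
display is built from the maximal cliques of the not-significantly-
different graph, which guarantees consistency with the pairwise
decision matrix: groups share a letter iff their difference was not
declared significant. Cells with fewer than two units are omitted from
the affected comparison and logged. α defaults to 0.05.

## The synthetic flock generator

No public footage exists for this kind of analysis, so validation runs
on an agent-based generator in which the quantities the indexes claim
to measure are dialled in directly. Each bird follows a first-order
discrete-time process at the 1-s index cadence,

    x[t+1] = x[t] + β (a − x[t]) + ε,  ε ~ N(0, σ² I),

reflected (not clipped) at the walls so motility is not attenuated
there. σ (`step_sigma`, px/s) is the unrest ground truth; β
(`attraction_beta`, fraction of the distance to the feeder point closed
per second) is the cluster ground truth. Birds render as filled
ellipses with per-frame uniform random orientation; overlaps merge into
one blob, as threshold segmentation of real footage produces. A
grayscale mode adds foreground/background intensities and Gaussian
sensor noise so the full filter/threshold chain is exercised, not just
the labelling.

Parameter choices, made once:

* **20 birds on a 240 × 352 px arena at 1 frame/s** mirror the housed
  groups and camera format the indexes were designed around; default
  recording length 900 s (a 15-min session).
* **Bird semi-axes (7, 4) px** (area ≈ 88 px²). The ellipse must
  comfortably clear the default 50 px² speck filter — smaller axes make
  single birds indistinguishable from noise by construction, a
  generator/segmentation inconsistency rather than a biological claim.
* **Initial positions** are uniform by default. With attraction active
  the process has a stationary spread s = σ/√(β(2 − β)); the
  `init="stationary"` option draws frame 0 from that Gaussian so short
  recordings sample steady-state clustering instead of the transient
  after a uniform release. Campaign simulations use it for attracted
  treatments.
* **Campaign ground truth**: blue σ=8/β=0, green σ=5/β=0, red σ=3/
  β=0.005. This encodes the qualitative pattern of interest — unrest
  ordered blue > green > red, clustering only under red — and makes
  blue and green *exactly* exchangeable for the cluster comparison
  (β=0 reflected random walks are distribution-identical in steady
  state), providing a built-in null. Red's β is set so the stationary
  spread (≈30 px) keeps the clustered flock loose enough that blob
  merge/split churn, which jitters centroids, does not swamp its
  motility signal in the unrest index.
* **Thermal series**: 12 records/hour (5-min cadence). Each scheduled
  hour draws a target THI uniformly inside a band strictly interior to
  its class (cold 50–57, comfort 62–75, heat 79–84), draws RH ≈
  N(65, 8²) clipped to [35, 95] %, inverts the THI formula for T per
  record, and applies one linear correction so the hourly-mean THI hits
  the target exactly. Campaign scheduling defaults to the 49:20:15
  comfort:heat:cold window proportions of the reference campaign.

What the generator does **not** emulate: bird posture, gait or
biomechanics; pecking/aggression events; any causal effect of light
spectrum or temperature on movement (treatment labels select generator
parameters, nothing more); illumination gradients, shadows or lens
distortion; behavior–thermal interaction. Passing tests therefore show
that the measurement chain recovers known motility/attraction ground
truth from rendered frames — they do not validate biological claims
about hens, nor reproduce the numeric tables of any particular
campaign, which would require the original videos.

## Problem sizes and determinism

Validation runs use compact sizes chosen to keep the full suite quick
while leaving comfortable statistical margins: 20 seeds per generator
level for the monotonicity sweeps, 8–42-day campaigns of 15–30-s
recordings for the ordering, null-calibration and bookkeeping checks
(effect separations in the campaign configuration are several
between-recording standard deviations, so short recordings suffice).
Every stochastic component draws from `numpy` generators seeded from an
explicit root seed — campaigns derive one child seed per recording via
`SeedSequence` — and identical configuration plus seed reproduces
trajectories, masks, thermal series and CSV outputs byte for byte.

## Known limitations

* No bird identity or tracking: the unrest index is a set statistic and
  saturates once blobs merge heavily; the cluster index is undefined on
  single-blob frames (flagged, not imputed), so extremely tight flocks
  are summarized by few valid frames with large values.
* The Hausdorff distance is sensitive to a single outlier bird by
  design — it measures the worst-moved member, not the mean flow.
* The ANOVA treats recording means as independent; day-to-day serial
  correlation is not modelled.
* Otsu assumes a bimodal intensity histogram; footage where birds and
  floor have similar luminance needs the fixed-threshold override and a
  polarity choice per run.
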