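# Methods

`tattooseq` implements the computational core of a photoconversion-indexed
single-cell RNA-seq experiment: embryonic tissue (the mouse forelimb bud)
expressing a green-to-red photoconvertible protein is photoconverted in one
of several user-drawn spatial patterns, dissociated, and index-sorted so
that every transcriptome carries a red (PE) and green (FITC) fluorescence
intensity.  The package turns those intensities into discrete color calls,
models the geometry that links position to color, inverts that model to
place groups of cells in space, and projects gene expression onto the
resulting spatial grid.

## Color calling

The positional readout of a cell is the ratio of logs

    s = log2(PE) / log2(FITC).

Cells with either intensity at or below 1 are rejected (they fall in the
low-fluorescence sorter gate anyway, and the statistic degenerates).  Within
one limb the distribution of `s` is multimodal — one mode per
photoconversion degree — but mode locations drift between limbs, so each
limb is modeled separately as a mixture of skew-normal components
f(x) = (2/ω)·φ((x−ξ)/ω)·Φ(α(x−ξ)/ω): three components for the PD and AP
patterns, four for the AER pattern.  Parameters are estimated by an ECM
algorithm built on the stochastic representation
x = ξ + ωδ|t| + e (t standard normal truncated to t > 0,
e ~ N(0, ω²(1−δ²)), δ = α/√(1+α²)), which needs only the first two
truncated-normal moments in the E-step and is monotone in the observed-data
log-likelihood.  Convergence is declared at a relative log-likelihood
change below 1e-6, capped at 500 iterations.

Initialization matters: a pure k-quantile split traps EM in local optima
that split the dominant (green) mode whenever mixing proportions are far
from uniform, which is the norm for AER-patterned limbs.  EM is therefore
run from several starts — the quantile split, a partition by the k
strongest kernel-density modes, and two seeded random center draws — and
the best final likelihood wins.  Components are then sorted by their mean
ξ + ωδ√(2/π) and labeled green → red in ascending order, making the output
invariant to initialization order.  Per-cell posteriors are the component
responsibilities; for AER limbs the two highest-mean components are summed
into a single red bin (fully converted cells are rare under that pattern).
Values farther than 6 fitted scales from every component mean are flagged
unassignable; the threshold is a conservative outlier guard, not a
calibrated quantity.

Some skew-normal estimators take a degrees-of-freedom argument for their
wider skew-t family; for the skew-normal member that parameter is inert and
this implementation does not expose it.

## Limb-bud model

The limb is a 2D shape bounded by cubic Bezier segments, flattened to 64
points per segment for all geometric computation (flattening error well
under 1e-3 of limb length).  The PD axis is +x (flank → tip), the AP axis
+y (anterior → posterior).  The packaged default outline is a paddle
calibrated to four qualitative constraints of a realistic hand-plate
geometry:

* G1 — the AER distance band nearest the ridge lies entirely within the
  distal PD third;
* G2 — every other (PD band × AP band × AER band) combination over the
  dissected region is nonempty;
* G3 — the band farthest from the ridge meets the distal PD third only in
  the anterior and posterior AP thirds (the limb is longest at mid-AP);
* G4 — the proximal third spans all three AP bands.

Patterns: PD and AP split the bounding box into three equal-length bands
along their axis (green/yellow/red from proximal and anterior ends).  The
AER pattern applies only to the dissected distal two-thirds (dissection
line at PD = 1/3); its bands are iso-distance bands of the marked distal
arc of the boundary with equal width w = 0.115 length units per
photoconversion degree, roughly a quarter of the half-width of the
dissected part.  Four degrees are laid down; the two nearest the ridge are
merged into one red band, so the red band spans two widths.  Band
direction (green = farthest) is configurable; all downstream math is
direction-agnostic.  Everything proximal to the dissection line is
"missed" under the AER pattern.

Under these constraints the three patterns jointly define 17 maximal
regions of deterministic fluorescence outcome (3 proximal/missed + 14
dissected combinations).  Working directly on those regions is brittle —
real limbs deviate slightly from any fixed outline — so the model instead
grids the bounding box 6 × 6 (36 cells), clips to the shape, drops empty
cells, and computes for every cell a forward distribution over
(green, yellow, red, missed) per pattern, proportional to photoconverted
areas.  Areas come from exact polygon clipping (iso-distance bands are
buffer polygons of the arc at 32 quadrant segments); Monte Carlo
integration reproduces the rows within 1e-3 total variation.  Adjacent
cells whose forward rows differ by less than τ total-variation under all
three patterns are merged agglomeratively, closest pair first, recomputing
rows from merged geometry.  The packaged τ = 0.32 sits in the middle of
the plateau (0.30–0.34) at which the default geometry yields 14 sbins;
merging never changes the area-weighted mean forward row.

## Position inference

For a cell group M (typically a metacell) with regularized empirical color
distributions P_emp,λ(F) (pseudocount ε = 1 per color; patterns with no
cells contribute nothing), the forward model predicts

    P_θ,λ(F|M) = Σ_s P_λ(F|S=s) · θ_s

and θ is estimated by minimizing Σ_λ KL[P_θ,λ(F|M) ‖ P_emp,λ(F)] with a
trust-region constrained interior-point method (analytic gradient,
Σθ = 1, −0.00005 ≤ θ_s ≤ 1 — a box slightly wider than [0,1] that keeps
the interior-point iterates off the boundary).  Probabilities entering the
logs are clamped to [0.001, 1], bounding each pattern's term below by
−3·0.001·|log 0.001|.  After convergence, negative entries are zeroed and
θ renormalized.  Empirical AER distributions contain only captured cells,
so the AER prediction is conditioned on capture (renormalized over the
three observed colors); the predicted missed probability is reported as a
per-group diagnostic.  θ is one vector per group shared across patterns.
Initialization is uniform over sbins with up to three Dirichlet(1)
restarts on optimizer failure; a non-converged fit is returned flagged,
not raised.  Groups under 10 cells are flagged low-confidence.

Six observed color frequencies cannot identify 14 free parameters, so the
minimizer generally lies on a degenerate optimal set; for concentrated
groups (real metacells) the set is small and recovery is sharp, but for
deliberately spread groups it is not.  For the one analysis that pools
*all* cells — estimating relative limb thickness as θ_s/area_s normalized
to max 1 — the inference therefore adds a small tie-break term
10⁻³·KL(θ ‖ θ_area), selecting among near-minimizers the solution closest
to uniform cell density (θ_area ∝ sbin areas).  The reported objective
excludes the tie-break.  Plain metacell inference uses no tie-break.

## Expression statistics

* **QC** — cells outside [min, max] total UMIs are dropped (defaults
  2000–15000; the lower cutoff may vary per batch), mitochondrial genes
  (prefix `mt-`) removed.  Idempotent.
* **Metacell profiles** — per-group UMI totals, per-group gene fractions,
  and enrichment (fraction over the gene's median fraction across groups).
  The regression/trend transform is log2(fraction·10⁴ + 1); enrichment
  feeds only the variability filter.
* **vISH** — the probability that a random UMI of a gene lies in each
  sbin: a mixture of group θ's weighted by the gene's depth-normalized
  per-group expression (each cell's counts divided by its total UMIs
  before summing, so deep cells do not dominate).  Gene-set and
  per-cell-type variants sum or restrict-and-renormalize the weights.
* **Spatial regression** — OLS of each gene's transformed expression on
  the groups' θ matrix (no intercept: θ rows sum to 1, so the constant
  vector is in the column space; collinear columns are dropped by pivoted
  QR), overall F-test against the best constant fit, Bonferroni correction
  over all tested genes, spatial call at adjusted p < 0.01.  The tested
  universe should be detected genes; including genes with a handful of
  UMIs lets single-spike profiles through the F-test.
* **Positional trends** — each group's expected coordinate
  c_m = Σ_s θ_m(s)·coord(s) along a chosen axis (normalized PD or AP
  centroid coordinate, or centroid distance to the AER arc); Spearman
  correlation of expression with c_m across groups, with a detection
  filter (> 100 total UMIs) and a variability filter (≥ 1 group above
  1.5× the median).  Constant genes report ρ = 0 with a degenerate flag.
  p-values use the t approximation and are reported raw.
* **TF specificity** — min-max rescale expression across groups to [0,1]
  and integrate the empirical CDF exactly (the step integral equals
  1 − mean of the rescaled values); specific genes score near 1, constant
  genes report 0.5 with a degenerate flag.  Affine-invariant by
  construction.
* **Batch-driven genes** — for each metacell with > 15 cells from both
  batches, repeat 10×: downsample each cell to the group's minimum depth,
  draw 10 cells per batch, aggregate, record the per-gene fold change
  (pseudocount 1).  The median of the *signed* folds across repeats is
  taken first and a gene is flagged when that median (either orientation)
  exceeds 1.6 in at least one metacell — requiring a consistent direction
  across resamples.  The statistic is intrinsically noisy for genes whose
  expected count per aggregate is of order 1; on sparse panels rare genes
  can be flagged by discreteness alone, a known limitation of
  resampling-fold procedures at this threshold.

## Synthetic data

The generator emulates exactly the process the inference assumes: cell
positions are drawn proportional to a thickness field over the shape
(default a half-ellipse cross-section thinning from flank to tip,
√(1 − 0.9·pd²) floored at 0.05); each simulated limb carries one pattern;
true colors follow from the pattern's regions (AER limbs drop proximal
cells); `s` is drawn from a per-color skew-normal (ξ = 1.0/1.3/1.6 for
green/yellow/red, plus 1.9 for the red-most AER degree, ω = 0.07, α = 2 —
adjacent modes ≈ 4.3ω apart, i.e. well-resolved but overlapping sorter
data) and inverted into intensities via FITC ~ log-normal(log 500, 0.4)
and PE = 2^(s·log2 FITC), so the calling module sees exactly the modeled
statistic.  Counts are multinomial per cell: depth ~ log-normal(log 3000,
0.35) clipped to [200, 30000]; gene probabilities are per-type Dirichlet
programs (concentration 0.5; 600 genes, 4 types by default) multiplied by
spatial-gene factors effect^g(coord) (linear or logistic g, axes cycling
PD/AP/distance-to-AER, alternating orientation so the panel's total UMI
mass stays roughly position-neutral; default 60 spatial genes at effect
4).  Spatial flags are placed on the better-expressed half of the panel —
a gradient on an undetectable gene is not usable ground truth.  Metacell
surrogates group cells by (type, sbin), by fine spatial k-means clusters,
or at random; groups under the minimum size merge into the spatially
nearest group.

What the generator does **not** emulate: ambient RNA, doublets,
overdispersion beyond multinomial sampling, imaging misregistration,
between-limb shape variation, or cell types with intrinsically spatial
abundance.  Passing tests therefore demonstrate correctness of the
pipeline under its own model assumptions, not robustness to every artifact
of real sorter or sequencing data.

## Validation studies and problem sizes

The bundled studies (`tattooseq.benchmarks`) run the pipeline end to end
at desk scale: position recovery uses 12 limbs × 3500 sampled cells
(≈ 38k collected) forming ≥ 50 metacells of ≥ 300 cells, recovered at
median total-variation ≈ 0.03; the mixture study fits 20 seeded
3-component mixtures of 2000 draws at 4ω separation; the regression
studies run 100 null and 20 gradient simulations of 2000 genes across
≈ 40 spatial groups; the thickness study uses 50k cells.  These sizes were
chosen to make the statistics stable while keeping a full run in minutes
on one core.

## Known limitations

* The default outline is a calibrated surrogate; the published experiment
  fitted its shape and band boundaries to micrographs that are not part of
  this package.  All counts (36/17/14) are properties of the packaged
  geometry and thresholds.
* θ is identified only up to sbins with identical forward rows under the
  available patterns; the inference reports a point on the optimal set,
  and only the all-cells thickness path applies a density tie-break.
* Whether the original pipeline weighted patterns by cell count in the KL
  sum is unknown; the sum here is unweighted.  Clamping is applied to both
  operands of every log ratio.
* Grid cells partially outside the shape are clipped (not kept whole);
  sbin coordinates for trends use centroid ranks of the merged geometry.
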