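# Methods

This note documents the model behind stripekit, the parameters that matter,
the numerical choices made where the procedure is underdetermined, what the
synthetic generator does and does not emulate, and known limitations.

## Input handling and normalization

Contact matrices are read per chromosome from the cooler HDF5 layout
(`.cool`, or `.mcool` with a stored resolution) directly through h5py; the
stored upper-triangle pixel table is mirrored into a dense symmetric
matrix of raw counts. Balancing weights stored in the file are ignored:
normalization is always performed internally so results do not depend on
upstream balancing choices. Two normalizations are supported for detection
and P-value scoring (`norm` parameter):

* `raw` — counts as stored;
* `sqrt_vc` (default) — square-root vanilla coverage: entry (i, j) is
  divided by `sqrt(s_i · s_j)`, where `s_k` is the row sum of bin k over
  the cis matrix. Zero-coverage bins stay zero.

Stripiness is always computed on the observed/expected matrix derived from
the detection matrix: the expected value at distance d is the mean over
*all* pixels of diagonal offset d (zeros included), and 0/0 maps to 0.
This per-diagonal-mean expected model is the standard O/E convention; it is
deterministic and makes every diagonal of the O/E matrix average to 1.

Rows/columns that are entirely zero (unmappable bins) are removed per
window before image rendering, and all reported coordinates are mapped back
to genomic bp (0-based, half-open, BED convention) through the bin index
map.

## Candidate search

Windows of 400 bins slide along the diagonal with step 200, so every
diagonal neighborhood of up to ~200 bins is interior to at least one
window; the last window is shifted to end exactly at the chromosome end.
Stripes are searched as *vertical* lines below the diagonal; 3′-stripes
are found by running the identical machinery on the genome-axis-mirrored
matrix (`values[::-1, ::-1]`) and mapping coordinates back. (For a
symmetric matrix, plain transposition is the identity; the axis mirror is
the transformation that actually exchanges 5′ and 3′ geometry.)

Rendering and edge detection per window, contrast level `M` (quantiles of
the chromosome's positive contact frequencies, default 0.95–0.99) and
brightness level `high_in` (0.5–1.0 in steps of 0.1, applied as the linear
remap `v → min(v/high_in, 1)`):

1. red-on-white rendering `R=255, G=B=max(255(M−P)/M, 0)`, rounded
   half-to-even to integers so tests can be bit-exact;
2. 3×3 mean blur (replicate borders; kernel size 1 disables);
3. BT.601 luma grayscale;
4. Canny edge detection at σ = 2.0 with the detector's automatic
   hysteresis thresholds (only σ is pinned).

**Orientation filter.** The binary edge map is correlated with the 3×3
Sobel kernels and each pixel is summarized by the edge-tangent angle
`θ = arctan2(G_x, G_y)` folded to [0°, 180°); pixels with θ ∈ [60°, 120°]
and a non-vanishing gradient are retained and then shifted one column
left. Under this convention the columns flanking a vertical line score
exactly 90° along the line's whole length: the right-flank response is
shifted back onto the true border column, while the left-flank copy (two
columns left after the shift) is deleted by the refinement step because
its pixels are background in the raw edge image. The gradient-direction
convention (`arctan2(G_y, G_x)`) was rejected because it assigns ~90° to
*horizontal* structure, makes ideal one-pixel vertical lines invisible
(both gradients vanish at their interior pixels), and leaves the
one-column shift and the refinement step without a function; the
edge-tangent reading is the only one under which all three steps cohere,
and it is validated end to end by planted-stripe recovery.

**Run assembly.** Retained pixels are assembled greedily top-to-bottom
into vertical runs that may drift ±1 column per row (ties prefer the
column nearest the run's current mean column, then the smaller column) and
may bridge up to 5 missing rows in total per run (a "gap" is one missing
row). Runs spanning fewer than `minL` = 10 rows are discarded and their
pixels released. Refinement drops run pixels that are background in the
pre-shift Canny image, groups surviving segments whose mean columns lie
within 2 of each other and whose row spans (±2 rows) overlap, and
represents each group by the length-weighted mean column (half-up
rounding). Lines are extended to the diagonal pixel of their column
(whichever end is nearer the diagonal moves onto it; the far end never
moves), and only lines whose bulk lies below the diagonal are kept in a
given pass — the mirrored pass owns the other side.

**Pairing and merging.** Column-sorted lines closer than `maxW` bins are
chained serially; each maximal chain of ≥2 lines becomes one candidate
(a stripe is a *pair* of Canny borders; single lines are discarded). The
anchor spans the chain's outer columns inclusive; the domain runs from the
anchor's diagonal end to the farthest member row. `maxW` defaults to 8
bins, the recommended maximum stripe width at 10 kb; use 16 at 5 kb.
Candidate pairs are first screened by median P-value (< `p_cutoff`,
default 0.1), and only then are duplicates pooled across windows,
contrast and brightness levels merged: anchor-overlapping candidates of
the same orientation collapse to the member with the largest
length/width ratio (ties: longer domain, then smaller start). Screening
before merging matters: a mislocalized pairing can carry a higher
length/width ratio than a well-anchored duplicate of the same stripe, and
filtering first guarantees the merge chooses among pairs that already
show significant contrast.

## Median P-value

For a stripe row at diagonal distance d, `C` is the mean intensity over a
smoothing window of N × width pixels centered on the row, where
N = max(1, round(50 kb / resolution)); `L` and `R` are the means of the
N × N blocks immediately left/right of the anchor columns. The row's
P-value per side is the plus-one empirical estimator
`p = (1 + #{null ≥ C − flank}) / (1 + n)` against a null of n = 1000
differences computed with *identical* window geometry at anchors drawn
uniformly (with replacement, seeded) over the feasible bins at the same
distance d; the row keeps the *less* significant side, and the stripe's
score is the median over rows. Distances are referenced to the anchor-side
pixel: first anchor column for 5′-stripes, last for 3′-stripes. Design
points:

* the plus-one rule bounds p in (0, 1] and forbids spurious zeros;
* nulls are sampled with the same smoothing as real rows — sampling single
  pixels instead would miscalibrate the comparison;
* flanks truncated by the matrix boundary are shortened; a row with an
  entirely missing flank is skipped in the median; rows at distances with
  no feasible null position conservatively score 1;
* null distributions are built per stripe width, to D = 400 bins from the
  diagonal, and cached; all randomness flows from the single run seed;
* no multiple-testing correction is applied — the 0.1 detection cutoff and
  the recommended downstream 0.05 threshold are raw cutoffs.

P-values are invariant under rescaling of the matrix (nulls rescale
identically), so raw and depth-scaled datasets are comparable.

## Stripiness

On the O/E matrix, each stripe row i yields `C_i` (mean over the anchor
columns), `L_i`, `R_i` (means over the 50 kb flanking column blocks).
Modified Sobel kernels over rows (i−1, i, i+1) give `G_{x,L}`, `G_{x,R}`
(each a [1,2,1]-weighted sum of C−L resp. C−R) and `G_y` (the vertical
derivative of L+2C+R); replicate padding supplies the neighbors at the
first and last rows. Then

```
ΔGⁱ = min(G_{x,L}ⁱ, G_{x,R}ⁱ) − G_yⁱ,   S = median(C) · Σ ΔGⁱ / L.
```

Taking the min of the two sides demands contrast against *both* flanks;
the G_y term penalizes discontinuity along the stripe, which is the
signature of a loop. A uniform stripe with C = 3 against unit flanks gives
ΔG = 8 in every row and S = 24 regardless of length — a useful closed-form
check. Note S is degree-2 homogeneous in the O/E values (the median and
the gradients are each linear), so stripiness values are comparable only
between properly normalized datasets; an all-zero stripe body scores 0.

Cross-condition workflows: `merge_stripe_sets` collapses anchor-overlapping
same-orientation stripes from two datasets to the higher-stripiness member;
`classify_condition_specific` labels a merged stripe condition-specific
when S > 2 in one condition and S < 0 in the other, else shared.

## Synthetic data

The generator emulates the features of cis contact data that the detector
and the scores actually consume:

* power-law distance decay `E[i,j] = A·(|i−j|+1)^(−α)`, default α = 1.0
  (generic cis decay) and A = 100 expected counts at the diagonal, i.e. a
  deeply sequenced library with ≥20 counts/pixel near the diagonal;
* Poisson counting noise, sampled once on the upper triangle and mirrored
  (or disabled for closed-form tests);
* stripes as multiplicative enhancements (factor f ≥ 1) of the expectation
  over an anchor × domain band touching the diagonal, with a continuity
  fraction selecting the enhanced rows (seeded subset);
* loops as Gaussian multiplicative bumps (peak f, radius r, truncated at
  4r) at an anchor pair — the negative control the caller must not report.

Planting operates on the noise-free expectation, so enhancement factors
are exact in expectation; features may not overlap. The benchmark scene —
2000 bins at 10 kb, three 5′-stripes (widths 3/2/4 bins, lengths 60/40/80)
and two 3′-stripes (widths 3/2, lengths 50/45) at f = 6 and full
continuity, plus three loops — is the repository's headline end-to-end
test: default parameters recover all five stripes with recall 1 and no
loop-derived calls, and every recovered stripe has median P < 0.05 and
S > 0.

What the generator does *not* emulate: TADs and compartments (no checkered
or block structure), stripe anchors detached from the diagonal, coverage
heterogeneity between bins, resolution-dependent mappability gaps, and
inter-chromosomal contacts. Passing tests therefore demonstrate correct
mechanics and calibration of the pipeline on idealized cis data, not
field performance on tissue Hi-C; on real data the contrast quantiles
should be re-chosen per sequencing depth (see `seeimage`).

Monotonicity of the scores in stripe contrast (S non-decreasing, median P
non-increasing in f over f ∈ {2,3,4,6,8}) and the discontinuity penalty
(continuity 0.5 scoring below continuity 1 at equal f) are asserted on
noise-free fixtures, which isolates the effect of the planted parameters
from realization noise.

## Numerical choices and determinism

* Image integers round half-to-even ([0, 255] clamp); the refinement's
  representative column rounds half up (required by its worked example).
* Rectangle means use a 2-D integral image; the identical code path
  produces the null samples and the observed row statistics, so exact
  ties (a null anchor landing on the tested row) are ranked consistently.
* All randomness (Poisson sampling, continuity subsets, null anchors)
  derives from explicit seeds; outputs are byte-identical across runs with
  the same seed and are independent of the `threads` setting (chromosomes
  are independent work units; the current scheduler is serial).
* Problem sizes in the shipped tests (300–2000 bins) keep the full suite
  around a minute while exercising every code path at realistic window
  sizes; the benchmark scene is scored once per session and shared.

## Limitations

* Curved "jet" features, stripes detached from the diagonal, and
  inter-chromosomal structure are out of scope.
* The 60°–120° orientation window plus ±1-bin jitter admits locally steep
  diagonal-ish runs; these are removed by the P-value screen in practice
  but may survive at marginal significance near strong anchors (observed
  as an occasional short wrong-orientation call at a true anchor under
  noise).
* sqrt-VC is the only balancing offered by design; KR-balanced inputs
  should be supplied as raw counts and normalized internally.
* Stripiness compares only between datasets on the same normalization
  scale (degree-2 homogeneity); median P-value is the scale-free score.
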