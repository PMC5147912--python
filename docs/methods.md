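# Methods

## Assay model

The package models an endpoint, fixed-cell, two-channel translocation assay:
one field per well, DAPI marking nuclei and GFP reporting the localization of
a shuttling protein. The biological signal of interest is the per-cell
nucleocytoplasmic ratio; everything else (segmentation, rings, normalization,
QC) exists to estimate that ratio and aggregate it robustly.

## Synthetic plates

`synthetic.render_well` draws `n_cells` non-overlapping cells by hard-core
rejection sampling (minimum center separation twice the maximal cell
footprint radius plus 2 px, bounded retries; exceeding the density limit is
an error, not a silent partial field). Each cell has:

- an elliptical nucleus, semi-axes uniform on 5–8 px, uniform orientation —
  a 10–16 px nuclear diameter, i.e. low-magnification scale;
- a cytoplasmic annulus: the nucleus dilated by a Euclidean disk of 6 px;
- DAPI level ~3000 a.u. ±15%, GFP total ~2·10⁵ a.u. (log-normal, σ=0.15);
- a translocation state drawn Bernoulli(p) at the well's planted fraction p,
  and an N/C ratio drawn log-normal with state-dependent median
  (resting 1.0, translocated 3.0, σ_log 0.2). The medians straddle the 1.8
  classification cutoff with a small overlap (≈0.2–0.5% intrinsic
  misclassification), which is a *generator choice*, not a biological claim:
  real within-population ratio distributions for this assay are not
  documented, so recovery results should be read as "given distributions at
  least this separated".

GFP is split so that mean(nucleus)/mean(annulus) equals the planted ratio
exactly and the compartment sum equals the cell's GFP total. The noise stage
— applied last — adds a constant background (default 100 a.u.), Poisson shot
noise on the expected counts, Gaussian read noise (σ=3), clips at zero and
quantizes to 16 bits. Because background lives in the noise stage, noise-off
renders satisfy the exact planted-ratio and conservation invariants; with
background on, measured ratios compress toward 1 exactly as in an
un-background-subtracted real assay. Control normalization absorbs that
compression, which is why midpoint recovery is unbiased even though raw
ratios are biased.

The dose model is a 4PL from concentration (µM) to planted translocated
fraction (defaults bottom 0.05, top 0.95, Hill 1). Plate rendering derives
each well's seed deterministically from (plate seed, well id) via a
`SeedSequence`, so any well can be re-rendered in isolation.

Dose plates default to **triplicate wells per concentration** with full
first/last control columns (8+8), matching standard screening practice for
this assay class; single wells per dose roughly double the EC50 estimator's
relative sd (~10–15% vs ~6–8% at 150 cells/well).

The MTT generator (`simulate_mtt_table`) produces absorbance reads:
blank + viability·(vehicle − blank) + Gaussian noise with sd 5% of the
vehicle signal, triplicate treated wells plus 6 vehicle and 6 blank wells.
Viability follows a decreasing 4PL from 100% to 0%.

### What the simulator does not model

No point-spread function, z-structure, vignetting or illumination gradients;
no touching/overlapping cells (so no watershed is needed or provided); no
cell-cycle, motion, or debris; no plate-edge or spatial effects. Passing
recovery tests therefore demonstrates correctness of the measurement and
statistics chain under clean geometry, not robustness to clumped cells or
shading — those failure modes need real images.

## Segmentation

Local-mean thresholding: a pixel is nuclear when it exceeds the mean of its
51×51 neighbourhood by 2% of the image dynamic range; the map is hole-filled,
8-connected-labeled, and components outside [40, 4000] px or touching the
border are removed (a border nucleus would have a truncated ring). A blank
(constant) image yields zero labels because the margin is strictly positive.

Rings: ring(L) = {background p : gap < d(p, L) ≤ gap+width, L nearest}. The
per-label distances are exact squared Euclidean distances (per-label EDT on a
padded bounding patch; squared EDT values are integral, so comparisons are
exact). Distance ties are broken by nearer nucleus centroid, then lower
label — fully deterministic, and verified in the tests against a per-pixel
brute-force partition oracle. Cells whose ring comes out empty are dropped
with a logged reason. Defaults gap 1 px, width 4 px: wide enough to sample
cytoplasm, narrow enough to stay inside the cell at this magnification; the
ring geometry of the original instrument configuration is not documented, so
these are package defaults, exposed in the configuration.

"Nuclear vertices" = per-label count of pixels with at least one 8-neighbour
outside the label (image edge counts as outside). It falls monotonically as a
nucleus shrinks, which is all the apoptosis monitor needs.

## Quantification

Per compartment the **mean** intensity is used (an `integrated` switch is
provided). The ratio divides regions of very different area, and the ring
has fixed width while nuclei vary — mean is the area-fair reading. No
background subtraction by default; ratios are computed on raw intensities.
Classification is strict: ratio > 1.8. Wells with <50 cells are flagged
`low_count`; empty wells are flagged and carry a NaN percentage rather than
a fabricated zero.

## Screening statistics

Activity normalization is affine against plate controls (vehicle → 0%,
positive control → 100%); values outside [0,100] are preserved. Hits are
strict: activity > 60%. Z′ uses the standard Zhang form with the absolute
control separation in the denominator; a commonly mis-typeset variant (only
the negative-control term divided) is available as `bracket="as-printed"`
for comparison but is not used anywhere. Hit calling is a fixed threshold,
not a hypothesis test, so no multiple-testing correction applies.

## Dose–response fitting

4PL on log10 concentration via bounded trust-region least squares,
multi-started from the 25/50/75th percentiles of tested log-concentrations
crossed with two Hill-slope magnitudes; the Hill sign is constrained by the
assay direction (activation vs inhibition), inferred from the trend when set
to `auto`. Tolerances are tight (1e-14) so noiseless self-consistency holds
to ~1e-6 relative. The optimizer is validated against an exhaustive
(midpoint, hill) grid with the linear parameters profiled out; fitted RSS
must match the grid within 1%.

Convergence is honest: a fit is `converged` only when the fitted dynamic
range exceeds max(`min_span` = 10 response units, 3× residual sd) and the
midpoint lies within a 10× extension of the tested range. Flat series —
including an inactive compound measured through the full image pipeline —
return `converged=False` with an undefined midpoint.

The reported midpoint is the *relative* EC50 (inflection between the curve's
own asymptotes); where the asymptotes bracket the absolute 50 level the
absolute crossing is serialized alongside (`midpoint_abs`), since verbal
"increases by 50%" definitions are ambiguous between the two. Viability
IC50s use the identical code path with a negative Hill slope. Duplicate
wells per dose fit identically to averaging first (equal replication ⇒ the
least-squares problems coincide). No outlier rejection is performed.

## Problem sizes and determinism

Default validation scales: 150 cells/well on 560×560 px fields for dose
plates (52 wells ≈ 20 s), 60 cells/well on 384×384 px for the 544-compound
single-dose screen (7 plates, 672 wells, ≈ 1 min) — field-scale sampling of
wells that physically contain ~2·10⁴ cells, sufficient because all
statistics are per-cell or per-well proportions. All randomness flows from a
single top-level seed; identical (config, seed) produce byte-identical CSV
artifacts.

## Known limitations

- Touching nuclei are not split; the generator never produces them.
- Segmentation accuracy is quantified only on synthetic geometry.
- Confidence on EC50/IC50 is limited to residual-based diagnostics (RSS,
  residual sd); no bootstrap intervals.
- The acceptance-style recovery results depend on the generator's state
  distributions (above); with heavier overlap the classification accuracy
  and thus the activity window would degrade, and recovery tolerances would
  need re-deriving.
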