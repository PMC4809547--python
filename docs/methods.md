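# Methods

## The metaprofile

Fragment midpoints stand in for nucleosome dyads (or ChIP fragment centers).
For every retained site anchor, midpoints are counted per base at signed
offsets in `[-half_window, +half_window]` (default 1000 bp, 2001 bases
inclusive of both endpoints); a midpoint inside two overlapping windows is
counted once per window. Counts are divided by `n_sites × total_fragments`
(per-site, per-read density; `total_fragments` is the post-length-filter
fragment count of the experiment — the quantity the pipeline actually
observes), then multiplied by one constant so the window mean equals a
common value (default 1.0). The equal-mean rescaling is what makes profiles
from libraries of different depth directly overlayable; both normalization
constants are carried in the profile object and its TSV header.

Smoothing is a centered moving average. An even window is widened by one
base (50 → 51) so the filter is symmetric with a well-defined center — a
1 bp change far below the resolution of the data. At window edges the
averaging window shrinks symmetrically to fit (no padding is invented), and
the result is re-rescaled, so smoothing preserves the window mean to 1e-9.

## Anchors, orientation and the proximity filter

The anchor is the interval midpoint `start + floor((end-start)/2)`, or the
narrowPeak summit when requested and present. Aggregation is unstranded by
default (metaprofiles around factor binding sites are conventionally plotted
without strand flipping); flipping by strand is one flag away. The
interference filter drops any site whose center lies within `radius`
(default 500 bp, boundary inclusive) of a reference-track (CTCF) site center
on the same chromosome. Distance is measured center-to-center: the rule is
symmetric, summit-compatible, and idempotent. Whether edge-to-edge distance
was ever intended is unknowable from a plotted figure; the radius is
configurable, and the two conventions differ by at most one interval width.

## Digestion matching

The mean fragment length of an MNase library decreases with digestion
extent; nucleosome-position profiles shift visibly between digestion
levels. Two samples are comparable when their mean fragment lengths agree
within 5 bp (inclusive — "within" is read as ≤). The mean is computed after
the fragment-length cap (default 500 bp) applied at read-in, i.e. on the
fragments the pipeline actually uses. The pipeline warns and flags the
manifest when compared conditions mismatch but still completes the run.

## Peak detection and spacing estimation

Peaks are local maxima of the smoothed profile with prominence at least
`prominence_frac` (default 0.25) times the profile s.d. — prominence is
expressed relative to the s.d. so the threshold is invariant to the
mean-rescaling constant. Candidates are localized by a base-subtracted
centroid over ±`min_separation/2` (the 51 bp box smoother turns a narrow
dyad bump into a near-flat plateau whose argmax wanders; the centroid of the
symmetric plateau does not, and on a noiseless profile it equals the exact
lattice position). Candidates are then kept greedily in decreasing
prominence order subject to pairwise separation ≥ `min_separation` (default
120 bp: below one core footprint, above smoothing-ripple scale), with ties
going to the peak nearer the anchor. Localizing before the separation test
matters: with a +1 nucleosome only ~129 bp from a strong site-centered peak,
argmax noise would otherwise intermittently discard a genuine +1.

`summarize_phasing` assigns peaks to flanks; a peak within 73 bp of the
anchor (half a core footprint) is the site-occupying nucleosome of unbound
sites and belongs to neither flank — a genuine +1/−1 dyad cannot sit closer
than that. Per flank the NRL is the least-squares slope of |offset| on
outward peak index 1..k (k ≤ 10); the slope uses every detected peak and is
translation-invariant. The profile-level NRL is the mean of the two flank
slopes; the +1/−1 distance is the offset difference of the innermost peaks.
The mean of adjacent peak differences is not used as the primary estimator:
it collapses to `(x_k − x_1)/(k−1)` and wastes the interior peaks.

Condition deltas are plain differences (experimental − control) of the
+1/−1 distance, NRL and central occupancy; the operation is antisymmetric
by construction. The ChIP occupancy-change statistic expresses each
profile's central band (±73 bp) relative to its own background — the mean
of the outermost 10% of the window per side — as `s = (center − bg)/bg`,
and reports `100 × (s_ctrl − s_expt)/s_ctrl`. Using the background-relative
ratio (not the raw difference) makes the percentage invariant to each
profile's rescaling constant; with peak/background enrichments of 10 and
4.6 the statistic returns (9 − 3.6)/9 = 60%, as required by the mixture
construction.

## The synthetic generator

The generator emulates exactly the structure the analysis assumes, so
parameter recovery is a meaningful end-to-end test:

- **Bound sites** (probability `bound_fraction`, default 0.9) carry dyads at
  `±(plus_one_distance/2 + k·nrl)`, k = 0..9; each lattice point is sampled
  Poisson(`dyads_per_site / 20`) times (default ~30 dyads/site total) with
  Gaussian jitter of s.d. `jitter_sd0 + k·jitter_growth`. Linear jitter
  growth (default 2 bp start, 2 bp/index) reproduces the observed decay of
  phasing away from the barrier with one parameter; no quantitative decay
  rate is published, so the growth rate is a calibration choice, not a
  measured value.
- **Unbound sites** carry Poisson(`dyads_per_site`) dyads at the site center
  (s.d. 15 bp): vacant CTCF sequences have high intrinsic nucleosome
  affinity, which is what produces the occupancy gain at sites after
  CTCF/SNF2H depletion.
- **Background** dyads arrive uniformly at `background_rate` (default
  0.002/bp) over each ±1 kb site window.
- **Digestion**: each dyad becomes a fragment of the 147 bp core plus
  independent geometric overhangs per side — the simplest one-parameter
  family with freely settable mean. `overhang_mean` 0 gives exactly 147 bp
  fragments (full digest); 11 gives a 169 bp analytic mean (light digest).
- **Scenario presets** perturb only the parameters the named depletion
  changes: SNF2H-like — NRL 176 → 183 bp, +1/−1 +25 bp, faster decay;
  SNF2L-like — NRL 176 → 173 bp, +1/−1 −10 bp; CTCF-loss —
  `bound_fraction` 0.9 → 0.3. The control +1/−1 distance is 280 bp, a
  mid-range value among surveyed factors (the published extremes are 258
  and 364 bp); no CTCF-specific +1/−1 value is published, and only shifts
  of this parameter are compared across conditions.
- **ChIP**: fragment midpoints from a per-site Gaussian (s.d. `peak_sd`)
  plus uniform background, with signal weight solved so the peak stands at
  `enrichment − 1` times background density.
- **DE tables**: shared responders get bivariate-normal log2 fold changes
  with Pearson parameter `2·sin(π·ρ_s/6)` (the inverse normal
  rank-correlation identity) to hit a target Spearman ρ_s; private
  responders are sampled independently per table (so with no shared genes
  the two significant sets are independent and the overlap test is
  null-calibrated); nulls have near-unit fold changes and uniform p;
  q-values are Benjamini–Hochberg within table.

What the generator does **not** model: sequence-dependent nucleosome
affinity, mappability/GC bias, chromosome structure beyond a single
synthetic chromosome, inter-site heterogeneity in NRL, and digestion-level
dependence of *positions* (only lengths shift). Passing tests therefore
demonstrate that the estimators recover the barrier-model parameters under
realistic counting noise — not that real chromatin obeys the model.

## Problem sizes and tolerances

Validation cohorts use 2000 sites × ~30 dyads/site (≈60k fragments), the
scale at which spacing estimates stabilize to well under 1 bp when averaged
over 10 seeds; fragment-length checks use ~10⁵ fragments, where the s.e. of
the mean is ≈0.05 bp. The overlap null-calibration check runs at the study
scale of 3294 measured genes, because at a few hundred genes the discrete
hypergeometric test is conservative enough (rejection rate ~0.035) to fall
outside a ±0.03 band around the nominal 0.05 level. The hypergeometric tail
is summed from log-pmf terms via log-sum-exp; `log10(p)` is reported
alongside `p` since observed overlaps push p below double underflow.

## Degenerate inputs and tie rules

All-zero profiles refuse normalization ("no signal in window"); flat
profiles yield an empty peak set; a flank with fewer than two peaks has no
NRL (one-flank summaries are legal, zero-flank summaries raise); length
statistics break mode ties toward the smaller length; fragments clipped at
coordinate 0 are kept and counted; interchromosomal or over-length BEDPE
pairs are dropped and counted, never fatal; duplicate DE gene ids keep the
first row with a warning. Fragment de-duplication after unique mapping is
not applied by default (the upstream handling is unspecified); it can be
added as a pre-filter on the fragment list if desired.
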