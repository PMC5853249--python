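# Methods

## The association statistic and its null model

Each analysed cell is an axis-aligned rectangular window (nm
coordinates, origin at a corner) representing one paradermal confocal
focal plane; the cell's papilla centres and actin bundle segments are
referenced to it. A papilla is **associated** when at least one endpoint
of at least one *linear* bundle lies at Euclidean distance strictly
below the threshold (default 400 nm) from its centre. Circular bundles
(actin rings around initiating papillae) have no ends and are excluded
from the statistic, though the data model carries them. The per-cell
statistic is the percentage of associated papillae.

The null model holds the papillae fixed at their measured coordinates
and re-places the observed bundle population — same count, same
(length, diameter) list — uniformly at random: segment midpoints uniform
over the window, orientations uniform on [0, π), conditioned on the
whole segment lying inside the window by rejection sampling (capped at
10⁶ draws). Full containment is used because observed bundles were
recorded within the cell; a `torus` edge mode (periodic wrapping, no
rejection) is available for sensitivity analysis. The single-tail
p-value is the proportion of the `n_sims` replicates (default 1000)
whose association percentage is ≥ the observed one, computed on raw
counts so ties are handled exactly. A raw p of 0 is reported numerically
as 0 and rendered `< 1/n_sims`; no +1 pseudo-count is applied by default
(the plain proportion matches the convention of reporting p-values like
0.004 and 0.001 at 1000 simulations), with `(k+1)/(n+1)` available as an
option. Cohort aggregation reports the mean of per-cell percentages with
the standard error `sd(ddof=1)/√n_cells`; the SE of a single cell is
defined as 0.

Randomness: each test invocation takes one integer seed; replicate
`i` uses the substream `SeedSequence([seed, i])`, so results are
bit-reproducible and independent of vectorization order.

Under the null the p-value is discrete and (up to the k/n convention)
uniform; the suite verifies an empirical type-I error ≤ 0.07 at nominal
0.05 over 500 synthetic null cells, and ≥ 90 % power at attachment
fraction 0.6 with 20 papillae and 25–30 bundles per 10 × 10 µm cell —
the measured geometry of the study system.

## Synthetic data

The generators emulate the statistical structure of the micrograph
measurements, not the images themselves.

- **Papillae**: a square lattice at pitch `spacing` (default 1500 nm).
  The window is tiled with `floor(side/spacing)` whole lattice cells per
  axis, one site at each cell centre; sites are jittered by isotropic
  Gaussian noise (`jitter_sd`, default 0; 150 nm in the test cohorts)
  and points displaced outside the window are dropped. A square lattice
  with jitter was chosen over a hexagonal one; the published spacing and
  areal density are consistent with either, and the true spacing
  distribution is not published.
- **Bundles**: lengths and diameters are truncated-normal (>0) with
  defaults 1100 ± 100 nm and 150 ± 40 nm. The published dimension
  uncertainties are standard errors of the mean (n = 120), not
  population spreads, so the sds here are package defaults exposed in
  the config. With probability `assoc_fraction` a bundle gets one
  endpoint uniform in the disc of radius `attach_radius` (default
  400 nm) around a uniformly chosen papilla, the other endpoint at the
  sampled length in a uniform direction redrawn until contained;
  otherwise it is placed exactly as the Monte-Carlo null places it (the
  two laws coincide at `assoc_fraction = 0`, verified by a two-sample
  KS test on end-to-nearest-papilla distances). The default
  `assoc_fraction` of 0.6 puts synthetic cohorts in the regime of the
  observed data (roughly 60 % papilla association against a ~20 %
  chance-overlap background at this geometry).
- **Fluorescence**: per-cell regional intensities are region true mean
  plus Gaussian cell noise, 25 cells per cotyledon × 4 cotyledons,
  for a treatment and its BFA baseline. Intensities are not clipped at
  zero: at realistic means and noise the boundary is never approached,
  and clipping would bias the null-correction check. Summaries average
  cells within cotyledons first and report mean ± SE across cotyledons
  (n = 4), matching the design of the fluorescence tables.
- **Time courses**: two logistic curves of % cells (midpoint 7 h, time
  scale 1.5 h on a 0–15 h hourly grid — the span of the culture
  experiments), the papilla curve displaced by `lag_h`, with additive
  Gaussian noise clipped to [0, 100].

What passing tests on these data show: the statistic, null model and
estimators behave correctly for point patterns and segment populations
with the measured first-order geometry. What they do not show: behaviour
under clustered (non-lattice) papilla arrangements, curved bundles,
segmentation error in endpoint detection, or 3-D effects collapsed into
a single focal plane — each focal plane is analysed as a separate cell
record.

## Fluorescence correction

Corrected regional mean = `max(0, treatment − BFA)`; negative
differences are floored at 0 for reporting (the published tables print
exact zeros) with the raw difference retained for diagnostics. The SE of
the unpaired difference of two independent means is `√(SE₁² + SE₂²)` —
the standard estimator. Totals sum regional means with SEs combined in
quadrature. Derived statistics are reported rounded the way such values
are conventionally printed (fold change to 1 decimal, percent decline to
1 decimal, percent inhibition to the nearest integer); raw values are
available via `raw=True`. Of the fourteen published corrected-table
rows, eleven reproduce their printed totals exactly from the printed
regional means, one differs by a single rounding unit, and two
(latrunculin B, 485 vs 505; the dynamin-series 9 h + 6 h control, 419 vs
429) do not sum — presumably totals computed before rounding or
typographic slips; the test suite quarantines those two and allows ±1 on
the rounding-level row.

## Membrane budget

The papilla solid is a cylinder of diameter `d` and height `h` with a
flat cap (retained area `πdh + πd²/4`, volume `π(d/2)²h`) or a
hemispherical cap (`πd(h − d/2) + πd²/2`; `π(d/2)²(h − d/2) + ⅔π(d/2)³`).
Defaults are the measured `d = 380` nm and `h = 500` nm with a flat cap.
Vesicle-delivered volume is `(1 − f_c)·V_p`, fused membrane
`6·V_d/d_v`, and retrieval `R = 1 − A_ret/A_fus`, clamped to 0 with a
warning when fusion cannot cover retention. `R` is strictly decreasing
in both `f_c` and `d_v` and invariant under uniform rescaling of all
lengths including `d_v`. The underlying published calculation's fixed
constants (vesicle size, callose fraction, cap treatment) are in
supplementary material not available here, so the module ships
`calibrate_budget` (Brent bisection, relative tolerance 1e-9) to solve
for one unknown instead of hard-coding unverifiable constants; at a
100 nm vesicle, matching the reported 61 % retrieval requires
`f_c ≈ 0.46`, and with no callose at all the same geometry retrieves
~79 % — consistent with in-situ callose synthesis being what lowers the
papilla estimate below the root-hair (87 %) and pollen-tube (79 %)
figures.

## Morphometrics

Wall thickness is cross-sectional area / cell width (nm² nm⁻¹ = nm),
the estimator used for uneven wall layers. The remodelled-cell
classifier is strict (`> 0.5` occupancy of the interface). Bundle
verticality is an upstream flag (through-plane bundles appear as dots),
not inferred from 2-D coordinates. The lag scan shifts the second series
by each candidate lag (default grid resolution 0.25 h), linearly
interpolates onto the overlapping grid (≥ 3 points required), and
returns the lag maximising the squared Pearson correlation (first
maximum on ties); the statistic is invariant to affine rescaling of
either series.

## Transcript filter

A transcript passes when it is expressed (RPKM > 1 at 3 h or 12 h) and
either shows log2FC > 1 on 0→3 h or 3→12 h with that interval's
FDR < 0.05, or is up-regulated on both intervals (both log2FC > 0) with
both FDRs < 0.05 — the "sustained up-regulation" branch, whose formal
predicate is this package's encoding. The optional relaxation for
Ca²⁺-sensitive candidates drops only the magnitude gate (log2FC > 1 →
log2FC > 0), keeping expression, direction and FDR requirements; the
original relaxation is described only qualitatively, so this is a
documented interpretation. Selection is monotone: raising any FDR or
lowering any RPKM never adds a gene.

## Problem sizes and numerical choices

The test suite runs its statistical guarantees at 500 null cells ×
200 simulations (type-I), 100 cells × 1000 simulations (power),
200 cells (attachment-fraction recovery) and 200 seeds (lag recovery) —
sizes at which the binomial noise on each checked proportion is well
inside the asserted margins. Distance comparisons use strict `<` at the
threshold; p-values compare integer counts, never floating percentages.
Degenerate inputs error early: zero papillae (statistic undefined),
empty cohorts, non-positive geometry, infeasible segment lengths, and
calibration targets outside the attainable range.

## Known limitations

The association test is 2-D per focal plane and treats bundles as
straight segments with exact endpoints. The null randomizes bundles
only; papilla patterns are conditioned on, so inference is about bundle
placement given papillae. The generators share the analysis module's
geometric primitives for placement (intentional for the distributional
identity at `assoc_fraction = 0`; the test oracles — brute-force
distance scans and an independently coded accept/reject sampler — do
not). The cohort-level mean ± SE treats cells as exchangeable and
ignores cotyledon-level clustering.
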