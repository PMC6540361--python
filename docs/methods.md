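# Methods

This note documents the models, conventions and design choices behind
`cytodiv`, in the order the pipeline applies them.

## Input model and gating

Samples are FCS 3.0/3.1 list-mode files assumed *preprocessed*
(compensated; amplification already resolved). The reader supports
float, double and unsigned-integer data in list mode, checks `$TOT`
against the data segment, and warns — without acting — on `$PnE` log
amplification and `$VOL` keywords. Analyzed volumes and dilution
factors come from the run configuration, not from FCS keywords, because
acquisition software populates the latter inconsistently.

Gates are declared in the configuration: rectangles over any number of
channels, simple polygons over two. The boundary convention is
`[low, high)` — closed low edge, open high edge — matching the binning
convention, so a gate edge and a bin edge classify an event the same
way; polygon boundary points count as inside (shapely `covers`).
Workspace formats from acquisition software are deliberately not
parsed: a self-describing YAML file keeps runs reproducible and
reviewable.

## Normalization

Translation (bead anchoring) happens on the pre-transform scale, then
the optional asinh step; both can be disabled. Bead statistics use the
arithmetic mean of the bead-gated events of the *ungated* file (beads
normally sit outside the target gate); a median option exists but is
not the default. With shift[i, j] = grand_mean[i] − bead_mean[i, j],
post-translation bead means are equal across samples by construction —
exactness is limited only by floating-point summation, and the test
suite asserts agreement to 1e−9.

The drift model corrected here is a pure per-sample translation. The
synthetic generator plants exactly this kind of drift; real instrument
drift can also stretch or warp intensities, which translation cannot
fix — a known limitation shared with the bead-anchoring model itself.

### asinh cofactors

When no user cofactors are given, each channel's cofactor is chosen
from a grid (default: powers of ten, 1e−1 … 1e5, refined once
geometrically around the winner at ×10<sup>±0.25</sup>,
×10<sup>±0.5</sup>). For each candidate c the channel is pooled over
samples, transformed by asinh(v/c), its 1-D modes found as peaks of a
Gaussian KDE (Silverman bandwidth, 512-point grid, prominence floor 5%
of the maximum density so noise wiggles of a unimodal density are not
mistaken for modes), events assigned to the nearest mode, and
Bartlett's statistic computed over the groups; the smallest statistic
wins, ties toward the smaller cofactor. Channels where no candidate
produces two usable modes fall back to a user cofactor or raise. This
is a deliberate simplification of variance-stabilization approaches
that optimize Bartlett's statistic over clustered 1-D intensities; the
selection contract (minimal Bartlett statistic) is preserved and is
what the recovery test pins down (a channel generated as
100·sinh(z), z a Gaussian mixture with unit variances, selects 100 from
{1, 10, 100, 1000}).

## Binning

* Ranges are computed **after** normalization/transformation, on the
  values actually binned — dynamic ranges are the pooled min/max per
  channel, fixed ranges are user limits (out-of-range events are
  dropped and tallied, never clamped).
* The Freedman–Diaconis count uses linear-interpolation ("type 7")
  quantiles for the IQR; that convention is load-bearing for exact
  oracle agreement and is therefore stated here. Worked example:
  values 0…99 give IQR 49.5, width 2·49.5·100<sup>−1/3</sup> ≈ 21.33,
  so ⌈99/21.33⌉ = 5 bins.
* The pipeline bin count is the **round-half-up** arithmetic mean of
  all per-(channel, sample) suggestions; degenerate pairs (zero IQR)
  are excluded with a warning. One common bin count applies to every
  channel.
* Bins are equal-width, half-open `[edge, next_edge)` with the final
  bin closed at the channel maximum (numpy's histogram convention), so
  in-range events map to exactly one cell — conservation is property-
  tested with events planted on the edge lattice.
* Vectorization is row-major over the channels in configured order and
  is invertible; empty bins are retained so every sample shares one bin
  universe (required for comparable β indices).
* Volume correction multiplies column j by d_j = min(volume)/volume_j.
  Using the minimum scales counts down rather than up, avoiding
  inflation of background noise from long runs; at least one d_j = 1
  and within-sample relative abundances are unchanged.

## Diversity

α indices per volume-corrected column, with p the positive-bin relative
abundances: richness #{x>0} (no minimum-count floor by default; a
configurable floor exists for noisy data), Shannon −Σp ln p (nats),
Simpson 1−Σp², inverse Simpson 1/Σp², Pielou shannon/ln(richness)
(reported as NaN with a warning when richness = 1, since ln 1 = 0).

Bray–Curtis on raw corrected counts, with A = Σmin, B and C the
one-sided surpluses: bray = (B+C)/(2A+B+C), balanced =
min(B,C)/(A+min(B,C)), gradient = bray − balanced. The identity
balanced + gradient = bray is exact and property-tested at 1e−12. When
A + min(B,C) = 0 (one profile empty) balanced is defined as 0, making
the whole dissimilarity gradient. Incidence-based β uses presences
F > 0 *after* volume correction and the 24 pairwise formulas tabulated
by Koleff (ids and formulas in `docs/koleff_indices.md`); undefined
combinations return NaN rather than raising.

Standardizations mirror the community-ecology conventions: total,
hellinger, pa and log act per sample (column of bins × samples); max,
range and standardize act per bin (row). Log is log₂(x)+1 for x > 0.

## Ordination and clustering

nMDS is SMACOF majorization with Kruskal's monotone regression
(pool-adjacent-violators, primary tie approach) for the disparities,
reporting Kruskal stress-1. Defaults: 2 dimensions, 20 random restarts
plus one classical-scaling start, 500 iterations, stress tolerance
1e−7; the lowest-stress configuration wins and scores are centered.
All randomness comes from the configured seed, so runs are bit-for-bit
reproducible. Exactly embeddable inputs (any 3-point metric, distances
of a planar configuration) reach stress < 1e−3, which the tests assert.

Bin ("species") scores are abundance-weighted averages of the sample
scores — the weighted-averages biplot convention; all-zero bins get NaN
scores and are excluded from clustering. K-means (k-means++, Lloyd,
best of 10 inits, seeded) clusters the bin scores; the number of
clusters maximizes the Calinski–Harabasz criterion over K = 2…10, ties
toward smaller K, with the full (K, C) table written out. C is
undefined at K = 1 (the K−1 divisor), hence the range starts at 2. A
`ch_rule: min` switch selects the minimizing K instead for
compatibility with descriptions that phrase the criterion as "lowest";
as defined, C grows with partition quality, so maximization is the
default. WG_SS = 0 (every point on its center) yields +inf with a
warning.

## Masking

Bin clusters are projected onto a chosen channel pair as one label grid
shared by all samples. With more than two binned channels, each 2-D
cell takes the label of the cluster holding the largest total corrected
count among the n-D bins above it (count-weighted majority); with two
channels this is the identity map. Cells with zero count stay
unlabeled. Overlays render the per-cell event density (log-shaded
grayscale) with cluster colors alpha-blended; the label grid is also
written as CSV so tests assert on labels and sampled pixels rather than
image bytes. The palette is cosmetic and configurable.

## Synthetic data

The generator emulates what the pipeline must correct and measure:
Gaussian-mixture subpopulations on the analysis channels, a tight bead
population (mean 3000, σ 5) identical across samples before drift,
per-sample translational drift applied to every event, and per-sample
volumes/dilutions. Events are simulated directly on the post-transform
scale so end-to-end tests can run with asinh disabled; a sinh
back-transformed raw-scale mode supports cofactor recovery. It does
**not** model doublets, debris, spectral spillover or nonlinear warp
(an optional warp flag exists only to document the translation model's
limits), so passing tests demonstrate correctness of the pipeline's
arithmetic and inference under its own drift model, not robustness to
every instrument artifact.

Canned scenarios (each with FCS files, config.yaml and truth.json):
identical-pair (two 10,000-event copies of a 3-subpopulation mixture),
disjoint-pair (non-overlapping mixtures → bray ≈ 1, balanced-dominant),
nested-pair (same locations at half abundance → gradient-dominant),
drifted-with-beads (3 samples, planted shifts ±100/0, 500 beads),
dilution-series (volumes 0.5/1/2 → d = 1/0.5/0.25), and a five-blob
2-D point set (σ = 0.1, separation ≥ 5, 100 points per blob) for
cluster-count recovery. Problem sizes (10⁴ events per sample, ≤ 34
bins per channel, 20 recovery seeds) were chosen so the whole suite
runs in seconds while keeping Monte-Carlo error well inside the
asserted bounds; self-consistency comparisons between identical samples
use the field's classic 16×16 grid, since multinomial noise in the
Bray–Curtis numerator grows with bin count at fixed event count.

## Numerical choices and degenerate inputs

* CSV artifacts are written with `%.17g` and re-read with round-trip
  float parsing, so staged and monolithic executions are byte-identical.
* Constant channels make dynamic ranges and the FD rule degenerate;
  both raise with advice to supply fixed limits / explicit bin counts.
* All-zero abundance columns raise, naming the sample; all-zero bins
  are allowed and simply carry no weight anywhere.
* Empty gates warn but do not raise (an empty gate is suspicious, not
  impossible).
* Exit codes: 0 ok, 2 configuration, 3 data, 4 numeric.

## Known limitations

Translation-only drift correction; no spillover compensation or
logicle/biexponential display transforms; no FlowJo workspace parsing
(config-declared gates instead); no adaptive/probability binning; no
rarefaction or Hill-number profiles; PCoA, PERMANOVA and environmental
fitting are out of scope — the β matrices are written as CSV precisely
so downstream statistical tools can consume them.
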