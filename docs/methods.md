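# Methods

## The occupancy model

The pipeline treats ChIP enrichment as a per-nucleotide intensity
surface rather than a collection of reads. The immunoprecipitated (IP)
and input libraries are summarized as coverage tracks; enrichment at a
position is the log2 ratio of IP to input after two guards and one
correction:

* positions where the IP count falls below the genome-wide IP mean are
  treated as unenriched and carry no value — the method only quantifies
  where there is at least average pull-down signal;
* input counts below the genome-wide input mean are floored to that
  mean, so that sampling zeros or near-zeros in the control cannot
  manufacture large ratios;
* the difference in sequencing depth between the two libraries is
  removed by subtracting log2 μ_IP − log2 μ_input. The subtraction is
  done in log space because the quantity being adjusted is a log2
  ratio; subtracting a raw count difference from a logarithm would mix
  units. The raw-difference variant remains available as
  `adjust_mode="raw"` for comparison.

Values are point samples at 35-bp grid positions, then median-smoothed
in centered, closed windows of 350 bp (11 candidate grid points);
windows holding fewer than 5 present values yield no output. The median
is robust to isolated spikes, and the 5-point floor prevents smoothed
values in data deserts from being dominated by one or two points. The
smoothing window's centering is a convention of this implementation
(trailing windows would shift every downstream coordinate by half a
window); the median of an even count is the mean of the two central
values.

Bound regions are the top tail of the smoothed value distribution: the
cutoff is the (1 − 0.05) empirical quantile (linear interpolation — at
practical track sizes the convention shifts the cutoff by less than the
spacing between adjacent order statistics). Above-cutoff positions
cluster while consecutive hits lie within 200 bp, a cluster's span is
`[first, last + 35)` — each grid value represents its 35-bp bin — and
spans under 200 bp are dropped. Under this reading six contiguous grid
points (span 210 bp) pass and five (175 bp) fail; the alternative
reading that measures only first-to-last distance is available as
`span_includes_bin=False`. Scoring uses *all* present smoothed values
inside the span, not only above-cutoff ones: the peak value is the best
mean over five consecutive present values (missing grid points are
skipped, since the track is sparse by construction), the peak center is
the grid position of the window's middle value, and ties go to the
leftmost window. A region with fewer than five values is scored by the
mean of all of them.

Cross-condition classification requantifies the second condition's
track inside each first-condition span with the same scoring rule and
no rescaling between conditions (each track has already been
depth-adjusted against its own input; the classifier asserts nothing
about the two libraries' relative scale). Labels partition the regions:
`lost` (condition-B value < 0.5 log2, tested first; spans with no
condition-B value at all get a −∞ sentinel and are lost), then by the
log2 change Δ: `up` (Δ > 1), `down` (Δ < −1), `unchanged` (closed band
−1 ≤ Δ ≤ 1). Boundary conventions: Δ of exactly ±1 is unchanged, a
condition-B value of exactly 0.5 is not lost. No condition-B-only class
is defined; the pipeline instead reports a diagnostic count of
condition-B regions with no condition-A counterpart.

Overlap statistics are deliberately asymmetric. Percent overlap counts
the fraction of *query* regions sharing at least one nucleotide with
any target region (a long query hitting several targets counts once),
and both directions are always computed explicitly, never averaged.
Cutoff sweeps step from the minimum to the maximum query score in 20
equal increments and stop after the first cutoff retaining at most 5%
of the query; the three-bin summary uses no cutoff, the ~5%-tail
cutoff, and their midpoint. Sweep cutoffs apply to region scores (the
"binding value" of a region), not to underlying track values.

Annotation ties regions to genes two ways, mirroring how the analyses
consume them: by closest TSS to the peak center (strand-independent
distance, ties to the smaller coordinate) for expression trajectories,
and by span proximity — overlap or a gap of at most 500 bp — for
expression-change comparisons. Promoters are TSS ± 500 bp with both
endpoints included (`[TSS−500, TSS+501)` half-open); gene features
overlap, so feature percentages need not sum to 100, and the genome
fraction of each feature is reported as the baseline for randomly
placed regions. In expression profiles a gene reached by several
regions of one class is counted once for that class. All confidence
intervals are normal-approximation 95% intervals (mean ± 1.96 SE); at
the group sizes involved the difference from t-quantiles is far smaller
than the intervals themselves, and intervals for groups of fewer than
two values are flagged undefined rather than reported as zero-width.

Statistical comparisons are two-tailed t-tests without the equal
variance assumption (Welch statistic, Welch–Satterthwaite degrees of
freedom) and paired t-tests over matched regions; differences with zero
variance make the paired statistic undefined and are flagged, never
silently reported. When several histone-modification marks are compared
between two genotypes, all marks' replicates are pooled into one sample
per genotype before the Welch test. ChIP-qPCR fold enrichment assumes
perfect per-cycle doubling (efficiency 2, configurable):
2^(Ct_input − mean of the IP duplicates), times an input-dilution
factor that is exposed as a plate-level constant but cancels under
reference normalization (the default of 1 is therefore safe whenever
only normalized values are reported, which is the supported use).
Values are normalized per replicate to a single control locus or to the
mean of two intergenic background sites, and histone marks are further
divided by the identically normalized total-H3 ratio at the same locus.

## The synthetic-data generator

The generator produces inputs with the statistical structure the
analysis assumes, not a sequencing emulator: no reads, fragments,
mappability or GC structure, and no biological replicates.

* **Coverage.** Input counts are Poisson with uniform rate λ_bg
  (default 10 reads/nt); IP counts are Poisson at λ_bg outside planted
  peaks and λ_bg·2^e(x) inside. The enrichment profile e(x) equals the
  peak's summit value at the midpoint and declines linearly by
  `summit_taper` (default 0.5 log2) toward the edges: real ChIP
  enrichment is unimodal around a binding site, and a perfectly flat
  profile would leave the summit position undefined for any scorer
  (with a rectangle, the best five-value window floats freely across
  the plateau). `summit_taper=0` restores rectangular peaks.
* **Reference conditions.** The default data set is a 1-Mb genome with
  20 peaks of summit enrichment 3.5 and widths 550–750 bp — a peak
  density of the order of a genome-wide call set of a few thousand
  peaks on a ~120-Mb genome. These numbers put the top-5% cutoff in the
  lower tail of the planted peak-value distribution, the regime the
  quantile rule is designed for (the cutoff below the bulk of true peak
  values, with background well underneath), and keep every
  cross-condition class away from the decision boundaries: with a
  second condition derived by +2/0/−2 log2 rescaling or removal
  (cycling over peaks), the expected requantified values sit several
  noise standard deviations from both the ±1 change band and the
  0.5-log2 lost floor. At a summit enrichment of 3.0 the "down" class
  lands almost exactly on the lost floor after the pipeline's own
  flooring, depth adjustment and median smoothing — a genuinely
  ambiguous truth assignment rather than a hard test. The
  second-condition seed is the root seed plus one, so the two
  "libraries" are independent draws, as separately prepared samples
  would be.
* **Factor compendium.** 40 factor sets of 60 scored regions each
  (about 1% of a genome-scale factor set, matching the 1% genome
  scale). A fraction `hotspot_fraction` (default 0.3) of each factor's
  regions sits at shared hotspot loci with identical coordinates; the
  rest are uniform. HOT regions are the maximal runs of constant
  factor-coverage ≥ 1, scored by that coverage, so the emitted HOTness
  is exactly recountable from the factor regions.
* **Expression.** Each gene carries a trajectory class; values are the
  class mean per time point plus Gaussian noise (SD 0.5 log2). The
  default class shapes follow the qualitative structure the analysis is
  meant to resolve: classes gaining occupancy in condition B start high
  and decline across development, classes losing occupancy start low
  and rise. A per-gene expression *change* between conditions is drawn
  the same way (+1/0/−1 by class). In the full pipeline, gene classes
  are assigned from the nearest planted peak's label, coupling the
  expression structure to the occupancy structure end to end.
* **Determinism.** One root seed feeds named, independent child streams
  (coverage, factors, expression, genes, placement), so adding a factor
  set never perturbs the coverage draw; every artifact pairs with a
  machine-readable truth table.

What passing tests on this generator shows: the implementation applies
the stated rules exactly (oracle equivalence), and under the generator's
idealized noise model the pipeline recovers planted peaks, labels, and
expression structure. What it does not show: robustness to
overdispersed or position-dependent coverage, mappability artifacts,
replicate variability, or peak shapes other than tapered plateaus.

## Problem sizes and tolerances

The test suite runs the deterministic operations against independent
brute-force oracles (track construction and smoothing to 1e-9 on fifty
100-kb genomes; caller boundaries, values and centers exactly on two
hundred tracks of up to 1000 grid points; overlap statistics exactly on
five hundred randomized set pairs; t-test p-values to 1e-6 against
numerical integration of the t density) and the stochastic recovery
checks on twenty seeds of the reference simulation (recall ≥ 0.95,
precision ≥ 0.90, mean peak-center error ≤ 70 bp — two grid steps —
and ≥ 95% correct class labels). Null-calibration checks use 2000
simulated tests (Kolmogorov–Smirnov uniformity of p-values at α = 0.01).
The acceptance script aggregates ten two-condition simulations. These
sizes were chosen so the whole suite completes in about a minute while
leaving the binomial uncertainty of each rate estimate well inside the
asserted margins.

## Known limitations

* The quantile cutoff ties the number of called regions to the *share*
  of present grid values that are truly enriched; data sets in which
  enrichment occupies far less than 5% of the informative genome will
  see the cutoff drop into the background distribution and call
  spurious short clusters. This is a property of the method, visible in
  the generator when peak mass is reduced.
* Presence of a grid value requires IP ≥ μ_IP, so heavy global
  enrichment inflates μ_IP and silently thins the background track;
  comparisons between conditions with very different total enrichment
  mass inherit that asymmetry (the classifier deliberately applies no
  cross-condition rescaling).
* Region count is not monotone in the threshold: raising the cutoff can
  split one long region into several that each still pass the length
  rule. Higher-threshold regions do always nest inside lower-threshold
  ones.
* Peak centers on wide, flat summits are identifiable only up to the
  plateau width; the reported center is the leftmost best window's
  middle position.
* No FDR control, local background modelling, or read-level processing:
  the pipeline starts from coverage tracks and makes no claims about
  alignment artifacts upstream of them.
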