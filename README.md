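# occudiff

Differential co-activator occupancy analysis for ChIP-seq.

Transcriptional co-activators such as CBP/p300 bind thousands of
regulatory regions, and a central question in regulatory genomics is how
that occupancy redistributes when a transcription-factor input is
removed — for example, comparing wild-type *Drosophila* embryos with
mutants in which a factor never enters the nucleus. `occudiff`
implements, as a tested and reusable pipeline, a bespoke analysis built
around per-nucleotide read-count tracks rather than read-level peak
callers: normalized log2(IP/input) enrichment tracks on a fixed grid,
quantile-threshold peak calling with explicit extension and scoring
rules, cross-condition classification of every bound region, interval
overlap statistics against transcription-factor region compendia and
high-occupancy-target (HOT) regions, gene/expression annotation, and
the accompanying ChIP-qPCR and t-test statistics. A seeded
synthetic-data generator reproduces the statistical structure the
method assumes, so every stage is testable end to end without
downloading sequencing data.

## The method

Given IP and input coverage tracks (reads per nucleotide), with
genome-wide means μ_IP and μ_input:

1. **Enrichment track.** At every grid position p (step 35 bp), if
   IP(p) ≥ μ_IP:

   v(p) = log2 IP(p) − log2 max(input(p), μ_input) − (log2 μ_IP − log2 μ_input)

   otherwise the position is missing. Flooring the input at its mean
   stops low-coverage noise from inflating ratios; the final term
   normalizes for sequencing depth.
2. **Smoothing.** v is median-filtered in centered 350-bp windows
   (11 grid points); windows with fewer than 5 data points are
   discarded.
3. **Peak calling.** The cutoff is the 95th percentile of all smoothed
   values (the top 5%). Above-cutoff positions are clustered left to
   right, extending while the next value lies within 200 bp; clusters
   spanning < 200 bp are dropped. Each region's **peak value** is the
   best mean over five consecutive values inside it and its **center**
   the middle position of that window.
4. **Classification.** Condition-B signal is requantified inside each
   condition-A region with the same scoring rule (no cross-condition
   rescaling). A region is **lost** if its condition-B value is below
   0.5 (log2); otherwise, with Δ = v_B − v_A, it is **up** if Δ > 1,
   **down** if Δ < −1, and **unchanged** for −1 ≤ Δ ≤ 1.
5. **Overlap statistics.** Percent overlap between scored interval sets
   counts a query region once if it shares ≥ 1 nucleotide with any
   target region; comparisons use all regions, the top-300 by score, or
   20-step increasing-cutoff sweeps stopped when ~5% of the query
   remains, with three summary cutoffs (none, midpoint, ~5% tail).
6. **Annotation.** Regions are tied to the closest TSS (expression
   trajectories per class with 95% CIs), to gene features
   (promoter = TSS ± 500 bp, intron, intergenic, against the genome
   coverage baseline), and to genes within 500 bp (expression change
   per class and per named gene set).
7. **Statistics.** Two-tailed Welch t-tests, paired t-tests over
   matched regions, pooled comparisons of histone-mark replicates, and
   ChIP-qPCR fold enrichment 2^(Ct_input − mean Ct_IP) normalized to
   reference loci (and to histone H3 for histone marks).

Every constant lives in `PipelineConfig` and can be overridden from
TOML.

## Worked example

```python
from occudiff import call_peaks, classify_regions
from occudiff.classify import class_summary
from occudiff.simulate import (
    default_sim_spec, condition_b_spec, simulate_coverage, simulate_factor_sets,
)

spec = default_sim_spec(seed=1)            # 1-Mb genome, 20 planted peaks
ip, inp = simulate_coverage(spec)
track_a, cutoff, regions = call_peaks(ip, inp)
print(f"cutoff = {cutoff:.3f} log2, {len(regions)} bound regions")

spec_b = condition_b_spec(spec)            # +2 / 0 / -2 log2 / removed
ip_b, inp_b = simulate_coverage(spec_b)
track_b, _, _ = call_peaks(ip_b, inp_b)
classified = classify_regions(regions, track_b)
factors, hot, _ = simulate_factor_sets(spec)
print(class_summary(classified, hot).round(2))
```

prints

```
cutoff = 2.865 log2, 20 bound regions
           n  pct_hot  mean_hotness  mean_peak_value
label
up         5     60.0          1.33             3.14
unchanged  5     60.0          1.67             3.08
down       5    100.0          1.60             3.11
lost       5     80.0          2.25             3.07
```

The cutoff (2.865) is the 95th percentile of the smoothed enrichment
values; all 20 planted peaks are recovered, and the classifier assigns
each its planted occupancy class (5 per class). `pct_hot` is the share
of each class overlapping a HOT region and `mean_hotness` the average
number of factors bound there.

The same stages are available from the shell:

```bash
occudiff simulate --seed 1 --outdir sim/
occudiff call-peaks --ip sim/ip.bedgraph --input sim/input.bedgraph \
    --genome sim/genome.tsv --out-bed peaks.bed
occudiff run-all --seed 1 --outdir run/     # full pipeline + manifest.json
```

## Layout

| module | contents |
| --- | --- |
| `occudiff.config` | `PipelineConfig`: every numeric constant of the method |
| `occudiff.tracks` | coverage/ratio tracks, flooring, depth adjustment, median smoothing |
| `occudiff.peaks` | quantile cutoff, region calling, top-5-consecutive scoring |
| `occudiff.classify` | requantification, up/unchanged/down/lost labels, HOT summaries |
| `occudiff.overlap` | `RegionSet`, percent overlap, top-N, cutoff sweeps, matrices |
| `occudiff.annotate` | closest TSS, feature profiles, expression trajectories and changes |
| `occudiff.stats` | Welch/paired/pooled t-tests, qPCR fold enrichment |
| `occudiff.simulate` | seeded generator for coverage, factor/HOT sets, genes, expression |
| `occudiff.io` | bedGraph / BED / BED12 / GFF3 / TSV readers and writers |
| `occudiff.pipeline`, `occudiff.cli` | orchestration and the `occudiff` command |

See `docs/methods.md` for the modelling assumptions, parameter
defaults, and known limitations.
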