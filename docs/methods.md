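# Methods

## Scope and coordinate conventions

The package analyzes promoter-centric MeDIP-chip data: per-replicate
probe tables of log2 MeDIP/input ratios on arrays tiling the
neighborhood of annotated TSSs. All genomic coordinates are 0-based and
half-open; TSS-relative positions are negative upstream, and every
TSS-relative window is half-open `[lo, hi)`, so the upstream (−1000..0)
and downstream (0..+1000) windows partition the promoter-proximal
region without double counting. Probe position is the interval
midpoint, the standard convention for tiling probes; strand is handled
by mirroring (`rel = tss − mid` on the minus strand), which makes the
two strands exactly symmetric (a property the test suite asserts).

## Normalization

Ratios are centered on zero per replicate. The default estimator is the
median (idempotent, rank-preserving, deterministic); a Tukey biweight
location is available for data with heavy asymmetric tails. Since the
enrichment statistic is rank-based, the choice affects only reported
levels (metagenes, medians), not calls.

## Windowed one-sided KS scoring

Each probe's window sample consists of all probes on the same
chromosome whose midpoint lies within ±375 bp (750-bp window); the
background is every other probe on the array (configurable to
per-chromosome background). The statistic is
`D+ = sup_x [F_bg(x) − F_win(x)]`, evaluated just below each window
value with strict-inequality tie handling, clamped to [0, 1]. Windows
with fewer than `min_window_probes = 4` members are left unscored
(p = 1, flagged): an "all probes" rule over a near-empty window would
be vacuous. Runs of qualifying probes are broken across tiling gaps
wider than 1 kb so that discontiguous tiled regions cannot fuse into
one peak.

Three p-value routes are provided, and the distinction matters:

- **asymptotic** — `p = exp(−2 D+² mn/(m+n))`, the first-order
  large-sample tail. This is the default for array scoring. It is
  smooth in `D+` and approaches 1 continuously as `D+ → 0`, which the
  hypomethylation rule (below) requires.
- **exact** — the finite-sample tail `P(D+ ≥ d)` for continuous data,
  computed by counting lattice paths over all interleavings of the two
  samples (an O(mn) dynamic program propagating hypergeometric path
  probabilities). This is the default for standalone two-sample tests
  at feasible sizes and agrees with an independent exact implementation
  to machine precision and with permutation oracles to Monte-Carlo
  error. The plain asymptotic formula, by contrast, deviates from the
  true null by 10–40% relative for window sizes of 5–8, which is why it
  is not the inference default.
- **permutation** — Monte-Carlo label shuffling (rank-based,
  vectorized, add-one smoothed), used as an oracle in validation.

Why the array scorer still uses the asymptotic route: the exact null of
`D+` for a small window has an atom near zero — `P(D+ > 0)` is bounded
below 1 (the window minimum beats the whole background with probability
≈ m/(m+n) alone) — so an exact p-value can essentially never reach the
0.99 confidence floor that defines hypomethylated promoters, and the
rule would be degenerate. The smooth asymptotic score assigns
confidently non-enriched probes p-values arbitrarily close to 1 and
makes the published rule operational; it also reproduces the scoring
semantics of the original array software this pipeline models. Both
cutoffs applied to it (0.01 for peaks, 0.99 for hypomethylation) are
used as published rather than as calibrated tail probabilities.

## Peak calling and promoter calls

A peak is a maximal run of ≥ 2 consecutive probes (array order, same
chromosome, gap rule above) with p ≤ 0.01; its interval spans the first
member's start to the last member's end. A promoter is **methylated**
when its TSS-relative analysis window (default −5 kb..+1 kb) overlaps at
least one peak in each of the two replicates — the replicate-consistency
requirement is what controls false positives. Methylated promoters are
subclassified by which of the −1..0 kb and 0..+1 kb windows are hit
(Up-only / Down-only / TSS).

A promoter is **hypomethylated** when the −1..0 kb window contains at
least `min_probes_present = 3` probes and *every* probe there has
p ≥ 0.99 in both replicates; with fewer probes the result is `no_call`
rather than a vacuous `yes`. Probe membership for this rule uses
footprint intersection with the window (not midpoint containment).
This choice makes methylated-upstream and hypomethylated structurally
mutually exclusive: any peak overlapping the window necessarily
contains a p ≤ 0.01 probe whose footprint lies inside it, vetoing the
all-probes rule. The batch caller (`call_promoters`) is an indexed
implementation of exactly these per-gene operations and is tested for
equivalence against them.

## CpG promoter classes

The 1-kb upstream sequence is scanned with a 500-bp window; a promoter
is HCP if any window has observed/expected CpG ratio ≥ 0.65 and CG
content strictly > 0.30, else LCP. The o/e ratio of a window of
effective length L is `N_CpG · L / (N_C · N_G)`, zero when C or G is
absent; N bases are excluded from all counts and from L, and windows
with > 10% N are flagged. The default scan step is 1 bp — exhaustive,
so no island can be missed by step artifacts; the 10-bp step is used
for CG-density profiling. The CG-content threshold is strict
(`> 0.30`) by default and configurable to inclusive. For region-level
CpG-island counting, qualifying windows whose spans overlap or touch
are merged into islands, and a gene in a cluster of ≥ 3 islands is
flagged; no further extension/trimming refinements are applied to
promoter classification itself, which is a plain window scan.

## Metagenes, levels, transitions

Metagene profiles average replicate-averaged probe ratios into
contiguous 100-bp TSS-relative bins (bin width chosen at the probe
spacing scale; configurable) over a gene set; when KS profiles are
supplied, membership is restricted to genes with ≥ 1 probe at p ≤ 0.01
inside the profiled window in both replicates ("high enrichment
probability"). Replicates are averaged probe-wise before binning. The
profile of a union of disjoint gene sets equals the probe-weighted
average of the parts (asserted as a conservation test). Median
methylation level is the median over genes of the mean windowed ratio.
Stage comparisons are pure set algebra on boolean call matrices with
the percent increase `(later − earlier)/earlier × 100`; identities
(`maintained ∪ lost = earlier`, `|later| = |maintained| + |gained|`)
are asserted.

The per-promoter summary intensity (`maxsixty`) is the maximum over all
runs of 60 consecutive probes of the mean ratio, falling back to the
mean of all probes when fewer than 60 are present; it is used for
replicate-correlation reporting.

## Contingency statistics

Fisher's exact test is two-sided with the probability-mass extremity
criterion (all tables as or less probable than the observed one), the
most common convention; a one-sided alternative is available by flag.
The reported odds ratio is the sample `ad/bc`, with 0.5 added to every
cell only when a zero cell occurs (flagged). The chi-square with Yates'
correction is `Σ (max(|O−E|−0.5, 0))²/E` on 1 df and requires positive
margins. No multiple-testing correction is applied by default, matching
the raw per-test reporting style of the analyses this package
reimplements; a Benjamini–Hochberg helper is provided. Strata for the
mark-by-methylation tables are mutually exclusive: methylated,
hypomethylated, and `no_me` (neither call — genome-average
methylation).

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions the pipeline targets:
1,000+ promoters on 25 chromosomes (40-kb spacing so tiled extents
never collide), probes every 100 bp with 50-bp footprints tiling
−15 kb..+5 kb, duplicate MeDIPs with per-probe noise sd σ = 0.3 of
which a fraction ρ = 0.8 is shared between replicates, methylation
effect Δ = +1.0 log2 units over planted domains, stage-wise methylated
fractions 0.32 / 0.45 / 0.47 with nested (maintained) membership, a
hypomethylated fraction of 0.41, 65% HCPs, cohort mixture
(0.15, 0.13, 0.09, 0.63) and logistic mark/expression associations
(H3K4me3 toward hypomethylated promoters, H3K9me3 toward methylated
ones).

Design choices that were genuinely open:

- **Hypomethylation is planted as signal below genome average** (shift
  −Δ over [−1400, +400)), not as mere absence of methylation. A
  domain-free promoter sits *at* the array average, its probes' scores
  are null-distributed, and the all-probes-p ≥ 0.99 rule essentially
  never fires; hypomethylation as defined here means methylation below
  genome average, and the planted domain extends past the called
  window by the KS smoothing margin, consistent with hypomethylated
  domains extending beyond promoters.
- **The default tiled range is the full −15 kb..+5 kb geometry.** The
  hypomethylation call is sensitive to the fraction of array background
  lying below average: truncating the tiling to the proximal 6 kb
  inflates that fraction roughly fourfold (~12% vs ~3.7%) and destroys
  recall of the 0.99 rule. `SimulationConfig.fast()` provides the
  truncated, smaller geometry for quick tests, with this caveat
  documented.
- Methylated-domain placement is deterministic per category (Up-only
  [−900, −150), Down-only [150, 900), TSS [−450, 450)), chosen so probe
  footprints stay strictly inside the intended windows; genome-average
  promoters optionally carry sub-threshold mosaic bumps (+0.25, two
  non-overlapping 300-bp patches) so the `no_me` stratum is populated
  by near-threshold signal rather than pure noise.
- Promoter sequences are dinucleotide-Markov samples: LCP-like
  background with the C→G transition suppressed to ~0.15 of its
  neutral rate (o/e ≈ 0.15, CG ≈ 0.35), and for HCP-truth genes a
  planted 500-bp i.i.d. segment with expected o/e ≈ 1.0 and CG ≈ 0.55.
  Every sequence is verified against the step-1 classifier (HCP: the
  planted window must reach o/e ≥ 0.8 and CG ≥ 0.5; LCP: every window
  o/e ≤ 0.4) and resampled on violation, so planted classes are exact
  by construction.

What the generator does **not** emulate: dye bias, spatial array
artifacts, amplification bias, copy-number structure, CpG-density-
dependent MeDIP efficiency, and genuinely continuous methylation
levels (domains are binary shifts). Passing the recovery tests
therefore demonstrates the correctness and calibration of the
*algorithms* under the stated noise model, not the biological accuracy
of any particular threshold on real arrays.

Problem sizes used in validation: the end-to-end recovery runs 1,000
genes at the full array geometry (200,000 probes per replicate, two
replicates, one or two stages); oracle-equivalence checks use 10,000
random probe profiles (peaks), 1,000 random 1-kb sequences
(classifier), 100 datasets × 10,000 shuffles (KS p-values) and 1,000
random 2×2 tables with 1,000 null replicates of the reporting pipeline
(statistics). All randomness flows from explicit integer seeds;
identical configuration and seed reproduce byte-identical outputs.

## Numerical details and edge cases

- KS p-values are clamped to (0, 1]; `D+` to [0, 1]. Ties are handled
  by strict-inequality counting on both samples; the permutation
  method assumes continuous data (ties broken by pooled order).
- The exact-null dynamic program propagates probabilities rather than
  path counts to stay in floating range; cost is O(mn) per test.
- Empty inputs (probe sets, gene sets, windows) raise errors rather
  than returning silent defaults; insufficient probe coverage yields
  the explicit `no_call` state.
- Fisher and chi-square inputs are validated (nonnegative integers,
  positive margins where required); degenerate cells in the
  expression-by-mark analysis are skipped with flags rather than
  fabricated.
- Percent increase between stages is undefined (NaN) for an empty
  earlier set.

## Known limitations

- The asymptotic probe score is a first-order approximation used for
  its smoothness and fidelity to the modeled array software, not for
  exact tail calibration; its 0.01/0.99 cutoffs are operational
  definitions.
- The hypomethylation rule's sensitivity depends on array composition
  (the below-average background fraction); on sparse or truncated
  designs it is conservative.
- The classifier treats N-rich windows permissively (N excluded from
  counts); assemblies with long gaps should be pre-filtered.
- `stage_transitions` requires a shared gene universe and does not
  model missing calls.
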