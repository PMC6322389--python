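# Methods

## The analysis model

The package treats a heterodimeric transcription factor as an obligate
α:β dimer whose two α-isoforms (α₁, α₂) compete for a common β partner.
At a bound site the observable is depth-normalized ChIP signal per assay:

    count  = sum of per-base coverage over the site interval
    CPM    = count × 10⁶ / total mapped reads
    RPKM   = CPM × 10³ / site length

Counts follow `samtools bedcov` semantics (per-base depth summed over the
interval); coverage is consumed as bedGraph plus a totals table, never
BAM. CPM is the working unit throughout; RPKM is always computed alongside
and selectable where site lengths differ materially. All coordinates are
0-based half-open; GTF is converted on read. Strand is ignored for peaks
and honoured only for the sign of TSS distances.

### Site definition

1. **Percentile filter.** A candidate peak survives if its raw count
   strictly exceeds the empirical 99.99th percentile of counts at random
   non-overlapping fixed-width (default 400 bp) background regions drawn
   from an accessible-region universe. The threshold is the value at
   0-based index ⌊p·N/100⌋ of the ascending sort — the smallest background
   value whose strict exceedance probability is below (100−p)/100 — so
   "above the 99.99th percentile" carries the empirical-P < 10⁻⁴ reading.
   No interpolation is used, for bit-identical thresholds across platforms.
   Counts are raw (not length-normalized); the background width is fixed,
   which makes the comparison fair, and is configurable.
2. **Replicate consensus.** Peaks from two replicates overlapping by ≥ 1 bp
   are clustered by single linkage; clusters containing both replicates
   become consensus sites spanning the union of member coordinates (no
   supported base is discarded), summit taken from the highest-scoring
   member. One wide peak overlapping two partner peaks yields one site.
3. **Canonical sites.** α-consensus sites overlapping β-consensus by
   ≥ 1 bp, α coordinates retained.
4. **Supersets.** Site sets from several conditions are merged by the same
   single-linkage clustering, keeping per-condition membership flags; the
   result is invariant to input order.

### Stoichiometry

Per site r = (α₁+α₂+c)/(β+c) with pseudocount c = 0.1 CPM (guards
division by zero at weak sites without shifting strong-site ratios. All
ratio work is log₂; correlation statistics are Pearson on log-transformed
signal, matching linear scatter presentations). The key inferential move
is *reproducibility*: per-site log₂ r is computed independently in each
replicate and correlated. Under pure assay noise the correlation is ≈ 0;
genuine site-wise stoichiometry differences reproduce (r well above the
0.2 "noise-dominated" flag threshold). The distribution summary reports
the median, the modal log₂ bin, and the central-98% fold range
(99th/1st percentile of r).

### Condition dynamics

For two conditions quantified on one superset, q = signal_B/signal_A per
site and assay. The tertile corroboration test ranks sites by q(α-total),
forms rank tertiles (sizes differ by ≤ 1, ties broken by site order), and
applies a two-sided Wilcoxon rank-sum test to q(β) between the upper and
lower tertiles; corroboration requires significance *and* a positive
direction. Because q is a ratio of ratios the test is invariant to global
rescaling of either condition's signal.

Wilcoxon tests (rank-sum and signed-rank) use the exact null for small
samples without ties (n ≤ 25), a full permutation enumeration over
midranks when ties occur at n ≤ 12, and the normal approximation with tie
and continuity corrections otherwise. This keeps small-sample P values
exactly reproducible across platforms.

Knockout contrasts are paired signed-rank tests on log₂ CPM of the
surviving isoform, reported per specificity class (classification
s = log₂((α₁+c)/(α₂+c)) with symmetric threshold, default |s| ≥ 1; the
cut-off is a package choice, the classification rule itself follows the
wild-type ratio). Both the two-sided P and a one-sided "increase" P are
reported. Classes with fewer than 5 sites are skipped with a warning.

**Known limitation.** Classifying sites on the same wild-type signal that
enters the contrast selects for downward noise in the surviving isoform's
WT signal and inflates the apparent one-sided "increase" rate by roughly
two percentage points at the default noise level (measured ≈ 7.0% vs
≈ 5.25% at nominal 5% over 400 null simulations). The calibration checks
therefore classify on an independent wild-type quantification; analyses
that must classify on the contrasted signal should interpret marginal
one-sided P values conservatively.

### Genomic distribution

Distances are summit-anchored and signed by gene strand (negative =
upstream). Nearest-TSS search is an exhaustive minimum over same-chromosome
TSSs (binary search over the sorted positions); equidistant ties break to
the lexicographically smaller gene id and are flagged. Profiles use
symmetric log-spaced magnitude bins (±0–1 kb, 1–10 kb, 10–100 kb, >100 kb
by default; the scheme is configurable and chi-squared conclusions are
robust across schemes in the tests). Two-sample comparisons are chi-squared
on the 2×k count table without continuity correction; joint-zero bins are
dropped and sparse tail bins are folded inward until ≥ 80% of cells have
expected counts ≥ 5.

### Enrichment

Co-binding uses the accessible-region universe as a finite population:
N accessible regions, K overlapping the other factor, n overlapping the
heterodimer, k overlapping both; P is the hypergeometric upper tail
(computed in log space via the survival function). GSEA is pre-ranked and
weighted (p = 1): hits add |π|^p normalized to sum 1, misses subtract
1/(N−m); ES is the signed maximum deviation of the running sum (classic
convention; extrema are evaluated in closed form at hit boundaries, which
the tests check against a full running-sum walk). The null permutes gene
labels — the only null available to a pre-ranked analysis — with
P = (1 + #direction-matched |ES_null| ≥ |ES|)/(n_perm+1), so P is never
zero; NES divides ES by the mean magnitude of same-sign null scores.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, on
a single synthetic chromosome:

- **Annotation:** n_genes TSSs uniformly spaced with jitter, random strand.
- **Sites:** isoform-1-specific sites placed Normal(TSS, 500 bp);
  isoform-2-specific sites uniform at 5–100 kb from any TSS; shared sites
  (fraction `shared_fraction`) placed proximally by default (conserved
  sites are the more promoter-proximal class). Minimum separation 1 kb.
  Isoform mixing: specific sites have α₁ share 0.9 / 0.1; shared sites
  draw the share from Uniform(0.2, 0.8) — wide enough to emulate the
  orders-of-magnitude isoform-ratio scatter real ratio-ratio comparisons
  show, while staying strictly inside the specific-site bounds.
- **Loading:** per-site base loading is log-normal (σ = 1 log₂), scaled so
  expected α reads at sites total `site_read_fraction` (default 0.5) of
  `depth_per_assay`. Condition labels map to global multipliers; a
  progressive subset (fraction `progressive_fraction`) responds as
  scale^2 instead of scale, so severity separates progressive from early-
  saturating sites in both α and β. Knockouts are per-isoform multipliers;
  β always tracks (α₁+α₂)/`alpha_beta_ratio`, implementing obligate
  heterodimer loading. A `ratio_log2_sd` > 0 adds site-wise systematic
  α:β offsets for reproducibility studies.
- **Counts:** site mean × log-normal replicate factor (unit mean, CV
  `replicate_cv`, default 0.2) → Poisson. Coverage lays site reads over a
  triangular footprint kernel (half-width 150 bp, a stand-in for fragment
  pileup) by multinomial draw, plus uniform background (Poisson per 200 bp
  bin) filling the library to `depth_per_assay` — the simplest null against
  which the percentile filter is meaningful.
- **Cells:** shared sites are present in all `n_cell_lines` with the same
  mixing parameter (the conserved-ratio core); specific sites belong to
  one random cell line. The per-cell fraction of sites in multi-cell
  clusters therefore equals `shared_fraction` by construction.
- **Expression:** genes nearest bound sites get log₂FC ~
  Normal(effect_size, σ) with small p-values (log-uniform 10⁻⁶–10⁻²);
  all other genes are null (Normal(0, σ), p uniform).
- **Determinism:** one master seed; each assay × condition × replicate
  stream is seeded by a SHA-256 hash of its labels, so adding an assay
  never perturbs another's draws, and identical config + seed produces
  byte-identical output files.

The default configuration is a deliberately desk-scale study: 10 Mb
genome, 200 genes, 150 sites per isoform (30% shared), two conditions
(severe = 1.0, mild = 0.5), two replicates, 10⁶ reads per assay. The
dedicated analyses in the test-suite and acceptance script state their own
sizes (up to 50 Mb / 2,000 sites where a statistic needs them).

### What the generator does *not* emulate

Fragment-level reads, mappability and GC bias, diploid genomes, peak-shape
heterogeneity, antibody-efficiency differences between the α and β ChIPs
(the 1:1 ratio is a property of the simulated loadings; in real data the
modal ratio absorbs unknown relative ChIP efficiencies and only the
*tightness* and *reproducibility* of the distribution are informative),
chromatin contact structure linking sites to target genes, and clonal
variation between knockout lines. Passing tests therefore demonstrate the
correctness and calibration of the analysis machinery under the stated
generative model — not that real libraries satisfy that model.

## Numerical choices and degenerate inputs

- Empirical percentile: sort + index, no interpolation (see above);
  strictly greater than the threshold is required.
- Pseudocounts: 0.1 CPM in all ratio work; 0 by default in
  `compare_conditions` so exact fold-changes survive (non-finite ratios
  are dropped with a warning).
- All-tied inputs short-circuit: constant samples give P = 1 in both
  Wilcoxon wrappers; an all-identical q(β) gives tertile P = 1 with the
  flag off; identical count vectors give chi-squared statistic 0.
- GSEA with all-zero scores degrades to the unweighted statistic; p-values
  of 0 in the ranking metric are clipped to 10⁻³⁰⁰ before −log₁₀.
- Heatmap windows truncated by the chromosome start are zero-padded.
- Summits default to the interval midpoint when absent (narrowPeak summit
  offsets are honoured on read).
- Equidistant-TSS ties and annotation-absent chromosomes are flagged, not
  silently resolved.

## Problem sizes in the acceptance script

The script's blocks run at the sizes the corresponding statistics need:
stoichiometry recovery at 2,000 sites and 2×10⁶ reads per assay; tertile
power/type-I at 100 simulations of the default configuration each;
knockout null at 200 simulations; distance separation at 100 simulations
of 500 sites per isoform; conservation at two cell lines sharing 25% of
1,000 sites per isoform; GSEA on 400 genes with 1,000 permutations (a
permutation count chosen to resolve P ≤ 0.01 while keeping the run short;
the permutation machinery is identical at any count); and site-calling
false-positive control against 10,000 background-only candidate regions,
where the expected canonical count under the 10⁻⁴ rule is ≪ 1.
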