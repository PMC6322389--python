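# hetdimer-chip

Quantitative downstream analysis of ChIP-seq for a heterodimeric
transcription factor with two α-isoforms — the hypoxia-inducible factor
(HIF) family being the motivating case, where HIF-1α or HIF-2α dimerizes
with a common β-subunit (HIF-1β) to bind hypoxia response elements.

The package is aimed at regulatory genomicists who have per-replicate peak
calls and coverage tracks for the α- and β-subunit ChIPs and want to answer
the questions that define isoform-specific heterodimer binding:

- **Which sites are real?** Peaks are filtered against the empirical
  99.99th percentile of read counts at random accessible background
  regions, then reduced to replicate-consensus sites; a *canonical* site
  requires support from both replicates of the α ChIP **and** both
  replicates of the β ChIP.
- **Is binding 1:1?** At each site the ratio
  r = (α₁ + α₂) / β of depth-normalized signal
  (CPM = count·10⁶/total mapped reads) is computed, its distribution
  summarized, and its *reproducibility* assessed: if per-site log₂ r
  correlates poorly between independent replicates, apparent deviations
  from 1:1 stoichiometry are noise, not biology.
- **Do sites load progressively with stimulus severity?** Sites are ranked
  by the loading ratio q(α) between two conditions and split into tertiles;
  a Wilcoxon rank-sum test asks whether the β-subunit ratio q(β)
  corroborates the α-defined tertiles (exact small-sample null, normal
  approximation with tie/continuity corrections otherwise).
- **Do the isoforms compete?** Paired Wilcoxon signed-rank contrasts of
  wild-type versus knockout signal per specificity class
  (s = log₂((α₁+c)/(α₂+c)) with symmetric threshold).
- **Where do the isoforms bind?** Signed summit-to-nearest-TSS distances,
  binned profiles, and two-sample chi-squared comparisons against each
  other and against accessible-motif baselines; conservation of sites and
  isoform ratios across cell lines.
- **What do the sites regulate?** Hypergeometric co-binding enrichment
  within an accessible-region universe, and pre-ranked weighted GSEA with
  the ranking metric πᵢ = φᵢ·(−log₁₀ Pvᵢ), where φᵢ is the log₂
  fold-change and Pvᵢ the p-value of gene i.

Every stage is exercised end-to-end on a ground-truthed synthetic data
generator (`hetdimer_chip.synthetic_data`) that emulates 1:1 α:β loading
with log-normal replicate noise and Poisson counts, site-wise isoform
mixing, promoter-proximal isoform-1 versus promoter-distal isoform-2
placement, graded and progressive loading, knockouts, cell-line
repertoires with a conserved shared core, and an expression table in which
genes nearest bound sites are upregulated.

## Worked example

```python
import hetdimer_chip as hc

cfg = hc.SimConfig(seed=11)                    # two conditions: mild, severe
ann = hc.generate_annotation(cfg)
sites, truth = hc.generate_sites(cfg, ann)

mat = hc.site_signal_matrix(cfg, truth, "severe")
res = hc.ratio_distribution(
    mat, ["alpha1_rep1", "alpha1_rep2"], ["alpha2_rep1", "alpha2_rep2"],
    ["beta_rep1", "beta_rep2"],
)
rep = hc.ratio_reproducibility(
    mat, (["alpha1_rep1"], ["alpha2_rep1"], ["beta_rep1"]),
         (["alpha1_rep2"], ["alpha2_rep2"], ["beta_rep2"]))
```

prints, together with the tertile and distance stages that follow:

```
255 sites placed on a 10 Mb genome
median alpha:beta ratio = 0.998 (central-98% fold range 2.4)
between-replicate log-ratio correlation r = 0.010 (noise-dominated: True)
tertile corroboration P = 0.284, flag = False
median |TSS distance|: isoform1 326 bp, isoform2 15269 bp (chi-squared P = 4e-39)
```

Read: the recovered stoichiometry is 1:1 at the median; the 2.4-fold
spread of per-site ratios does **not** reproduce between replicates
(r ≈ 0), so it is assay noise; with `progressive_fraction=0` the β-subunit
does not corroborate the α tertiles (P = 0.28, flag off); and isoform-1
sites sit at promoters while isoform-2 sites are distal (chi-squared on
the binned distance profiles, P ≈ 10⁻³⁹).

A thin CLI wraps the same functions:

```sh
hetdimer-chip simulate --outdir sim --seed 4
hetdimer-chip quantify --peaks sim/truth_sites.bed \
    --track sim/alpha1_severe_rep1.bedgraph --totals sim/totals.tsv --out q.tsv
hetdimer-chip overlap --universe acc.bed --factor tf.bed --target hif.bed
```

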