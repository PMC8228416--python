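# Methods

## The per-CpG differential methylation test

At CpG *i* with samples *j* (methylated count m_ij, coverage n_ij) and a
two-level group factor, the model is binomial logistic regression of the
methylated proportion on the group indicator. Because the only
covariate is binary, the maximum-likelihood fit is closed-form: the
fitted proportion in each group is the coverage-weighted pooled
proportion, and the null fit is the overall pooled proportion. The
likelihood-ratio statistic is the deviance difference

    LR = D_null − D_full,

evaluated with fitted proportions clipped to [1e-8, 1 − 1e-8] so that
boundary fits (a group entirely unmethylated or entirely methylated)
stay finite. Replicate animals are not binomial draws from one
proportion — they carry biological variance — so the statistic is
scaled by the Pearson dispersion of the full model,

    phi = max(1, Σ r_ij² / (k − 2)),   r_ij = (m_ij − n_ij p̂_g) / √(n_ij p̂_g (1 − p̂_g)),

with k the number of covered samples at the site. The clamp at 1 makes
the correction one-sided: under-dispersion never inflates the
statistic. LR/phi is referred to χ²(1). This is the classic
quasi-likelihood ("overdispersion-corrected chi-square") approach used
by standard RRBS differential-methylation tools; the implementation here
is vectorized over all sites at once, and the test suite checks it
against an independently coded numeric likelihood maximization to 1e-6.

Multiple testing uses Benjamini–Hochberg q-values over all tested sites
of a comparison, with a strict q < 0.01 call and no minimum-difference
filter: a 1-point difference with q < 0.01 is a DMS. The reported
effect size is the pooled percentage-point difference, not a model
coefficient, because pooled differences are what per-site reports in
this field conventionally show.

Filtering: a cell needs coverage ≥ 10 (a depth of 9 is dropped); a site
needs either every sample covered (strict mode) or at least
`min_samples_per_group` covered cells per group (the relaxed k-of-n
inclusion rule used for pooled six-vs-six comparisons, default 4).

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 10 reads | per-cell depth floor |
| `min_samples_per_group` | all (None) | relaxed presence rule, e.g. 4 of 6 |
| `q_threshold` | 0.01 | strict BH cutoff for DMS |
| promoter window | ±1000 bp of TSS | gene-axis promoter definition |
| shore width | 2000 bp | fixed by the CpG-shore definition |
| co-direction radius | 100 bp | pair window for same-direction fraction |
| bin size | 1 Mb | density track bins, anchored at 0, half-open |
| delta-screen threshold | 20 points | inclusive (≥) |
| `n_resamples` | 100 | draws for the distance null |

## Genome-context annotation

Each site receives exactly one label per axis. Gene axis precedence is
promoter > exon > intron > intergenic, evaluated across all genes (a
site in one gene's promoter window and another gene's exon is a
promoter site); introns are gene body minus exons. CpG axis precedence
is island > shore > open sea, a shore being within 2 kb of a CGI edge
but outside every (merged) island. The nearest-gene lookup reports
distance 0 inside a gene body and otherwise the gap to the closest gene
boundary, ties resolved to the lexicographically smaller gene id for
determinism. Interval queries run on merged sorted interval sets via
binary search.

## Spatial and comparative analyses

Neighbour distances are successive position differences within each
chromosome. The clustering null redraws the same number of sites
uniformly without replacement from the background CpG set (genome-wide,
not per-chromosome — a stratified option exists), recomputes distances,
and averages histograms over exactly `n_resamples` draws; histogram
bins are 30 logarithmic bins from 1 bp to 10 Mb. The same-direction
fraction is computed over *pairs* of DMS within the radius (not
connected clusters), together with the median absolute difference of
their effect sizes as an amplitude-agreement summary. The 1-Mb track
counts DMS per half-open bin anchored at coordinate 0 and reports
count_2 − count_1 per bin. Nested correlations are product-moment
(Pearson) coefficients of per-CpG pooled differences on three nested
sets: all CpGs tested in both comparisons, CpGs that are DMS in at
least one, CpGs that are DMS in both; subsets under 3 points are
undefined. The delta screen keeps CpGs that are DMS in at least one
comparison and whose changes differ by ≥ 20 points (boundary included).

## The synthetic cohort generator

The generator emulates the *statistical* structure of the study, not
its sequences:

* **Genome**: configurable chromosomes (default 2 × 1 Mb) with genes
  (strand, TSS, 1–4 exons) placed in equal slots, and CGIs of 0.3–1.5 kb,
  half anchored on TSSs to mimic the promoter–CGI association. CCGG
  restriction sites are a Poisson process (mean gap 400 bp, 150 bp
  inside CGIs); fragments are inter-CCGG intervals and only CpGs on
  fragments of 50–1200 bp receive coverage, emulating RRBS size
  selection. CpGs are likewise Poisson (mean gap 100 bp, 12 bp inside
  CGIs).
* **Coverage**: 1 + Poisson(mean_depth − 1) per covered CpG per sample
  (mean 30), so selected fragments always yield at least one read.
* **Methylation**: CpGs are clustered into co-methylation regions
  (consecutive CpGs within 100 bp). Each region draws a baseline level
  from a Beta distribution with context-dependent mean — 0.1 for
  CGI/promoter regions, 0.5 for shores, 0.8 for open sea
  (concentration 30). Each *animal* draws a region-level deviation from
  a Beta with intra-class correlation `dispersion` (default 0.01); both
  hemisphere samples of that animal share the draw, so the two striata
  are near-identical replicates by construction (a side-effect knob
  exists, default 0). Counts are binomial given the animal latent.
* **Effects**: an effect table shifts latent levels additively by
  delta/100 in the target group(s) only. Selection is by whole
  co-methylation regions, so nearby affected CpGs co-direct; candidates
  are restricted to the preferred context (open sea / gene body /
  promoter / any) *and* to sites where the shifted level stays inside
  [0.02, 0.98] — without the feasibility constraint, clipping would
  silently shrink large effects and the truth table would overstate
  them. A target-group list injects identical sites into several
  groups, which is how the shared levodopa/levodopa+riluzole response
  is emulated. Defaults follow the study's observations: ~3:1
  hypo:hyper bias, losses concentrated in the open sea, 40-point
  magnitudes, most effects shared between the treated groups.

Everything is driven by one integer seed through per-stage child
streams; identical configs produce byte-identical emitted datasets.

### Calibration of the noise defaults

The study reports neither per-CpG depth distributions nor dispersion
estimates, so these defaults are calibrated against the package's own
invariants rather than against any published count: with
dispersion 0.01 the null cohort yields a DMS fraction ≈ 0 at q < 0.01
(≤ 2% required) while 40-point effects at 30× depth in a 3-vs-3 design
are recovered at 75–80% with the correct sign (≥ 70% / ≥ 95% required).
Dispersion 0.02 fails the recovery bound on some seeds; 0.01 is within
the range reported for beta-binomial intra-class correlations in
isogenic rodent RRBS data.

### What a green test does and does not establish

The simulator reproduces: count conservation, RRBS fragment selection,
context-dependent baselines, local co-methylation, near-identical
hemispheres, hypo-biased open-sea effects, and shared-vs-private
treatment responses. It does **not** model: real nucleotide sequence or
actual CCGG motifs, bisulfite conversion errors, mapping artifacts,
per-CpG depth heterogeneity beyond Poisson, chromosome-scale
methylation domains, or genuine biological pathway structure. Green
recovery/FDR tests therefore establish that the statistics behave as
designed under the stated generative model — not that the original
study's specific DMS counts would be reproduced (those depend on the
deposited raw data and on the original tool's unstated q-value
variant).

## Numerical and design choices

* Coordinates are 0-based half-open internally; all emitted reports are
  1-based to match the Bismark coverage dialect.
* CpGs on opposite strands would be distinct sites (no destranding);
  the coverage format carries no strand, so read records are '+'.
* Missingness in the count matrix is explicit (NaN), never
  zero-coverage, making the k-of-n rule well-defined.
* Boundary fits use proportion clipping (1e-8), never infinities; sites
  where a whole group has zero total coverage are excluded and logged.
* q exactly at the threshold is *not* a DMS (strict inequality).
* Zero-difference sites are never DMS regardless of q.
* The six striata of a group enter pooled comparisons as six samples,
  exactly as in the study design. This is pseudo-replication (the two
  sides of one animal are correlated), and the per-site test has no
  animal-level random effect; the 3-vs-3 side-restricted comparisons
  are the statistically clean ones. Replicated deliberately; flagged as
  a limitation.
* BH was chosen for the q-values for transparency and testability; the
  original tool's default q-value procedure differs, which is one
  reason absolute DMS counts are not comparable.

## Known limitations

* No covariates, no paired within-animal model, no region-level (DMR)
  calling, no sliding windows.
* The resampling null treats the background as fixed and uniform;
  coverage-matched or CpG-density-matched nulls are out of scope.
* The simulator's truth is defined at CpG resolution; region-level
  truth (e.g. for DMR callers) is not emitted.
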