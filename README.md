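# rrbsdiff

Differential DNA-methylation analysis for reduced-representation
bisulfite sequencing (RRBS) count data, built around the study design of
a rat model of levodopa-induced dyskinesia (LID): a unilateral
6-OHDA-lesioned striatum, three treatment groups (untreated, chronic
levodopa, levodopa + riluzole), three animals per group, and both the
lesioned and contralateral striatum sequenced per animal.

The package is for epigenomics analysts who have per-CpG methylation
counts (Bismark coverage files) and a group design, and want the full
per-site analysis chain plus a ground-truth simulator to validate it:

* **Per-CpG testing** (`rrbsdiff.dms`). At each CpG a binomial logistic
  model of the methylated proportion on a two-group indicator is fitted
  (trials = coverage). The deviance statistic is corrected for
  extra-binomial scatter between replicates by the Pearson dispersion of
  the full model, `phi = max(1, sum(r_i^2) / (n - 2))`, and
  `(D_null - D_full) / phi` is referred to a chi-square with 1 df.
  Sites are filtered at coverage >= 10 per sample (optionally a relaxed
  k-of-n presence rule per group), q-values are Benjamini–Hochberg, and
  a DMS is a site with q < 0.01 — no minimum-difference threshold.
  The reported effect is the coverage-weighted pooled difference
  `100 * (sum M_b / sum C_b - sum M_a / sum C_a)` in percentage points.
* **Context annotation** (`rrbsdiff.annotation`). Two axes per site:
  promoter > exon > intron > intergenic (promoter = ±1 kb of TSS) and
  CpG island > shore (±2 kb of a CGI edge) > open sea, plus nearest-gene
  lookup and DMS-vs-background enrichment summaries.
* **Spatial and comparative analyses** (`rrbsdiff.spatial`).
  Neighbour-distance distributions against a null built from 100 uniform
  redraws of the same number of sites from the background CpG set;
  the fraction of DMS pairs within 100 bp changing in the same
  direction; per-1-Mb-bin DMS count differencing between comparisons;
  nested Pearson correlations of per-CpG changes (all shared CpGs ->
  DMS in either -> DMS in both); and the screen for CpGs that are DMS in
  either treatment comparison with >= 20 points difference between
  treatments.
* **Simulator** (`rrbsdiff.simulate`). A miniature genome (genes, CGIs,
  MspI-style CCGG sites), fragment size selection (50–1200 bp),
  beta-binomial counts over latent regional methylation levels shared
  within ~100 bp (low in CGIs/promoters, high in open sea; both
  hemispheres of an animal share the animal's latent levels), and
  injected group effects recorded in a ground-truth table.

## Worked example

The numbered scripts under `analysis/` run the whole study design on a
simulated cohort (all outputs under `results/`):

```bash
python analysis/01_simulate_cohort.py      # seeded cohort + ground truth
python analysis/02_call_dms.py             # all six preset comparisons
python analysis/03_annotate_dms.py         # context enrichment
python analysis/04_spatial_clustering.py   # distances vs resampling null
python analysis/05_treatment_contrast.py   # nested correlations + screen
```

With the default seed (7) this prints:

```
  UNT_lesioned_vs_control: tested 17955, DMS 0 (0 hyper / 0 hypo)
  LDOPA_lesioned_vs_control: tested 17956, DMS 0 (0 hyper / 0 hypo)
  LDOPA_R_lesioned_vs_control: tested 17956, DMS 0 (0 hyper / 0 hypo)
  LDOPA_vs_UNT: tested 17956, DMS 90 (26 hyper / 64 hypo)
  LDOPA_R_vs_UNT: tested 17956, DMS 91 (25 hyper / 66 hypo)
  LDOPA_R_vs_LDOPA: tested 17956, DMS 48 (25 hyper / 23 hypo)
  ...
  cpg_context enrichment (DMS/background): cpg_island=0.08, cpg_shore=3.13, other=1.01
  neighbour pairs <100 bp: observed 34 vs null mean 0.58
  same-direction fraction within 100 bp: 1.000 over 60 pairs
  nested correlations: r_all=0.557 (17956) < r_any=0.681 (121) < r_both=0.990 (60)
  delta screen (>= 20 points, DMS in either): 42 CpGs
```

Reading: the two hemispheres of an animal are near-identical replicates,
so side-vs-side comparisons call no DMS; the treated-vs-untreated
comparisons recover the injected effects with the 3:1 hypomethylation
bias; called DMS are depleted in CpG islands, cluster far beyond the
uniform null within 100 bp and always co-direct there; correlation of
methylation changes between the two treatments tightens across the
nested DMS sets because most true effects are shared; and the delta
screen isolates the treatment-specific sites.

The same chain is scriptable via the CLI
(`rrbsdiff simulate | validate | call-dms | annotate | spatial |
run-all | demo`) or the library (`rrbsdiff.pipeline.run_pipeline` with a
YAML `RunConfig`).

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch on a
freshly simulated cohort — generation, assembly, filtering, testing,
calling, annotation, and the spatial/contrast analyses for every preset
comparison — and writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Statistical guarantees (oracle equivalence of the per-site test against
a brute-force likelihood fit, FDR control, effect recovery, the
correction's conservativeness, co-direction, null unbiasedness and the
exact filtering/BH arithmetic) are asserted by `tests/test_acceptance.py`.

See `docs/methods.md` for the model, the simulator's assumptions and the
known limitations.
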