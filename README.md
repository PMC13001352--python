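# acuteomix

Integrative multi-omics analysis of the acute exercise response in skeletal
muscle, packaged as a tested, reusable pipeline. It covers:

- **`acuteomix.synthetic`** — synthetic multi-omic cohorts (RNA/ATAC counts,
  protein/phospho log-ratios, metabolites) with a CON/EE/RE design, pre plus
  arm-dependent post-exercise timepoints, participant random intercepts,
  configurable missingness, and planted ground truth: injected
  group-by-time effects, a TF-phosphosite → target-gene regulatory network,
  peak→gene links on a synthetic chromosome, and pathway priors.
- **`acuteomix.preprocess`** — ome-specific feature filters (CPM rule,
  ATAC 10-in-6, proteomics 30% quantification, metabolomics 20% missingness),
  TMM + log-CPM normalization, per-sample median centering, metabolite
  KNN/half-minimum imputation, 5×IQR PCA outlier flagging, and
  design-protected batch residualization.
- **`acuteomix.differential`** — per-feature cell-means mixed models
  (profiled REML with a participant random intercept), voom-style precision
  weights for count omes, difference-in-changes ("delta-delta") contrasts,
  empirical-Bayes variance moderation, and BH adjustment per contrast/ome.
- **`acuteomix.enrichment`** — moderated-t → z matrices, multi-site phospho
  splitting, set filtering (≥5 members, ≥70% retention), CAMERA-PR, ORA, and
  a PTM signature running-sum test with permutation NES (weight 0, 1000
  permutations, min overlap 5).
- **`acuteomix.plier`** — cross-omic pathway-guided latent variables with
  cumulative promoter-accessibility and cumulative phosphorylation scores,
  parallel-analysis LV count selection (doubled; fallback 100), a
  block-coordinate solver for `||Y−ZB||² + λ1||Z−CU||² + λ2||B||² + λ3|U|₁`
  with `U ≥ 0`, and within-subject LV significance tests.
- **`acuteomix.regnet`** — TF-phosphosite regulators (≤40% missing, averaged
  MICE over 15 imputations), fuzzy c-means feature clustering with the
  standard fuzzifier estimator, random-forest edge importances, 100-fold
  permutation edge trimming (adj p < 0.05 and weight > 0.1), a simplified
  cis-regulatory circuit linker (±100 kb, peak p < 0.005, gene adj p < 0.05),
  multiset network integration, and per-node motif counts (FFL, diamond,
  3-chain) with a min-max-normalized Network Motif Score.
- **`acuteomix.neighbors`** — nearest-neighbor phosphosite analysis
  (Pearson r ≥ 0.8 over the EE/RE × timepoint fold-change profile, DA
  requirement, protein-level ORA).
- **`acuteomix.cpg`** — CpG coverage filtering (≥5× in ≥50% of samples) and
  the four-step MCL merge of correlated nearby sites into regions.

## CLI

```sh
acuteomix simulate --config cohort.yaml --seed 7 --outdir sim/
acuteomix preprocess --ome rna --matrix sim/rna.tsv --design sim/design.tsv --out rna_norm.tsv
acuteomix differential --ome protein --matrix prot_norm.tsv --design sim/design.tsv --out prot_da.tsv
acuteomix enrich --method camera --zmatrix z.tsv --contrast EE.15min --gmt sets.gmt --out camera.tsv
acuteomix network --modality EE --regulators reg.tsv --targets tgt.tsv --out ee_edges.tsv
acuteomix integrate ee_edges.tsv re_edges.tsv circuits.tsv --out combined.tsv
acuteomix nms --edges combined.tsv --out nms.tsv
acuteomix neighbors --anchor HIPK3_Y359 --results phospho_da.tsv --rmin 0.8 --out neigh.tsv
acuteomix cpg-merge --coverage covdir/ --window 1000 --out-prefix regions
```

`cohort.yaml` holds any `CohortConfig` field (e.g. `n_participants`,
`group_counts`, `n_perturbed`, `missingness`).

## Layout

```
src/acuteomix/    package modules (one per pipeline stage)
tests/            pytest suite; tests/test_acceptance.py holds the
                  acceptance criteria at their stated tolerances
scripts/          acceptance report script
```
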