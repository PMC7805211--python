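# methylcontrast

Analysis toolkit for contrasting DNA-methylation profiles between two tumor
groups on EPIC-like beta-value matrices. It implements, as a tested and
reusable pipeline:

- **QC / preprocessing** — detection-p failure masking (`p < 0.01` passes),
  failed-sample removal (`> 10%` failed probes, strict), blacklist-probe
  removal, beta ↔ M-value conversion.
- **Per-probe differential methylation** — hierarchical beta-likelihood GLMM
  with a logit link, age and sex covariates, and random intercepts for slide
  and patient-nested-within-slide (Laplace approximation, L-BFGS over
  variance parameters). Significance by likelihood-ratio test (df = 1),
  Benjamini–Hochberg adjustment, convergence filtering, odds-ratio
  effect-size selection (`|log OR| > log 4`).
- **DMR calling** — Gaussian-kernel smoothing of squared Wald statistics
  (`sigma = lambda / C`, defaults 1000 bp / 2), Satterthwaite-matched
  chi-square p-values, genome-wide BH, run chaining (gap ≤ lambda,
  ≥ 2 CpGs), quasi-beta fold-change filter (two-fold, two-sided on the log
  scale), genomic-context annotation.
- **A/B compartments** — open-sea probe subsetting (≥ 4 kb from an island),
  kNN imputation, 100 kb median bins, leading eigenvector of the per-
  chromosome bin correlation matrix (A = positive, B = negative, oriented by
  probe density), cross-group discordance with the `|eigen| ≥ 0.02` retention
  filter in both groups.
- **Tumor-size association** — per-probe GLMM with size in mm as a
  continuous covariate and a patient random intercept, Kendall tau-b on
  model-significant probes, delta-beta (`max − min > 0.2`) filter.
- **Gene-set enrichment** — Wallenius noncentral hypergeometric
  over-representation correcting the probes-per-gene sampling bias; reduces
  exactly to the one-sided Fisher test with equal probe counts.
- **Synthetic cohorts** — a first-class generator producing EPIC-like
  fixtures (beta/detection-p matrices, sample sheet, manifest) with planted
  group effects, DMR intervals, compartment blocks (including group-
  discordant ones), size-associated probes, probe failures, and a JSON truth
  record for parameter-recovery testing. Identical (config, seed) pairs are
  byte-identical.

## CLI

```bash
methylcontrast simulate --seed 7 --out fixture/        # synthetic cohort
methylcontrast qc   --beta fixture/beta.tsv --detp fixture/detp.tsv \
                    --manifest fixture/manifest.tsv --out qc/
methylcontrast dmp  --qc-dir fixture --contrast CNF:PNF --out dmps.tsv
methylcontrast dmr  --dmps dmps.tsv --manifest fixture/manifest.tsv \
                    --lambda 1000 --c 2 --out dmr/
methylcontrast compartments --qc-dir fixture --groups CNF,PNF --out comp/
methylcontrast size --qc-dir fixture --group CNF --out size_hits.tsv
methylcontrast enrich --dmps dmps.tsv --manifest fixture/manifest.tsv \
                    --gmt fixture/gene_sets.gmt --out enrichment.tsv
methylcontrast run  --input-dir fixture --out out/     # full pipeline
```

Exit codes: 0 ok, 2 usage error, 1 data/configuration error. All genomic
coordinates are 1-based inclusive internally; BED/bedGraph exports convert
to 0-based half-open.

A fixture directory contains `beta.tsv`, `detp.tsv`, `samples.csv`
(`sample_id,patient_id,slide_id,group,age,sex,size_mm`), `manifest.tsv`
(`probe_id,chrom,pos,relation,gene,promoter,enhancer,blacklist`), and
optionally `truth.json` / `gene_sets.gmt`.

## Layout

```
src/methylcontrast/
  data.py          containers + plain-text IO (TSV/CSV/GMT/BED)
  qc.py            filters and beta/M transforms
  betareg.py       beta-GLMM engine (Laplace approximation)
  diffmeth.py      per-probe contrast scan, LRT, BH, selection
  dmr.py           kernel smoothing, region calling, context, enrichment
  compartments.py  open-sea, kNN imputation, binning, eigenvector tracks
  size.py          size GLMM, Kendall tau-b, delta-beta filter
  stats.py         Shapiro-gated correlation
  synthetic.py     cohort generator + truth record
  config.py / pipeline.py / cli.py
```
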