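# composkern

Kernel-based supervised learning and model analysis for compositional
(simplex-valued) data, such as microbiome relative-abundance tables.

The package provides:

- **Simplex kernels** — linear, RBF, Aitchison (centered log-ratio with a
  tunable zero-shift), Aitchison-RBF, four probability-distribution kernels
  (Jensen–Shannon, Hellinger, total variation, chi-square, built from their
  squared distances via an anchored construction), and the heat-diffusion
  kernel on the multinomial manifold.
- **Prior-knowledge weighting** — entrywise non-negative PSD weight matrices
  applied to any kernel; builders from partitions (block projectors) and from
  phylogenetic trees (Gaussian of patristic distance with spectral clipping —
  a declared approximation of UniFrac-style constructions; user-supplied
  weight files are always accepted as an override).
- **Kernel ridge regression/classification** in dual form, with a two-step
  hierarchical cross-validation: the kernel is selected by nested CV (inner
  folds pick lambda per outer fold), then lambda is re-selected on the full
  data. The default grid has 55 kernels; with the default lambda grid of 10
  and 5 inner / 10 outer folds the inner loop performs exactly 27,500 fits,
  audited by a counter.
- **Compositionality-respecting interpretation** — compositional feature
  influence (CFI: mean derivative along the multiplicative perturbation
  `psi`) and compositional perturbation dependence (CPD: mean prediction
  after pinning one component with `phi`, minus baseline). For log-contrast
  models `beta^T log(x)` the CFI equals `beta` exactly.
- **Embedding and summaries** — kernel PCA with per-component PC influence
  (the CFI of each PC score function), kernel-distance closeness scores to a
  reference point, geometric medians, and a data-adaptive alpha-diversity
  (for the linear kernel: the Gini–Simpson index shifted by `(p-1)/p`).
- **Synthetic data** — compositional log-normal covariates, multinomial
  zero-inflation at finite depth, log-contrast responses, and two
  block-structured generating processes for studying when weighting helps.

## CLI

```sh
# generate a 4-component log-contrast dataset
composkern simulate --n 100 --p 4 --seed 1 --outdir sim/

# two-step hierarchical CV, model + CV table + metadata
composkern fit --table sim/data.csv --response y --outdir run/ --seed 0

# analysis of the stored model
composkern cfi --model run/model.json --table sim/data.csv --out cfi.csv
composkern cpd --model run/model.json --table sim/data.csv --component c0 --out cpd.csv
composkern kpca --model run/model.json --table sim/data.csv --outdir emb/
composkern summarize --model run/model.json --table sim/data.csv --out scores.csv
```

Tables are CSV/TSV with sample IDs in the first column; count tables are
closed to proportions automatically. Restrict the kernel grid with
`--kernels aitchison,linear`; supply prior knowledge with `--weights-file`
or `--tree` (Newick with branch lengths) plus `--tree-bandwidth`.

## Notes

- For the linear kernel, the closeness of a composition to the barycenter
  satisfies `D(x) + (p-1)/p = 1 - sum_j x_j^2` (Gini–Simpson); the shift
  constant follows from direct expansion.
- The heat-diffusion kernel is only approximately positive definite; its
  Gram matrices are spectrally repaired (negative eigenvalues clipped)
  before entering solvers, with a logged warning.
- The default lambda grid has 10 values; pass `--n-lambda 40` for a denser
  search.
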