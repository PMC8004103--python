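# encoop

Quantifying how multiple enhancers cooperate to drive target-gene
transcription, from nascent-RNA (TT-seq) time courses.

During a transdifferentiation time course, enhancers produce short-lived
enhancer RNAs (eRNAs) whose synthesis level tracks enhancer activity. For a
gene paired with several enhancers, the question is whether promoter activity
*P* follows the **sum** *S* of its enhancers' activities additively or
super-additively. `encoop` implements the full analysis:

1. **Transcription-unit classification** — TUs from nascent-RNA segmentation
   are classified against a reference annotation (mRNA, lincRNA, uaRNA,
   convRNA, dsRNA); remaining ncRNAs within 1 kb of both an ATAC and an
   H3K4me1 peak at any time point are called eRNAs, and eRNAs within 1 kb of
   each other are merged strand-agnostically into enhancers with per-kb,
   size-factor-normalized activities.
2. **Enhancer–promoter pairing** — by nearest transcribed mRNA
   (*neighboring*), by a 1 Mb window, or within a shared topologically
   associating domain (*TAD*), the latter two gated on both ends being
   differential (|log2FC| > 1, FDR < 0.05) and Spearman ρ > 0.4.
3. **Cooperation-model selection** — for each gene with 2–20 paired enhancers
   (top 75% of S-vs-P Spearman correlations), three models are fitted by
   seeded bounded differential evolution with local refinement:

   | model | form |
   |---|---|
   | additive | P = αS + β |
   | synergistic (exponential) | P = exp(αS + β) |
   | logistic | P = δ / (1 + exp(−(αS + β))) |

   Fits are compared with BIC = n·ln(RSS/n) + (k+1)·ln(n). If the logistic
   model has the strictly lowest BIC the point with the highest S is excluded
   (the promoter may have saturated) and all models are refitted on the
   remaining six points. Otherwise the **relative BIC**
   (BIC_additive − BIC_exponential) classifies the gene: > 2 synergistic,
   [0, 2] ambiguous, < 0 additive.
4. **Diagnostics** — cross-method overlap (Fisher's exact test),
   strongest-enhancer dominance, dual-target concordance (binomial test),
   eRNA-signal inflation robustness, a logarithmic negative-control model,
   and a ROSE-style stitched superenhancer caller (12.5 kb stitching, elbow
   cutoff on width-normalized signal).

A synthetic-data module generates complete desk-scale studies — genome
annotation, TADs, peak sets, and negative-binomial count tables whose
promoter trajectories follow a known generating model — so every stage is
testable with ground truth.

## Worked example

```python
import numpy as np
from encoop import PromoterActivityModel

S = np.array([12.1, 18.4, 35.2, 48.9, 60.3, 71.8, 74.5])   # summed eRNA level
P = np.array([3.1, 4.4, 11.2, 27.0, 62.5, 154.0, 182.0])   # mRNA synthesis
model = PromoterActivityModel(S, P, gene_id="CEBPB")
result = model.select(seed=0)
print(result.summary())
```

prints

```
gene CEBPB: synergistic (relative BIC = 40.107)
  additive     RSS=7425  BIC=54.605
  exponential  RSS=24.12  BIC=14.498
  logistic     RSS=80.18  BIC=24.852
```

The promoter trajectory rises far faster than the summed enhancer activity:
the exponential fit cuts the residual sum of squares ~300-fold relative to
the best straight line, the relative BIC (54.6 − 14.5 ≈ 40) is far above the
threshold of 2, and the gene is called synergistically regulated.
`result.plot(S, P)` overlays the three fitted curves on the data;
`result.fits["exponential"].alpha` etc. expose the parameters.

For a whole cohort:

```python
from encoop import SimConfig, simulate, classify_all

sim = simulate(SimConfig(seed=1))                   # 60 genes, 200 enhancers
table = classify_all(sim.truth_pairs, sim.activity, seed=1)
print(table["final_class"].value_counts())
```

The command line mirrors the library
(`encoop simulate|annotate|pair|fit|diagnose|run --config cfg.yaml`); `run`
executes every stage from BED/GTF/TSV inputs and writes classified TUs,
merged enhancers, pair tables, per-gene classifications, diagnostics, and a
run manifest.

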