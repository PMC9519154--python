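# pagicross

Pathway-crosstalk screening and prognostic gene modelling for case–control
transcriptomics, with a synthetic-cohort generator that plants known truth
for validation.

Complex diseases rarely act through one pathway: signalling pathways share
genes, and those shared (crosstalk) genes can matter more than any single
pathway's private members. This package implements a complete analysis
chain for finding disease-associated, crosstalk-aware prognostic genes in
bulk RNA-seq case–control cohorts with survival follow-up (the design it
emulates is an Alzheimer's-disease cohort with autophagy as the anchor
process):

1. **Preprocessing** — CPM filtering (drop genes below 1 CPM in ≥ 50% of
   samples), TPM normalisation, and a two-group lncRNA differential
   expression test (median-of-ratios size factors, Welch t on
   log2-normalised counts; significant at *p* < 0.05 and |log2FC| > 0.5).
2. **Global-influence pathway scoring** — all within-pathway interaction
   edges merge into one global gene network; differential expression
   (|Welch *t*|) seeds a random walk with restart,
   *P*<sup>t+1</sup> = (1−r) M *P*<sup>t</sup> + r *P*<sup>0</sup>,
   whose stationary probabilities become a per-gene **global dysregulated
   score** GDS<sub>i</sub> = (P<sup>∞</sup><sub>i</sub> − min P<sup>∞</sup>) /
   (max P<sup>∞</sup> − min P<sup>∞</sup>). Genes are ranked by
   w<sub>j</sub> = |t<sub>j</sub>|<sup>1+GDS<sub>j</sub></sup> and each
   pathway is scored with a weighted running-sum statistic (maximum
   deviation between the weighted cumulative hit fraction and the uniform
   miss fraction), with phenotype-permutation *p*-values and
   Benjamini–Hochberg FDR (< 0.01).
3. **Crosstalk gene extraction** — FDR-significant pathways rich in
   autophagy genes become feature pathways; the union of their members is
   the feature (crosstalk) gene set.
4. **Coexpression modules** — unsigned WGCNA-style network over feature
   mRNAs + significant DE lncRNAs: soft threshold β chosen by scale-free
   fit (R² > 0.85, β = 1..20), topological overlap, average-linkage
   clustering with an adaptive static cut (minimum module size 50), and
   eigengene merging at height 0.25.
5. **Module enrichment and selection** — hypergeometric pathway enrichment
   per module (*p* and BH *q* < 0.05); the module richest in autophagy
   genes becomes the analysis module.
6. **Prognostic model** — univariate Cox screen (*p* < 0.01) on the
   training split, backward stepwise multivariate Cox by lowest AIC,
   riskScore = Σ<sub>k</sub> coef(k)·x(k), median split into high/low
   risk, Kaplan–Meier + log-rank, multivariate independent-prognostic
   forest quantities, and IPCW time-dependent ROC (3- and 5-year AUC).

Every stage reads and writes plain TSV/GMT/JSON files, so runs are fully
inspectable, and the synthetic generator (`pagicross.synthio`) writes the
planted truth next to the data so each stage can be scored against known
answers.

## Worked example

Simulate the default cohort (155 AD cases vs 86 controls, 20 pathways of
80–120 genes in a crosstalk ring, 4 dysregulated pathways at ±1 log2 unit,
three 120-gene coexpression modules, two planted protective prognostic
genes with coefficients −1.13 and −1.41) and run every stage:

```bash
pagicross run-all --out run1 --seed 1
```

or in Python:

```python
from pagicross import RunConfig, run_all
manifest = run_all(RunConfig(), "run1", seed=1)
```

`run1/pathway_scores.tsv` then starts (columns mirror a pathway-score
table: running-sum score, peak position as a fraction of the ranked list,
leading-edge signal, permutation *p*, BH FDR, autophagy-gene count):

```
pathway_id  size  score   gene_pct  signal  perm_p  fdr     significant  autophagy_count
pw01        99    0.8908  0.0865    0.4854  0.0010  0.0018  True         11
pw02        100   0.5414  0.0720    0.0781  0.0010  0.0018  True         2
pw03        110   0.2293  0.6125    0.2423  0.9850  1.0000  False        2
```

In this run the four planted pathways (pw01, pw06, pw11, pw16 — the
`truth.json` answer key) all score ≥ 0.83 and pass FDR < 0.01, and they are
exactly the pathways selected as autophagy-rich features. Seven crosstalk
neighbours (sharing 20% of their genes with a planted pathway) are also
flagged — crosstalk leakage, visible because their running-sum peaks sit
early in the ranked list. The coexpression stage recovers four modules
(118/114/113/102 genes); module 1 holds the most autophagy genes and both
planted prognostic genes, and the final risk model

```json
{"genes": ["G1194", "G1133", "G0083", "G1205", "G0797"],
 "coefficients": {"G1133": -1.32, "G1194": -1.72, ...},
 "train_median_cutoff": 0.0319}
```

contains planted gene G1133 with a coefficient near its planted value
(−1.13) alongside co-module proxies. The median split separates survival
sharply (log-rank p = 9.4e-10 train, 4.3e-12 test) and the risk score
discriminates better than any single clinical index
(`run1/td_auc.tsv`): 5-year AUC 0.91 (train) / 0.93 (test) versus 0.84
for the strongest clinical covariate.

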