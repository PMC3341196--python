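# tagnorm

Scaling-factor normalization for tag count data (RNA-seq, ChIP-seq, small-RNA
sequencing) that removes potential differentially expressed genes (DEGs)
**before** computing the factor, plus the negative-binomial simulation and
ROC/AUC machinery needed to benchmark it.

## The problem

Between-sample normalization of a gene expression matrix usually assumes most
genes are not differentially expressed. When differential expression is
*biased* — say 20% of genes are DE and 90% of those are up in condition A
(P<sub>DEG</sub> = 20%, P<sub>A</sub> = 90%) — global scaling factors absorb
the bias, the log-ratio M = log2(B/A) of truly unchanged genes drifts away
from zero, and downstream DE tests lose both sensitivity and specificity.
The trimmed mean of M-values (TMM) guards against this with fixed trims that
implicitly assume up to 60% DE with no directional bias; when the bias is
directional, fixed trims are not enough.

## The method

`tagnorm` implements a three-step DEG-elimination strategy ("TbT"):

1. **Temporary normalization** — TMM factors on the raw counts: for each
   sample against a reference, a precision-weighted mean of per-gene
   M = log2((y_o/N_o)/(y_r/N_r)) after trimming the extreme 30% tails of M
   and 5% tails of A on each side.
2. **DEG identification** — an empirical-Bayes negative-binomial detector run
   on reads-per-million data under the step-1 effective library sizes
   N<sub>k</sub>·f<sub>k</sub>. It bootstraps genes to build an empirical
   prior over (μ, φ) (counts modeled NB with variance V = μ + φμ²), computes
   per-gene marginal likelihoods of a no-DE and a DE model, and estimates the
   DE mixture weight p̂ = P̂<sub>DEG</sub> by fixed-point iteration on the
   mean posterior. The top p̂·G genes by posterior are flagged.
3. **Final normalization** — TMM on the matrix with the flagged genes
   removed; the returned factor is
   (step-3 TMM factor) × (library size after elimination)/(library size
   before), rescaled to geometric mean 1 so it is directly comparable to a
   plain TMM factor.

Steps 2–3 can be iterated (TbT1, TbT2, …), rerunning the detector under the
previous round's factors, until the factors converge.

The package also ships the two gene rankers used for evaluation (the
conditional NB exact test with common/tagwise dispersion, and the detector's
posterior ranking), a two-group NB simulator with known DE truth, and an
evaluation module (Mann–Whitney AUC, confusion metrics, median non-DE M,
true-discovery curves, Wilcoxon rank-sum comparisons).

## Worked example

Simulate a biased dataset (5,000 genes, 3 vs 3 replicates, 20% DE genes at
4-fold, 90% of them up in A), normalize it with TbT, rank genes with the NB
exact test, and score the ranking against the known truth:

```sh
tagnorm simulate --genes 5000 --reps 3,3 --pdeg 0.2 --pa 0.9 --fc 4 \
    --seed 1 --out counts.tsv --truth truth.tsv
tagnorm normalize counts.tsv --groups A,A,A,B,B,B --method tbt \
    --bootstrap 500 --seed 1 --out factors.tsv --report report.json
tagnorm rank counts.tsv --groups A,A,A,B,B,B --factors factors.tsv \
    --ranker nbexact --out ranks.tsv
tagnorm evaluate ranks.tsv truth.tsv --out eval.json
```

The normalize step logs the detector's estimates

```
tagnorm: TbT: pdeg_hat=0.1298 pa_hat=0.6703 eliminated=649 round=0
```

(13.0% of genes flagged as potential DEGs, 67% of them A-up — the true
values are 20% and 90%; the estimate is conservative but directionally
right), and `factors.tsv` holds the per-sample factors and effective sizes:

```
sample  factor              lib_size   effective_size
A1      0.8676447120933457  181859.0   157788.99969658375
A2      0.8981960061513282  170147.0   152825.35585863004
A3      0.859350461285716   175762.0   151041.15577650003
B1      1.1304409327454639  124220.0   140423.3726656415
B2      1.1763999025895895  122135.0   143679.60210277952
B3      1.1228294295503198  124511.0   139804.61510273986
```

A-group factors sit below 1 and B-group factors above 1: the A-up DEG excess
inflates the A library totals, and the factors compensate. The evaluate step
prints `AUC = 0.8598`; running the same data through plain TMM factors gives
a lower AUC and a median non-DE M further from zero.

The same grid of experiments is available in one shot:

```sh
tagnorm benchmark --pdeg 0.20 --pa 0.5,0.9 --trials 10 --genes 5000 --seed 1 \
    --out grid.tsv
```

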