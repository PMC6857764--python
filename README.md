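# methmr

Matched-pair EWAS, fixed-effects meta-analysis and Mendelian randomization
(MR) for DNA-methylation exposures, plus a synthetic-data generator that
reproduces the statistical structure the analysis assumes — so the whole
chain is verifiable end to end without any external data.

The central question the toolkit is built around: when blood methylation at a
CpG is observationally associated with disease, is that association causal,
or does a shared exposure (here, a continuous "smoking burden") drive both?
The generator can plant exactly that confounded-null scenario, and the
analysis chain separates it: the observational matched-pair estimate departs
from the null while the genetic (MR) estimate stays at it.

## Modules

| module | what it does |
| --- | --- |
| `methmr.synthetic_data` | cohort generator (cis-SNPs → methylation, confounder → methylation + disease, optional causal effect, survival times), greedy 1:1 exact matching, per-SNP summary-statistic export |
| `methmr.ewas` | 1:1 conditional logistic regression (Newton on within-pair differences), residual-PC surrogate variables, constrained cell-proportion deconvolution, smoking-stratified runs, paired tumour/normal comparison |
| `methmr.meta_analysis` | inverse-variance fixed-effects pooling, Cochran's Q / I², BH-FDR, direction strings, Kruskal-Wallis + Dunn model comparison |
| `methmr.instruments` | LD pruning (r² < 0.01), cis-window filter (1 Mb), r²/F instrument strength, replication flags, behaviour-trait confounder scan |
| `methmr.two_sample_mr` | harmonization, Wald ratios with delta-method SEs, IVW with Q, MR-Egger, correlated-instrument IVW, Z difference test, binary-outcome power |
| `methmr.one_sample_mr` | allele scores, score-exposure strength, confounder balance, two-stage Cox with bootstrap CIs, smoking-stratified fits |
| `methmr.io` / `methmr.cli` | TSV formats with provenance headers, YAML config, stage orchestration, VCF dosage extraction |

## CLI

```sh
# end-to-end synthetic pipeline: simulate -> ewas -> meta -> instruments -> mr
methmr pipeline --seed 1 --out runs/demo

# individual stages against the same directory
methmr simulate --seed 1 --out runs/demo
methmr ewas --out runs/demo
methmr mr --out runs/demo

# a-priori two-sample MR power for a binary outcome
methmr power --n-cases 29863 --n-controls 55586 --r2 0.008 --odds-ratio 0.474

# paired tumour/normal comparison, one-sample MR
methmr tissue --tumour tumour.tsv --normal normal.tsv --out tissue.tsv
methmr onesample --survival survival.tsv --out onesample.tsv
```

All outputs are TSV with `# key: value` provenance headers (seed,
thresholds, package version); reruns with the same seed are byte-identical.
Exit code 2 marks input errors, 3 numerical failures.

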