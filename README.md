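# rnadecay

Genome-wide RNA half-life estimation from short expression time courses —
no transcriptional inhibition, no metabolic labeling.

## The problem

RNA abundance is the balance of transcription and degradation, and the
decay side is actively regulated: transcript stability shapes every
transient response. Half-lives are usually measured by blocking
transcription and watching transcripts disappear, but inhibition itself
perturbs decay regulation and the experiments are costly. This package
estimates per-transcript half-lives *computationally*, from an ordinary
expression time course with as few as 5–6 samples.

## The model

Each gene follows first-order kinetics,

    dx_i/dt = P_i(t) − k_i x_i(t),        h_i = ln2 / k_i,

where the promoter activity P_i(t) is not measured. For a pair of genes
whose promoter activities are proportional, P_i = γ_i u(t) and
P_j = γ_j u(t), the unknown u(t) can be eliminated between the two
equations. Integrating over each sampling interval with the trapezoidal
rule (differences D, integrals I) gives one linear relation per interval:

    D_j = θ₁ D_i + θ₂ I_i − θ₃ I_j,    θ = [γ_j/γ_i, (γ_j/γ_i)·k_i, k_j]

Each orientation of each pair yields a tiny l1-regularized non-negative
least-squares problem

    min_{θ ≥ 0} ‖Aθ − y‖₂² + α Σ θ_i

solved *exactly* by enumerating the 8 active-set patterns of θ ∈ R³ (the
penalty is linear on the orthant, so each pattern has a closed form). A
gene's half-life estimate from one pair is h = ln2·θ₁/θ₂. All m(m−1)
estimates are collected in an m×m matrix H with their squared-residual fit
errors in Q; entries whose fit error exceeds a threshold q_max are
discarded, and each gene is summarized by the median of its surviving row.

q_max is chosen against a permutation null: the whole procedure is re-run
on data whose time samples were shuffled per gene, and q_max is the
smallest fit-error percentile at which ≥90% of genes have a half-life
distribution significantly different from their null counterpart
(two-sample Kolmogorov–Smirnov, Benjamini–Hochberg FDR < 0.05). The
global α is selected by the L-curve corner criterion.

## Worked example

Simulate a 200-gene, 6-sample time course with 10% signal-proportional
noise, then estimate half-lives:

```bash
rnadecay simulate --m 200 --n-times 6 --noise 0.1 --seed 7 \
    --out expr.tsv --truth truth.tsv
rnadecay estimate expr.tsv --no-normalize --seed 7 --out-dir out/
```

which prints

```
alpha_opt=0.016156 q_max_percentile=100 reported=200/200 genes
results in out/halflives.tsv
```

`out/halflives.tsv` holds one row per gene: its identifier, the median
half-life in minutes of the pairwise estimates surviving the error filter,
the number of surviving estimates, and the gene's FDR value against the
shuffled-time null. Comparing against the simulated truth:

```python
import pandas as pd
from scipy import stats
est = pd.read_csv("out/halflives.tsv", sep="\t")
truth = pd.read_csv("truth.tsv", sep="\t")
print(stats.pearsonr(truth["halflife"], est["halflife"]))
```

```
PearsonRResult(statistic=0.486..., pvalue=2.9e-13)
```

i.e. the recovered half-lives track the true ones (the correlation is
highly significant at this small sample size and noise level). On noise-free data the
correlation reaches 1.00 (discretization is then the only error source);
it degrades gracefully as noise grows.

The `--no-normalize` flag is appropriate here because simulated genes
share a common transcription scale; for real expression matrices, where
measurement scales differ per gene, omit it to apply the standard z-score
pre-processing. Real matrices are plain delimited text: first column gene
ids, header row of sampling times in minutes (non-uniform grids are
supported and, when strongly uneven, re-partitioned into trapezoids of
comparable area before system construction).

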