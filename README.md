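# bimr — bidirectional two-sample Mendelian randomization

`bimr` estimates the causal effect of one trait on another from GWAS
summary statistics alone, using genetic variants as instrumental
variables. It was built for analyses of the kind that ask whether
circulating protein levels (for example serum matrix metalloproteinases)
causally influence disease risk (for example estrogen-receptor-negative
breast cancer) — and, run in the reverse direction, whether the disease
feeds back on the protein. No individual-level genotypes and no remote
databases are required: the inputs are plain tab-separated summary
tables, and a built-in generator produces fully synthetic tables with
known ground truth so every stage can be exercised offline.

## The method

For SNP *j* with estimated effect β̂<sub>Xj</sub> (SE σ<sub>Xj</sub>) on
the exposure and β̂<sub>Yj</sub> (SE σ<sub>Yj</sub>) on the outcome, the
per-SNP Wald ratio is θ̂<sub>j</sub> = β̂<sub>Yj</sub>/β̂<sub>Xj</sub>
with first-order SE σ<sub>Yj</sub>/|β̂<sub>Xj</sub>|. The package
combines the ratios five ways:

- **IVW** (primary): θ̂ = Σw<sub>j</sub>θ̂<sub>j</sub> / Σw<sub>j</sub>
  with w<sub>j</sub> = β̂<sub>Xj</sub>²/σ<sub>Yj</sub>²; the default
  multiplicative random-effects SE inflates the fixed-effect SE by
  max(1, √(Q/(J−1))).
- **MR-Egger**: weighted regression β̂<sub>Yj</sub> = α + θβ̂<sub>Xj</sub>
  after orienting all SNPs to positive exposure effects; α ≠ 0 indicates
  directional pleiotropy.
- **Weighted median**: the weight-0.5 quantile of the ordered ratios,
  consistent while valid instruments hold >50% of the weight.
- **Simple and weighted mode**: the kernel-density mode of the ratios.

Instruments are screened before estimation: genome-wide significance
(p < 5×10⁻⁸), a user-supplied confounder exclusion list, greedy LD
clumping (r² < 0.01 within 5 Mb), and the strength statistics
R² = 2·EAF·(1−EAF)·β² and F = (N−2)·R²/(1−R²), dropping SNPs with
F < 10. Analyses with fewer than five surviving instruments are skipped.
Harmonization aligns each outcome record to the exposure's effect
allele, resolving allele swaps and strand flips and removing ambiguous
palindromic (A/T, C/G) variants. Sensitivity diagnostics cover
Cochran's Q and I², the Egger intercept test, simulation-based
residual-sum outlier detection (MR-PRESSO), and leave-one-out
re-estimation. Evidence is tiered by a Bonferroni policy: p below
α/n<sub>tests</sub> (0.05/25 = 0.002 for a five-exposure, five-outcome
batch) is strong, p below 0.05 suggestive.

## Worked example

```python
import numpy as np
from bimr import MRModel, MRConfig, SimConfig, simulate_pair

exposure, outcome, truth = simulate_pair(
    SimConfig(theta=np.log(0.92), n_snps=17, palindromic_fraction=2 / 17, seed=11)
)
config = MRConfig(palindrome_policy="drop_all")
results = MRModel.from_datasets(exposure, outcome, config=config).fit(seed=11)
print(results.summary())
```

```
Two-sample Mendelian randomization
  exposure: sim-exposure    outcome: sim-outcome
  instruments: 15 (removed during harmonization: 2)

                   method  n_snp      OR (95% CI)     pval
                 MR Egger     15 0.89 (0.85-0.93) 6.03e-05
          Weighted median     15 0.91 (0.89-0.93) 2.68e-19
Inverse variance weighted     15 0.91 (0.90-0.93) 1.21e-30
              Simple mode     15 0.94 (0.90-0.98)  0.00277
            Weighted mode     15 0.90 (0.87-0.92) 9.93e-13

  Cochran's Q (IVW): 8.91 on 14 df, p = 0.837, I2 = 0.0%
  Egger intercept: 0.0050 (p = 0.125)
  MR-PRESSO global p = 0.812; outliers: none
  Leave-one-out influential SNPs: none
```

The generator planted a true odds ratio of 0.92 per SD of exposure on 17
instruments, two of them palindromic. Harmonization under the
`drop_all` palindrome policy removes those two, the five estimators
agree near OR 0.91–0.94, and none of the diagnostics signals
heterogeneity, pleiotropy or an influential SNP — the pattern a
well-behaved protective exposure produces.

The same analysis runs from the shell on TSV files:

```sh
bimr simulate --config sim.yaml --out data/
bimr run --exposure data/exposure.tsv --outcome data/outcome.tsv \
    --direction both --out report/
bimr report --in report/
```

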