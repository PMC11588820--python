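# seasonpower

Power analysis for seasonal, spatially clustered longitudinal surveys
(e.g. mosquito surveillance). Given a dampened autoregressive seasonal
correlation model, a between-location clustering level, an effect size and
power/significance targets, the tool computes the optimal number of
repeated measurements and survey locations, the total number of specimens
to collect under the correlated design versus under assumed-independent
measurements, a power-level sweep table, and a simulated seasonal curve for
visual parameter elicitation.

## Model in brief

* **Correlation law.** Values `l` time units apart correlate as
  `rho ** (l ** theta)`: `theta = 0` is compound symmetry (plug in an ACF
  value directly), `theta = 1` is AR(1), larger `theta` decays faster.
* **Cluster design.** The number of locations follows the classic
  cluster-randomised formula with a variance inflation factor
  `1 + (m - 1) * rho_c`; spread over `m` expected specimens per trap-visit
  it fixes a total collection budget.
* **Seasonal design.** For each candidate number of repeated measurements
  `k` on the grid `2 .. 2*k_max`, a repeated-measures sample size prices the
  temporal correlation; the optimal `k` is where the seasonal design's
  effort comes closest to the cluster budget, and the locations are the
  budget spread over those `k` visits.
* **Independent baseline.** A two-tailed two-sample t-test size (with the
  circular t quantile resolved to its smallest self-consistent integer)
  gives the collection total under assumed independence.

The initial population size `N` and the random seed affect only the
simulated seasonal curve, never the power results.

## Command-line usage

```bash
# write a template config (illustrative defaults - do not use for real planning)
seasonpower init-config config.yaml

# run; flags use the same kebab-case names as the config keys and override it
seasonpower run -c config.yaml -o results/ --rho 0.3 --theta 1.0 --yes-i-know
```

Outputs in the chosen directory:

| file | contents |
| --- | --- |
| `design_table.csv` | optimal locations per power level (rows) and repeated measurements 1..2k (columns) |
| `summary.csv` | optimal (k, locations), sampling effort, correlated and independent collection totals, variance ratio |
| `seasonal_curve.csv` / `seasonal_curve.png` | simulated population-vs-time curve |
| `power_curves.png` | locations vs repeated measurements per power level |
| `resolved_config.yaml` | the fully resolved parameter set (round-trips) |

Invalid parameters abort with a non-zero exit naming the field and its
legal interval; the tool never warns-and-proceeds.

## Python API

```python
from seasonpower import SeasonalModel, StudySpec, optimize_design, summarize

spec = StudySpec(x=20, sd_effect_1=3.0, m_1=15, rho_c=0.2,
                 alpha=0.05, power=0.8)
model = SeasonalModel(rho=0.2, theta=0.1)
print(optimize_design(spec, model, k_max=10))
print(summarize(spec, model, k_max=10))
```

Lower-level closed forms (`sample_size_ttest`, `sample_size_taylor`,
`sample_size_seasonal`, `sample_size_cluster`, `variance_inflation_factor`,
`intra_cluster_correlation`, `small_sample_adjustment`, `variance_ratio`)
are exposed as pure functions in `seasonpower.sample_size`.

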