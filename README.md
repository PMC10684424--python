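# fraxforge

Synthesis and comparison of country-specific FRAX-style 10-year
fracture-probability models, exercised end-to-end on synthetic
epidemiological inputs with known ground truth.

## The problem

FRAX-type tools report an individual's 10-year probability of hip fracture
and of major osteoporotic fracture (MOF: hip, clinical spine, forearm,
humerus) from age, sex, BMI, six dichotomous clinical risk factors (CRFs)
and, optionally, femoral-neck BMD, while accounting for the competing risk
of death. Such models are calibrated country by country to local fracture
incidence and mortality; when a country's incidence estimates are revised
(typically downwards, as recent registry studies have found in several
middle-income countries), the national model must be re-synthesised and
compared against its predecessor.

`fraxforge` implements that full synthesis chain for users who study
fracture epidemiology or maintain risk calculators:

1. **Registry emulation** (`synthetic_data`) — city-level hip-fracture
   counts by sex and 5-year age band with Poisson noise around an
   exponential age gradient (women ≈50% higher risk from age 70),
   Gompertz mortality, age-dependent non-hip MOF:hip site ratios, national
   demography, and a generated set of CRF coefficients.
2. **Incidence synthesis** (`incidence_synthesis`) — region-population-
   weighted combination of city rates; continuous piecewise log-linear
   (segmented) regression of log incidence on age with fixed breakpoints
   (62/87 years for men, 62/82 for women); the expected annual national
   fracture count from demography; MOF rates imputed via site:hip ratios.
3. **Probability engine** (`probability_engine`) — proportional-hazards
   individual risk `h(a) = h0(a)·exp(βᵀx)·g^(−T)`, with per-age-group
   baselines calibrated so the population-mean hazard reproduces the input
   incidence and mortality exactly, and the discrete competing-risk
   integration

   `P = Σ_t S(t) · h_f/(h_f+h_d) · (1 − e^{−(h_f+h_d)})`,
   `S(t+1) = S(t)·e^{−(h_f+h_d)}`.

4. **Model comparison** (`model_comparison`) — exhaustive scenario grids
   (2⁶ CRF combinations × 8 T-scores from 0 to −3.5 SD at BMI 25, i.e. 512
   scenarios per age/sex), Pearson/Spearman agreement, a continuous
   two-segment regression of updated on original probability with a knot
   at 30 percentage points, and the updated probability with a 95%
   tolerance interval read at the median of the original model's
   distribution.
5. **Pipeline** (`pipeline`, `cli`) — a deterministic end-to-end driver
   with a JSON config, artifact manifest and `fraxforge` command line.

## Worked example

```python
from fraxforge import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1), write=False)
print(f"national hip fractures: {result.burden.total:,.0f} "
      f"({100 * result.burden.male_share:.0f}% in men)")
print(result.report.to_text())
```

prints (seed 1):

```
national hip fractures: 71,577 (31% in men)
10-year probability (%), outcome: HIP
 Age     Sex  Original  Update       95% TI      r  Reduction
  50    male       1.5     0.8   0.8-0.8     1.000      44.7%
  60    male       2.4     1.3   1.3-1.3     1.000      44.5%
  70    male       3.8     2.1   2.1-2.2     1.000      44.0%
  80    male       4.9     2.8   2.7-2.9     1.000      43.5%
  ...
```

Here the "updated" model was built from hip-fracture incidence 0.55× that
of the "original" (emulating a downward revision of registry incidence).
Every cell shows the signature of such a revision: near-perfect
correlation (rank order of patients essentially unchanged) alongside a
40–45% drop in the absolute probability at the median scenario — the
median 10-year hip probability in 50-year-old men falls from 1.5% to 0.8%.

Single profiles, from the shell:

```bash
fraxforge run --seed 1 --out out/
fraxforge prob --model out/model_updated.json --age 65 --sex female \
    --crf prior_fracture --bmi 25 --tscore -2.5
# 10-year HIP probability: 1.4%
```

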