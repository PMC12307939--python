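# bioecon

Economic appraisal of genomics investments with Leontief input–output
modelling and cost–benefit analysis, exercisable entirely on synthetic
supply–use data.

National genome-sequencing initiatives — for example sequencing 1000 local
genomes — are capital projects whose case rests on economy-wide ripple
effects: the investment lands in R&D and agriculture, propagates through
inter-industry purchases, and pays back over decades. Evaluating that case
needs an inter-industry flow table, which statistical offices publish but
rarely license for redistribution. `bioecon` provides the full analysis
chain — impact modelling, scenario adjustment, multi-horizon benefit
projection, cost–benefit appraisal — together with a synthetic-economy
generator so every step is testable without the proprietary table.

## The model

For an *n*-sector economy with inter-industry flow matrix **Z** and total
output **x**, the technical coefficients are

    A_ij = Z_ij / x_j

(column *j* is sector *j*'s input recipe per unit of output). A
final-demand injection **F** requires gross output

    x = (I − A)⁻¹ F = L F

where **L** is the Leontief inverse, defined whenever the economy is
productive (spectral radius of **A** below one; equivalently the
Hawkins–Simon condition). The impact decomposes into the *direct* effect
(**F** itself), the *indirect* supply-chain ripple ((L − I) F), and — under
Type II closure with an endogenized household — the *induced* effect of
household spending. Output multipliers are the column sums of **L**.

Scenario adjustments: a productivity gain *g* in target sectors scales
their coefficient columns by 1/(1+g) (same output from fewer inputs);
strengthened linkages raise a source sector's coefficient row by a fixed
delta in target columns.

Benefits follow a geometric annual stream b(1+g)^(t−1) whose two parameters
are calibrated exactly to two printed cumulative totals. Appraisal uses
year-end discounting over years t = 1..T:

    NPV = Σ (Benefits_t − Costs_t) / (1+r)^t,   BCR = PV(benefits) / PV(costs)

with r = 5% and T = 10 years by default.

## Worked example

```python
from bioecon import PipelineConfig, render_summary, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))   # 27-sector synthetic economy
print(render_summary(report))
```

prints (abridged):

```
Total Cost: 20.00
Discounted Cost: 15.44
Total Benefit: 56.85
Discounted Benefit: 45.54
NPV: 30.10
BCR: 2.95
Sector shares (adjusted case):
  agriculture: 22%
  ...
  R&D: 23%
Cumulative benefits by horizon:
  5 years: 35.00
  10 years: 56.85
  20 years: 79.00
```

The US$20M injection (split equally between R&D and agriculture) generates
US$37.5M of gross output in the base case, concentrated in the two
recipient sectors. The benefit stream calibrated to the 35 → 79 cumulative
anchors implies a *negative* annual growth rate (≈ −9%/yr, a decelerating
stream) — the calibration surfaces this rather than hiding it. Discounted
over ten years at 5% the appraisal nets US$30.1M with US$2.95 of benefit
per dollar invested.

Each capability has a narrative script under `examples/`:
`generate_economy.py`, `investment_impacts.py`, `projection_and_cba.py`,
`full_report.py`. The same functionality is exposed as a thin CLI
(`bioecon synth|impact|scenario|project|cba|run|validate`).

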