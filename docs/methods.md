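# Methods

## Model

The analysis is demand-side input–output accounting. An economy of *n*
sectors is described by the inter-industry flow matrix **Z** (entry (i, j):
sales from sector *i* to sector *j*, million USD), total output **x**,
final demand **f** and value added **va**, linked by the accounting
identities

* row: `x_i = Σ_j Z_ij + f_i` (output is sold as intermediates or to final
  demand),
* column: `x_j = Σ_i Z_ij + va_j` (output is paid out as intermediate
  purchases or value added).

Technical coefficients are `A_ij = Z_ij / x_j`: we adopt the standard
orientation in which **columns are input recipes** of the purchasing
sector, so column sums of the Leontief inverse are the output multipliers.
The phraseology around coefficient definitions in the applied literature is
sometimes ambiguous about transposition; results here are
convention-consistent rather than byte-matched to any one study.

The economy must be *productive* before inversion: spectral radius of **A**
strictly below 1, equivalently all leading principal minors of I − A
positive (Hawkins–Simon). Both checks are implemented; the spectral radius
drives the error message (it is a single interpretable number), the minors
drive the validator (tolerance 1e−12 on positivity). Inversion is refused
when the spectral radius exceeds 1 − 1e−9 rather than returning a
numerically meaningless matrix.

### Impact decomposition

For an injection **F**, the total gross-output requirement is `L F` with
`L = (I − A)⁻¹`. We define

* **direct** = **F** (the injection itself — not A·F; this convention makes
  direct + indirect + induced sum to `L F` exactly),
* **indirect** = `(L_I − I) F`,
* **induced** = the industry block of `(L_II − L_I) F`, where L_II is the
  inverse of the household-augmented (n+1)-system: the coefficient matrix
  gains a household consumption column (spending per unit of labor income)
  and a labor-income row (income per unit of sectoral output). Type I
  closure (no household) is the default; induced effects are then zero.

Sector shares are percentages of the all-sector total and are left
undefined (reported as null) for a zero total rather than fabricating a
0/0.

## Synthetic economy generator

Real supply–use tables are not redistributable, so the generator emulates
their structure directly:

1. draw a nonnegative matrix and rescale each column so its sum is uniform
   on `[min(0.2, cap/2), cap)` — for a nonnegative matrix the spectral
   radius is bounded by the largest column sum, so productivity and the
   requested spectral cap hold *by construction*, with no rejection step;
2. draw final demand `f` uniform on [50, 500] million USD per sector, solve
   `x = (I − A)⁻¹ f` (positive because L ≥ 0 and f > 0), and set
   `Z = A · diag(x)`;
3. value added follows as `va_j = x_j (1 − colsum_j(A)) > 0`.

Both identities then hold to machine precision and every generated table
passes the validator. The optional household account draws labor-income
shares of value added uniform on [0.4, 0.7] and household consumption
proportional to final demand with an aggregate propensity uniform on
[0.5, 0.8]; this keeps household consumption inside final demand, labor
income inside value added, and the augmented matrix productive.

What the generator does **not** emulate: realistic sectoral sparsity
patterns, the heavy-tailed size distribution of actual economies, imports
and taxes as separate rows, or any base-year calibration. Passing tests
therefore demonstrate correctness of the accounting and the solver on
economies with the assumed structure, not predictive accuracy for any real
country.

The default 27-sector label set spans primary production (agriculture,
fishing, forestry, mining), processing and manufacturing, infrastructure,
services, and knowledge sectors (R&D, education) — the sectoral breadth a
middle-income national account would show.

## Scenario conventions

* **Injection**: investment total (default US$20M) split by allocation
  weights (default 0.5/0.5 between R&D and agriculture); the demand vector
  sums to the total exactly.
* **Productivity gain** (default 10% in the agriculture-related sectors,
  resolved as the configurable set {agriculture, fishing}): treated as
  *input efficiency* — target columns of A scaled by 1/(1+g), i.e. the same
  output from proportionally fewer intermediate inputs. One could instead
  read a productivity story as raising coefficients; we keep the two
  mechanisms separate: efficiency lowers coefficients, linkage
  strengthening raises them, and each is its own operation.
* **Linkage strengthening**: `A[source, t] += delta` for each target. The
  default delta is 0 (off) so the base pipeline never injects a parameter
  that has no stated value; the operation rejects (input unchanged) any
  delta that drives a column sum to 1 or the matrix non-productive.
* **Composition order** is fixed: productivity gain first, then linkage
  strengthening. Matrix edits do not commute in their effect on L, so the
  order is part of the contract.

## Projection

The benefit stream is geometric: `benefit_t = b (1+g)^(t−1)`, year-end
timing, so the cumulative total is `C(T) = b ((1+g)^T − 1)/g` (`b·T` at
g = 0, handled exactly). Two anchors (T₁, C₁), (T₂, C₂) identify (b, g)
exactly: the ratio `C₂/C₁ = S_{T₂}(g)/S_{T₁}(g)` is strictly increasing in
g, so Brent root-finding on [−0.99, g_hi] (bracket widened upward as
needed, xtol 1e−12) recovers g, and b follows from the T₁ anchor. Anchors
with C₂ < C₁ are infeasible for a nonnegative stream and are rejected; a
ratio exactly T₂/T₁ takes the g = 0 branch.

The default anchors — cumulative US$35M over 5 years rising to US$79M by
year 20 — force g ≈ −9%/yr, a *decelerating* stream. The report carries
the calibrated g explicitly so this implication is visible rather than
buried. Whether such published horizon totals arise from repeated annual
injections or an exogenous growth assumption is not stated in the sources
that print them; the module treats them purely as calibration anchors.

## Cost–benefit appraisal

Year-end discounting over t = 1..T: `PV = Σ amount_t/(1+r)^t`, with r = 5%
and T = 10 years by default. The timing convention is stated prominently
because beginning-of-year discounting shifts every PV by a factor (1+r)
(~5% here). NPV is PV(benefits) − PV(costs) (bit-exact by construction in
the result object); BCR is their ratio, undefined at zero discounted cost.

The default cost stream spreads the investment evenly over the appraisal
window (`spread_years = T`); a lump-sum first-year reading is available via
`spread_years = 1`. At 5% over 10 years the even spread discounts US$20M to
US$15.44M. Published appraisals of this kind sometimes print a discounted
cost near US$12.2M for a US$20M outlay, which neither the lump-sum nor the
even-spread reading reproduces; the cost-stream shape behind such figures
is not recoverable, so both supported readings are explicit config options
and full-precision values are always carried. Relatedly, a printed triple
(discounted benefit 40, NPV 28, BCR 3.29) is mutually inconsistent at its
stated precision (40 − 40/3.29 = 27.84; 40/(40 − 28) = 3.33); this package
rounds only at the render layer and keeps full precision in the JSON
report.

## Pipeline and report

Stages run in fixed order — load/generate table, validate, base and
adjusted impacts, projection, CBA — and any failure aborts with the stage
name; nothing is written on failure. The JSON report carries full-precision
values plus a provenance block (seed, canonical config, SHA-256 config
hash, package version) sufficient to regenerate the identical report byte
for byte. A structural JSON schema ships with the package
(`report_schema.json`) and `validate_report` checks documents against it.
Rendering rounds currency to 2 decimals and shares to the nearest percent;
rounding never feeds back into stored values.

## Problem sizes and determinism

Property suites run on economies of up to 30 sectors and coefficient
matrices up to n = 6 against a truncated Neumann-series oracle (truncation
order chosen from the spectral radius so the remainder bound is below
1e−10); calibration recovery uses 200 random (b, g) pairs. These sizes
exercise every code path while keeping the full suite around a second.
All randomness flows through seeded `numpy` generators; hypothesis tests
run derandomized.

## Known limitations

* Demand-side (Leontief) model only; no price-side (Ghosh) dual, no
  multi-regional linkage, no employment or income satellite accounts beyond
  the optional household closure.
* The synthetic generator's uniform draws understate the sparsity and
  skewness of real flow tables (see above).
* The geometric projection is a two-parameter reduced form, not a
  structural link from the input–output impacts to future benefits.
* Environmental co-benefits (emissions, land, water) are out of scope: no
  quantification formula is available to implement.
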