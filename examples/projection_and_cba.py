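"""Calibrate the benefit projection and run the cost-benefit appraisal.

Two cumulative totals — US$35M over the first five years, US$79M by year
twenty — pin down the geometric benefit stream; those anchors force a
decelerating stream (negative annual growth). The appraisal discounts a
10-year window at 5% against the US$20M investment spread evenly.
"""

from bioecon import (
    CashFlowSeries,
    build_default_cost_stream,
    calibrate_projection,
    npv,
    project_cumulative_benefits,
)

params = calibrate_projection([(5, 35.0), (20, 79.0)], horizons=(5, 10, 20))
print(f"initial annual benefit b = {params.initial_benefit:.3f} MUSD/yr")
print(f"implied annual growth  g = {params.growth * 100:.2f}%/yr  (decelerating)")

for T, total in project_cumulative_benefits(params).items():
    print(f"  cumulative benefit after {T:2d} years: {total:6.2f} MUSD")

T = 10
flows = CashFlowSeries(
    benefits=params.annual_stream(T),
    costs=build_default_cost_stream(20.0, T, T),
    rate=0.05,
)
result = npv(flows)
print(f"discounted benefits: {result.pv_benefits:.2f} MUSD")
print(f"discounted costs:    {result.pv_costs:.2f} MUSD")
print(f"NPV:                 {result.npv:.2f} MUSD")
print(f"BCR:                 {result.bcr:.2f}  (benefit per dollar invested)")
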