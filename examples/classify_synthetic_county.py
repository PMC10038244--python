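"""Classify a synthetic county end-to-end and project treatment cost.

Generates a deterministic 10-mi synthetic county (rivers, lakes, preserves,
wetlands, addresses, census blocks), runs the 18-step protocol, and prints the
per-class summary: Approved cells are treatable mosquito habitat, Warning
cells are treatable but within 100 ft of protected land, Not Significant cells
hold structures without wetland habitat.  The cost projection multiplies the
vetted (Approved + Warning) acreage by a per-acre rate.
"""

import mczones as mz

params = mz.CountyParams(seed=7)
bundle = mz.generate_county(params)
config = mz.default_config(params)

grid, summary = mz.run_pipeline(bundle, config)
print(summary.to_frame().to_string(index=False))

report = mz.estimate_treatment_cost(summary, cost_per_acre=1.75, product_rate=0.08)
print(f"\nvetted acres:      {report.treatable_acres:12.1f}")
print(f"application cost:  {report.total_cost:12.2f}  (at $1.75/acre)")
print(f"product needed:    {report.product_amount:12.2f}  (at 0.08 units/acre)")
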