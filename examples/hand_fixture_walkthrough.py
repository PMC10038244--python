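"""Walk through the hand-derivable 5x5-cell fixture county.

A preserve fills the centre cell, so the 100-ft drift buffer erases that cell
and drags its eight neighbours (distance zero to the erased boundary) into
Warning.  A wetland strip covers the west column, so its five cells are
Approved; the remaining eleven are Not Significant.  The printed map should
show exactly that ring-and-strip pattern.
"""

import mczones as mz

layers, expected = mz.expected_simple_case()
grid, summary = mz.run_pipeline(layers, mz.default_config())

symbol = {"Approved": "A", "Warning": "W", "Not Significant": "."}
got = {c.cell_id: c.type for c in grid.cells}
print("grid (row 4 at top; X = erased centre cell):")
for r in range(4, -1, -1):
    print("  " + " ".join(symbol.get(got.get((r, c)), "X") for c in range(5)))

mismatch = sum(1 for k in expected if got.get(k) != expected[k])
print(f"\ncells matching the hand-derived classes: {len(expected) - mismatch}"
      f"/{len(expected)}")
print(summary.to_frame().to_string(index=False))
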