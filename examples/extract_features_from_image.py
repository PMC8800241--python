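"""Extract per-window morphometric features from a rendered section.

Renders a synthetic IBA1-like plane (ramified cells on a noisy
background), then runs the sliding-window feature extraction: Phansalkar
local threshold, intensity measures, box-counting fractal dimension,
skeleton branch census and soma segmentation.
"""

import gliaclust as g

planes, truth = g.render_section(g.SyntheticTissueSpec(
    section_size_um=(300.0, 300.0), cell_density_per_mm2=350.0, seed=4))
print(f"rendered {len(truth.cells)} cells on a "
      f"{planes['IBA1'].shape[0]}x{planes['IBA1'].shape[1]} px plane "
      f"(1.5 px/µm)")

table = g.build_feature_table({"IBA1": planes["IBA1"]},
                              feature_set="microglia", section_id="demo")
print(f"{len(table)} windows x {len(table.feature_columns)} model features")

row = table.data.iloc[len(table) // 2]
print(f"centre window ({row.x_um:.0f}, {row.y_um:.0f}) µm: "
      f"Area {row.Area:.0f} µm², Mean {row.Mean:.1f} a.u., "
      f"D {row.FracDim:.2f}, {row.NumCells:.0f} cells, "
      f"{row.NumBranches:.0f} branches, {row.NumEndPoints:.0f} branch ends")
print("Ramified (resting) cells give a fractal dimension well above 1 and "
      "tens of branch ends per 100 µm window; activation would push D and "
      "branch counts down and intensity up.")
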