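"""Detect activated-glia clusters on synthetic sections, end to end.

Generates control and test feature tables with an implanted activation
region, trains the control-anchored pipeline (z-score -> PCA -> one-class
SVM), labels every test window distal/proximal/focal, and compares the
recovered proximal footprint against the known implant.
"""

import numpy as np
from shapely.ops import unary_union

import gliaclust as g

spec = g.SyntheticFeatureSpec(seed=1)
control, test, truth = g.generate_feature_table(spec)
print(f"control: {len(control)} windows over {len(control.sections())} sections; "
      f"test: {len(test)} windows over {len(test.sections())} sections")

model = g.fit_pipeline(control, g.OcsvmConfig(nu=0.05, gamma=0.1), min_size=5)
print(f"PCA retained {model.projection.n_retained} components "
      f"(target {model.projection.variance_target:.0%} of control variance)")

labeling = g.label_table(model, test)
counts = labeling.labels["region"].value_counts().to_dict()
print(f"window labels: {counts}")

implant = truth.implant_polygon()
for sec in test.sections():
    polys = [c.polygon for c in labeling.clusters
             if c.section_id == sec and c.region == "proximal"]
    u = unary_union(polys)
    iou = u.intersection(implant).area / u.union(implant).area
    print(f"  {sec}: proximal footprint {u.area / 1e6:.3f} mm², "
          f"IoU vs implanted region = {iou:.2f}")
print("IoU near 1 means the detected proximal region matches the implanted "
      "activation geometry; distal windows are the unaffected remainder.")
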