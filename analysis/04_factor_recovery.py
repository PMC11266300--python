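#!/usr/bin/env python
"""Score the shape model's modes against the generator's ground truth.

The central validation: on an n=30 femur population whose latent factors
are known (log-scale SD 0.1 dominating; varus/valgus, procurvation, torsion
and condyle width as secondary factors), the PCA modes should line up with
the factors — Mode 1 = size/scale, Mode 2 = varus/valgus — exactly the
qualitative reading reported for real canine femora.

Two correspondence routes are compared: the generator's ground-truth shared
connectivity, and the pipeline's nearest-neighbor resampling. The NN route
is noticeably lossier at this scale range (tangential motion is invisible
to closest-point matching), which is quantified here rather than assumed.
Writes results/factor_recovery.csv.
"""

import csv
from pathlib import Path

import numpy as np

from ossa.recovery import factor_recovery
from ossa.synthetic import BonePopulationSpec

SEED = 1
spec = BonePopulationSpec(n=30, seed=SEED)

rows = []
for route in ("direct", "nn_vertex", "nn_surface"):
    rec = factor_recovery(spec, correspondence=route)
    vt = rec["variance_table"]
    a = [float(x) for x in vt.rounded()[0]]
    c = rec["correlations"]
    rows.append([route, *a, c["log_scale"][0], c["varus_deg"][1]])
    nn = rec["mean_nn_distance"]
    nn_txt = f", mean NN dist {np.mean(nn):.2f} mm" if nn is not None else ""
    print(f"{route:10s}: A = {a} | corr(Mode1, log-scale) = {c['log_scale'][0]:.3f}, "
          f"corr(Mode2, varus) = {c['varus_deg'][1]:.3f}{nn_txt}")

print("\nPer-factor |correlation| with modes 1-5 (ground-truth correspondence):")
rec = factor_recovery(spec, correspondence="direct")
for factor, cors in rec["correlations"].items():
    print(f"  {factor:14s} {np.round(cors, 2)}")

out = Path("results/factor_recovery.csv")
out.parent.mkdir(exist_ok=True)
with out.open("w", newline="") as fh:
    writer = csv.writer(fh)
    writer.writerow(["correspondence", "A1", "A2", "A3", "A4", "A5", "corr_mode1_logscale", "corr_mode2_varus"])
    writer.writerows(rows)
print(f"-> {out}")
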