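#!/usr/bin/env python
"""Generate the synthetic bone populations used throughout the analysis.

Real canine CT data are access-restricted, so the study conditions are
emulated: femur groups partitioned by body-size band (plus chondrodystrophic
and retriever analogues), a tibia group and a patella group, each with the
study's specimen counts. Writes the per-specimen latent records (the ground
truth every later script scores against) to results/, and the meshes +
landmark files to scratch/ for inspection.
"""

import csv
import json
from pathlib import Path

from ossa.mesh import write_mesh
from ossa.synthetic import GROUP_FIXTURES, make_group_fixture

SEED = 1
GROUPS = ["group1_whole_femur", "group2_0_10kg", "group6_retrievers", "tibia", "patella"]

results = Path("results")
scratch = Path("scratch/populations")
results.mkdir(exist_ok=True)

with (results / "population_latents.csv").open("w", newline="") as fh:
    writer = csv.writer(fh)
    writer.writerow(["group", "id", "scale", "varus_deg", "procurv_deg", "torsion_deg", "condyle_width"])
    for group in GROUPS:
        meshes, records, landmarks = make_group_fixture(group, seed=SEED)
        gdir = scratch / group
        gdir.mkdir(parents=True, exist_ok=True)
        for m, r, lm in zip(meshes, records, landmarks):
            write_mesh(m, gdir / f"{m.name}.ply")
            (gdir / f"{m.name}.landmarks.json").write_text(json.dumps(lm.to_dict()))
            writer.writerow([group, r.id, r.scale, r.varus_deg, r.procurv_deg, r.torsion_deg, r.condyle_width])
        print(f"{group}: {len(meshes)} specimens "
              f"({meshes[0].n_vertices} vertices each), bone={GROUP_FIXTURES[group][0]}")

print(f"latent records -> {results / 'population_latents.csv'}")
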