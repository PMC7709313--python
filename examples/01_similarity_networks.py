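"""Build the three similarity matrices the walks run on.

Generates the default synthetic tripartite dataset, then computes the
Gaussian interaction-profile (GIP) kernel between miRNAs, the ontology-based
disease semantic similarity, and the best-match-average functional
similarity for miRNAs.  Within-group entries should be visibly larger than
between-group ones: that contrast is the planted signal every later stage
consumes.
"""

import numpy as np

from fvtlda import FvtldaParams, build_pipeline_data, generate

dataset = generate()  # default block fixture, seed 0
data = build_pipeline_data(dataset.md, dataset.ml, dataset.ld, dataset.mesh,
                           params=FvtldaParams())

g_m = dataset.groups["miRNA"]
km = data.km.values
same = g_m[:, None] == g_m[None, :]
off = ~np.eye(len(g_m), dtype=bool)

print(f"miRNAs: {len(data.mirnas)}, diseases: {len(data.md.cols)}, "
      f"lncRNAs: {len(data.ml.cols)}")
print(f"GIP kernel      within-group mean {km[same & off].mean():.4f}  "
      f"between-group mean {km[~same].mean():.4f}")

fm = data.fm.values
print(f"miRNA functional within-group mean {fm[same & off].mean():.4f}  "
      f"between-group mean {fm[~same].mean():.4f}")

ds = data.ds_md.values
g_d = np.array([dataset.groups["disease"][int(n.split('-')[1])]
                for n in data.ds_md.labels])
same_d = g_d[:, None] == g_d[None, :]
off_d = ~np.eye(len(g_d), dtype=bool)
print(f"disease semantic within-group mean {ds[same_d & off_d].mean():.4f}  "
      f"between-group mean {ds[~same_d].mean():.4f}")
print("\nA larger within-group mean means the network carries the planted "
      "group structure.  The contrast is strong for the ontology-driven "
      "matrices and deliberately faint for the GIP kernel, whose bandwidth "
      "shrinks with the total interaction mass: on a dense matrix the kernel "
      "saturates toward 1.")
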