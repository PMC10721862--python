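"""Whole pipeline to the network-based statistic.

Simulates the default cohort, computes per-session post-minus-pre Fisher-z
difference matrices, and runs the NBS treatment contrast with within-subject
exchange blocks: 5000 permutations, primary threshold F > 7.31 (the upper
1% point of F(1, 40)).
"""

import numpy as np

from psiloconn import atlas, pipeline, synthetic
from psiloconn.nbs import EdgeGlmDesign, NbsParams, nbs_permutation_test

cohort = synthetic.generate_cohort(15, 6, seed=1)
analysis = pipeline.analyze_cohort(cohort, seed=7)

design = EdgeGlmDesign(analysis.subjects, analysis.groups,
                       analysis.diff_psi, analysis.diff_sal,
                       analysis.labels, contrast="treatment")
result = nbs_permutation_test(design, NbsParams(f_pt=7.31, n_perm=5000, seed=3))

print(f"edge GLM df = {result.df}; primary threshold F > {result.f_pt}")
for comp in result.components[:3]:
    print(f"component: {comp.extent} edges, p_FWE = {comp.p_fwe:.4f}")

top = result.components[0]
hubs = set(atlas.indices(atlas.HUB_REGIONS))
hub_edges = [(i, j) for i, j in top.edges if i in hubs or j in hubs]
neg = sum(result.mean_effect[i, j] < 0 for i, j in top.edges)
print(f"\ntop component: {neg}/{top.extent} edges show psilocybin-induced "
      f"hypoconnectivity (cortical), {len(hub_edges)} involve the DRN/HypR "
      "hubs and show hyperconnectivity:")
for i, j in hub_edges[:5]:
    print(f"  {analysis.labels[i]} - {analysis.labels[j]}: "
          f"mean z difference {result.mean_effect[i, j]:+.3f}")
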