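"""Auxiliary tumor assays: IHC H-score and the CD8/PD-L1 proximity index.

Computes an immunohistochemistry H-score from staining percentages and the
percentage of CD8+ cells with a PD-L1+ neighbor within a distance cutoff on
a simulated 2-D cell map.
"""

from immunotrack import gen_cell_map, h_score, proximity_index

print(f"H-score for 10% strong / 20% moderate / 30% weak: {h_score(10, 20, 30)}")

random_map = gen_cell_map(n_cd8=200, n_pdl1=100, clustering="none", seed=3)
clustered_map = gen_cell_map(
    n_cd8=100, n_pdl1=200, clustering="attract", attract_radius_um=5, seed=3
)
for cutoff in (20, 40, 60, 80):
    print(
        f"proximity index at {cutoff:>2} um: "
        f"random {proximity_index(random_map, cutoff):5.1f}  "
        f"clustered {proximity_index(clustered_map, cutoff):5.1f}"
    )
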