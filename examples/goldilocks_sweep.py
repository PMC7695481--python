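"""Avidity sweep in the agent-based transwell: the Goldilocks optimum.

Runs a reduced sweep of the apparent permeability over ligand number per
particle at fixed single-ligand affinity (Kd = 300 nM), particle radius
50 nm and receptor density 30 um^-2, and prints P(L).  Intermediate
valency binds strongly enough to be endocytosed yet weakly enough to be
released basally, so P peaks at an interior L.

A full-scale sweep (L grid {1,22,36,56,110,220}, 500 agents x 3 seeds)
takes a few minutes; see scripts/acceptance.py.
"""

from transcytokit.transwell import TranswellModel, sweep_heatmap

model = TranswellModel(receptor_density_um2=30.0)
heatmap = sweep_heatmap(
    model,
    radius_nm=50.0,
    L_grid=[1, 22, 110],
    Kd_grid_nM=[300.0],
    n_agents=200,
    t_end_s=400.0,
    n_seeds=2,
    seed=1,
)

print("apparent permeability vs ligand number (Kd = 300 nM):")
for L, p in heatmap.iloc[0].items():
    print(f"  L = {L:>3d}   P = {p:6.1f} nm/s")
best = int(heatmap.iloc[0].idxmax())
print(f"optimum at L = {best}: high enough avidity to bind and be endocytosed,")
print("low enough to detach on the basal side within the assay time.")
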