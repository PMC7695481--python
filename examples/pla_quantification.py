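"""Proximity-ligation-assay quantification on a synthetic confocal z-stack.

Renders diffraction-limited puncta with detector noise and channel
cross-talk, then runs the per-slice pipeline (denoise, rolling-average
background removal, maxima detection, single-linkage z-grouping) and prints
the per-cell summaries N_E (events per cell) and PLA_C (volume-normalized
signal per cell).
"""

from transcytokit import pla
from transcytokit.synth import PunctaScene, gen_pla_stack

scene = PunctaScene(n_puncta=120, crosstalk_au=30.0, n_cells=4, seed=3)
stack, truth = gen_pla_stack(scene)
puncta, summary = pla.quantify_stack(stack, scene.voxel_size_um, n_cells=scene.n_cells)
tp, fp, fn = pla.match_to_truth(puncta, truth)

print(f"scripted {len(truth)} puncta; detected {summary.n_puncta} "
      f"(recall {tp/(tp+fn):.2f}, precision {tp/(tp+fp):.2f})")
print(f"N_E   = {summary.events_per_cell:.1f} events/cell  -- how distributed the interaction is")
print(f"PLA_C = {summary.signal_per_cell:.3g} a.u./um^3 per cell  -- how strong it is")

# treated-vs-control comparison on a second, denser condition
treated_scene = PunctaScene(n_puncta=160, crosstalk_au=30.0, n_cells=4, seed=4)
t_stack, _ = gen_pla_stack(treated_scene)
_, treated = pla.quantify_stack(t_stack, treated_scene.voxel_size_um, n_cells=4)
out = pla.compare(treated, summary)
print(f"deviation treated-control: {out['deviation_events_per_cell']:+.1f} events/cell "
      f"({'physiological fluctuation' if out['physiological_fluctuation'] else 'regulation'})")
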