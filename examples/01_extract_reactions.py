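"""Extract species, concentrations and reaction events from a bond trajectory.

Generates a ground-truth methane-fragment trajectory (20 CH4 molecules, 2000
frames), partitions each frame's bond graph into molecules, and detects the
elementary reaction events between consecutive frames.
"""

import numpy as np

import kmclearn as km

net, templates = km.toy_methane_network()
x0 = np.zeros(net.m, dtype=int)
x0[net.species_labels.index("C1 H4 4(H–C)")] = 20
bond_traj, truth = km.generate_reacting_system(
    net, templates, x0, t_end=20.0, frame_dt=0.01, seed=11
)

partitions, conc = km.molecules_per_frame(bond_traj)
events, counts, skeleton = km.detect_reaction_events(partitions, frame_dt=0.01)

print(f"frames: {bond_traj.n_frames}, atoms: {bond_traj.n_atoms}")
print(f"true events fired: {len(truth.events)}, events detected: {len(events)}")
print(f"species observed: {conc.species}")
print("reaction types and total counts:")
for rx in skeleton.reactions:
    print(f"  {rx.observed_count_total:4d}  {rx.key}")
# Every detected event is one elementary reaction; identical totals mean the
# extraction recovered the simulated chemistry exactly (tau = 1, no flicker).
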