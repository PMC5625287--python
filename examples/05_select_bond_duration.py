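"""Bond-duration (τ) smoothing and model selection.

Shows the hysteresis filter rejecting vibrational flicker on a noisy bond
signal, and the τ model-selection loop scoring extracted models against the
source concentrations on a flicker-free trajectory.
"""

import numpy as np

import kmclearn as km

# 1. the hysteresis filter on a flickered boolean bond signal
raw, clean = km.generate_bond_signal(
    n_frames=300,
    true_transitions=[(60, True), (180, False)],
    flicker_rate=0.02,
    flicker_max_len=4,
    seed=12,
)
recovered = km.hysteresis_filter(raw, tau=4, initial=bool(clean[0]))
print(f"flickered frames: {int((raw != clean).sum())} of {raw.size}")
print(f"filter at τ = 4 recovers the clean signal exactly: {bool(np.array_equal(recovered, clean))}")
leaky = km.hysteresis_filter(raw, tau=2, initial=bool(clean[0]))
print(f"filter at τ = 2 leaves residual errors: {int((leaky != clean).sum())} frames")

# 2. τ model selection on a generated trajectory
net, templates = km.toy_methane_network()
x0 = np.zeros(net.m, dtype=int)
x0[net.species_labels.index("C1 H4 4(H–C)")] = 15
bond_traj, _ = km.generate_reacting_system(net, templates, x0, t_end=10.0, frame_dt=0.01, seed=2)
tau_star, curve = km.select_bond_duration(bond_traj, [1, 2, 4, 8], n_replicates=5, seed=0)
print("\ntau  mean RMSE  reactions")
for tau, err, r in curve:
    print(f"{tau:3d}  {err:9.3f}  {r:9d}")
print(f"selected τ* = {tau_star} frames (smallest error, ties to smaller τ)")
# On clean data every τ below the shortest bond lifetime extracts the same
# network, so the curve is flat there; real data trades off flicker noise
# (small τ) against missed genuine reactions (large τ).
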