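"""Force-velocity relations of a growing actin network.

The same network shows a concave-down force-velocity relation when loaded
slowly by an elastic cantilever (the aging, disassembling gel recoils under
load) and a concave-up one when the force is clamped briefly on a young
network (no recoil: per-filament ratchet mechanics).  This script evaluates
the 1D aging-recoil theory for both protocols and a scaled-down 2D clamp
simulation, and prints the concavity class of each curve.
"""
import numpy as np

from mesotail import clamp_fv, recoil_theory_1d
from mesotail.experiments import default_clamp_forces, fv_config

th_cant = recoil_theory_1d(k_dis=0.01, mode="cantilever")
th_clamp = recoil_theory_1d(k_dis=0.01, mode="clamp", age=60.0)
th_rigid = recoil_theory_1d(k_dis=0.0, mode="clamp", age=60.0)
print(f"1D theory, cantilever (aging)   : {th_cant.classify()}")
print(f"1D theory, clamp (young network): {th_clamp.classify()}")
print(f"1D theory, no disassembly       : {th_rigid.classify()} "
      f"(pure ratchet law, V(0) = {th_rigid.V[0]:.2f} um/s)")

cfg = fv_config()
curve = clamp_fv(default_clamp_forces(cfg), window=12.0, cfg=cfg,
                 seed=3, n_seeds=2, surface="round")
print(f"2D clamp simulation             : {curve.classify()}")
print("  F (pN):", np.round(curve.F, 1))
print("  V(um/s):", np.round(curve.V, 3))
# Concave-down vs concave-up from one model, controlled only by whether the
# measurement outlasts the network's disassembly time 1/k_dis.
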