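"""Curvature statistics of spherical-bead trajectories.

The trajectory curvature kappa = angular velocity / speed fluctuates with
the random filament number imbalance at the bead rear.  This script runs a
small spherical-bead ensemble, then prints the root-mean-square curvature,
the shape of the normalized curvature distribution, and the entrapment
count (sustained pauses inside the actin cloud).
"""
from mesotail import SimConfig, trajectory_assay

cfg = SimConfig(T_end=300.0)
res = trajectory_assay(n_runs=4, cfg=cfg, seed0=2)
print(f"kappa_rms per run (1/um): {[round(float(k), 2) for k in res.kappa_rms]}")
print(f"pooled excess kurtosis  : {res.pooled_kurtosis:.2f}")
print(f"pooled KS vs Gaussian   : {res.pooled_ks:.3f}")
print(f"entrapment events       : {[int(e) for e in res.entrapments]}")
print(f"mean speed              : {res.mean_speed:.3f} um/s")
print(f"mean pushing filaments  : {res.mean_n_pushing:.1f}")
# Near-zero excess kurtosis means near-Gaussian turning driven by random
# filament-number fluctuations; rerun with k_det0 = cfg.k_det0 / 4 to see the
# sharply peaked distribution and entrapment of strongly attached beads.
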