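"""Quasi-static mechanics of the node-spring gel on its own.

Builds a small network, loads it, relaxes it to force balance and shows the
Hookean response; then demonstrates crosslink rupture and stochastic
disassembly, the two turnover channels that make the gel viscoelastic on
long time scales.
"""
import numpy as np

from mesotail import GelNetwork

net = GelNetwork(kappa_net=2.0)
left = net.add_node((-1.0, 0.0), mobile=False)
right = net.add_node((1.0, 0.0), mobile=False)
mid = net.add_node((0.0, 0.0))
net.add_spring(mid, left, rest_length=1.0)
net.add_spring(mid, right, rest_length=1.0)

f = 0.1
res = net.relax({mid: np.array([f, 0.0])}, tol=1e-9, max_sweeps=20000)
print(f"relaxed in {res.sweeps} sweeps, residual {res.residual:.2e} pN")
print(f"displacement {net.px[mid]:.4f} um vs Hooke prediction "
      f"{f / (2 * net.kappa_net):.4f} um (two springs in parallel)")

rng = np.random.default_rng(0)
for k in range(30):
    net.anchor_node(rng.uniform(-1, 1, 2), anchor_radius=0.6)
print(f"grown network: {net.n_nodes} nodes, {net.n_springs} springs")
removed = net.disassemble(k_dis=1.0, dt=0.1, rng=rng)
print(f"disassembly removed {removed.size} nodes "
      f"(per-node removal probability {1 - np.exp(-0.1):.3f})")
# stretch the whole network and let overloaded crosslinks break
ids = net.node_ids
net.px[ids] *= 1.5
ruptured = net.rupture(F_rup=0.2)
print(f"after a 50% x-stretch, rupture removed {ruptured.size} "
      f"of {net.n_springs + ruptured.size} springs")
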