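"""Surface filaments: rate laws, forces, nucleation, state kinetics."""
import math

import numpy as np
import pytest
from scipy import stats

from mesotail._kernels import ATTACHED, FREE
from mesotail.filaments import (
    FilamentSystem, KineticRates, detachment_rate, filament_force,
    polymerization_velocity, spawn_filaments, update_filament_states,
)
from mesotail.gel import GelNetwork
from mesotail.geometry import Bead, outward_normal, surface_point


class TestRateLaws:
    def test_bell_law_anchor_points(self):
        assert detachment_rate(0.0, 0.5, 2.0) == pytest.approx(0.5)
        assert detachment_rate(2.0, 0.5, 2.0) == pytest.approx(0.5 * math.e)

    def test_bell_law_exponential_identity(self):
        # rate(2F) * k0 == rate(F)^2 for an exponential law
        k0, Fd = 0.7, 1.3
        for F in np.linspace(0.0, 5.0, 11):
            assert detachment_rate(2 * F, k0, Fd) * k0 == pytest.approx(
                detachment_rate(F, k0, Fd) ** 2, rel=1e-12)

    def test_bell_law_rejects_bad_scale(self):
        with pytest.raises(ValueError):
            detachment_rate(1.0, 0.5, 0.0)

    def test_ratchet_velocity_anchor_points(self):
        V, d, kT = 0.5, 0.0027, 0.0041
        assert polymerization_velocity(0.0, V, d, kT) == pytest.approx(V)
        F_half = kT * math.log(2) / d
        assert polymerization_velocity(F_half, V, d, kT) == pytest.approx(V / 2)

    def test_ratchet_velocity_monotone_to_zero(self):
        V, d, kT = 0.5, 0.0027, 0.0041
        F = np.linspace(0, 60, 200)
        v = polymerization_velocity(F, V, d, kT)
        assert np.all(np.diff(v) < 0)
        assert v[-1] < 1e-8


def _setup(bead=None, kappa_f=100.0):
    bead = bead or Bead(1.0, 1.0)
    net = GelNetwork(kappa_net=10.0)
    fils = FilamentSystem(kappa_f=kappa_f)
    return bead, net, fils


class TestFilamentForce:
    def test_free_filament_out_of_contact(self):
        bead, net, fils = _setup()
        a = net.add_node((1.5, 0.0))
        i = fils.add(0.0, a, rest_length=0.1, attached=False)
        f, r, _ = filament_force(fils, i, bead, net)
        assert np.allclose(f, 0) and np.allclose(r, 0)

    def test_free_filament_push_hooke(self):
        # anchor 0.2 outside, rest length 0.25 -> penetration 0.05,
        # push 5 pN along the inward normal, reaction opposite
        bead, net, fils = _setup()
        a = net.add_node((1.2, 0.0))
        i = fils.add(0.0, a, rest_length=0.25, attached=False)
        f, r, q = filament_force(fils, i, bead, net)
        assert np.allclose(f, [-5.0, 0.0], atol=1e-9)
        assert np.allclose(f + r, 0.0)
        assert np.allclose(q, [1.0, 0.0], atol=1e-9)

    def test_attached_at_rest_length_is_force_free(self):
        bead, net, fils = _setup()
        t = 0.8
        q = surface_point(bead, t)
        a = net.add_node(q + 0.05 * outward_normal(bead, t))
        i = fils.add(t, a, rest_length=0.05, attached=True)
        f, r, _ = filament_force(fils, i, bead, net)
        assert np.allclose(f, 0) and np.allclose(r, 0)

    def test_attached_pulls_toward_anchor_when_stretched(self):
        bead, net, fils = _setup()
        a = net.add_node((1.3, 0.0))
        i = fils.add(0.0, a, rest_length=0.1, attached=True)
        f, r, site = filament_force(fils, i, bead, net)
        assert f[0] == pytest.approx(100.0 * 0.2)
        assert np.allclose(f + r, 0.0)
        assert np.allclose(site, [1.0, 0.0], atol=1e-12)

    def test_attached_never_pushes_through_tether(self):
        bead, net, fils = _setup()
        a = net.add_node((1.05, 0.0))
        i = fils.add(0.0, a, rest_length=0.5, attached=True)  # slack tether
        f, r, _ = filament_force(fils, i, bead, net)
        assert np.allclose(f, 0.0)


class TestKernelConsistency:
    def test_batch_kernel_matches_reference_forces(self, rng):
        """The fused engine kernel and the readable per-filament reference
        implementation produce identical forces (Newton's third law both)."""
        bead = Bead(1.6, 0.9, center=(0.4, -0.2), orientation=0.5)
        net = GelNetwork()
        fils = FilamentSystem(kappa_f=80.0)
        for k in range(40):
            t = rng.uniform(0, 2 * np.pi)
            q = surface_point(bead, t)
            n = outward_normal(bead, t)
            a = net.add_node(q + rng.uniform(0.0, 0.4) * n)
            fils.add(t, a, rest_length=rng.uniform(0.05, 0.5),
                     attached=bool(rng.integers(2)))
        ref_F = np.zeros(2)
        ref_T = 0.0
        ref_reactions = np.zeros((net.n_top, 2))
        for i in fils.ids:
            f, r, pnt = filament_force(fils, i, bead, net)
            ref_F += f
            rel = pnt - bead.center
            ref_T += rel[0] * f[1] - rel[1] * f[0]
            ref_reactions[fils.anchor[i]] += r
        F, T, (fxe, fye), diag = update_filament_states(
            fils, bead, net, KineticRates(k_att=0, k_det0=0, k_cap=0),
            dt=0.01, rng=rng, V_max=0.0)
        assert np.allclose(F, ref_F, atol=1e-9)
        assert T == pytest.approx(ref_T, abs=1e-9)
        assert np.allclose(fxe[:net.n_top], ref_reactions[:, 0], atol=1e-9)
        assert np.allclose(fye[:net.n_top], ref_reactions[:, 1], atol=1e-9)
        # global bookkeeping: reactions balance the bead wrench exactly
        assert np.allclose([fxe.sum(), fye.sum()], -F, atol=1e-9)


class TestSpawn:
    def test_spontaneous_births_uniform_in_arclength(self, rng):
        bead, net, fils = _setup(Bead(2.0, 1.0))
        rates = KineticRates(k_nuc=5.0, k_br=0.0)
        for _ in range(80):
            spawn_filaments(fils, bead, net, rates, dt=1.0, rng=rng)
        s = np.array([bead.arclength_of_param(t)
                      for t in fils.t_contact[fils.ids]])
        p = stats.kstest(s / bead.perimeter, "uniform").pvalue
        assert fils.n > 3000
        assert p > 0.01

    def test_no_parents_no_branching(self, rng):
        bead, net, fils = _setup()
        rates = KineticRates(k_nuc=0.0, k_br=10.0)
        new = spawn_filaments(fils, bead, net, rates, dt=1.0, rng=rng)
        assert new == []

    def test_branch_births_proportional_to_cluster_size(self, rng):
        """Two parent clusters with 2:1 filaments draw branch births 2:1."""
        bead, net, fils = _setup()
        a = net.add_node((1.05, 0.0))
        for _ in range(2):
            fils.add(0.0, a, rest_length=0.05)          # cluster A at t=0
        fils.add(np.pi, a, rest_length=0.05)            # cluster B at t=pi
        rates = KineticRates(k_nuc=0.0, k_br=1.0)
        n_a = n_b = 0
        for _ in range(4000):
            n0 = fils.n
            spawn_filaments(fils, bead, net, rates, dt=0.05, rng=rng,
                            sigma_br=0.01)
            new_ids = fils.ids[n0:]
            for i in new_ids:
                if np.cos(fils.t_contact[i]) > 0:
                    n_a += 1
                else:
                    n_b += 1
            # reset to keep parent ratio fixed
            for i in new_ids:
                fils.remove(i)
        tot = n_a + n_b
        p = n_a / tot
        se = math.sqrt(p * (1 - p) / tot)
        assert abs(p - 2 / 3) < 3 * se + 1e-12

    def test_newborns_are_attached_and_undeformed(self, rng):
        bead, net, fils = _setup()
        rates = KineticRates(k_nuc=2.0, k_br=0.0)
        new = []
        while not new:
            new = spawn_filaments(fils, bead, net, rates, dt=0.1, rng=rng, L0=0.05)
        for i in new:
            assert fils.state[i] == ATTACHED
            f, r, _ = filament_force(fils, i, bead, net)
            assert np.allclose(f, 0.0, atol=1e-9)
            assert net.n_alive_mask[fils.anchor[i]]


class TestStateKinetics:
    def test_all_rates_zero_is_inert(self, rng):
        bead, net, fils = _setup()
        a = net.add_node((1.2, 0.0))
        fils.add(0.0, a, rest_length=0.1, attached=True)
        fils.add(1.0, net.add_node((0.3, 1.2)), rest_length=0.1, attached=False)
        st0 = fils.state[fils.ids].copy()
        update_filament_states(fils, bead, net,
                               KineticRates(k_att=0, k_det0=0, k_cap=0),
                               dt=0.01, rng=rng, V_max=0.0)
        assert np.array_equal(fils.state[fils.ids], st0)

    def test_capping_binomial_mean(self, rng):
        """~ n(1-exp(-k dt)) free filaments cap per step; anchors persist."""
        bead, net, fils = _setup()
        n = 10_000
        for k in range(n):
            a = net.add_node((2.0 + 1e-4 * k, 0.0))
            fils.add(0.0, a, rest_length=0.01, attached=False)
        rates = KineticRates(k_att=0.0, k_det0=0.0, k_cap=1.0)
        steps = 20
        for _ in range(steps):
            update_filament_states(fils, bead, net, rates, dt=0.01, rng=rng)
        capped = n - fils.n
        q = 1 - (math.exp(-0.01)) ** steps   # P(capped within 20 steps)
        se = math.sqrt(n * q * (1 - q))
        assert abs(capped - n * q) < 3 * se
        assert net.n_nodes == n  # capped filaments leave their anchor nodes

    def test_two_state_occupancy_matches_master_equation(self, rng):
        """With force-free geometry the attached:free ratio converges to the
        dominant eigenvector of the two-state (+capping loss) generator."""
        bead, net, fils = _setup(kappa_f=0.0)   # no forces -> constant rates
        n = 4000
        for k in range(n):
            a = net.add_node((1.5, 1e-4 * k))
            fils.add(0.0, a, rest_length=0.01, attached=bool(k % 2))
        rates = KineticRates(k_att=1.0, k_det0=0.5, k_cap=0.5, k_nuc=0, k_br=0)
        dt = 0.02
        for _ in range(400):
            update_filament_states(fils, bead, net, rates, dt=dt, rng=rng)
        # generator on (attached, free): quasi-stationary ratio
        G = np.array([[-rates.k_det0, rates.k_att],
                      [rates.k_det0, -(rates.k_att + rates.k_cap)]])
        w, v = np.linalg.eig(G)
        vec = np.abs(v[:, np.argmax(w.real)])
        expected = vec[0] / vec[1]
        n_att, n_free = fils.counts()
        ratio = n_att / n_free
        assert ratio == pytest.approx(expected, rel=0.2)

    def test_unloaded_growth_rate_is_Vmax(self, rng):
        bead, net, fils = _setup()
        ids = []
        for k in range(1000):
            a = net.add_node((3.0, 1e-3 * k))   # far away: no load
            ids.append(fils.add(0.0, a, rest_length=0.01, attached=False))
        rates = KineticRates(k_att=0.0, k_det0=0.0, k_cap=0.0)
        r0 = fils.rest[ids].copy()
        V_max, dt = 0.5, 0.01
        update_filament_states(fils, bead, net, rates, dt=dt, rng=rng, V_max=V_max)
        growth = (fils.rest[ids] - r0) / dt
        assert np.mean(growth) == pytest.approx(V_max, rel=1e-9)
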