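"""Reaction kinetics: calibration map, step operators, product placement."""

import math

import numpy as np
import pytest

import smolsim as sm
from smolsim import reactions as rx
from tests.conftest import run_config


class TestRateCalibration:
    def test_well_mixed_limit(self):
        """s >> sigma_b: every in-range pair reacts, k -> (4/3) pi sigma^3/dt."""
        dt = 1.0
        for x in (0.02, 0.08):
            k = rx.rate_from_binding_radius(x, s=1.0, dt=dt)
            assert k == pytest.approx(4.0 / 3.0 * math.pi * x**3, rel=0.005)

    def test_smoluchowski_limit(self):
        """s << sigma_b: k approaches the diffusion-limited 4 pi D sigma."""
        dt = 1.0
        D = 0.5  # s = sqrt(2 D dt) = 1
        k30 = rx.rate_from_binding_radius(30.0, s=1.0, dt=dt)
        assert k30 == pytest.approx(4 * math.pi * D * 30.0, rel=0.03)
        # deficit shrinks as sigma/s grows
        k10 = rx.rate_from_binding_radius(10.0, s=1.0, dt=dt)
        assert (1 - k30 / (4 * math.pi * D * 30.0)) \
            < (1 - k10 / (4 * math.pi * D * 10.0))

    def test_round_trip_three_decades(self):
        """rate(radius(k)) = k to 0.1% across the regimes."""
        D_mut, dt = 2.0, 1e-3
        s = math.sqrt(2 * D_mut * dt)
        for k in (1e-4 * s**3 / dt, 1e-1 * s**3 / dt, 30.0 * s**3 / dt):
            sigma = rx.binding_radius_from_rate(k, D_mut, dt)
            back = rx.rate_from_binding_radius(sigma, s, dt)
            assert back == pytest.approx(k, rel=1e-3)

    def test_monotone_in_rate_and_timestep(self):
        D_mut = 2.0
        radii_k = [rx.binding_radius_from_rate(k, D_mut, 1e-3)
                   for k in (1e-3, 1e-2, 1e-1)]
        assert radii_k == sorted(radii_k)
        assert len(set(radii_k)) == 3
        radii_dt = [rx.binding_radius_from_rate(1e-2, D_mut, dt)
                    for dt in (1e-4, 1e-3, 1e-2)]
        assert radii_dt == sorted(radii_dt)

    def test_smoluchowski_inversion_as_dt_shrinks(self):
        """For k = 4 pi D sigma the radius converges to sigma as dt -> 0."""
        D_mut, sigma = 1.0, 1.0
        k = 4 * math.pi * D_mut * sigma
        errs = []
        for dt in (2e-3, 5e-4):
            got = rx.binding_radius_from_rate(k, D_mut, dt)
            errs.append(abs(got - sigma) / sigma)
        assert errs[1] < errs[0]
        assert errs[1] < 0.03

    def test_zero_rate_and_infeasible_rate(self):
        assert rx.binding_radius_from_rate(0.0, 1.0, 1e-3) == 0.0
        assert rx.rate_from_binding_radius(0.0, 1.0, 1e-3) == 0.0

    def test_unbinding_radius_formula(self):
        assert rx.unbinding_radius_from_pgem(1e-3, 0.2) \
            == pytest.approx(5e-3)
        assert rx.unbinding_radius_from_pgem(1.0, 0.999) \
            == pytest.approx(1.001, rel=1e-3)
        with pytest.raises(ValueError):
            rx.unbinding_radius_from_pgem(1.0, 1.0)
        with pytest.raises(ValueError):
            rx.unbinding_radius_from_pgem(1.0, 0.0)

    def test_geminate_capture_probability(self, rng):
        """A pair released at sigma_u is ever captured at sigma_b with
        probability sigma_b/sigma_u; checked by a walk-on-spheres
        first-passage simulation with an escape cap at 20 sigma_b."""
        sigma_b, p_gem = 1.0, 0.2
        sigma_u = rx.unbinding_radius_from_pgem(sigma_b, p_gem)
        R_esc, tol, n = 20.0, 1e-4, 100_000
        pos = np.zeros((n, 3))
        pos[:, 0] = sigma_u
        state = np.zeros(n, dtype=np.int8)  # 0 walking, 1 captured, 2 escaped
        for _ in range(200):
            walking = state == 0
            if not walking.any():
                break
            r = np.linalg.norm(pos[walking], axis=1)
            step = np.minimum(r - sigma_b, R_esc - r)
            u = rng.standard_normal((int(walking.sum()), 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pos[walking] += u * step[:, None]
            r_new = np.linalg.norm(pos[walking], axis=1)
            idx = np.flatnonzero(walking)
            state[idx[r_new < sigma_b + tol]] = 1
            state[idx[r_new > R_esc - tol]] = 2
        captured = (state == 1).mean()
        expected = (sigma_b / sigma_u - sigma_b / R_esc) / (1 - sigma_b / R_esc)
        assert captured == pytest.approx(expected, abs=3 * 0.0013)


class TestZerothOrder:
    def test_poisson_moments(self, run):
        txt = """dim 3
bounds x 0 2 reflective
bounds y 0 2 reflective
bounds z 0 2 reflective
time_stop 2
time_step 0.001
species A
difc A 0
reaction gen 0 -> A 0.25
"""
        # lam = k V dt = 0.25 * 8 * 0.001 = 2e-3 -> across 2000 steps
        sim = run(txt, seed=3)
        n = sim.store.count_alive()
        lam_tot = 0.25 * 8.0 * 2.0
        assert abs(n - lam_tot) < 4 * math.sqrt(lam_tot)

    def test_zero_rate_never_fires(self, run):
        txt = """dim 3
bounds x 0 1 reflective
bounds y 0 1 reflective
bounds z 0 1 reflective
time_stop 0.1
time_step 0.001
species A
difc A 0
reaction gen 0 -> A 0
"""
        assert run(txt, seed=1).store.count_alive() == 0

    def test_compartment_restricted_containment(self, run):
        txt = """dim 3
bounds x 0 2 reflective
bounds y 0 2 reflective
bounds z 0 2 reflective
time_stop 0.5
time_step 0.001
species A
difc A 0
start_surface ball
  panel s sphere 1 1 1 0.5
end_surface
start_compartment core
  surface ball
  point 1 1 1
end_compartment
reaction gen 0 -> A 200
reaction_region gen compartment core
"""
        sim = run(txt, seed=2)
        pos = sim.store.pos[sim.store.alive_idx()]
        assert sim.store.count_alive() > 20
        r = np.linalg.norm(pos - 1.0, axis=1)
        assert (r <= 0.5 + 1e-9).all()


class TestFirstOrder:
    def test_single_channel_half_life(self, run):
        dt = 1e-3
        k = math.log(2) / dt  # k dt = ln 2 -> half react per step
        txt = f"""dim 3
bounds x 0 1 reflective
bounds y 0 1 reflective
bounds z 0 1 reflective
time_stop {dt}
time_step {dt}
species A
difc A 0
mol 10000 A uniform
reaction dec A -> 0 {k}
"""
        sim = run(txt, seed=4)
        n = sim.store.count_alive()
        assert abs(n - 5000) < 3 * math.sqrt(10000 * 0.25)

    def test_multichannel_split(self, run):
        """k1 = 1, k2 = 3, dt = 0.1: total P = 1 - e^-0.4, split 1:3."""
        txt = """dim 3
bounds x 0 1 reflective
bounds y 0 1 reflective
bounds z 0 1 reflective
time_stop 0.1
time_step 0.1
species A B C
difc A 0
difc B 0
difc C 0
mol 40000 A uniform
reaction toB A -> B 1
reaction toC A -> C 3
cmd at 0.1 molcount out.txt
"""
        sim = run(txt, seed=5)
        row = sim.outputs["out.txt"].rows[-1]
        counts = dict(zip(sim.outputs["out.txt"].header[1:], row[1:]))
        p_tot = 1 - math.exp(-0.4)
        p1, p2 = 0.25 * p_tot, 0.75 * p_tot
        assert abs(counts["B"] - 40000 * p1) < 3 * math.sqrt(40000 * p1)
        assert abs(counts["C"] - 40000 * p2) < 3 * math.sqrt(40000 * p2)
        assert counts["A"] + counts["B"] + counts["C"] == 40000


class TestBimolecular:
    def test_no_pair_within_radius_no_reaction(self, run):
        txt = """dim 3
bounds x 0 10 reflective
bounds y 0 10 reflective
bounds z 0 10 reflective
time_stop 0.001
time_step 0.001
species A B C
difc A 1e-6
difc B 1e-6
difc C 1e-6
mol 1 A 1 1 1
mol 1 B 9 9 9
reaction bind A + B -> C 1e-9
"""
        sim = run(txt, seed=1)
        assert sim.event_counts.get("bind", 0) == 0
        assert sim.store.count_alive() == 2

    def test_mass_balance_every_step(self, run):
        txt = sm.generate_fixture(
            "bimolecular_ab",
            {"nA": 1500, "nB": 1200, "stop": 1.0, "out_every": 0.05})
        txt = txt.replace("reaction annihilate A + B -> 0",
                          "reaction annihilate A + B -> C")
        txt = txt.replace("species A B", "species A B C")
        txt = txt.replace("difc B 5\n", "difc B 5\ndifc C 5\n")
        sim = run(txt, seed=6)
        tab = sim.outputs["ab.txt"]
        A, B, C = tab.column("A"), tab.column("B"), tab.column("C")
        np.testing.assert_array_equal(1500 - A, C)
        np.testing.assert_array_equal(1200 - B, C)

    def test_neighbor_search_equivalent_to_all_pairs(self, rng):
        """KD-tree candidate pairs with the closest-first exclusivity rule
        reproduce a brute-force all-pairs scan exactly."""
        for trial in range(5):
            posA = rng.uniform(0, 1, size=(250, 3))
            posB = rng.uniform(0, 1, size=(250, 3))
            radius = 0.06
            pairs = rx.find_pairs(posA, posB, radius)
            # brute force: all pairs under the same ordering rule
            d = np.linalg.norm(posA[:, None, :] - posB[None, :, :], axis=2)
            ii, jj = np.nonzero(d < radius)
            order = np.lexsort((jj, ii, d[ii, jj]))
            brute = np.column_stack([ii[order], jj[order]])
            np.testing.assert_array_equal(pairs.astype(int), brute)

    def test_greedy_matching_consumes_each_molecule_once(self, run):
        # nearly immobile reactants: sigma_b ~ 4e-3 um exceeds both pair
        # separations, so both B are candidates but only one can react
        txt = """dim 3
bounds x 0 1 reflective
bounds y 0 1 reflective
bounds z 0 1 reflective
time_stop 0.001
time_step 0.001
species A B C
difc A 1e-4
difc B 1e-4
difc C 1e-4
mol 1 A 0.5 0.5 0.5
mol 1 B 0.502 0.5 0.5
mol 1 B 0.5 0.503 0.5
reaction bind A + B -> C 1e-5
"""
        sim = run(txt, seed=7)
        assert sim.event_counts.get("bind", 0) == 1
        assert sim.store.count_alive() == 2  # surviving B + product C
        counts = sm.cmd_molcount(sim)
        assert counts.tolist() == [0, 1, 1]


class TestPlaceProducts:
    def _params(self, sigma_u=0.0, bounce=0.0):
        p = rx.ReactionStepParams()
        p.unbinding_radius = sigma_u
        p.bounce_sep = bounce
        p.D_reactants = (1.0, 3.0)
        return p

    def test_conf_spread_keeps_reactant_positions(self, rng):
        rxn = rx.ReactionDef("cs", 2, [(0, 0), (1, 0)], [(2, 0), (1, 0)],
                             1.0, placement="conf_spread",
                             conf_spread_dist=0.1)
        posA = rng.uniform(size=(50, 3))
        posB = rng.uniform(size=(50, 3))
        out = rx.place_products(rxn, posA, posB, self._params(), rng, 3)
        np.testing.assert_array_equal(out[0], posA)
        np.testing.assert_array_equal(out[1], posB)

    def test_dissociation_separation_and_isotropy(self, rng):
        """Products separated by exactly sigma_u, directions uniform on the
        sphere (Rayleigh-style resultant test on the direction vectors)."""
        n = 100_000
        sigma_u = 0.005
        rxn = rx.ReactionDef("dis", 1, [(0, 0)], [(1, 0), (2, 0)], 1.0,
                             placement="unbinding_radius")
        center = np.zeros((n, 3))
        out = rx.place_products(rxn, center, None,
                                self._params(sigma_u=sigma_u), rng, 3)
        sep = np.linalg.norm(out[1] - out[0], axis=1)
        np.testing.assert_allclose(sep, sigma_u, rtol=1e-12)
        dirs = (out[1] - out[0]) / sigma_u
        resultant = np.linalg.norm(dirs.sum(axis=0))
        # under uniformity E|sum|^2 = n -> |sum| ~ sqrt(n) chi_3 scale
        assert resultant < 4.0 * math.sqrt(n / 3.0) * 1.8

    def test_bounce_separation_factor(self, rng):
        sigma_b = 0.01
        rxn = rx.ReactionDef("bounce", 2, [(0, 0), (1, 0)],
                             [(0, 0), (1, 0)], 1.0, placement="bounce",
                             bounce_factor=1.01)
        posA = np.array([[0.0, 0.0, 0.0]])
        posB = np.array([[0.004, 0.0, 0.0]])
        out = rx.place_products(rxn, posA, posB,
                                self._params(bounce=1.01 * sigma_b), rng, 3)
        sep = np.linalg.norm(out[1] - out[0], axis=1)
        np.testing.assert_allclose(sep, 1.01 * sigma_b, rtol=1e-12)
        # pushed apart along the connecting line
        np.testing.assert_allclose((out[1] - out[0])[0, 1:], 0.0, atol=1e-15)

    def test_default_bimolecular_placement_diffusion_weighted(self, rng):
        rxn = rx.ReactionDef("join", 2, [(0, 0), (1, 0)], [(2, 0)], 1.0)
        posA = np.array([[0.0, 0.0, 0.0]])
        posB = np.array([[1.0, 0.0, 0.0]])
        out = rx.place_products(rxn, posA, posB, self._params(), rng, 3)
        # r_C = (D_B r_A + D_A r_B)/(D_A + D_B): closer to the slower A
        np.testing.assert_allclose(out[0][0, 0], 0.25)


class TestConformationalSpread:
    def test_out_of_range_pair_never_converts(self, run):
        txt = """dim 3
bounds x 0 1 reflective
bounds y 0 1 reflective
bounds z 0 1 reflective
time_stop 0.05
time_step 0.001
species A Astar B
difc A 0
difc Astar 0
difc B 0
mol 1 A 0.2 0.5 0.5
mol 1 B 0.8 0.5 0.5
reaction spread A + B -> Astar + B 693.147
reaction_placement spread conf_spread 0.01
"""
        sim = run(txt, seed=1)
        assert sim.event_counts.get("spread", 0) == 0

    def test_geometric_conversion_law(self, run):
        """Fixed pairs inside r_c convert on step n ~ Geometric(1/2) when
        k dt = ln 2."""
        # 600 isolated pairs on a grid; conversion counted per step
        lines = ["dim 3", "bounds x 0 40 reflective",
                 "bounds y 0 40 reflective", "bounds z 0 40 reflective",
                 "time_stop 0.01", "time_step 0.001",
                 "species A Astar B", "difc A 0", "difc Astar 0", "difc B 0"]
        k = 0
        for i in range(10):
            for j in range(10):
                for l in range(6):
                    x, y, z = 2 + 4 * i, 2 + 4 * j, 2 + 6 * l
                    lines.append(f"mol 1 A {x} {y} {z}")
                    lines.append(f"mol 1 B {x + 0.005} {y} {z}")
                    k += 1
        lines.append("reaction spread A + B -> Astar + B 693.147")
        lines.append("reaction_placement spread conf_spread 0.01")
        lines.append("cmd every 0.001 0 0.01 molcount cs.txt")
        sim = run_config("\n".join(lines), seed=8)
        tab = sim.outputs["cs.txt"]
        remaining = tab.column("A")
        assert remaining[0] == 600
        # survival halves per step; fraction converted is non-decreasing
        expected = 600 * 0.5 ** np.arange(len(remaining))
        resid = remaining - expected
        sd = np.sqrt(np.maximum(expected * (1 - 0.5 ** np.arange(len(remaining))), 1e-9))
        assert np.all(np.abs(resid[1:4]) < 4 * sd[1:4] + 4)
        assert np.all(np.diff(remaining) <= 0)
        # B molecules survive untouched
        assert tab.column("B")[-1] == 600
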