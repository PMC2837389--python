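"""Molecule-surface transitions: adsorption, desorption, permeation,
state conversion, and unbounded-emitter absorption."""

import math

import numpy as np
import pytest
from scipy import stats

import smolsim as sm
from smolsim import geometry as geo
from smolsim import surfacechem as sc
from smolsim.model import SOLUTION, FRONT, BACK


class TestAdsorptionProbability:
    def test_zero_kappa_never_sticks(self):
        assert sc.adsorption_probability(0.0, 1.0, 1e-4) == 0.0

    def test_baseline_closed_form(self):
        # kappa sqrt(pi dt / D) in the small reduced-coefficient regime
        P = sc.adsorption_probability(0.01, 1.0, 1e-4)
        assert P == pytest.approx(0.01 * math.sqrt(math.pi * 1e-4), rel=1e-12)

    def test_calibrated_table_is_monotone_and_joins_baseline(self):
        ks, ps = sc._sticking_table()
        assert np.all(np.diff(ks) > 0)
        assert np.all(np.diff(ps) > 0)
        # small entries agree with the baseline mapping P = k' sqrt(2 pi)
        assert ps[0] == pytest.approx(ks[0] * math.sqrt(2 * math.pi),
                                      rel=0.02)
        # large entries need a stronger P than the baseline would say
        assert ps[-2] < ks[-2] * math.sqrt(2 * math.pi)

    def test_unreachable_flux_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="sticking"):
            P = sc.adsorption_probability(500.0, 1.0, 1e-2)
        assert P == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sc.adsorption_probability(-1.0, 1.0, 1e-4)
        with pytest.raises(ValueError):
            sc.adsorption_probability(1.0, 0.0, 1e-4)


class TestPermeability:
    def test_impermeable_and_transparent_limits(self):
        assert sc.permeability_probability(0.0, 1.0, 1e-4) == 0.0
        assert sc.permeability_probability(math.inf, 1.0, 1e-4) == 1.0

    def test_two_chamber_relaxation(self):
        """A permeable wall between two well-mixed chambers relaxes the
        count difference as exp(-kappa A (1/V1 + 1/V2) t).

        The compartmental ODE neglects the diffusion resistance 2 l/(3D) in
        series with the membrane, so the chambers are kept thin
        (kappa l / D ~ 0.03) to stay membrane-limited.
        """
        kappa, D, dt = 0.125, 1.0, 2e-4
        txt = f"""dim 3
bounds x 0 0.5 reflective
bounds y 0 1 reflective
bounds z 0 1 reflective
time_stop 1.5
time_step {dt}
species A
difc A {D}
mol 3000 A uniform compartment left
start_surface wall
  action A front transmit
  action A back transmit
  rate A permeable front {kappa}
  rate A permeable back {kappa}
  panel w rect +x 0.25 0 0 1 1
end_surface
start_compartment left
  surface wall
  point 0.125 0.5 0.5
end_compartment
cmd every 0.05 0 1.5 molcount_in_compartment left left.txt
"""
        sim = sm.init_sim(sm.parse_config(txt), seed=9)
        sim.run()
        tab = sim.outputs["left.txt"]
        t = tab.times
        n_left = tab.column("A")
        delta = 2 * n_left - 3000  # N_left - N_right
        rate = kappa * 1.0 * (1.0 / 0.25 + 1.0 / 0.25)  # V = 0.25 each
        sel = (delta > 300) & (t > 0)
        slope = np.polyfit(t[sel], np.log(delta[sel]), 1)[0]
        assert -slope == pytest.approx(rate, rel=0.05)


class TestDesorption:
    def test_zero_rate_no_desorption(self):
        sim = _bound_sim(n=200, k_d=0.0)
        sim.run()
        assert (sim.store.state[: sim.store.n][sim.store.alive[: sim.store.n]]
                == FRONT).all()

    def test_half_desorb_when_kdt_is_ln2(self):
        sim = _bound_sim(n=10000, k_d=math.log(2) / 1e-3, stop=1e-3)
        sim.run()
        st = sim.store
        still = int((st.state[: st.n][st.alive[: st.n]] == FRONT).sum())
        assert abs(still - 5000) < 3 * math.sqrt(10000 * 0.25)

    def test_irreversible_offsets_match_folded_gaussian_oracle(self, rng):
        """The reflected-substep walk must match the exact mixture of folded
        Gaussians |N(0, sqrt(2 D (dt - tau)))|, tau ~ U(0, dt)."""
        D, dt, n = 2.0, 1e-3, 40_000
        offsets, survived = sc.sample_desorption_offsets(
            n, D, dt, reversible=False, rng=rng)
        assert survived.all()
        orng = np.random.default_rng(77)
        tau = orng.uniform(0.0, dt, size=n)
        oracle = np.abs(orng.normal(0.0, np.sqrt(2 * D * (dt - tau))))
        d, p = stats.ks_2samp(offsets, oracle)
        assert d < 0.015
        assert (offsets >= 0).all()

    def test_reversible_offsets_match_conditioned_walk_oracle(self, rng):
        """Placement law for reversible desorption: the free walk conditioned
        on never touching the surface (checked against an independent
        cumulative-sum implementation of the same micro-process)."""
        D, dt, n = 2.0, 1e-3, 30_000
        offsets, survived = sc.sample_desorption_offsets(
            n, D, dt, reversible=True, rng=rng)
        assert survived.all()
        oracle = _conditioned_walk_oracle(n, D, dt,
                                          np.random.default_rng(78))
        d, p = stats.ks_2samp(offsets, oracle)
        assert d < 0.015
        # reversible offsets are stochastically larger than irreversible
        irrev, _ = sc.sample_desorption_offsets(n, D, dt, False, rng)
        assert offsets.mean() > irrev.mean()

    def test_desorbed_molecules_leave_on_the_correct_side(self):
        sim = _bound_sim(n=4000, k_d=2000.0, stop=2e-3, state="front")
        sim.run()
        st = sim.store
        sol = st.alive[: st.n] & (st.state[: st.n] == SOLUTION)
        assert sol.sum() > 100
        assert (st.pos[: st.n][sol][:, 2] > 0.5).all()  # front side is +z
        simb = _bound_sim(n=4000, k_d=2000.0, stop=2e-3, state="back")
        simb.run()
        st = simb.store
        sol = st.alive[: st.n] & (st.state[: st.n] == SOLUTION)
        assert sol.sum() > 100
        assert (st.pos[: st.n][sol][:, 2] < 0.5).all()


class TestStateConversion:
    def test_zero_rate_no_conversion(self):
        sim = _bound_sim(n=500, conv_rate=0.0)
        sim.run()
        st = sim.store
        assert (st.state[: st.n][st.alive[: st.n]] == FRONT).all()

    def test_half_convert_when_kdt_is_ln2(self):
        sim = _bound_sim(n=10000, conv_rate=math.log(2) / 1e-3, stop=1e-3)
        sim.run()
        st = sim.store
        back = int((st.state[: st.n][st.alive[: st.n]] == BACK).sum())
        assert abs(back - 5000) < 3 * math.sqrt(2500)

    def test_reversible_conversion_reaches_half_occupancy(self):
        sim = _bound_sim(n=4000, conv_rate=200.0, conv_back_rate=200.0,
                         stop=0.1)
        sim.run()
        st = sim.store
        alive = st.alive[: st.n]
        front = int((st.state[: st.n][alive] == FRONT).sum())
        assert abs(front - 2000) < 4 * math.sqrt(1000)
        # positions never move during conversion (D_bound = 0)
        assert (st.pos[: st.n][alive][:, 2] == 0.5).all()

    def test_conversion_to_solution_rejected_at_parse(self):
        txt = _BOUND_TEMPLATE.format(extra="  rate R convert front solution 5",
                                     n=10, stop=0.01)
        with pytest.raises(sm.ConfigError, match="desorption"):
            sm.parse_config(txt)


class TestEmitterAbsorption:
    def test_no_emitters_zero_probability(self):
        surf = geo.Surface("s", geo.icosphere([0, 0, 0], 1.0, 1))
        probs = sc.emitter_absorption(surf, "L", 1.0, 1e-4)
        assert (probs == 0.0).all()

    def test_central_emitter_gives_uniform_kappa_D_over_R(self):
        """For a central emitter in a sphere of radius R the matched Robin
        coefficient is D/R on every panel."""
        R, D, dt = 1.0, 1.0, 1e-4
        surf = geo.Surface("s", geo.icosphere([0, 0, 0], R, 1))
        surf.emitters["L"] = [geo.Emitter(np.zeros(3), 1000.0)]
        probs = sc.emitter_absorption(surf, "L", D, dt)
        expected = sc.adsorption_probability(D / R, D, dt)
        np.testing.assert_allclose(probs, expected, rtol=0.08)
        assert probs.std() / probs.mean() < 0.03

    def test_flux_balance_normalization(self):
        """Total kappa-weighted area flux equals total emission."""
        R, D, dt = 1.0, 1.0, 1e-4
        surf = geo.Surface("s", geo.icosphere([0, 0, 0], R, 1))
        surf.emitters["L"] = [geo.Emitter(np.array([0.3, 0.0, 0.0]), 700.0),
                              geo.Emitter(np.array([-0.2, 0.1, 0.0]), 300.0)]
        panels = surf.panels
        centers = np.array([p.verts.mean(axis=0) for p in panels])
        areas = np.array([p.area() for p in panels])
        conc = np.zeros(len(panels))
        flux = np.zeros(len(panels))
        for e in surf.emitters["L"]:
            dvec = centers - e.pos
            dist = np.linalg.norm(dvec, axis=1)
            conc += e.rate / (4 * math.pi * D * dist)
            n = np.array([p.normal_at(c[None])[0]
                          for p, c in zip(panels, centers)])
            flux += e.rate * np.einsum("ij,ij->i", dvec, n) \
                / (4 * math.pi * dist**3)
        # reproduce the kappa construction and check the balance identity
        beta = 1000.0 / float(areas @ flux)
        kappa = beta * D * flux / conc
        assert float(areas @ (kappa * conc)) == pytest.approx(1000.0,
                                                              rel=1e-9)

    def test_emitter_outside_surface_rejected(self):
        surf = geo.Surface("s", geo.icosphere([0, 0, 0], 1.0, 1))
        surf.emitters["L"] = [geo.Emitter(np.array([2.0, 0.0, 0.0]), 10.0)]
        with pytest.raises(ValueError):
            sc.emitter_absorption(surf, "L", 1.0, 1e-4)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_BOUND_TEMPLATE = """dim 3
bounds x 0 1 reflective
bounds y 0 1 reflective
bounds z 0 1 reflective
time_stop {stop}
time_step 0.001
species R
difc R 1
difc R front 0
difc R back 0
start_surface memb
  action R front reflect
  action R back reflect
{extra}
  panel p rect +z 0 0 0.5 1 1
end_surface
surface_mol {n} R front memb
"""


def _bound_sim(n=100, k_d=None, conv_rate=None, conv_back_rate=None,
               stop=0.01, state="front"):
    extra = []
    if k_d is not None:
        extra.append(f"  rate R desorb {state} {k_d}")
    if conv_rate is not None:
        extra.append(f"  rate R convert front back {conv_rate}")
    if conv_back_rate is not None:
        extra.append(f"  rate R convert back front {conv_back_rate}")
    txt = _BOUND_TEMPLATE.format(extra="\n".join(extra), n=n, stop=stop)
    if state == "back":
        txt = txt.replace(f"surface_mol {n} R front memb",
                          f"surface_mol {n} R back memb")
    return sm.init_sim(sm.parse_config(txt), seed=13)


def _conditioned_walk_oracle(n, D, dt, rng, n_sub=100):
    """Independent brute-force oracle for reversible desorption: build whole
    substep paths by cumulative summation and keep only those that never go
    negative."""
    out = []
    while len(out) < n:
        m = 40_000
        tau = rng.uniform(0.0, dt, size=m)
        h = (dt - tau) / n_sub
        steps = rng.standard_normal((m, n_sub)) \
            * np.sqrt(2.0 * D * h)[:, None]
        paths = np.cumsum(steps, axis=1)
        ok = (paths >= 0.0).all(axis=1)
        out.extend(paths[ok, -1].tolist())
    return np.array(out[:n])


class TestDesorptionStepOperation:
    def test_partition_into_remaining_and_desorbed(self):
        sim = _bound_sim(n=5000, stop=0.01)
        bound = sim.store.select(0, FRONT)
        rng = np.random.default_rng(5)
        remaining, desorbed = sc.desorption_step(sim, bound,
                                                 math.log(2) / sim.dt, rng)
        assert len(remaining) + len(desorbed) == 5000
        assert abs(len(desorbed) - 2500) < 3 * math.sqrt(5000 * 0.25)
        assert (sim.store.state[desorbed] == SOLUTION).all()
        assert (sim.store.state[remaining] == FRONT).all()
        assert (sim.store.pos[desorbed][:, 2] >= 0.5).all()

    def test_zero_rate_is_identity(self):
        sim = _bound_sim(n=50, stop=0.01)
        bound = sim.store.select(0, FRONT)
        remaining, desorbed = sc.desorption_step(
            sim, bound, 0.0, np.random.default_rng(1))
        assert len(desorbed) == 0
        assert len(remaining) == 50
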