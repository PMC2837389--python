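"""Config parsing, output tables, commands, fixtures, chi-squared harness,
and the command-line interface."""

import numpy as np
import pytest
from click.testing import CliRunner
from scipy import stats

import smolsim as sm
from smolsim.cli import main as cli_main
from smolsim.validate import chi2_report

MINIMAL = """dim 3
bounds x 0 1 reflective
bounds y 0 1 reflective
bounds z 0 1 reflective
time_stop 0.1
time_step 0.001
species A
difc A 1
"""


class TestParseConfig:
    def test_minimal_file_fills_defaults(self):
        m = sm.parse_config(MINIMAL)
        assert m.dim == 3 and m.dt == 1e-3 and m.t_start == 0.0
        assert m.species == ["A"]
        assert m.btypes == ["reflective"] * 3

    def test_undeclared_species_reported_with_line(self):
        bad = MINIMAL + "reaction r1 A + B -> A 1\n"
        with pytest.raises(sm.ConfigError) as exc:
            sm.parse_config(bad)
        msg = str(exc.value)
        assert "B" in msg and "line 9" in msg

    def test_unknown_statement_is_an_error(self):
        with pytest.raises(sm.ConfigError, match="unknown statement"):
            sm.parse_config(MINIMAL + "frobnicate 3\n")

    @pytest.mark.parametrize("missing,needle", [
        ("dim 3", "dim"),
        ("time_step 0.001", "time_step"),
        ("bounds y 0 1 reflective", "bounds for axis y"),
    ])
    def test_missing_required_statements(self, missing, needle):
        txt = MINIMAL.replace(missing + "\n", "")
        with pytest.raises(sm.ConfigError, match=needle):
            sm.parse_config(txt)

    def test_negative_rate_and_bad_geometry_rejected(self):
        with pytest.raises(sm.ConfigError, match="rate"):
            sm.parse_config(MINIMAL + "reaction r1 A -> 0 -5\n")
        bad_panel = (MINIMAL
                     + "start_surface s\n  panel p sphere 0 0 0 -1\nend_surface\n")
        with pytest.raises(sm.ConfigError, match="panel"):
            sm.parse_config(bad_panel)

    def test_molar_rate_conversion(self):
        txt = MINIMAL.replace("species A", "species A B C") \
            + "difc B 1\ndifc C 1\nreaction_molar r1 A + B -> C 1e6\n"
        m = sm.parse_config(txt)
        assert m.reactions[0].rate == pytest.approx(1e6 * sm.MOLAR_TO_UM3)

    def test_benchmark_fixture_reaction_structure(self):
        m = sm.parse_config(sm.generate_fixture("mm_benchmark"))
        by_name = {r.name: r for r in m.reactions}
        assert by_name["bind"].order == 2
        assert by_name["unbind"].order == 1
        assert len(by_name["unbind"].products) == 2
        assert by_name["cat"].order == 1
        # ES -> E + S and ES -> E + P are competing channels of one species
        assert by_name["unbind"].reactants == by_name["cat"].reactants


class TestEmitRoundTrip:
    def test_round_trip_is_stable(self):
        txt = sm.generate_fixture("adsorption_plane")
        m1 = sm.parse_config(txt)
        emitted = sm.emit_config(m1)
        m2 = sm.parse_config(emitted)
        assert sm.emit_config(m2) == emitted

    def test_round_trip_covers_surfaces_reactions_commands(self):
        txt = MINIMAL.replace("species A", "species A B C") + """difc B 2
difc C 0.5
difc C front 0.05
drift A 1 0 0
start_surface memb
  action all front reflect
  action A front adsorb
  rate A adsorb front 0.4
  rate C desorb front 2 reversible
  rate C convert front back 1.5
  panel p0 rect +z 0 0 0.5 1 1
  panel p1 sphere 0.5 0.5 0.25 0.1
end_surface
start_compartment ball
  surface memb
  point 0.5 0.5 0.25
end_compartment
reaction r1 A + B -> C 0.01
reaction_placement r1 bounce 1.05
reaction r2 C -> A + B 3
reaction_placement r2 unbinding 0.004
reaction_region r1 compartment ball
mol 10 A uniform
surface_mol 5 C front memb
cmd every 0.01 0 0.1 molcount out.txt
cmd end listmols mols.txt
"""
        emitted = sm.emit_config(sm.parse_config(txt))
        assert sm.emit_config(sm.parse_config(emitted)) == emitted


class TestOutputsAndCommands:
    def test_molcount_empty_system_is_zero(self):
        sim = sm.init_sim(sm.parse_config(MINIMAL), seed=1)
        assert sm.cmd_molcount(sim).tolist() == [0]

    def test_molcount_static_population(self):
        txt = MINIMAL.replace("difc A 1", "difc A 0") + \
            "mol 100 A uniform\ncmd every 0.01 0 0.1 molcount out.txt\n"
        sim = sm.init_sim(sm.parse_config(txt), seed=1)
        sim.run()
        tab = sim.outputs["out.txt"]
        assert all(v == 100 for v in tab.column("A"))

    def test_output_strictly_time_ordered_no_duplicates(self):
        txt = MINIMAL + "mol 5 A uniform\ncmd every 0.01 0 0.1 molcount o.txt\n"
        sim = sm.init_sim(sm.parse_config(txt), seed=1)
        sim.run()
        t = sim.outputs["o.txt"].times
        assert (np.diff(t) > 0).all()
        assert len(t) == 11

    def test_table_text_format(self):
        txt = MINIMAL + "mol 3 A uniform\ncmd at 0.05 molcount o.txt\n"
        sim = sm.init_sim(sm.parse_config(txt), seed=1)
        sim.run()
        text = sim.outputs["o.txt"].to_text()
        lines = text.splitlines()
        assert lines[0] == "time\tA"
        assert lines[1].split("\t") == ["0.05", "3"]

    def test_add_and_kill_commands(self):
        txt = MINIMAL.replace("difc A 1", "difc A 0") + """mol 10 A uniform
start_surface ball
  panel s sphere 0.5 0.5 0.5 10
end_surface
start_compartment everywhere
  surface ball
  point 0.5 0.5 0.5
end_compartment
cmd at 0.02 add_molecules 25 A uniform
cmd at 0.05 kill_molecules_in_region A everywhere
cmd every 0.01 0 0.1 molcount o.txt
"""
        sim = sm.init_sim(sm.parse_config(txt), seed=1)
        sim.run()
        counts = sim.outputs["o.txt"].column("A")
        assert counts[0] == 10
        assert counts[3] == 35  # after the addition
        assert counts[-1] == 0  # after the purge

    def test_set_surface_action_switches_behavior(self):
        txt = """dim 3
bounds x 0 1 reflective
bounds y 0 1 reflective
bounds z 0 2 reflective
time_stop 0.4
time_step 0.001
species A
difc A 2
mol 200 A uniform compartment top
start_surface wall
  action A front reflect
  action A back reflect
  panel w rect +z 0 0 1 1 1
end_surface
start_compartment top
  surface wall
  point 0.5 0.5 1.5
end_compartment
cmd at 0.2 set_surface_action wall A both transmit
cmd every 0.05 0 0.4 molcount_in_compartment top o.txt
"""
        sim = sm.init_sim(sm.parse_config(txt), seed=2)
        sim.run()
        counts = sim.outputs["o.txt"].column("A")
        assert (counts[:4] == 200).all()  # sealed while reflective
        assert counts[-1] < 160  # leaks after the switch


class TestFixtures:
    @pytest.mark.parametrize("name,params", [
        ("mm_benchmark", {"n_total": 100, "stop": 0.01}),
        ("free_diffusion", {"n": 20, "stop": 0.01}),
        ("first_order_decay", {"n": 20, "stop": 0.01}),
        ("bimolecular_ab", {"nA": 20, "nB": 20, "stop": 0.01}),
        ("adsorption_plane", {"n": 20, "stop": 0.001}),
        ("crowders", {"n_spheres": 10, "n_tracer": 5, "stop": 0.0005}),
        ("icosphere_cell", {"n": 20, "stop": 0.01}),
    ])
    def test_all_fixtures_parse_validate_and_run(self, name, params):
        rng = np.random.default_rng(3)
        txt = sm.generate_fixture(name, params, rng=rng)
        sim = sm.init_sim(sm.parse_config(txt), seed=5)
        sim.run()  # completes without error

    def test_crowders_zero_spheres(self):
        txt = sm.generate_fixture("crowders", {"n_spheres": 0, "n_tracer": 0})
        m = sm.parse_config(txt)
        assert m.surfaces[0].panels == []

    def test_crowders_non_overlapping(self):
        rng = np.random.default_rng(0)
        txt = sm.generate_fixture("crowders",
                                  {"n_spheres": 100, "radius": 0.05},
                                  rng=rng)
        m = sm.parse_config(txt)
        centers = np.array([p.center for p in m.surfaces[0].panels])
        assert len(centers) == 100
        d = centers[:, None, :] - centers[None, :, :]
        d -= 1.0 * np.round(d)  # periodic minimum image in the unit box
        dist = np.linalg.norm(d, axis=2)
        np.fill_diagonal(dist, 1.0)
        assert dist.min() >= 0.1 - 1e-12

    def test_infeasible_packing_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(RuntimeError, match="packing"):
            sm.generate_fixture("crowders",
                                {"n_spheres": 200, "radius": 0.2,
                                 "max_tries": 500}, rng=rng)

    def test_unknown_fixture_name(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            sm.generate_fixture("not_a_fixture")


class TestChiSquareReport:
    def test_perfect_agreement_gives_p_one(self):
        rep = chi2_report([10, 20, 30], [10, 20, 30], [10, 20, 30])
        assert rep.statistic == 0.0
        assert rep.pvalue == 1.0
        assert rep.dof == 3

    def test_low_expectation_bins_are_merged(self):
        rep = chi2_report([1, 2, 4, 30], [1, 2, 4, 30], [1, 2, 4, 30])
        assert rep.dof == 2  # 1+2+4 accumulate into one bin of 7
        assert rep.n_merged == 2
        assert "merged" in rep.text

    def test_calibration_p_values_uniform(self):
        """Conditionally-binomial decay increments give exact chi-squared
        behavior: over replicates, p-values are uniform."""
        rng = np.random.default_rng(99)
        k, dt = 5.0, 0.02
        surv = np.exp(-k * dt)
        pvals = []
        for _ in range(100):
            N = 1000
            obs, exp, var = [], [], []
            for _ in range(20):
                nxt = rng.binomial(N, surv)
                obs.append(nxt)
                exp.append(N * surv)
                var.append(N * surv * (1 - surv))
                N = nxt
            pvals.append(chi2_report(obs, exp, var).pvalue)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.005

    def test_power_against_wrong_theory(self):
        """A 20% error in the decay rate is decisively rejected at n=1e4."""
        rng = np.random.default_rng(7)
        k, dt = 5.0, 0.02
        surv = np.exp(-k * dt)
        wrong = np.exp(-1.2 * k * dt)
        N = 10_000
        obs, exp, var = [], [], []
        for _ in range(20):
            nxt = rng.binomial(N, surv)
            obs.append(nxt)
            exp.append(N * wrong)
            var.append(N * wrong * (1 - wrong))
            N = nxt
        assert chi2_report(obs, exp, var).pvalue < 1e-3

    def test_input_validation(self):
        with pytest.raises(ValueError):
            chi2_report([1, 2], [1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            chi2_report([1], [1.0], [-1.0])


class TestCLI:
    def test_validate_good_file(self, tmp_path):
        path = tmp_path / "ok.txt"
        path.write_text(MINIMAL)
        res = CliRunner().invoke(cli_main, ["validate", str(path)])
        assert res.exit_code == 0
        assert "OK" in res.output

    def test_validate_bad_file_reports_lines(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(MINIMAL + "difc Z 1\n")
        res = CliRunner().invoke(cli_main, ["validate", str(path)])
        assert res.exit_code == 2
        assert "line 9" in res.output

    def test_calibrate_prints_reference_binding_radius(self):
        res = CliRunner().invoke(cli_main, [
            "calibrate", "--rate", "1e6", "--difc", "10", "--difc2", "10",
            "--dt", "1e-4", "--molar"])
        assert res.exit_code == 0
        assert "3.41 nm" in res.output

    def test_run_outputs_are_byte_identical_for_fixed_seed(self, tmp_path):
        cfg = tmp_path / "d.txt"
        cfg.write_text(sm.generate_fixture("first_order_decay",
                                           {"n": 200, "stop": 0.1}))
        out1, out2 = tmp_path / "o1", tmp_path / "o2"
        r1 = CliRunner().invoke(cli_main, ["run", str(cfg), "--seed", "7",
                                           "--out-dir", str(out1)])
        r2 = CliRunner().invoke(cli_main, ["run", str(cfg), "--seed", "7",
                                           "--out-dir", str(out2)])
        assert r1.exit_code == 0 and r2.exit_code == 0
        b1 = (out1 / "decay.txt").read_bytes()
        b2 = (out2 / "decay.txt").read_bytes()
        assert b1 == b2
        r3 = CliRunner().invoke(cli_main, ["run", str(cfg), "--seed", "8",
                                           "--out-dir", str(out2)])
        assert (out2 / "decay.txt").read_bytes() != b1

    def test_fixture_subcommand_emits_parseable_config(self, tmp_path):
        out = tmp_path / "f.txt"
        res = CliRunner().invoke(cli_main, [
            "fixture", "mm_benchmark", "--out", str(out),
            "--param", "n_total=500"])
        assert res.exit_code == 0
        m = sm.parse_config(out.read_text())
        counts = [p[1] for p in m.placements]
        assert sum(counts) == 500
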