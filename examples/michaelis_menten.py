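"""Michaelis-Menten kinetics: particle simulation vs mass-action ODE.

Runs a reduced version of the standard benchmark (E + S <-> ES -> E + P,
10% enzyme / 90% substrate, 1 ms steps) and prints the substrate and
product counts next to the deterministic mass-action solution.  At these
copy numbers the stochastic trajectory should track the ODE to within
about a percent.
"""

import smolsim as sm
from smolsim.validate import michaelis_menten_ode

N_TOTAL, STOP = 2000, 2.0

text = sm.generate_fixture("mm_benchmark",
                           {"n_total": N_TOTAL, "stop": STOP})
sim = sm.init_sim(sm.parse_config(text), seed=7)
sim.run()

tab = sim.outputs["mm.txt"]
t = tab.times
ode = michaelis_menten_ode(N_TOTAL // 10, 9 * N_TOTAL // 10, 100.0,
                           0.01, 1.0, 1.0, t)

print(f"binding radius used: "
      f"{sim.step_params['bind'].binding_radius * 1e3:.2f} nm")
print(f"{'t (s)':>6} {'S sim':>7} {'S ode':>8} {'P sim':>7} {'P ode':>8}")
for i in range(0, len(t), len(t) // 8):
    print(f"{t[i]:6.2f} {tab.column('S')[i]:7.0f} {ode[i, 1]:8.1f} "
          f"{tab.column('P')[i]:7.0f} {ode[i, 3]:8.1f}")
print()
print("Columns 'sim' are molecule counts from the particle simulation;")
print("'ode' is the mass-action prediction with the same rate constants.")
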