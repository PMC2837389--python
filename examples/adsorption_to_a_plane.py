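"""Adsorption of a uniform population to a sticky plane.

Molecules diffuse in a tall column above a surface with adsorption
coefficient kappa (the Robin boundary-condition parameter, um/s).  The
per-collision sticking probability is calibrated so the adsorbed flux
equals kappa times the surface-adjacent concentration; the adsorbed count
over time should therefore follow the closed-form solution of the
diffusion equation with a radiation boundary.
"""

import smolsim as sm
from smolsim.model import SOLUTION
from smolsim.surfacechem import adsorption_probability, \
    robin_adsorbed_per_area

N, LZ, D, KAPPA, STOP = 10000, 20.0, 1.0, 5.0, 0.4

text = sm.generate_fixture("adsorption_plane",
                           {"n": N, "kappa": KAPPA, "D": D, "stop": STOP})
sim = sm.init_sim(sm.parse_config(text), seed=3)

P = adsorption_probability(KAPPA, D, sim.dt)
print(f"kappa = {KAPPA} um/s, dt = {sim.dt} s -> sticking probability "
      f"P = {P:.4g}")
print(f"{'t (s)':>6} {'adsorbed':>9} {'theory':>8}")
for frac in (0.25, 0.5, 0.75, 1.0):
    sim.run(t_stop=STOP * frac)
    st = sim.store
    bound = int((st.alive[: st.n] & (st.state[: st.n] != SOLUTION)).sum())
    theory = N * float(robin_adsorbed_per_area(STOP * frac, KAPPA, D)) / LZ
    print(f"{STOP * frac:6.2f} {bound:9d} {theory:8.1f}")
print()
print("'adsorbed' counts surface-bound molecules in the simulation;")
print("'theory' is N * Gamma(t) / (C0 Lz) from the Robin closed form.")
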