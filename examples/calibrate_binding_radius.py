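"""Calibrate a bimolecular binding radius from a macroscopic rate constant.

A fixed-time-step Brownian simulation fires a reaction A + B -> C whenever
the pair ends a step closer than the binding radius sigma_b.  This script
inverts the steady-state rate map for the classic reference point -- two
reactants with D = 10 um^2/s each, k = 1e6 M^-1 s^-1, dt = 0.1 ms -- and
shows the two analytic limits that bracket the answer.
"""

import math

from smolsim import reactions as rx

D_A = D_B = 10.0          # um^2/s
k_molar = 1.0e6           # M^-1 s^-1
dt = 1.0e-4               # s

k = k_molar * rx.MOLAR_TO_UM3          # -> um^3/s
D_mut = D_A + D_B
s = math.sqrt(2.0 * D_mut * dt)        # rms per-axis relative step

sigma = rx.binding_radius_from_rate(k, D_mut, dt)
k_back = rx.rate_from_binding_radius(sigma, s, dt)

print(f"rate constant          k       = {k_molar:.3g} M^-1 s^-1 "
      f"({k:.4g} um^3/s)")
print(f"rms relative step      s       = {s * 1e3:.1f} nm")
print(f"calibrated             sigma_b = {sigma * 1e3:.3f} nm")
print(f"well-mixed closed form         = "
      f"{(3 * k * dt / (4 * math.pi)) ** (1 / 3) * 1e3:.3f} nm")
print(f"diffusion-limited form         = {k / (4 * math.pi * D_mut) * 1e3:.4f} nm")
print(f"round trip             k(sigma_b) = {k_back / rx.MOLAR_TO_UM3:.4g} "
      f"M^-1 s^-1")
print()
print("The step length (63 nm) dwarfs the binding radius (3.4 nm), so the")
print("well-mixed limit (3 k dt / 4 pi)^(1/3) nearly coincides with the")
print("full steady-state solution; at much smaller dt the answer would")
print("approach the diffusion-limited k / (4 pi D) instead.")
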