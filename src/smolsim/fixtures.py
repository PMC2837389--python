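"""Ready-made model configurations for validation and benchmarking.

Each fixture is a complete config text that parses, validates, and runs at
desk scale.  The ``mm_benchmark`` fixture is the classic particle-simulator
benchmark: 10,000 molecules (10% enzyme, 90% substrate initially) reacting
through E + S <-> ES -> E + P for 10 s of simulated time in 1 ms time steps.
The remaining fixtures are the validation models: free diffusion (mean
square displacement vs 2 dim D t), first-order decay (exp(-kt)), irreversible
bimolecular annihilation, adsorption to a plane (Robin boundary), fields of
non-overlapping crowding spheres, and a triangulated spherical cell.

Numeric parameters are the package's documented defaults (docs/methods.md);
override them through the ``params`` dict.
"""

from __future__ import annotations

import numpy as np

FIXTURE_NAMES = ("mm_benchmark", "free_diffusion", "first_order_decay",
                 "bimolecular_ab", "adsorption_plane", "crowders",
                 "icosphere_cell")

#: benchmark box volume (um^3); side = 100^(1/3) um
_MM_SIDE = 100.0 ** (1.0 / 3.0)

_MM_DEFAULTS = dict(n_total=10000, enzyme_frac=0.1, dt=1e-3, stop=10.0,
                    side=_MM_SIDE, D_E=10.0, D_S=10.0, D_ES=5.0, D_P=10.0,
                    k1=0.01, k2=1.0, k3=1.0, out_every=0.05)


def generate_fixture(name: str, params: dict | None = None, rng=None) -> str:
    """Emit the named fixture as config text.

    ``rng`` is only used by the dart-throwing ``crowders`` fixture; pass a
    seeded ``numpy.random.Generator`` for reproducible sphere fields.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture '{name}'; choose from "
                         f"{FIXTURE_NAMES}")
    p = dict(params or {})
    return globals()["_fx_" + name](p, rng)


def _fx_mm_benchmark(p, rng):
    d = {**_MM_DEFAULTS, **p}
    nE = int(round(d["n_total"] * d["enzyme_frac"]))
    nS = d["n_total"] - nE
    L = d["side"]
    return f"""# Michaelis-Menten benchmark: E + S <-> ES -> E + P
dim 3
bounds x 0 {L:.9g} reflective
bounds y 0 {L:.9g} reflective
bounds z 0 {L:.9g} reflective
time_start 0
time_stop {d['stop']:.9g}
time_step {d['dt']:.9g}
species E S ES P
difc E {d['D_E']:.9g}
difc S {d['D_S']:.9g}
difc ES {d['D_ES']:.9g}
difc P {d['D_P']:.9g}
mol {nE} E uniform
mol {nS} S uniform
reaction bind E + S -> ES {d['k1']:.9g}
reaction unbind ES -> E + S {d['k2']:.9g}
reaction cat ES -> E + P {d['k3']:.9g}
cmd every {d['out_every']:.9g} 0 {d['stop']:.9g} molcount mm.txt
"""


def _fx_free_diffusion(p, rng):
    d = dict(n=2000, D=(1.0, 3.0, 10.0), L=20.0, dt=1e-3, stop=0.1)
    d.update(p)
    names = [f"A{i}" for i in range(len(d["D"]))]
    lines = [
        "# free diffusion: MSD(t) = 2 dim D t per population",
        "dim 3",
        f"bounds x 0 {d['L']:.9g} periodic",
        f"bounds y 0 {d['L']:.9g} periodic",
        f"bounds z 0 {d['L']:.9g} periodic",
        "time_start 0",
        f"time_stop {d['stop']:.9g}",
        f"time_step {d['dt']:.9g}",
        "species " + " ".join(names),
    ]
    for n, D in zip(names, d["D"]):
        lines.append(f"difc {n} {D:.9g}")
    for n in names:
        lines.append(f"mol {d['n']} {n} uniform")
    for n in names:
        lines.append(f"cmd every {d['dt']*10:.9g} 0 {d['stop']:.9g} "
                     f"meansqrdisp {n} msd_{n}.txt")
    return "\n".join(lines) + "\n"


def _fx_first_order_decay(p, rng):
    d = dict(n=5000, k=(2.0, 10.0, 50.0), L=10.0, dt=1e-3, stop=2.0)
    d.update(p)
    names = [f"A{i}" for i in range(len(d["k"]))]
    lines = [
        "# first-order decay: N(t) = N0 exp(-k t)",
        "dim 3",
        f"bounds x 0 {d['L']:.9g} reflective",
        f"bounds y 0 {d['L']:.9g} reflective",
        f"bounds z 0 {d['L']:.9g} reflective",
        "time_start 0",
        f"time_stop {d['stop']:.9g}",
        f"time_step {d['dt']:.9g}",
        "species " + " ".join(names),
    ]
    for n in names:
        lines.append(f"difc {n} 1")
        lines.append(f"mol {d['n']} {n} uniform")
    for n, k in zip(names, d["k"]):
        lines.append(f"reaction decay_{n} {n} -> 0 {k:.9g}")
    lines.append(f"cmd every {d['dt']*10:.9g} 0 {d['stop']:.9g} molcount "
                 "decay.txt")
    return "\n".join(lines) + "\n"


def _fx_bimolecular_ab(p, rng):
    d = dict(nA=5000, nB=5000, L=100.0 ** (1.0 / 3.0), D=5.0, k=0.005,
             dt=1e-3, stop=4.0, out_every=0.05)
    d.update(p)
    return f"""# irreversible bimolecular annihilation A + B -> 0
dim 3
bounds x 0 {d['L']:.9g} reflective
bounds y 0 {d['L']:.9g} reflective
bounds z 0 {d['L']:.9g} reflective
time_start 0
time_stop {d['stop']:.9g}
time_step {d['dt']:.9g}
species A B
difc A {d['D']:.9g}
difc B {d['D']:.9g}
mol {d['nA']} A uniform
mol {d['nB']} B uniform
reaction annihilate A + B -> 0 {d['k']:.9g}
cmd every {d['out_every']:.9g} 0 {d['stop']:.9g} molcount ab.txt
"""


def _fx_adsorption_plane(p, rng):
    d = dict(n=5000, kappa=5.0, D=1.0, Lz=20.0, dt=2e-4, stop=0.5,
             out_every=0.01)
    d.update(p)
    return f"""# adsorption of a uniform population to a sticky plane at z=0
dim 3
bounds x 0 1 periodic
bounds y 0 1 periodic
bounds z 0 {d['Lz']:.9g} reflective
time_start 0
time_stop {d['stop']:.9g}
time_step {d['dt']:.9g}
species A
difc A {d['D']:.9g}
mol {d['n']} A uniform
start_surface wall
  action A front adsorb
  rate A adsorb front {d['kappa']:.9g}
  panel w0 rect +z 0 0 0 1 1
end_surface
cmd every {d['out_every']:.9g} 0 {d['stop']:.9g} molcount ads.txt
"""


def _fx_crowders(p, rng):
    d = dict(n_spheres=100, radius=0.05, L=1.0, dt=1e-4, stop=0.01,
             n_tracer=100, D=1.0, max_tries=20000)
    d.update(p)
    if rng is None:
        rng = np.random.default_rng(0)
    centers = _dart_throw(int(d["n_spheres"]), d["radius"], d["L"], rng,
                          d["max_tries"])
    lines = [
        "# field of random non-overlapping crowding spheres with a tracer",
        "dim 3",
        f"bounds x 0 {d['L']:.9g} periodic",
        f"bounds y 0 {d['L']:.9g} periodic",
        f"bounds z 0 {d['L']:.9g} periodic",
        "time_start 0",
        f"time_stop {d['stop']:.9g}",
        f"time_step {d['dt']:.9g}",
        "species T",
        f"difc T {d['D']:.9g}",
        "start_surface crowders",
        "  action T front reflect",
    ]
    for i, c in enumerate(centers):
        lines.append(f"  panel c{i} sphere {c[0]:.9g} {c[1]:.9g} "
                     f"{c[2]:.9g} {d['radius']:.9g}")
    lines.append("end_surface")
    if d["n_tracer"]:
        lines.append(f"mol {d['n_tracer']} T uniform")
        lines.append(f"cmd every {d['dt']*10:.9g} 0 {d['stop']:.9g} "
                     "meansqrdisp T msd.txt")
    return "\n".join(lines) + "\n"


def _dart_throw(n, radius, L, rng, max_tries):
    """Random non-overlapping sphere centers (periodic minimum image)."""
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} spheres of radius {radius} in a box of "
                f"side {L} after {max_tries} attempts (packing infeasible)")
        c = rng.uniform(0.0, L, size=3)
        ok = True
        for other in centers:
            delta = c - other
            delta -= L * np.round(delta / L)
            if float(delta @ delta) < (2.0 * radius) ** 2:
                ok = False
                break
        if ok:
            centers.append(c)
    return centers


def _fx_icosphere_cell(p, rng):
    from .geometry import icosphere

    d = dict(radius=1.0, center=(1.5, 1.5, 1.5), L=3.0, subdivisions=1,
             n=1000, D=1.0, dt=1e-3, stop=1.0)
    d.update(p)
    lines = [
        "# molecules confined in a reflective triangulated sphere",
        "dim 3",
        f"bounds x 0 {d['L']:.9g} reflective",
        f"bounds y 0 {d['L']:.9g} reflective",
        f"bounds z 0 {d['L']:.9g} reflective",
        "time_start 0",
        f"time_stop {d['stop']:.9g}",
        f"time_step {d['dt']:.9g}",
        "species A",
        f"difc A {d['D']:.9g}",
        "start_surface cell",
        "  action A front reflect",
        "  action A back reflect",
    ]
    panels = icosphere(d["center"], d["radius"], d["subdivisions"])
    for i, tri in enumerate(panels):
        v = " ".join(f"{x:.9g}" for x in tri.verts.ravel())
        lines.append(f"  panel t{i} tri {v}")
    lines += [
        "end_surface",
        "start_compartment inside",
        "  surface cell",
        "  point " + " ".join(f"{x:.9g}" for x in d["center"]),
        "end_compartment",
        f"mol {d['n']} A uniform compartment inside",
        f"cmd every {d['stop']/10:.9g} 0 {d['stop']:.9g} "
        "molcount_in_compartment inside inside.txt",
    ]
    return "\n".join(lines) + "\n"
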