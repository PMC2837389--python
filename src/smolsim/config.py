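"""Model configuration files.

The dialect is line-oriented: one statement per line, ``#`` starts a comment,
identifiers are case-sensitive, and every physical quantity uses the package
units (um, s, um^2/s; second-order rates in um^3/s, or M^-1 s^-1 via the
``reaction_molar`` statement).  Unknown statements are errors, not warnings.

Statement summary (details in the README)::

    dim 3
    bounds x 0 10 reflective            # axis lo hi type
    time_start 0
    time_stop 10
    time_step 0.001
    random_seed 7
    species E S ES P
    difc E 10                           # solution diffusion coefficient
    difc R front 0.05                   # explicit molecule state
    drift E 0 0 1
    difm E 1 0 0 0 4 0 0 0 0            # anisotropic tensor, row-major
    mol 100 E uniform                   # uniform in the volume
    mol 100 E uniform compartment nuc
    mol 10 E 0.5 0.5 0.5                # fixed point
    surface_mol 50 R front memb         # random on the surface's panels
    start_surface memb
      action all front reflect
      action E front adsorb
      rate E adsorb front 0.01          # kappa, um/s
      rate R desorb front 5 reversible  # k_d, 1/s
      rate E permeable front 0.5        # kappa_perm, um/s
      rate R convert front back 2       # bound-state conversion, 1/s
      panel p0 rect +z 0 0 0 1 1
      panel p1 tri 0 0 0 1 0 0 0 1 0
      panel p2 sphere 0.5 0.5 0.5 0.3
      panel p3 cyl 0 0 0 0 0 1 0.2
      panel p4 hemi 0.5 0.5 0.5 0.3 0 0 1
      panel p5 disk 0.5 0.5 0.5 0.3 0 0 1
      panel_mesh cell.tri               # plain triangle list, 9 floats/line
      jump p0 p1                        # panel pair for the jump action
      emitter L 30000 0.5 0.5 0.5       # species rate x y z
      disabled                          # starts disabled; enable by command
    end_surface
    start_compartment nuc
      surface memb
      point 0.5 0.5 0.5
    end_compartment
    reaction r1 E + S -> ES 0.003
    reaction_molar r1m E + S -> ES 1.8e6
    reaction r2 ES -> E + P 10
    reaction gen 0 -> S 5               # zeroth order, molecules/(um^3 s)
    reaction_placement r1 pgemmax 0.2
    reaction_placement r2 unbinding 0.005
    reaction_placement r3 bounce 1.01
    reaction_placement r4 conf_spread 0.01
    reaction_region r1 compartment nuc
    cmd every 0.1 0 10 molcount out.txt
    cmd at 5 add_molecules 100 E uniform
    cmd end listmols mols.txt
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from . import reactions as rx

AXES = {"x": 0, "y": 1, "z": 2}
BOUND_TYPES = ("reflective", "absorbing", "periodic", "transparent")
STATE_NAMES = ("solution", "front", "back", "up", "down")
COMMAND_ACTIONS = (
    "molcount", "molcount_in_compartment", "listmols", "meansqrdisp",
    "set_surface_action", "add_surface", "add_molecules",
    "kill_molecules_in_region")


class ConfigError(Exception):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("\n".join(self.errors))


@dataclass
class ConfigModel:
    """Validated in-memory form of a configuration file."""

    dim: int = 3
    lo: np.ndarray = field(default_factory=lambda: np.zeros(3))
    hi: np.ndarray = field(default_factory=lambda: np.ones(3))
    btypes: list = field(default_factory=lambda: ["reflective"] * 3)
    dt: float = 0.0
    t_start: float = 0.0
    t_stop: float = 0.0
    seed: int = 0
    species: list = field(default_factory=list)
    diff_coefs: dict = field(default_factory=dict)  # (name, state) -> D
    drifts: dict = field(default_factory=dict)
    tensors: dict = field(default_factory=dict)
    surfaces: list = field(default_factory=list)
    compartments: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    placements: list = field(default_factory=list)
    commands: list = field(default_factory=list)  # (timing, action, args, target)


def parse_config(text: str, mesh_dir: str = ".") -> ConfigModel:
    """Parse and validate a configuration; raises :class:`ConfigError` with
    line-numbered messages on any problem."""
    m = ConfigModel()
    errors: list[str] = []
    surface: geo.Surface | None = None
    compartment: dict | None = None
    species_set: set[str] = set()
    rxn_by_name: dict[str, rx.ReactionDef] = {}
    rxn_regions: list = []  # (lineno, rxn_name, kind, region_name)
    seen = {"dim": False, "dt": False, "stop": False, "bounds": set()}

    def err(lineno, msg):
        errors.append(f"line {lineno}: {msg}")

    def need_species(lineno, name):
        if name not in species_set:
            err(lineno, f"species '{name}' not declared")
            return False
        return True

    def parse_entity(tok):
        """'A' or 'A(front)' -> (name, state_name)."""
        mm = re.fullmatch(r"([A-Za-z_]\w*)(?:\(([a-z]+)\))?", tok)
        if not mm:
            return None
        state = mm.group(2) or "solution"
        if state not in STATE_NAMES:
            return None
        return mm.group(1), state

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        toks = line.split()
        kw = toks[0]
        try:
            if surface is not None and kw != "end_surface":
                _parse_surface_stmt(surface, toks, lineno, err, species_set,
                                    mesh_dir, m)
                continue
            if compartment is not None and kw != "end_compartment":
                if kw == "surface":
                    compartment["surfaces"].append((lineno, toks[1]))
                elif kw == "point":
                    compartment["point"] = [float(v) for v in toks[1:]]
                else:
                    err(lineno, f"unknown compartment statement '{kw}'")
                continue

            if kw == "dim":
                m.dim = int(toks[1])
                if m.dim not in (1, 2, 3):
                    err(lineno, "dim must be 1, 2, or 3")
                seen["dim"] = True
            elif kw == "bounds":
                ax = AXES.get(toks[1])
                if ax is None:
                    err(lineno, f"unknown axis '{toks[1]}'")
                    continue
                lo, hi = float(toks[2]), float(toks[3])
                if hi <= lo:
                    err(lineno, "bounds: high must exceed low")
                bt = toks[4] if len(toks) > 4 else "reflective"
                if bt not in BOUND_TYPES:
                    err(lineno, f"unknown boundary type '{bt}'")
                m.lo[ax], m.hi[ax] = lo, hi
                m.btypes[ax] = bt
                seen["bounds"].add(ax)
            elif kw == "time_start":
                m.t_start = float(toks[1])
            elif kw == "time_stop":
                m.t_stop = float(toks[1])
                seen["stop"] = True
            elif kw == "time_step":
                m.dt = float(toks[1])
                if m.dt <= 0:
                    err(lineno, "time_step must be positive")
                seen["dt"] = True
            elif kw == "random_seed":
                m.seed = int(toks[1])
            elif kw == "species":
                for name in toks[1:]:
                    if name in species_set:
                        err(lineno, f"species '{name}' declared twice")
                    species_set.add(name)
                    m.species.append(name)
            elif kw == "difc":
                if not need_species(lineno, toks[1]):
                    continue
                if len(toks) == 3:
                    sp, st, D = toks[1], "solution", float(toks[2])
                else:
                    sp, st, D = toks[1], toks[2], float(toks[3])
                if st not in STATE_NAMES:
                    err(lineno, f"unknown state '{st}'")
                    continue
                if D < 0:
                    err(lineno, "diffusion coefficient must be >= 0")
                m.diff_coefs[(sp, st)] = D
            elif kw == "drift":
                if need_species(lineno, toks[1]):
                    m.drifts[toks[1]] = [float(v) for v in toks[2:5]]
            elif kw == "difm":
                if need_species(lineno, toks[1]):
                    vals = [float(v) for v in toks[2:]]
                    if len(vals) != 9:
                        err(lineno, "difm needs 9 tensor entries")
                        continue
                    t = np.array(vals).reshape(3, 3)
                    if not np.allclose(t, t.T):
                        err(lineno, "diffusion tensor must be symmetric")
                        continue
                    if np.linalg.eigvalsh(t).min() < -1e-12:
                        err(lineno, "diffusion tensor must be positive "
                            "semi-definite")
                        continue
                    m.tensors[toks[1]] = t
            elif kw == "mol":
                count = int(toks[1])
                sp = toks[2]
                if count < 0:
                    err(lineno, "molecule count must be >= 0")
                if not need_species(lineno, sp):
                    continue
                if toks[3] == "uniform":
                    if len(toks) > 4:
                        if toks[4] != "compartment":
                            err(lineno, "expected 'compartment NAME'")
                            continue
                        m.placements.append(
                            ("uniform", count, sp, ("compartment?", toks[5],
                                                    lineno)))
                    else:
                        m.placements.append(("uniform", count, sp, None))
                else:
                    pt = [float(v) for v in toks[3:]]
                    if len(pt) != m.dim:
                        err(lineno, f"position needs {m.dim} coordinates")
                        continue
                    m.placements.append(("point", count, sp, pt))
            elif kw == "surface_mol":
                count, sp, st, sname = int(toks[1]), toks[2], toks[3], toks[4]
                if st not in STATE_NAMES[1:]:
                    err(lineno, f"'{st}' is not a surface-bound state")
                    continue
                if need_species(lineno, sp):
                    m.placements.append(("surface", count, sp, st, sname))
            elif kw == "start_surface":
                surface = geo.Surface(name=toks[1])
            elif kw == "end_surface":
                if surface is None:
                    err(lineno, "end_surface without start_surface")
                else:
                    m.surfaces.append(surface)
                    surface = None
            elif kw == "start_compartment":
                compartment = {"name": toks[1], "surfaces": [], "point": None,
                               "line": lineno}
            elif kw == "end_compartment":
                if compartment is None:
                    err(lineno, "end_compartment without start_compartment")
                else:
                    surfs = []
                    for ln, sname in compartment["surfaces"]:
                        hit = [s for s in m.surfaces if s.name == sname]
                        if not hit:
                            err(ln, f"compartment references unknown "
                                f"surface '{sname}'")
                        else:
                            surfs.append(hit[0])
                    if compartment["point"] is None:
                        err(compartment["line"],
                            "compartment needs an interior point")
                    else:
                        m.compartments.append(geo.Compartment(
                            compartment["name"], surfs, compartment["point"]))
                    compartment = None
            elif kw in ("reaction", "reaction_molar"):
                rdef = _parse_reaction(toks, lineno, err, m, species_set,
                                       parse_entity, molar=(kw == "reaction_molar"))
                if rdef is not None:
                    if rdef.name in rxn_by_name:
                        err(lineno, f"reaction '{rdef.name}' declared twice")
                    rxn_by_name[rdef.name] = rdef
                    m.reactions.append(rdef)
            elif kw == "reaction_placement":
                name, key = toks[1], toks[2]
                if name not in rxn_by_name:
                    err(lineno, f"unknown reaction '{name}'")
                    continue
                rdef = rxn_by_name[name]
                if key == "pgemmax":
                    v = float(toks[3])
                    if not (0.0 < v < 1.0):
                        err(lineno, "pgemmax must be in (0, 1)")
                        continue
                    rdef.pgemmax = v
                    rdef.placement = "unbinding_radius"
                elif key == "unbinding":
                    rdef.unbinding_radius = float(toks[3])
                    rdef.placement = "unbinding_radius"
                elif key == "bounce":
                    rdef.bounce_factor = float(toks[3])
                    rdef.placement = "bounce"
                elif key == "conf_spread":
                    rdef.conf_spread_dist = float(toks[3])
                    rdef.placement = "conf_spread"
                    if len(rdef.reactants) != 2 or len(rdef.products) != 2:
                        err(lineno, "conformational spread needs two "
                            "reactants and two products")
                else:
                    err(lineno, f"unknown placement '{key}'")
            elif kw == "reaction_region":
                if toks[1] not in rxn_by_name:
                    err(lineno, f"unknown reaction '{toks[1]}'")
                    continue
                rxn_regions.append((lineno, toks[1], toks[2], toks[3]))
            elif kw == "cmd":
                _parse_command(toks, lineno, err, m)
            else:
                err(lineno, f"unknown statement '{kw}'")
        except (ValueError, IndexError) as exc:
            err(lineno, f"malformed '{kw}' statement ({exc})")

    if surface is not None:
        errors.append("unterminated start_surface block")
    if compartment is not None:
        errors.append("unterminated start_compartment block")
    if not seen["dim"]:
        errors.append("missing required statement 'dim'")
    if not seen["dt"]:
        errors.append("missing required statement 'time_step'")
    for ax in range(m.dim):
        if ax not in seen["bounds"]:
            errors.append(f"missing bounds for axis {'xyz'[ax]}")

    # resolve deferred cross-references
    comp_by_name = {c.name: c for c in m.compartments}
    for i, pl in enumerate(m.placements):
        if pl[0] == "uniform" and pl[3] is not None:
            _, cname, lineno = pl[3]
            if cname not in comp_by_name:
                err(lineno, f"unknown compartment '{cname}'")
            else:
                m.placements[i] = ("uniform", pl[1], pl[2],
                                   ("compartment", comp_by_name[cname]))
        elif pl[0] == "surface":
            if not any(s.name == pl[4] for s in m.surfaces):
                errors.append(f"surface_mol references unknown surface "
                              f"'{pl[4]}'")
    for lineno, rname, kind, region_name in rxn_regions:
        if kind == "compartment":
            if region_name not in comp_by_name:
                err(lineno, f"unknown compartment '{region_name}'")
            else:
                rxn_by_name[rname].region = ("compartment",
                                             comp_by_name[region_name])
        elif kind == "surface":
            hit = [s for s in m.surfaces if s.name == region_name]
            if not hit:
                err(lineno, f"unknown surface '{region_name}'")
            else:
                rxn_by_name[rname].region = ("surface", hit[0])
        else:
            err(lineno, f"unknown region kind '{kind}'")
    for surf in m.surfaces:
        for pname, partner in surf.jump_partner.items():
            names = {p.name for p in surf.panels}
            if partner not in names:
                errors.append(f"surface {surf.name}: jump partner "
                              f"'{partner}' is not a panel of this surface")
    for cmd in m.commands:
        errors.extend(_validate_command(cmd, m, comp_by_name))

    if errors:
        raise ConfigError(errors)
    return m


def _parse_surface_stmt(surface, toks, lineno, err, species_set, mesh_dir, m):
    kw = toks[0]
    if kw == "action":
        sp, side, action = toks[1], toks[2], toks[3]
        if sp != "all" and sp not in species_set:
            err(lineno, f"species '{sp}' not declared")
            return
        if side not in ("front", "back", "both"):
            err(lineno, f"unknown side '{side}'")
            return
        if action not in geo.ACTIONS:
            err(lineno, f"unknown action '{action}'")
            return
        sides = ("front", "back") if side == "both" else (side,)
        for s in sides:
            surface.actions[(sp, s)] = action
    elif kw == "rate":
        sp, transition = toks[1], toks[2]
        if sp not in species_set:
            err(lineno, f"species '{sp}' not declared")
            return
        if transition == "adsorb":
            side, kappa = toks[3], float(toks[4])
            if kappa < 0:
                err(lineno, "adsorption coefficient must be >= 0")
            surface.adsorb_kappa[(sp, side)] = kappa
            if len(toks) > 5:  # target bound state
                surface.adsorb_state[(sp, side)] = \
                    {"front": 1, "back": 2, "up": 3, "down": 4}[toks[5]]
        elif transition == "desorb":
            state, kd = toks[3], float(toks[4])
            if kd < 0:
                err(lineno, "desorption rate must be >= 0")
            surface.desorb_rate[(sp, state)] = kd
            surface.desorb_reversible[(sp, state)] = (
                len(toks) > 5 and toks[5] == "reversible")
        elif transition == "permeable":
            side, kp = toks[3], float(toks[4])
            if kp < 0:
                err(lineno, "permeability must be >= 0")
            surface.permeability[(sp, side)] = kp
        elif transition == "convert":
            from_state, to_state, rate = toks[3], toks[4], float(toks[5])
            if to_state == "solution":
                err(lineno, "conversion to solution must be declared as "
                    "desorption")
                return
            if rate < 0:
                err(lineno, "conversion rate must be >= 0")
            surface.conversion.setdefault((sp, from_state), []).append(
                (to_state, rate))
        else:
            err(lineno, f"unknown rate transition '{transition}'")
    elif kw == "panel":
        try:
            panel = _parse_panel(toks[1:], m.dim)
        except (ValueError, IndexError) as exc:
            err(lineno, f"bad panel: {exc}")
            return
        surface.panels.append(panel)
    elif kw == "panel_mesh":
        path = os.path.join(mesh_dir, toks[1])
        if not os.path.exists(path):
            err(lineno, f"mesh file '{toks[1]}' not found")
            return
        surface.panels.extend(geo.read_triangle_mesh(
            path, name_prefix=f"{surface.name}_mesh"))
    elif kw == "jump":
        surface.jump_partner[toks[1]] = toks[2]
    elif kw == "emitter":
        sp, rate = toks[1], float(toks[2])
        if sp not in species_set:
            err(lineno, f"species '{sp}' not declared")
            return
        if rate <= 0:
            err(lineno, "emitter rate must be positive")
            return
        pos = [float(v) for v in toks[3:6]]
        surface.emitters.setdefault(sp, []).append(geo.Emitter(
            np.array(pos), rate))
    elif kw == "disabled":
        surface.enabled = False
    else:
        err(lineno, f"unknown surface statement '{kw}'")


def _parse_panel(toks, dim):
    name, shape = toks[0], toks[1]
    vals = [float(v) for v in toks[2:]] if shape not in ("rect",) else None
    if shape == "rect":
        mm = re.fullmatch(r"([+-])([xyz])", toks[2])
        if not mm:
            raise ValueError("rect needs a signed axis like +z")
        sign = 1 if mm.group(1) == "+" else -1
        axis = AXES[mm.group(2)]
        rest = [float(v) for v in toks[3:]]
        origin, lengths = rest[:3], tuple(rest[3: 3 + max(dim - 1, 0)])
        if dim == 3 and len(lengths) != 2:
            raise ValueError("3-D rect needs two edge lengths")
        return geo.Rectangle(axis=axis, sign=sign, origin=origin,
                             lengths=lengths, name=name)
    if shape == "tri":
        if len(vals) != 9:
            raise ValueError("tri needs 9 floats")
        return geo.Triangle(np.array(vals).reshape(3, 3), name=name)
    if shape == "sphere":
        if len(vals) != 4:
            raise ValueError("sphere needs cx cy cz r")
        return geo.Sphere(vals[:3], vals[3], dim=dim, name=name)
    if shape == "cyl":
        if len(vals) != 7:
            raise ValueError("cyl needs x1 y1 z1 x2 y2 z2 r")
        return geo.Cylinder(vals[:3], vals[3:6], vals[6], name=name)
    if shape == "hemi":
        if len(vals) != 7:
            raise ValueError("hemi needs cx cy cz r px py pz")
        return geo.Hemisphere(vals[:3], vals[3], vals[4:7], name=name)
    if shape == "disk":
        if len(vals) != 7:
            raise ValueError("disk needs cx cy cz r nx ny nz")
        return geo.Disk(vals[:3], vals[3], vals[4:7], name=name)
    raise ValueError(f"unknown panel shape '{shape}'")


def _parse_reaction(toks, lineno, err, m, species_set, parse_entity, molar):
    name = toks[1]
    try:
        arrow = toks.index("->")
    except ValueError:
        err(lineno, "reaction needs '->'")
        return None
    rate = float(toks[-1])
    if rate < 0:
        err(lineno, "rate must be >= 0")
        return None
    lhs = [t for t in toks[2:arrow] if t != "+"]
    rhs = [t for t in toks[arrow + 1: -1] if t != "+"]
    if lhs == ["0"]:
        lhs = []
    if rhs == ["0"]:
        rhs = []

    def resolve(tok_list, what):
        out = []
        for tok in tok_list:
            ent = parse_entity(tok)
            if ent is None:
                err(lineno, f"malformed {what} '{tok}'")
                return None
            sp, st = ent
            if sp not in species_set:
                err(lineno, f"{what} species '{sp}' not declared")
                return None
            out.append((m.species.index(sp), STATE_NAMES.index(st)))
        return out

    reactants = resolve(lhs, "reactant")
    products = resolve(rhs, "product")
    if reactants is None or products is None:
        return None
    order = len(reactants)
    if order > 2:
        err(lineno, "reaction orders above two are not supported; decompose "
            "into bimolecular steps")
        return None
    if molar:
        if order != 2:
            err(lineno, "reaction_molar applies to second-order reactions")
            return None
        rate *= rx.MOLAR_TO_UM3
    try:
        return rx.ReactionDef(name=name, order=order, reactants=reactants,
                              products=products, rate=rate)
    except ValueError as exc:
        err(lineno, str(exc))
        return None


def _parse_command(toks, lineno, err, m):
    i = 1
    if toks[i] == "at":
        timing = ("at", float(toks[i + 1]))
        i += 2
    elif toks[i] == "every":
        timing = ("every", float(toks[i + 1]), float(toks[i + 2]),
                  float(toks[i + 3]))
        if timing[1] <= 0:
            err(lineno, "'every' interval must be positive")
            return
        i += 4
    elif toks[i] == "end":
        timing = ("end",)
        i += 1
    else:
        err(lineno, f"unknown command timing '{toks[i]}'")
        return
    action = toks[i]
    if action not in COMMAND_ACTIONS:
        err(lineno, f"unknown command action '{action}'")
        return
    args = toks[i + 1:]
    target = None
    if action in ("molcount", "molcount_in_compartment", "listmols",
                  "meansqrdisp"):
        if not args:
            err(lineno, f"command {action} needs an output target")
            return
        target = args[-1]
        args = args[:-1]
    m.commands.append({"timing": timing, "action": action, "args": args,
                       "target": target, "line": lineno})


def _validate_command(cmd, m, comp_by_name):
    errors = []
    ln = cmd["line"]
    a, args = cmd["action"], cmd["args"]
    if a == "molcount_in_compartment":
        if len(args) != 1 or args[0] not in comp_by_name:
            errors.append(f"line {ln}: molcount_in_compartment needs a "
                          "declared compartment")
    elif a == "meansqrdisp":
        if len(args) != 1 or args[0] not in m.species:
            errors.append(f"line {ln}: meansqrdisp needs a declared species")
    elif a == "set_surface_action":
        if len(args) != 4:
            errors.append(f"line {ln}: set_surface_action needs SURF SPECIES "
                          "SIDE ACTION")
        else:
            if not any(s.name == args[0] for s in m.surfaces):
                errors.append(f"line {ln}: unknown surface '{args[0]}'")
            if args[1] != "all" and args[1] not in m.species:
                errors.append(f"line {ln}: unknown species '{args[1]}'")
            if args[2] not in ("front", "back", "both"):
                errors.append(f"line {ln}: unknown side '{args[2]}'")
            if args[3] not in geo.ACTIONS:
                errors.append(f"line {ln}: unknown action '{args[3]}'")
    elif a == "add_surface":
        if len(args) != 1 or not any(s.name == args[0] for s in m.surfaces):
            errors.append(f"line {ln}: add_surface needs a declared surface")
    elif a == "add_molecules":
        if len(args) < 2 or args[1] not in m.species:
            errors.append(f"line {ln}: add_molecules needs COUNT SPECIES "
                          "[x y z | uniform]")
    elif a == "kill_molecules_in_region":
        if len(args) != 2 or args[0] not in m.species \
                or args[1] not in comp_by_name:
            errors.append(f"line {ln}: kill_molecules_in_region needs "
                          "SPECIES COMPARTMENT")
    return errors


# ---------------------------------------------------------------------------
# canonical emission (round-trip support)
# ---------------------------------------------------------------------------


def _fmt(x) -> str:
    return f"{float(x):.12g}"


def emit_config(m: ConfigModel) -> str:
    """Render a model back to canonical statement text; parsing the result
    reproduces the model."""
    out = [f"dim {m.dim}"]
    for ax in range(m.dim):
        out.append(f"bounds {'xyz'[ax]} {_fmt(m.lo[ax])} {_fmt(m.hi[ax])} "
                   f"{m.btypes[ax]}")
    out.append(f"time_start {_fmt(m.t_start)}")
    out.append(f"time_stop {_fmt(m.t_stop)}")
    out.append(f"time_step {_fmt(m.dt)}")
    if m.seed:
        out.append(f"random_seed {m.seed}")
    if m.species:
        out.append("species " + " ".join(m.species))
    for (sp, st), D in m.diff_coefs.items():
        out.append(f"difc {sp} {st} {_fmt(D)}")
    for sp, v in m.drifts.items():
        out.append(f"drift {sp} " + " ".join(_fmt(x) for x in v))
    for sp, t in m.tensors.items():
        out.append(f"difm {sp} " + " ".join(_fmt(x) for x in np.ravel(t)))
    for surf in m.surfaces:
        out.append(f"start_surface {surf.name}")
        if not surf.enabled:
            out.append("  disabled")
        for (sp, side), action in surf.actions.items():
            out.append(f"  action {sp} {side} {action}")
        for (sp, side), kappa in surf.adsorb_kappa.items():
            extra = ""
            if (sp, side) in surf.adsorb_state:
                extra = " " + ("front", "back", "up", "down")[
                    surf.adsorb_state[(sp, side)] - 1]
            out.append(f"  rate {sp} adsorb {side} {_fmt(kappa)}{extra}")
        for (sp, st), kd in surf.desorb_rate.items():
            rev = " reversible" if surf.desorb_reversible.get((sp, st)) else ""
            out.append(f"  rate {sp} desorb {st} {_fmt(kd)}{rev}")
        for (sp, side), kp in surf.permeability.items():
            out.append(f"  rate {sp} permeable {side} {_fmt(kp)}")
        for (sp, st), conv in surf.conversion.items():
            for to_state, rate in conv:
                out.append(f"  rate {sp} convert {st} {to_state} {_fmt(rate)}")
        for p in surf.panels:
            out.append("  " + _emit_panel(p, m.dim))
        for pname, partner in surf.jump_partner.items():
            out.append(f"  jump {pname} {partner}")
        for sp, ems in surf.emitters.items():
            for e in ems:
                out.append(f"  emitter {sp} {_fmt(e.rate)} "
                           + " ".join(_fmt(x) for x in e.pos))
        out.append("end_surface")
    for c in m.compartments:
        out.append(f"start_compartment {c.name}")
        for s in c.surfaces:
            out.append(f"  surface {s.name}")
        out.append("  point " + " ".join(_fmt(x) for x in
                                         c.interior_point[: m.dim]))
        out.append("end_compartment")
    for r in m.reactions:
        out.append(_emit_reaction(r, m))
        if r.placement == "conf_spread":
            out.append(f"reaction_placement {r.name} conf_spread "
                       f"{_fmt(r.conf_spread_dist)}")
        elif r.placement == "bounce":
            out.append(f"reaction_placement {r.name} bounce "
                       f"{_fmt(r.bounce_factor)}")
        elif r.placement == "unbinding_radius":
            if r.unbinding_radius is not None:
                out.append(f"reaction_placement {r.name} unbinding "
                           f"{_fmt(r.unbinding_radius)}")
            elif r.pgemmax is not None:
                out.append(f"reaction_placement {r.name} pgemmax "
                           f"{_fmt(r.pgemmax)}")
        if r.region is not None:
            kind, obj = r.region
            out.append(f"reaction_region {r.name} {kind} {obj.name}")
    for pl in m.placements:
        if pl[0] == "uniform":
            region = ""
            if pl[3] is not None:
                region = f" compartment {pl[3][1].name}"
            out.append(f"mol {pl[1]} {pl[2]} uniform{region}")
        elif pl[0] == "point":
            out.append(f"mol {pl[1]} {pl[2]} "
                       + " ".join(_fmt(x) for x in pl[3]))
        else:
            out.append(f"surface_mol {pl[1]} {pl[2]} {pl[3]} {pl[4]}")
    for cmd in m.commands:
        t = cmd["timing"]
        if t[0] == "at":
            timing = f"at {_fmt(t[1])}"
        elif t[0] == "every":
            timing = f"every {_fmt(t[1])} {_fmt(t[2])} {_fmt(t[3])}"
        else:
            timing = "end"
        parts = ["cmd", timing, cmd["action"], *cmd["args"]]
        if cmd["target"]:
            parts.append(cmd["target"])
        out.append(" ".join(parts))
    return "\n".join(out) + "\n"


def _emit_panel(p, dim):
    if isinstance(p, geo.Rectangle):
        sign = "+" if p.sign > 0 else "-"
        return (f"panel {p.name} rect {sign}{'xyz'[p.axis]} "
                + " ".join(_fmt(x) for x in p.origin)
                + (" " if p.lengths else "")
                + " ".join(_fmt(x) for x in p.lengths))
    if isinstance(p, geo.Triangle):
        return (f"panel {p.name} tri "
                + " ".join(_fmt(x) for x in p.verts.ravel()))
    if isinstance(p, geo.Sphere):
        return (f"panel {p.name} sphere "
                + " ".join(_fmt(x) for x in p.center) + f" {_fmt(p.radius)}")
    if isinstance(p, geo.Cylinder):
        return (f"panel {p.name} cyl " + " ".join(_fmt(x) for x in p.a) + " "
                + " ".join(_fmt(x) for x in p.b) + f" {_fmt(p.radius)}")
    if isinstance(p, geo.Hemisphere):
        return (f"panel {p.name} hemi " + " ".join(_fmt(x) for x in p.center)
                + f" {_fmt(p.radius)} " + " ".join(_fmt(x) for x in p.pole))
    if isinstance(p, geo.Disk):
        return (f"panel {p.name} disk " + " ".join(_fmt(x) for x in p.center)
                + f" {_fmt(p.radius)} " + " ".join(_fmt(x) for x in p.normal))
    raise TypeError(f"cannot emit panel of type {type(p)}")


def _emit_reaction(r: rx.ReactionDef, m: ConfigModel) -> str:
    def side(ents):
        if not ents:
            return "0"
        toks = []
        for sp, st in ents:
            name = m.species[sp]
            toks.append(name if st == 0 else f"{name}({STATE_NAMES[st]})")
        return " + ".join(toks)

    return (f"reaction {r.name} {side(r.reactants)} -> {side(r.products)} "
            f"{_fmt(r.rate)}")
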