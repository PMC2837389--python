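"""Chemical kinetics: zeroth-, first-, and second-order reactions.

The centerpiece is the discrete-time Smoluchowski calibration.  Bimolecular
reactions fire when two reactants end a time step closer than a *binding
radius* sigma_b.  The effective steady-state rate constant of that discrete
process (Gaussian relative displacement with per-axis rms s = sqrt(2 D_mut dt)
followed by absorption of all pairs inside sigma_b) is computed by numerically
propagating the radial pair density to steady state; ``binding_radius_from_rate``
inverts that map by root finding so the simulated steady-state rate equals the
requested rate constant.  As dt -> 0 the calibrated dynamics converge to
Smoluchowski dynamics: sigma_b -> k / (4 pi D_mut); in the opposite, well-mixed
limit sigma_b -> (3 k dt / 4 pi)^(1/3).

Dissociation products that can re-react are separated by an *unbinding radius*
sigma_u; releasing a pair at separation sigma_u gives it an ever-capture
(geminate recombination) probability of sigma_b / sigma_u in 3-D, so
``sigma_u = sigma_b / p_gem_max`` bounds recombination by ``p_gem_max``.

Units: lengths um, time s; second-order rates in um^3/s after the molar
conversion (1 M^-1 s^-1 = 1e15/N_A um^3/s) done at parse time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

AVOGADRO = 6.02214076e23
#: 1 M^-1 s^-1 expressed in um^3/s
MOLAR_TO_UM3 = 1.0e15 / AVOGADRO

__all__ = [
    "ReactionDef",
    "ReactionStepParams",
    "rate_from_binding_radius",
    "binding_radius_from_rate",
    "unbinding_radius_from_pgem",
    "zeroth_order_step",
    "first_order_step",
    "bimolecular_step",
    "conf_spread_step",
    "place_products",
]


# ---------------------------------------------------------------------------
# binding-radius calibration (radial pair-density propagation)
# ---------------------------------------------------------------------------


def _grid(x: float, h_fine: float, h_cap: float, r_max: float):
    """Radial nodes: fine near the absorbing radius x, geometric growth to a
    capped spacing in the far field.

    Cell-centered nodes are aligned so that a cell *edge* falls exactly at x;
    otherwise the absorbed-mass quadrature (a sharp cutoff at r = x)
    mis-weights the boundary cell by O(h) of the hole volume.
    """
    nodes = []
    if x <= 1.0:
        n_in = max(8, math.ceil(x / h_fine))
        h = x / n_in  # x sits on a cell edge
        r = h / 2.0
        hi = 3.0 * x
        while r <= hi:
            nodes.append(r)
            r += h
        h_fine = h
    else:
        lo = max(0.0, x - 6.0)
        r = lo + 0.1
        while r < x - 2.0:
            nodes.append(r)
            r += 0.2
        h = 2.0 / math.ceil(2.0 / h_fine)  # x - 2 and x on cell edges
        r = (x - 2.0) + h / 2.0
        while r <= x + 2.0:
            nodes.append(r)
            r += h
        h_fine = h
    h = h_fine
    r = nodes[-1]
    while r < r_max:
        h = min(h * 1.12, h_cap)
        r += h
        nodes.append(r)
    return np.asarray(nodes)


def _trap_weights(r: np.ndarray) -> np.ndarray:
    w = np.empty_like(r)
    w[1:-1] = (r[2:] - r[:-2]) / 2.0
    w[0] = (r[1] - r[0]) / 2.0 + r[0]  # first cell extends to r=0
    w[-1] = (r[-1] - r[-2]) / 2.0
    return w


def _propagator(r: np.ndarray, w: np.ndarray, dim: int) -> np.ndarray:
    """Column-stochastic matrix K[i, j] = P(land in cell i | start at r_j) for
    one Gaussian step with per-axis sigma = 1 (reduced units)."""
    ri = r[:, None]
    rj = r[None, :]
    if dim == 3:
        f = (ri / (rj * math.sqrt(2.0 * math.pi))) * (
            np.exp(-((ri - rj) ** 2) / 2.0) - np.exp(-((ri + rj) ** 2) / 2.0)
        )
    elif dim == 2:
        from scipy.special import i0e

        f = ri * i0e(ri * rj) * np.exp(-((ri - rj) ** 2) / 2.0)
    else:
        f = (1.0 / math.sqrt(2.0 * math.pi)) * (
            np.exp(-((ri - rj) ** 2) / 2.0) + np.exp(-((ri + rj) ** 2) / 2.0)
        )
    K = f * w[:, None]
    colsum = K.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return K / colsum


def _sphere_shell(r: np.ndarray, w: np.ndarray, dim: int) -> np.ndarray:
    if dim == 3:
        return 4.0 * math.pi * r**2 * w
    if dim == 2:
        return 2.0 * math.pi * r * w
    return 2.0 * w  # both sides of the 1-D pair coordinate


def _reduced_rate(x: float, dim: int = 3, h_fine=None, h_cap=0.12) -> float:
    """Steady-state captures per step, per unit far-field density, for an
    absorbing radius ``x`` in units of the rms per-axis step (s = 1).

    The discrete-time pair process alternates absorption (zero the density
    inside x, record the flux) with one radial Gaussian propagation; its
    steady state is the fixed point of a linear map, so it is solved
    directly:  writing the step as c' = A c with the tail nodes pinned to
    the far-field form t(a) = 1 - a/r (harmonic tails are invariant under
    diffusion; a = flux / 4 pi D with D = 1/2), the interior density obeys
    (I - A_II) c = A_IT t(a).  Both t components are solved at once and the
    scalar self-consistency a = flux(c(a)) / 2 pi closes the system.
    """
    if x <= 0:
        return 0.0
    if h_fine is None:
        h_fine = min(x, 1.0) / 30.0
    r_max = x + 14.0
    r = _grid(x, h_fine, h_cap, r_max)
    w = _trap_weights(r)
    vol = _sphere_shell(r, w, dim)
    K = _propagator(r, w, dim)
    inside = r < x
    tail = r >= x + 9.0
    interior = ~tail
    # one sweep in mass coordinates: m' = K Z m, Z zeroes the absorber
    A = K * vol[None, :] / vol[:, None]
    A[:, inside] = 0.0
    A_II = A[np.ix_(interior, interior)]
    A_IT = A[np.ix_(interior, tail)]
    lhs = np.eye(A_II.shape[0]) - A_II
    if dim == 3:
        t1 = np.ones(int(tail.sum()))
        t2 = 1.0 / r[tail]
        sol = np.linalg.solve(lhs, np.column_stack([A_IT @ t1, A_IT @ t2]))
        u_int, w_int = sol[:, 0], sol[:, 1]
        vin = vol[inside]
        iin = inside[interior]
        f1 = float(u_int[iin] @ vin)  # flux from the t = 1 component
        f2 = float(w_int[iin] @ vin)  # flux removed per unit tail 1/r
        a = f1 / (2.0 * math.pi + f2)
        return 2.0 * math.pi * a
    c_int = np.linalg.solve(lhs, A_IT @ np.ones(int(tail.sum())))
    return float(c_int[inside[interior]] @ vol[inside])


def rate_from_binding_radius(sigma_b: float, s: float, dt: float, dim: int = 3,
                             grid_tol: float = 1e-4) -> float:
    """Effective steady-state rate constant of the discrete-time pair process.

    Parameters
    ----------
    sigma_b : binding radius (length).
    s : rms per-axis relative displacement per step, sqrt(2 * D_mutual * dt).
    dt : time step.
    dim : spatial dimension (3-D is the validated case; 1-D and 2-D use the
        matching radial propagator with a clamped far field).

    Returns the rate in length^dim / time.  The radial grid is refined
    automatically until the flux changes by less than ``grid_tol`` relatively.
    """
    if sigma_b < 0:
        raise ValueError("binding radius must be >= 0")
    if sigma_b == 0:
        return 0.0
    x = sigma_b / s
    h_fine = min(x, 1.0) / 30.0
    h_cap = 0.12
    k_red = _reduced_rate(x, dim, h_fine, h_cap)
    for _ in range(3):
        h_fine /= 1.6
        h_cap /= 1.6
        k_next = _reduced_rate(x, dim, h_fine, h_cap)
        if abs(k_next - k_red) <= grid_tol * k_red:
            k_red = k_next
            break
        k_red = k_next
    return k_red * s**dim / dt


def binding_radius_from_rate(k: float, D_mutual: float, dt: float, dim: int = 3,
                             rtol: float = 1e-5) -> float:
    """Binding radius whose steady-state discrete-time rate equals ``k``.

    ``k`` must already be in volumetric units (um^dim/s for the package
    convention).  Bracketing uses the two analytic limits -- Smoluchowski
    (sigma = k / (4 pi D_mutual)) and well-mixed (sigma = (3 k dt/4 pi)^(1/3))
    -- between which the true radius always lies, then Brent root finding.
    """
    if k < 0:
        raise ValueError("rate constant must be >= 0")
    if k == 0:
        return 0.0
    if D_mutual <= 0 or dt <= 0:
        raise ValueError("D_mutual and dt must be positive")
    s = math.sqrt(2.0 * D_mutual * dt)
    k_red = k * dt / s**dim
    if dim == 3:
        x_lo = max((3.0 * k_red / (4.0 * math.pi)) ** (1.0 / 3.0),
                   k_red / (2.0 * math.pi))
    elif dim == 2:
        x_lo = math.sqrt(k_red / math.pi)
    else:
        x_lo = k_red / 2.0
    x_lo *= 0.98

    def g(x):
        return _reduced_rate_cached(x, dim) - k_red

    x_hi = x_lo * 1.5
    g_lo = g(x_lo)
    if g_lo > 0:
        # bracket downward (x_lo overshoots only by grid error)
        while g(x_lo) > 0:
            x_hi = x_lo
            x_lo /= 1.5
    else:
        tries = 0
        while g(x_hi) < 0:
            x_lo = x_hi
            x_hi *= 1.5
            tries += 1
            if tries > 60:
                raise ValueError(
                    "requested rate exceeds the diffusion-limited maximum "
                    f"reachable for D_mutual={D_mutual}, dt={dt}")
    x = brentq(g, x_lo, x_hi, rtol=rtol)
    return x * s


_RED_CACHE: dict = {}


def _reduced_rate_cached(x: float, dim: int) -> float:
    key = (round(x, 12), dim)
    if key not in _RED_CACHE:
        h_fine = min(x, 1.0) / 45.0
        _RED_CACHE[key] = _reduced_rate(x, dim, h_fine, h_cap=0.08)
    return _RED_CACHE[key]


def unbinding_radius_from_pgem(sigma_b: float, p_gem_max: float) -> float:
    """Default unbinding radius: a pair released at sigma_u is ever captured
    at sigma_b with probability sigma_b / sigma_u (3-D first-passage), so
    sigma_u = sigma_b / p_gem_max caps geminate recombination."""
    if not (0.0 < p_gem_max < 1.0):
        raise ValueError("p_gem_max must be in (0, 1)")
    return sigma_b / p_gem_max


# ---------------------------------------------------------------------------
# reaction definitions
# ---------------------------------------------------------------------------


@dataclass
class ReactionDef:
    """A declared reaction.

    ``reactants`` / ``products`` are lists of ``(species_index, state)``;
    ``rate`` is the macroscopic rate constant in volumetric units
    (conc/time for order 0, 1/s for order 1, um^3/s for order 2).
    ``placement`` is one of ``default | unbinding_radius | conf_spread |
    bounce``.
    """

    name: str
    order: int
    reactants: list
    products: list
    rate: float
    placement: str = "default"
    conf_spread_dist: float | None = None  # r_c, conformational spread only
    region: object | None = None  # Compartment or Surface restriction
    pgemmax: float | None = None
    unbinding_radius: float | None = None
    bounce_factor: float = 1.01

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError(f"reaction {self.name}: rate must be >= 0")
        expected = 2 if self.placement == "conf_spread" else self.order
        if len(self.reactants) != expected:
            raise ValueError(
                f"reaction {self.name}: order {self.order} with "
                f"{len(self.reactants)} reactants")
        if self.order > 2:
            raise ValueError(
                f"reaction {self.name}: orders above two are not supported; "
                "decompose into bimolecular steps")


@dataclass
class ReactionStepParams:
    """Derived per-step parameters (recomputed whenever dt changes)."""

    lam: float = 0.0  # order 0: mean events per step (k V dt)
    prob: float = 0.0  # order 1 / conf_spread per-step probability
    binding_radius: float = 0.0
    unbinding_radius: float = 0.0
    bounce_sep: float = 0.0
    D_reactants: tuple = (0.0, 0.0)


# ---------------------------------------------------------------------------
# per-step reaction operations (operate on a SimState duck type)
# ---------------------------------------------------------------------------


def zeroth_order_step(sim, rxn: ReactionDef, rng) -> int:
    """Poisson(k V dt) product molecules at uniform random positions in the
    volume (rejection-sampled into the compartment if restricted)."""
    region = rxn.region
    if region is not None:
        V = sim.region_volume(region)
    else:
        V = sim.volume()
    lam = rxn.rate * V * sim.dt
    n = int(rng.poisson(lam))
    if n == 0:
        return 0
    pos = sim.sample_uniform(n, region, rng)
    for sp, st in rxn.products:
        sim.store.add(len(pos), sp, st, pos, used=True)
    sim.log_event(rxn.name, n)
    return n


def first_order_step(sim, channels, idx, rng):
    """Multi-channel first-order kinetics for the molecules ``idx``.

    ``channels`` is a list of ``(rxn, k)`` sharing the same reactant
    (species, state).  A molecule reacts with probability 1 - exp(-k_tot dt)
    and the channel is chosen with probability k_i / k_tot.
    """
    if len(idx) == 0 or not channels:
        return
    ks = np.array([k for _, k in channels])
    k_tot = ks.sum()
    if k_tot <= 0:
        return
    p_react = 1.0 - math.exp(-k_tot * sim.dt)
    u = rng.uniform(size=len(idx))
    hit = u < p_react
    if not hit.any():
        return
    which = rng.choice(len(channels), size=int(hit.sum()), p=ks / k_tot)
    hit_idx = idx[hit]
    for ci, (rxn, _) in enumerate(channels):
        sel = hit_idx[which == ci]
        if len(sel) == 0:
            continue
        _apply_unimolecular(sim, rxn, sel, rng)
        sim.log_event(rxn.name, len(sel), reactants=sel)


def _apply_unimolecular(sim, rxn: ReactionDef, idx, rng):
    store = sim.store
    pos = store.pos[idx].copy()
    panel = store.panel[idx].copy()
    if len(rxn.products) == 0:
        store.kill(idx)
        return
    if len(rxn.products) == 1:
        sp, st = rxn.products[0]
        store.species[idx] = sp
        store.state[idx] = st
        if st == 0:
            store.panel[idx] = -1
        store.used[idx] = True
        return
    # two (or more) products: dissociation
    store.kill(idx)
    prod_pos = place_products(rxn, pos, None, sim.step_params[rxn.name], rng, sim.dim)
    for (sp, st), ppos in zip(rxn.products, prod_pos):
        ppos = sim.resolve_placement(pos, ppos)
        new_panel = panel if st != 0 else None
        sim.store.add(len(idx), sp, st, ppos, used=True,
                      panel=new_panel)


def bimolecular_step(sim, rxn: ReactionDef, rng):
    """React all A-B pairs closer than the binding radius, nearest first.

    Candidate pairs come from a KD-tree range query that is exactly
    equivalent to an all-pairs search (minimum-image on periodic axes); each
    molecule reacts at most once per step.
    """
    params = sim.step_params[rxn.name]
    sigma = params.binding_radius if rxn.placement != "conf_spread" else rxn.conf_spread_dist
    if sigma is None or sigma <= 0:
        return
    (spA, stA), (spB, stB) = rxn.reactants
    store = sim.store
    candA = store.select(spA, stA, unused=True)
    candB = store.select(spB, stB, unused=True)
    if rxn.region is not None:
        candA = candA[sim.region_mask(rxn.region, store.pos[candA])]
        candB = candB[sim.region_mask(rxn.region, store.pos[candB])]
    if len(candA) == 0 or len(candB) == 0:
        return
    pairs = find_pairs(store.pos[candA], store.pos[candB], sigma,
                       boxsize=sim.kd_boxsize(), offset=sim.kd_offset(),
                       same=(spA == spB and stA == stB))
    if len(pairs) == 0:
        return
    ia = candA[pairs[:, 0].astype(int)]
    ib = candB[pairs[:, 1].astype(int)]
    if rxn.placement == "conf_spread":
        _conf_spread_pairs(sim, rxn, ia, ib, rng)
        return
    # nearest pairs first; each molecule at most once
    taken = set()
    keep = []
    for r in range(len(ia)):
        a, b = int(ia[r]), int(ib[r])
        if a in taken or b in taken or a == b:
            continue
        taken.add(a)
        taken.add(b)
        keep.append(r)
    if not keep:
        return
    keep = np.asarray(keep)
    ia, ib = ia[keep], ib[keep]
    posA = store.pos[ia].copy()
    posB = store.pos[ib].copy()
    store.kill(ia)
    store.kill(ib)
    prod_pos = place_products(rxn, posA, posB, params, rng, sim.dim)
    anchor = posA if len(rxn.products) != 1 else None
    for (sp, st), ppos in zip(rxn.products, prod_pos):
        ppos = sim.resolve_placement(anchor if anchor is not None else posA, ppos)
        sim.store.add(len(ia), sp, st, ppos, used=True)
    sim.log_event(rxn.name, len(ia), reactants=np.concatenate([ia, ib]))


def find_pairs(posA, posB, radius, boxsize=None, offset=None, same=False):
    """(i, j) index pairs with |posA[i] - posB[j]| < radius, sorted by
    separation (minimum image on periodic axes via the KD-tree boxsize)."""
    pa, pb = posA, posB
    if boxsize is not None:
        pa = np.mod(posA - offset, boxsize)
        pb = np.mod(posB - offset, boxsize)
    ta = cKDTree(pa, boxsize=boxsize)
    if same:
        prs = np.array(sorted(ta.query_pairs(radius)), dtype=float)
        if len(prs) == 0:
            return np.empty((0, 2))
        ii = prs[:, 0].astype(int)
        jj = prs[:, 1].astype(int)
    else:
        tb = cKDTree(pb, boxsize=boxsize)
        neigh = ta.query_ball_tree(tb, radius)
        ii = np.array([i for i, lst in enumerate(neigh) for _ in lst], dtype=int)
        jj = np.array([j for lst in neigh for j in lst], dtype=int)
        if len(ii) == 0:
            return np.empty((0, 2))
    d = pa[ii] - pb[jj]
    if boxsize is not None:
        d -= boxsize * np.round(d / boxsize)
    dist = np.linalg.norm(d, axis=1)
    inside = dist < radius
    ii, jj, dist = ii[inside], jj[inside], dist[inside]
    order = np.lexsort((jj, ii, dist))
    return np.column_stack([ii[order], jj[order]]).astype(float)


def _conf_spread_pairs(sim, rxn, ia, ib, rng):
    """First-order conversion of reactant A for every A-B contact pair.

    Pairs are non-exclusive: an A with m in-range partners gets m independent
    chances per step.  Positions never change; B survives untouched.
    """
    p = sim.step_params[rxn.name].prob
    fire = rng.uniform(size=len(ia)) < p
    if not fire.any():
        return
    targets = np.unique(ia[fire])
    # A must still match the reactant signature (it may have converted via an
    # earlier pair this same step)
    spA, stA = rxn.reactants[0]
    store = sim.store
    ok = (store.species[targets] == spA) & (store.state[targets] == stA)
    targets = targets[ok]
    if len(targets) == 0:
        return
    sp_new, st_new = rxn.products[0]
    store.species[targets] = sp_new
    store.state[targets] = st_new
    sim.log_event(rxn.name, len(targets), reactants=targets)


def conf_spread_step(sim, rxn: ReactionDef, rng):
    """Conformational spread: contact-mediated state conversion within r_c."""
    bimolecular_step(sim, rxn, rng)


def place_products(rxn: ReactionDef, posA, posB, params: ReactionStepParams,
                   rng, dim: int):
    """Product positions for one batch of reaction events.

    default        -> all products at the reaction point; for bimolecular
                      events that point is the diffusion-weighted encounter
                      point r_C = (D_B r_A + D_A r_B) / (D_A + D_B);
    unbinding_radius -> two products separated by sigma_u along a uniformly
                      random direction, centered on the reaction point;
    conf_spread    -> products keep the reactant positions;
    bounce         -> products pushed apart along the line that connected the
                      reactants, to separation bounce_factor * sigma_b.
    """
    n = len(posA)
    if posB is None:
        center = posA
    else:
        Da, Db = params.D_reactants
        wa = Db / (Da + Db) if (Da + Db) > 0 else 0.5
        center = wa * posA + (1.0 - wa) * posB

    if rxn.placement == "conf_spread":
        return [posA if i == 0 else posB for i in range(len(rxn.products))]

    if rxn.placement == "bounce" and posB is not None:
        sep = params.bounce_sep
        d = posB - posA
        dist = np.linalg.norm(d, axis=1, keepdims=True)
        u = np.where(dist > 0, d / np.where(dist == 0, 1.0, dist),
                     _rand_dirs(n, dim, rng))
        mid = 0.5 * (posA + posB)
        return [mid - 0.5 * sep * u, mid + 0.5 * sep * u]

    if rxn.placement == "unbinding_radius" and len(rxn.products) >= 2:
        sigma_u = params.unbinding_radius
        u = _rand_dirs(n, dim, rng)
        out = [center - 0.5 * sigma_u * u, center + 0.5 * sigma_u * u]
        out += [center.copy() for _ in range(len(rxn.products) - 2)]
        return out

    return [center.copy() for _ in rxn.products]


def _rand_dirs(n, dim, rng):
    v = rng.standard_normal((n, 3))
    if dim < 3:
        v[:, dim:] = 0.0
    nrm = np.linalg.norm(v, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return v / nrm
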