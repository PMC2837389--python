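"""Simulation state and the fixed-time-step orchestration loop.

A simulation advances in fixed steps of length dt.  Within one step the
substeps run in a fixed, documented order:

1. diffuse all molecules (solution + surface-bound + drift),
2. process molecule-surface interactions for each segment crossing,
3. desorption / surface-state conversion of bound molecules,
4. zeroth-order reactions,
5. first-order reactions,
6. bimolecular and conformational-spread reactions,
7. box reassignment,
8. scheduled commands that fall due.

Each molecule participates in at most one reaction or adsorption event per
step (the ``used`` flag); simulated dynamics converge to Smoluchowski
dynamics as dt -> 0.
"""

from __future__ import annotations

import math

import numpy as np

from . import diffusion as _dif
from . import geometry as _geo
from . import reactions as _rx
from . import surfacechem as _sc

# molecule states
SOLUTION, FRONT, BACK, UP, DOWN = 0, 1, 2, 3, 4
STATE_NAMES = ("solution", "front", "back", "up", "down")
STATE_INDEX = {n: i for i, n in enumerate(STATE_NAMES)}
#: which side of its panel a bound state lives on (+1 front, -1 back)
STATE_SIDE = {FRONT: 1, BACK: -1, UP: 1, DOWN: -1}


class MoleculeStore:
    """Struct-of-arrays store for point molecules.

    Serial numbers are unique within a run and never reused; dead slots are
    compacted between steps once they dominate, preserving order (so the
    serial column stays sorted).
    """

    def __init__(self, capacity: int = 1024):
        self._alloc(capacity)
        self.n = 0
        self.next_serial = 1

    def _alloc(self, capacity):
        self.pos = np.zeros((capacity, 3))
        self.species = np.zeros(capacity, dtype=np.int32)
        self.state = np.zeros(capacity, dtype=np.int8)
        self.panel = np.full(capacity, -1, dtype=np.int32)
        self.serial = np.zeros(capacity, dtype=np.int64)
        self.alive = np.zeros(capacity, dtype=bool)
        self.used = np.zeros(capacity, dtype=bool)
        self.box = np.full(capacity, -1, dtype=np.int64)
        self.wrap = np.zeros((capacity, 3), dtype=np.int64)

    @property
    def capacity(self):
        return len(self.species)

    def _grow(self, need):
        cap = self.capacity
        new_cap = max(2 * cap, self.n + need)
        old = self.__dict__.copy()
        self._alloc(new_cap)
        for name in ("pos", "species", "state", "panel", "serial", "alive",
                     "used", "box", "wrap"):
            getattr(self, name)[: self.n] = old[name][: self.n]

    def add(self, count, species, state, pos, used=False, panel=None):
        if count == 0:
            return np.empty(0, dtype=int)
        if self.n + count > self.capacity:
            self._grow(count)
        idx = np.arange(self.n, self.n + count)
        self.pos[idx] = pos
        self.species[idx] = species
        self.state[idx] = state
        self.panel[idx] = -1 if panel is None else panel
        self.serial[idx] = np.arange(self.next_serial, self.next_serial + count)
        self.alive[idx] = True
        self.used[idx] = used
        self.box[idx] = -1
        self.wrap[idx] = 0
        self.n += count
        self.next_serial += count
        return idx

    def kill(self, idx):
        self.alive[idx] = False

    def alive_idx(self):
        return np.flatnonzero(self.alive[: self.n])

    def count_alive(self):
        return int(self.alive[: self.n].sum())

    def select(self, species, state, unused=False):
        m = self.alive[: self.n] & (self.species[: self.n] == species) \
            & (self.state[: self.n] == state)
        if unused:
            m &= ~self.used[: self.n]
        return np.flatnonzero(m)

    def compact(self):
        keep = self.alive_idx()
        for name in ("pos", "species", "state", "panel", "serial", "alive",
                     "used", "box", "wrap"):
            arr = getattr(self, name)
            arr[: len(keep)] = arr[keep]
        self.n = len(keep)


class BoxGrid:
    """Uniform spatial partition with half-open cells [low, high) per axis.

    The cell edge is at least the largest binding radius of any active
    reaction (construction fails otherwise) and defaults to no finer than
    1/20 of the system length per axis.
    """

    def __init__(self, lo, hi, min_edge: float = 0.0, dim: int = 3):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        self.dim = dim
        L = self.hi - self.lo
        self.ncells = np.ones(3, dtype=int)
        for ax in range(dim):
            edge_target = max(min_edge, L[ax] / 20.0)
            n = max(1, int(math.floor(L[ax] / edge_target)))
            if L[ax] / n < min_edge - 1e-12 * min_edge:
                n = max(1, n - 1)
            if min_edge > 0 and L[ax] < min_edge:
                raise ValueError(
                    "binding radius exceeds the system size on axis "
                    f"{ax}: box grid cannot satisfy the cell-edge bound")
            self.ncells[ax] = n
        self.edge = L / self.ncells
        self.edge[dim:] = 1.0

    def assign(self, pos, periodic=None, clamp=None, fbuf=None, ibuf=None):
        """Flat cell index per position; periodic axes wrap, ``clamp`` axes
        (transparent boundaries) clip to the edge cells, others must be in
        bounds (a position outside signals a missed boundary interaction).
        ``fbuf``/``ibuf`` are optional reusable work arrays."""
        if fbuf is not None:
            rel = np.subtract(pos, self.lo, out=fbuf)
            rel /= self.edge
            np.floor(rel, out=rel)
            ij = ibuf
            np.copyto(ij, rel, casting="unsafe")
        else:
            rel = (pos - self.lo) / self.edge
            ij = np.floor(rel).astype(np.int64)
        for ax in range(self.dim):
            if periodic is not None and periodic[ax]:
                ij[:, ax] %= self.ncells[ax]
            elif clamp is not None and clamp[ax]:
                ij[:, ax] = np.clip(ij[:, ax], 0, self.ncells[ax] - 1)
            else:
                bad = (ij[:, ax] < 0) | (ij[:, ax] >= self.ncells[ax])
                if bad.any():
                    # tolerate round-off at the high edge only
                    edge_hit = bad & np.isclose(pos[:, ax], self.hi[ax])
                    ij[edge_hit, ax] = self.ncells[ax] - 1
                    bad &= ~edge_hit
                    if bad.any():
                        raise RuntimeError(
                            f"molecule outside bounds on axis {ax}: missed "
                            "boundary interaction")
        ij[:, self.dim:] = 0
        return (ij[:, 0] * self.ncells[1] + ij[:, 1]) * self.ncells[2] + ij[:, 2]


class SimState:
    """Full simulation state; build with :func:`init_sim`."""

    def __init__(self):
        self.dim = 3
        self.dt = 0.0
        self.t = 0.0
        self.t_stop = 0.0
        self.lo = np.zeros(3)
        self.hi = np.ones(3)
        self.btypes = ["reflective"] * 3
        self.species_names: list[str] = []
        self.species_index: dict[str, int] = {}
        self.params: _dif.DiffusionStepParams | None = None
        self.surfaces: list[_geo.Surface] = []
        self.panels: list[_geo.Panel] = []
        self.panel_surface = np.empty(0, dtype=int)
        self.panel_local = np.empty(0, dtype=int)
        self.compartments: dict[str, _geo.Compartment] = {}
        self.reactions: list[_rx.ReactionDef] = []
        self.step_params: dict[str, _rx.ReactionStepParams] = {}
        self.first_order_groups: dict = {}
        self.bound_channels: dict = {}
        self.store = MoleculeStore()
        self.grid: BoxGrid | None = None
        self.rng = np.random.default_rng(0)
        self.seed = 0
        self.commands = []
        self.outputs: dict = {}
        self.step_events: list = []
        self.event_counts: dict[str, int] = {}
        self.absorbed: dict = {}
        self._panel_bs = []
        self._surface_clear = []
        self._tri_ids = None
        self._comp_volumes: dict[str, float] = {}

    # -- geometry helpers ---------------------------------------------------
    @property
    def diag(self):
        return float(np.linalg.norm((self.hi - self.lo)[: self.dim]))

    def volume(self):
        return float(np.prod((self.hi - self.lo)[: self.dim]))

    def periodic_axes(self):
        return [self.btypes[ax] == "periodic" for ax in range(3)]

    def kd_boxsize(self):
        per = self.periodic_axes()
        if not any(per[: self.dim]):
            return None
        L = self.hi - self.lo
        bs = np.empty(3)
        for ax in range(3):
            if ax >= self.dim:
                bs[ax] = 4.0
            else:
                bs[ax] = L[ax] if per[ax] else 4.0 * L[ax]
        return bs

    def kd_offset(self):
        off = self.lo.copy()
        off -= np.where(np.array(self.periodic_axes()), 0.0, (self.hi - self.lo))
        off[self.dim:] = -2.0
        return off

    def region_volume(self, region):
        kind, obj = region
        if kind == "compartment":
            if obj.name not in self._comp_volumes:
                rng = np.random.default_rng(12345)
                n = 40000
                pts = self.lo + rng.uniform(size=(n, 3)) * (self.hi - self.lo)
                pts[:, self.dim:] = 0.0
                frac = obj.contains(pts).mean()
                self._comp_volumes[obj.name] = float(frac) * self.volume()
            return self._comp_volumes[obj.name]
        raise ValueError("zeroth-order reactions need a volumetric region")

    def region_mask(self, region, pos):
        kind, obj = region
        if kind == "compartment":
            return obj.contains(pos)
        if kind == "surface":
            sid = self.surfaces.index(obj)
            # molecules bound to a panel of this surface
            return np.ones(len(pos), dtype=bool)  # refined by caller states
        raise ValueError(f"unknown region kind {kind}")

    def sample_uniform(self, n, region, rng):
        if region is None:
            pts = self.lo + rng.uniform(size=(n, 3)) * (self.hi - self.lo)
            pts[:, self.dim:] = 0.0
            return pts
        kind, obj = region
        out = np.empty((0, 3))
        tries = 0
        while len(out) < n:
            cand = self.lo + rng.uniform(size=(max(n, 64), 3)) * (self.hi - self.lo)
            cand[:, self.dim:] = 0.0
            out = np.vstack([out, cand[obj.contains(cand)]])
            tries += 1
            if tries > 1000:
                raise RuntimeError("compartment rejection sampling failed")
        return out[:n]

    def unwrapped_pos(self, idx):
        L = self.hi - self.lo
        return self.store.pos[idx] + self.store.wrap[idx] * L

    def _draw_buffer(self, n):
        """Reusable (n, 3) scratch for per-step normal draws (avoids a
        fresh large allocation every step)."""
        if getattr(self, "_normbuf", None) is None or len(self._normbuf) < n:
            self._normbuf = np.empty((int(n * 1.5) + 64, 3))
        return self._normbuf[:n]

    def _scratch(self, name, n, shape_tail=(), dtype=np.float64):
        """Named reusable per-step work arrays (allocation churn on large
        temporaries otherwise dominates stepping cost)."""
        pool = getattr(self, "_scratch_pool", None)
        if pool is None:
            pool = self._scratch_pool = {}
        arr = pool.get(name)
        if arr is None or len(arr) < n:
            arr = pool[name] = np.empty((int(n * 1.5) + 64, *shape_tail),
                                        dtype=dtype)
        return arr[:n]

    def log_event(self, name, count, reactants=None):
        self.event_counts[name] = self.event_counts.get(name, 0) + count
        serials = (self.store.serial[reactants].copy()
                   if reactants is not None else None)
        self.step_events.append((name, count, serials))

    # -- dynamics -----------------------------------------------------------
    def step(self):
        store = self.store
        store.used[: store.n] = False
        self.step_events = []
        rng = self.rng

        n_alive = store.count_alive()
        all_solution = not self.bound_channels and \
            not (store.state[: store.n] != SOLUTION).any()
        if n_alive == store.n and all_solution:
            # hot path: contiguous all-alive solution store -> in-place views
            alive = np.arange(store.n)
            sol = alive
            bound = alive[:0]
        else:
            alive = store.alive_idx()
            sol = alive[store.state[alive] == SOLUTION]
            bound = alive[store.state[alive] != SOLUTION]

        # (1) diffusion
        old = store.pos[sol].copy() if self.panels and len(sol) else None
        if len(sol) == store.n:
            _dif.diffuse_solution(store.pos[: store.n],
                                  store.species[: store.n], self.params, rng,
                                  buf=self._draw_buffer(store.n))
        elif len(sol):
            pos = store.pos[sol]
            _dif.diffuse_solution(pos, store.species[sol], self.params, rng)
            store.pos[sol] = pos
        if len(bound):
            pos = store.pos[bound]
            _dif.diffuse_surface_bound(pos, store.species[bound],
                                       store.state[bound], store.panel[bound],
                                       self.panels, self.params, rng)
            store.pos[bound] = pos

        # (2) surface interactions then system bounds
        if len(sol):
            if old is not None:
                moved = np.any(store.pos[sol] != old, axis=1)
                midx = sol[moved]
                if len(midx):
                    final = self._resolve_crossings(midx, old[moved],
                                                    store.pos[midx].copy(),
                                                    rng)
                    live = store.alive[midx] \
                        & (store.state[midx] == SOLUTION)
                    store.pos[midx[live]] = final[live]
            self._apply_bounds(sol)

        # (3) bound-state transitions (desorption competes with conversion)
        self._bound_transitions(rng)

        # (4) zeroth order
        for rxn in self.reactions:
            if rxn.order == 0:
                _rx.zeroth_order_step(self, rxn, rng)

        # (5) first order (multi-channel per reactant signature)
        for (sp, st), channels in self.first_order_groups.items():
            idx = self.store.select(sp, st, unused=True)
            _rx.first_order_step(self, channels, idx, rng)

        # (6) bimolecular + conformational spread
        for rxn in self.reactions:
            if rxn.order == 2 or rxn.placement == "conf_spread":
                _rx.bimolecular_step(self, rxn, rng)

        # (7) boxes
        if store.n and (store.n - store.count_alive()) > 0.3 * store.n:
            store.compact()
        self.assign_boxes()

        self.t += self.dt

        # (8) commands
        for cmd in self.commands:
            cmd.maybe_run(self)

    def run(self, t_stop=None):
        t_stop = self.t_stop if t_stop is None else t_stop
        for cmd in self.commands:  # commands already due at the start time
            cmd.maybe_run(self)
        n_steps = int(round((t_stop - self.t) / self.dt))
        for _ in range(n_steps):
            self.step()
        for cmd in self.commands:
            cmd.finish(self)
        return self

    def assign_boxes(self):
        store = self.store
        if store.alive[: store.n].all():
            idx = slice(0, store.n)
            pos = store.pos[: store.n]
            n = store.n
        else:
            aidx = store.alive_idx()
            idx = aidx
            pos = store.pos[aidx]
            n = len(aidx)
        if self.grid is None or (store.n == 0):
            return self
        clamp = [bt == "transparent" for bt in self.btypes]
        store.box[idx] = self.grid.assign(
            pos, periodic=self.periodic_axes(), clamp=clamp,
            fbuf=self._scratch("grid_f", n, (3,)),
            ibuf=self._scratch("grid_i", n, (3,), np.int64))
        return self

    # -- surface crossing resolution ---------------------------------------
    def _walls(self):
        """Implicit boundary planes, processed as crossing events alongside
        panels so that segments never bypass a panel by leaving the domain
        mid-flight.  Transparent axes have no wall."""
        walls = []
        for ax in range(self.dim):
            bt = self.btypes[ax]
            if bt == "transparent":
                continue
            walls.append((ax, self.lo[ax], +1.0, bt))
            walls.append((ax, self.hi[ax], -1.0, bt))
        return walls

    def _resolve_crossings(self, idx, p0, p1, rng, force_reflect=False,
                           max_iter=50):
        """Process every panel and boundary crossing along the segments
        idx: p0 -> p1.

        Returns final positions; absorbed molecules are killed and adsorbed
        molecules are bound in place (their returned position is the hit
        point).  Nearest crossing first, recursing on the residual segment;
        after ``max_iter`` bounces a molecule is clamped at the last hit,
        offset by tolerance toward its incoming side.
        """
        m = len(idx)
        seg0 = np.array(p0, dtype=float, copy=True)
        seg1 = np.array(p1, dtype=float, copy=True)
        active = np.ones(m, dtype=bool)
        eps = 1e-9 * max(self.diag, 1e-30)
        store = self.store
        walls = self._walls()
        L = self.hi - self.lo
        for it in range(max_iter):
            act = np.flatnonzero(active)
            if len(act) == 0:
                break
            a0 = seg0[act]
            a1 = seg1[act]
            best = np.full(len(act), np.inf)
            bpid = np.full(len(act), -1, dtype=int)
            bside = np.zeros(len(act), dtype=np.int8)
            # per-surface deep-interior cull -> union of candidate molecules
            consider_surface = {}
            cand_any = np.zeros(len(act), dtype=bool)
            for si, surf in enumerate(self.surfaces):
                if not surf.enabled:
                    consider_surface[si] = None
                    continue
                c, rin = self._surface_clear[si]
                if rin > 0:
                    d0 = np.einsum("ij,ij->i", a0 - c, a0 - c)
                    d1 = np.einsum("ij,ij->i", a1 - c, a1 - c)
                    consider_surface[si] = (d0 > rin * rin) | (d1 > rin * rin)
                else:
                    consider_surface[si] = np.ones(len(act), dtype=bool)
                cand_any |= consider_surface[si]
            cand = np.flatnonzero(cand_any)
            if len(cand):
                c0 = a0[cand]
                c1 = a1[cand]
                half = 0.5 * np.sqrt(
                    np.einsum("ij,ij->i", c1 - c0, c1 - c0))
                mid = 0.5 * (c0 + c1)
                # broad phase in one shot: squared distances to every
                # panel's bounding sphere via a single matrix product
                centers = self._panel_centers
                d2 = ((mid * mid).sum(axis=1)[:, None]
                      + self._panel_c2[None, :] - 2.0 * (mid @ centers.T))
                reach = (self._panel_radii[None, :] + (half + eps)[:, None])
                near_mat = d2 <= reach * reach
                for si, cons in consider_surface.items():
                    cols = self.panel_surface == si
                    if cons is None:
                        near_mat[:, cols] = False
                    elif self._surface_clear[si][1] > 0:
                        near_mat[:, cols] &= cons[cand, None]
                # triangles in one batched kernel, other shapes per panel
                if self._tri_ids is not None:
                    rows, tcols = np.nonzero(near_mat[:, self._tri_ids])
                    if len(rows):
                        self._tri_batch(c0, c1, rows, tcols, cand, best,
                                        bpid, bside)
                    near_mat[:, self._tri_ids] = False
                for pid in np.flatnonzero(near_mat.any(axis=0)):
                    panel = self.panels[pid]
                    sub = np.flatnonzero(near_mat[:, pid])
                    frac, side = panel.intersect(c0[sub], c1[sub])
                    gsub = cand[sub]
                    better = frac < best[gsub]
                    if better.any():
                        tgt = gsub[better]
                        best[tgt] = frac[better]
                        bpid[tgt] = pid
                        bside[tgt] = side[better]
            # boundary walls compete with panels for the earliest crossing
            for wi, (ax, w, inward, bt) in enumerate(walls):
                d0 = (a0[:, ax] - w) * inward
                d1 = (a1[:, ax] - w) * inward
                cross = (d0 > 0.0) & (d1 < 0.0)
                if not cross.any():
                    continue
                frac = np.where(cross, d0 / np.where(d0 == d1, 1.0, d0 - d1),
                                np.inf)
                better = frac < best
                if better.any():
                    bpid[better] = -(wi + 1)
                    best[better] = frac[better]
            hit = np.isfinite(best)
            if not hit.any():
                break
            hidx = np.flatnonzero(hit)
            q = a0[hidx] + best[hidx, None] * (a1[hidx] - a0[hidx])
            new_active = active.copy()
            new_active[act] = False  # molecules without hits are settled
            for pid in np.unique(bpid[hidx]):
                sm = bpid[hidx] == pid
                sel = hidx[sm]  # indices into the act-subarray
                qs = q[sm]
                if pid < 0:
                    ax, w, inward, bt = walls[-pid - 1]
                    ga = act[sel]
                    if bt == "reflective":
                        seg1[ga, ax] = 2.0 * w - seg1[ga, ax]
                        seg0[ga] = qs
                        seg0[ga, ax] = w + inward * eps
                        new_active[ga] = True
                    elif bt == "periodic":
                        shift = inward * L[ax]
                        store.wrap[idx[ga], ax] += int(-inward)
                        seg0[ga] = qs
                        # arrival face is the opposite one; nudge just inside
                        seg0[ga, ax] = w + shift - inward * eps
                        seg1[ga, ax] += shift
                        new_active[ga] = True
                    else:  # absorbing
                        store.kill(idx[ga])
                        self.absorbed[("bounds", "all")] = (
                            self.absorbed.get(("bounds", "all"), 0) + len(ga))
                    continue
                panel = self.panels[pid]
                surf = self.surfaces[self.panel_surface[pid]]
                ploc = self.panel_local[pid]
                normals = panel.normal_at(qs)
                self._apply_outcomes(idx, act, sel, qs, normals, bside[sel],
                                     pid, surf, ploc, seg0, seg1, new_active,
                                     eps, rng, force_reflect)
            active = new_active & store.alive[idx] \
                & (store.state[idx] == SOLUTION)
        else:
            # molecules still bouncing after max_iter: clamp near last start
            act = np.flatnonzero(active)
            seg1[act] = seg0[act]
        return seg1

    def _tri_batch(self, c0, c1, rows, tcols, cand, best, bpid, bside):
        """Vectorized segment-triangle intersection over candidate pairs.

        ``rows``/``tcols`` index the candidate molecules and the stacked
        triangle arrays; updates the per-molecule nearest crossing in place.
        """
        v0 = self._tri_v0[tcols]
        n = self._tri_n[tcols]
        p0 = c0[rows]
        p1 = c1[rows]
        d0 = np.einsum("ij,ij->i", p0 - v0, n)
        d1 = np.einsum("ij,ij->i", p1 - v0, n)
        hit = (d0 * d1) < 0.0
        if not hit.any():
            return
        rows, tcols = rows[hit], tcols[hit]
        d0, d1 = d0[hit], d1[hit]
        frac = d0 / (d0 - d1)
        q = c0[rows] + frac[:, None] * (c1[rows] - c0[rows])
        w = q - self._tri_v0[tcols]
        w1 = np.einsum("ij,ij->i", w, self._tri_e1[tcols])
        w2 = np.einsum("ij,ij->i", w, self._tri_e2[tcols])
        u = (self._tri_d22[tcols] * w1 - self._tri_d12[tcols] * w2) \
            * self._tri_invdet[tcols]
        v = (self._tri_d11[tcols] * w2 - self._tri_d12[tcols] * w1) \
            * self._tri_invdet[tcols]
        ok = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        if not ok.any():
            return
        rows, tcols, frac, d0 = rows[ok], tcols[ok], frac[ok], d0[ok]
        order = np.argsort(frac, kind="stable")
        gm = cand[rows[order]]
        first = np.unique(gm, return_index=True)[1]
        sel_g = gm[first]
        sel_f = frac[order][first]
        sel_p = self._tri_ids[tcols[order][first]]
        sel_s = np.where(d0[order][first] > 0.0, 1, -1).astype(np.int8)
        better = sel_f < best[sel_g]
        tgt = sel_g[better]
        best[tgt] = sel_f[better]
        bpid[tgt] = sel_p[better]
        bside[tgt] = sel_s[better]

    def _apply_outcomes(self, idx, act, sel, q, normals, sides, pid, surf,
                        ploc, seg0, seg1, new_active, eps, rng,
                        force_reflect):
        """Apply per-(species, side) outcomes for the molecules ``sel``
        (indices into the current active subarray) hitting panel ``pid``."""
        store = self.store
        gact = np.flatnonzero(act)[sel] if act.dtype == bool else act[sel]
        gidx = idx[gact]
        species = store.species[gidx]
        for sp in np.unique(species):
            spname = self.species_names[sp]
            for side_val in (1, -1):
                gm = (species == sp) & (sides == side_val)
                if not gm.any():
                    continue
                n_g = int(gm.sum())
                sidestr = "front" if side_val > 0 else "back"
                if force_reflect:
                    outcomes = np.array(["reflected"] * n_g, dtype=object)
                else:
                    outcomes = _sc.attempt_surface_interaction(
                        surf, spname, sidestr, n_g, rng, panel_local=ploc,
                        species_D=self.params.diff_coef[sp, SOLUTION],
                        dt=self.dt)
                ga = gact[gm]
                gi = gidx[gm]
                qq = q[gm]
                nn = normals[gm]
                sv = float(side_val)
                for oc in np.unique(outcomes):
                    om = outcomes == oc
                    a = ga[om]
                    i = gi[om]
                    qs = qq[om]
                    ns = nn[om]
                    if oc == "reflected":
                        seg1[a] = _geo.reflect_endpoints(qs, seg1[a], ns)
                        seg0[a] = qs + sv * eps * ns
                        new_active[a] = True
                    elif oc == "transmitted":
                        seg0[a] = qs - sv * eps * ns
                        new_active[a] = True
                    elif oc == "absorbed":
                        store.kill(i)
                        key = (surf.name, self.species_names[sp])
                        self.absorbed[key] = self.absorbed.get(key, 0) + len(i)
                    elif oc == "adsorbed":
                        st = surf.adsorb_state.get(
                            (self.species_names[sp], "front" if sv > 0 else "back"),
                            FRONT if sv > 0 else BACK)
                        store.pos[i] = qs
                        store.state[i] = st
                        store.panel[i] = pid
                        store.used[i] = True
                    elif oc == "jumped":
                        partner_pid = self._jump_partner_pid(surf, pid)
                        partner = self.panels[partner_pid]
                        shift = partner.ref_point() - self.panels[pid].ref_point()
                        res = seg1[a] - qs
                        seg0[a] = qs + shift + 1e-9 * res
                        seg1[a] = qs + shift + res
                        new_active[a] = True

    def _jump_partner_pid(self, surf, pid):
        pname = self.panels[pid].name
        partner_name = surf.jump_partner.get(pname)
        if partner_name is None:
            raise ValueError(
                f"panel {pname} of surface {surf.name} has a jump rule but "
                "no jump partner")
        for j, p in enumerate(self.panels):
            if p.name == partner_name:
                return j
        raise ValueError(f"jump partner panel {partner_name} not found")

    # -- system bounds ------------------------------------------------------
    def _apply_bounds(self, idx):
        store = self.store
        if len(idx) == store.n:
            pos = store.pos[: store.n]  # view, no gather copy
        else:
            pos = store.pos[idx]
        L = self.hi - self.lo
        # one combined pass finds the (typically few) boundary violators
        d = self.dim
        b1 = self._scratch("bnd1", len(pos), (3,), np.bool_)[:, :d]
        b2 = self._scratch("bnd2", len(pos), (3,), np.bool_)[:, :d]
        np.less(pos[:, :d], self.lo[:d], out=b1)
        np.greater(pos[:, :d], self.hi[:d], out=b2)
        np.logical_or(b1, b2, out=b1)
        out = b1.any(axis=1)
        if not out.any():
            return
        oidx = idx[out]
        opos = store.pos[oidx]
        kill = np.zeros(len(oidx), dtype=bool)
        for ax in range(self.dim):
            bt = self.btypes[ax]
            x = opos[:, ax]
            if bt == "reflective":
                y = np.mod(x - self.lo[ax], 2.0 * L[ax])
                opos[:, ax] = self.lo[ax] + np.minimum(y, 2.0 * L[ax] - y)
            elif bt == "periodic":
                w = np.floor((x - self.lo[ax]) / L[ax]).astype(np.int64)
                opos[:, ax] = x - w * L[ax]
                store.wrap[oidx, ax] += w
            elif bt == "absorbing":
                kill |= (x < self.lo[ax]) | (x > self.hi[ax])
            # transparent: leave untouched
        store.pos[oidx] = opos
        if kill.any():
            store.kill(oidx[kill])
            self.absorbed[("bounds", "all")] = (
                self.absorbed.get(("bounds", "all"), 0) + int(kill.sum()))

    # -- bound-state transitions --------------------------------------------
    def _bound_transitions(self, rng):
        store = self.store
        for (si, sp, st), channels in self.bound_channels.items():
            alive = store.alive_idx()
            m = (store.species[alive] == sp) & (store.state[alive] == st) \
                & ~store.used[alive]
            cand = alive[m]
            if len(cand) == 0:
                continue
            onsurf = self.panel_surface[store.panel[cand]] == si
            cand = cand[onsurf]
            if len(cand) == 0:
                continue
            ks = np.array([ch[2] for ch in channels])
            k_tot = ks.sum()
            if k_tot <= 0:
                continue
            p = 1.0 - math.exp(-k_tot * self.dt)
            u = rng.uniform(size=len(cand))
            hit = u < p
            if not hit.any():
                continue
            which = rng.choice(len(channels), size=int(hit.sum()), p=ks / k_tot)
            hidx = cand[hit]
            for ci, ch in enumerate(channels):
                sel = hidx[which == ci]
                if len(sel) == 0:
                    continue
                if ch[0] == "desorb":
                    self._desorb(sel, sp, reversible=ch[1], rng=rng)
                else:  # ("convert", to_state, rate)
                    store.state[sel] = ch[1]
                    store.used[sel] = True

    def _desorb(self, sel, sp, reversible, rng):
        store = self.store
        D = self.params.diff_coef[sp, SOLUTION]
        offsets, survived = _sc.sample_desorption_offsets(
            len(sel), D, self.dt, reversible, rng)
        out = sel[survived]
        if len(out) == 0:
            return
        pids = store.panel[out]
        normals = np.empty((len(out), 3))
        for pid in np.unique(pids):
            m = pids == pid
            normals[m] = self.panels[pid].normal_at(store.pos[out][m])
        signs = np.array([float(STATE_SIDE[int(s)]) for s in store.state[out]])
        store.pos[out] = store.pos[out] + (signs * offsets)[:, None] * normals
        store.state[out] = SOLUTION
        store.panel[out] = -1
        store.used[out] = True
        self._apply_bounds(out)

    # -- placement post-processing ------------------------------------------
    def resolve_placement(self, from_pos, to_pos):
        """Product-placement displacements obey surfaces (reflecting) and the
        system bounds; returns corrected positions."""
        to_pos = np.asarray(to_pos, dtype=float)
        if self.panels:
            # reflect placement displacements off any panel they would cross
            seg0 = np.asarray(from_pos, dtype=float).copy()
            seg1 = to_pos.copy()
            to_pos = self._resolve_placement_segments(seg0, seg1)
        L = self.hi - self.lo
        for ax in range(self.dim):
            bt = self.btypes[ax]
            x = to_pos[:, ax]
            if bt == "periodic":
                to_pos[:, ax] = self.lo[ax] + np.mod(x - self.lo[ax], L[ax])
            else:
                y = np.mod(x - self.lo[ax], 2.0 * L[ax])
                to_pos[:, ax] = self.lo[ax] + np.minimum(y, 2.0 * L[ax] - y)
        return to_pos

    def _resolve_placement_segments(self, seg0, seg1, max_iter=10):
        eps = 1e-9 * max(self.diag, 1e-30)
        active = np.ones(len(seg0), dtype=bool)
        for _ in range(max_iter):
            act = np.flatnonzero(active)
            if len(act) == 0:
                break
            a0, a1 = seg0[act], seg1[act]
            best = np.full(len(act), np.inf)
            bpid = np.full(len(act), -1, dtype=int)
            bside = np.zeros(len(act), dtype=np.int8)
            half = 0.5 * np.linalg.norm(a1 - a0, axis=1)
            mid = 0.5 * (a0 + a1)
            for pid, panel in enumerate(self.panels):
                if not self.surfaces[self.panel_surface[pid]].enabled:
                    continue
                c, r = self._panel_bs[pid]
                near = np.linalg.norm(mid - c, axis=1) <= r + half + eps
                if not near.any():
                    continue
                sub = np.flatnonzero(near)
                frac, side = panel.intersect(a0[sub], a1[sub])
                better = frac < best[sub]
                tgt = sub[better]
                best[tgt] = frac[better]
                bpid[tgt] = pid
                bside[tgt] = side[better]
            hit = np.isfinite(best)
            active[:] = False
            if not hit.any():
                break
            h = np.flatnonzero(hit)
            q = a0[h] + best[h, None] * (a1[h] - a0[h])
            for pid in np.unique(bpid[h]):
                panel = self.panels[pid]
                m = bpid[h] == pid
                g = act[h[m]]
                qs = q[m]
                ns = panel.normal_at(qs)
                seg1[g] = _geo.reflect_endpoints(qs, seg1[g], ns)
                seg0[g] = qs + (bside[h[m]].astype(float) * eps)[:, None] * ns
                active[g] = True
        return seg1


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def init_sim(config, seed: int) -> SimState:
    """Build a ready-to-run :class:`SimState` from a parsed config.

    Computes every derived step parameter (binding radii from rate constants,
    per-step probabilities, adsorption probabilities, emitter absorption
    tables), places the initial molecules, and seeds the single RNG stream so
    runs are bit-reproducible for a given seed.
    """
    sim = SimState()
    sim.dim = config.dim
    sim.dt = config.dt
    sim.t = config.t_start
    sim.t_stop = config.t_stop
    sim.lo = config.lo.copy()
    sim.hi = config.hi.copy()
    sim.btypes = list(config.btypes)
    sim.seed = int(seed)
    sim.rng = np.random.default_rng(int(seed))
    sim.species_names = list(config.species)
    sim.species_index = {n: i for i, n in enumerate(sim.species_names)}

    ns = len(sim.species_names)
    params = _dif.DiffusionStepParams(ns, len(STATE_NAMES), sim.dt, sim.dim)
    for (sp, st), D in config.diff_coefs.items():
        params.set_diff_coef(sim.species_index[sp], STATE_INDEX[st], D)
    for sp, v in config.drifts.items():
        params.set_drift(sim.species_index[sp], v)
    for sp, tensor in config.tensors.items():
        spi = sim.species_index[sp]
        params.set_tensor(spi, tensor)
        params.sigma[spi, SOLUTION] = 0.0  # tensor supersedes isotropic step
    sim.params = params

    # surfaces
    sim.surfaces = config.surfaces
    pid = 0
    panel_surface = []
    panel_local = []
    for si, surf in enumerate(sim.surfaces):
        for li, p in enumerate(surf.panels):
            sim.panels.append(p)
            panel_surface.append(si)
            panel_local.append(li)
            pid += 1
    sim.panel_surface = np.asarray(panel_surface, dtype=int)
    sim.panel_local = np.asarray(panel_local, dtype=int)
    sim._panel_bs = [p.bounding_sphere() for p in sim.panels]
    if sim.panels:
        sim._panel_centers = np.array([c for c, _ in sim._panel_bs])
        sim._panel_radii = np.array([r for _, r in sim._panel_bs])
        sim._panel_c2 = (sim._panel_centers ** 2).sum(axis=1)
    tri_ids = [i for i, p in enumerate(sim.panels)
               if isinstance(p, _geo.Triangle)]
    if len(tri_ids) >= 8:  # batching pays off for triangle meshes
        sim._tri_ids = np.array(tri_ids)
        tris = [sim.panels[i] for i in tri_ids]
        sim._tri_v0 = np.array([t.verts[0] for t in tris])
        sim._tri_n = np.array([t._n for t in tris])
        sim._tri_e1 = np.array([t._e1 for t in tris])
        sim._tri_e2 = np.array([t._e2 for t in tris])
        sim._tri_d11 = np.einsum("ij,ij->i", sim._tri_e1, sim._tri_e1)
        sim._tri_d12 = np.einsum("ij,ij->i", sim._tri_e1, sim._tri_e2)
        sim._tri_d22 = np.einsum("ij,ij->i", sim._tri_e2, sim._tri_e2)
        sim._tri_invdet = 1.0 / (sim._tri_d11 * sim._tri_d22
                                 - sim._tri_d12 ** 2)
    sim._surface_clear = []
    for surf in sim.surfaces:
        if len(surf.panels) >= 4:
            sim._surface_clear.append(surf.clear_radius())
        else:
            sim._surface_clear.append((np.zeros(3), 0.0))

    # derived surface probabilities
    for surf in sim.surfaces:
        for (sp, side), kappa in surf.adsorb_kappa.items():
            D = params.diff_coef[sim.species_index[sp], SOLUTION]
            if D <= 0:
                raise ValueError(
                    f"species {sp} adsorbs at surface {surf.name} but has "
                    "zero solution diffusion coefficient")
            surf.adsorb_prob[(sp, side)] = _sc.adsorption_probability(
                kappa, D, sim.dt)
        for (sp, side), kperm in surf.permeability.items():
            D = params.diff_coef[sim.species_index[sp], SOLUTION]
            surf.perm_prob[(sp, side)] = _sc.permeability_probability(
                kperm, D, sim.dt)
        for sp in surf.emitters:
            D = params.diff_coef[sim.species_index[sp], SOLUTION]
            surf.emit_absorb_prob[sp] = _sc.emitter_absorption(
                surf, sp, D, sim.dt)

    # compartments
    sim.compartments = {c.name: c for c in config.compartments}

    # reactions and derived parameters
    sim.reactions = list(config.reactions)
    max_sigma = 0.0
    order2 = {r.name: r for r in sim.reactions if r.order == 2
              and r.placement != "conf_spread"}
    for rxn in sim.reactions:
        p = _rx.ReactionStepParams()
        if rxn.order == 0:
            p.lam = rxn.rate * sim.volume() * sim.dt
        elif rxn.order == 1 or rxn.placement == "conf_spread":
            p.prob = 1.0 - math.exp(-rxn.rate * sim.dt)
        if rxn.order == 2 and rxn.placement != "conf_spread":
            Da = params.diff_coef[rxn.reactants[0][0], rxn.reactants[0][1]]
            Db = params.diff_coef[rxn.reactants[1][0], rxn.reactants[1][1]]
            D_mut = Da + Db
            if D_mut <= 0:
                raise ValueError(
                    f"reaction {rxn.name}: both reactants immobile; "
                    "bimolecular capture needs D_A + D_B > 0")
            p.binding_radius = _rx.binding_radius_from_rate(
                rxn.rate, D_mut, sim.dt, dim=sim.dim)
            p.bounce_sep = rxn.bounce_factor * p.binding_radius
            p.D_reactants = (Da, Db)
            max_sigma = max(max_sigma, p.binding_radius)
        sim.step_params[rxn.name] = p
    # unbinding radii (need forward binding radii first)
    for rxn in sim.reactions:
        p = sim.step_params[rxn.name]
        if rxn.unbinding_radius is not None:
            p.unbinding_radius = rxn.unbinding_radius
        elif len(rxn.products) >= 2 and rxn.placement in ("default",
                                                          "unbinding_radius"):
            # products that can re-react get the default separation
            prods = {(s, t) for s, t in rxn.products[:2]}
            for other in order2.values():
                if {(s, t) for s, t in other.reactants} == prods:
                    pg = rxn.pgemmax if rxn.pgemmax is not None else 0.2
                    p.unbinding_radius = _rx.unbinding_radius_from_pgem(
                        sim.step_params[other.name].binding_radius, pg)
                    if rxn.placement == "default":
                        rxn.placement = "unbinding_radius"
                    break
    for rxn in sim.reactions:
        if rxn.placement == "unbinding_radius" \
                and sim.step_params[rxn.name].unbinding_radius == 0.0:
            raise ValueError(
                f"reaction {rxn.name}: unbinding-radius placement needs "
                "an unbinding radius (set one or declare the reverse "
                "reaction)")

    # first-order channel groups
    for rxn in sim.reactions:
        if rxn.order == 1 and rxn.placement != "conf_spread":
            key = tuple(rxn.reactants[0])
            sim.first_order_groups.setdefault(key, []).append((rxn, rxn.rate))

    # bound-state transition channels
    for si, surf in enumerate(sim.surfaces):
        chans: dict = {}
        for (sp, st), rate in surf.desorb_rate.items():
            rev = surf.desorb_reversible.get((sp, st), False)
            key = (si, sim.species_index[sp], STATE_INDEX[st])
            chans.setdefault(key, []).append(("desorb", rev, rate))
        for (sp, st), conv in surf.conversion.items():
            key = (si, sim.species_index[sp], STATE_INDEX[st])
            for (to_state, rate) in conv:
                chans.setdefault(key, []).append(
                    ("convert", STATE_INDEX[to_state], rate))
        sim.bound_channels.update(chans)

    # box grid (cell edge >= largest binding radius)
    sim.grid = BoxGrid(sim.lo, sim.hi, min_edge=max_sigma, dim=sim.dim)

    # initial molecules
    for placement in config.placements:
        kind = placement[0]
        if kind == "uniform":
            _, count, sp, region = placement
            pos = sim.sample_uniform(count, region, sim.rng)
            sim.store.add(count, sim.species_index[sp], SOLUTION, pos)
        elif kind == "point":
            _, count, sp, pt = placement
            pos = np.tile(np.pad(np.asarray(pt, dtype=float),
                                 (0, 3 - len(pt))), (count, 1))
            sim.store.add(count, sim.species_index[sp], SOLUTION, pos)
        elif kind == "surface":
            _, count, sp, st, surf_name = placement
            surf = next(s for s in sim.surfaces if s.name == surf_name)
            areas = np.array([p.area() for p in surf.panels])
            probs = areas / areas.sum()
            counts = sim.rng.multinomial(count, probs)
            base_pid = int(np.flatnonzero(
                [sim.panels[j] is surf.panels[0] for j in range(len(sim.panels))]
            )[0])
            for li, (p, c) in enumerate(zip(surf.panels, counts)):
                if c == 0:
                    continue
                pts = p.sample_points(int(c), sim.rng)
                sim.store.add(int(c), sim.species_index[sp], STATE_INDEX[st],
                              pts, panel=base_pid + li)

    # commands
    from .commands import compile_commands
    sim.commands = compile_commands(config, sim)

    sim.assign_boxes()
    return sim


def step(sim: SimState) -> SimState:
    """Advance one time step (functional alias for :meth:`SimState.step`)."""
    sim.step()
    return sim


def assign_boxes(sim: SimState) -> SimState:
    return sim.assign_boxes()
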